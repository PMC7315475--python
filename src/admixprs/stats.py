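"""Ancestry regression and the random-SNP-set permutation null.

Two inference tools sit here.  First, the simple linear model

    PRS_i = alpha + beta * x_i + eps_i

regressing individual scores on one continental ancestry fraction, fit by
ordinary least squares (closed form: beta = cov(x, y)/var(x)); the fit
reports slope, standard error, r², t statistic and a two-tailed P from the
t distribution with n - 2 degrees of freedom.

Second, a permutation null for the between-population score difference:
random SNP sets of the trait-set size are drawn uniformly without
replacement from a genome-wide catalog (independently across draws,
500,000 by default) and the count-scale ΔPRS of each is recorded.  If
risk-allele frequencies carried no systematic between-population structure
beyond that of arbitrary catalog SNPs, the observed ΔPRS would be an
ordinary draw from this distribution; the empirical tail probability
quantifies how unusual it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._sampling import sample_index_sets
from .containers import GenotypeMatrix
from .prs import per_snp_count_deltas


@dataclass
class RegressionFit:
    """OLS fit of PRS on one ancestry fraction."""

    alpha: float
    beta: float
    se_beta: float
    r2: float
    t_stat: float
    p_two_tailed: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(x, dtype=float)


def fit_ols(prs_values: Sequence[float], ancestry_fractions: Sequence[float]) -> RegressionFit:
    """Closed-form simple OLS of ``prs_values`` on ``ancestry_fractions``.

    Requires n >= 3 and non-degenerate x.  P is two-tailed from t with
    n - 2 df; for an exact fit (zero residual) se is 0 and P is 0.
    """
    y = np.asarray(prs_values, dtype=float)
    x = np.asarray(ancestry_fractions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate ancestry fractions: all values equal")
    if np.ptp(y) == 0.0:
        # constant response: zero slope, nothing explained, nothing to test
        return RegressionFit(
            alpha=float(y[0]), beta=0.0, se_beta=0.0, r2=0.0,
            t_stat=0.0, p_two_tailed=1.0, n=n,
        )
    res = sp_stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    return RegressionFit(
        alpha=float(res.intercept),
        beta=float(res.slope),
        se_beta=float(res.stderr),
        r2=r2,
        t_stat=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        p_two_tailed=float(res.pvalue),
        n=n,
    )


class AncestryRegression:
    """Estimator form of the PRS-on-ancestry OLS.

    ``component`` picks the ancestry fraction (``"African"``,
    ``"European"`` or ``"NativeAmerican"``) when X is a profile frame;
    a plain 1-D array is used as-is.  After :meth:`fit`: ``coef_``,
    ``intercept_``, ``fit_`` (the full :class:`RegressionFit`).
    """

    def __init__(self, component: str = "African") -> None:
        self.component = component

    def get_params(self, deep: bool = True) -> dict:
        return {"component": self.component}

    def set_params(self, **params) -> "AncestryRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _column(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            col = f"f_{self.component}"
            if col not in X.columns:
                raise ValueError(f"profile frame lacks column {col!r}")
            return X[col].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        return arr

    def fit(self, X, y) -> "AncestryRegression":
        self.fit_ = fit_ols(np.asarray(y, dtype=float), self._column(X))
        self.coef_ = np.array([self.fit_.beta])
        self.intercept_ = self.fit_.alpha
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ValueError("AncestryRegression is not fitted")
        return self.fit_.predict(self._column(X))

    def score(self, X, y) -> float:
        """Coefficient of determination on (X, y), sklearn-style."""
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        total = y - y.mean()
        denom = float(total @ total)
        return 1.0 - float(resid @ resid) / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Resampled ΔPRS values with summary moments.

    ``provenance`` records how the sets were drawn: plain uniform
    permutation of catalog SNPs, or frequency-matched resampling.
    """

    samples: np.ndarray
    n_draws: int
    mean: float
    sd: float
    seed: int | None
    provenance: str  # "permutation" | "daf_matched"
    scale: str = "count"

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        seed: int | None,
        provenance: str,
        scale: str = "count",
    ) -> "NullDistribution":
        samples = np.asarray(samples, dtype=float)
        return cls(
            samples=samples,
            n_draws=samples.size,
            mean=float(samples.mean()),
            sd=float(samples.std(ddof=0)),
            seed=seed,
            provenance=provenance,
            scale=scale,
        )


def permutation_null(
    catalog_matrix: GenotypeMatrix,
    catalog_associations,
    set_size: int,
    pop_a,
    pop_b,
    n_draws: int = 500_000,
    seed: int | None = None,
) -> NullDistribution:
    """Null ΔPRS from uniform random catalog SNP sets.

    Each draw samples ``set_size`` catalog SNPs without replacement
    (independently across draws) and records the count-scale ΔPRS of the
    set between the two cohorts, computed with each catalog SNP's own
    effect allele.  ``pop_a``/``pop_b`` are individual-id lists or boolean
    masks over the matrix rows.
    """
    from .prs import orient_dosages  # local to avoid cycle at import time

    oriented = orient_dosages(catalog_matrix, catalog_associations)
    mask_a = catalog_matrix.individual_mask(pop_a)
    mask_b = catalog_matrix.individual_mask(pop_b)
    deltas = per_snp_count_deltas(oriented.dosages, mask_a, mask_b)
    if set_size > deltas.size:
        raise ValueError(
            f"set_size {set_size} exceeds catalog size {deltas.size}"
        )
    rng = np.random.default_rng(seed)
    sets = sample_index_sets(rng, deltas.size, set_size, n_draws)
    samples = deltas[sets].sum(axis=1)
    return NullDistribution.from_samples(samples, seed, "permutation")


def empirical_p(
    observed: float, null: NullDistribution, alternative: str = "observed"
) -> float:
    """One-tailed empirical P of ``observed`` against the null samples.

    P = (r + 1) / (n + 1) with r the number of null samples at least as
    extreme as the observation in the tested direction.  ``alternative``
    is ``"greater"``, ``"less"``, or ``"observed"`` (direction of the
    observation relative to the null mean — anti-conservative under the
    null, since the tail is chosen after seeing the data; prefer a fixed
    direction when the hypothesis is directional).
    """
    s = null.samples
    if s.size == 0:
        raise ValueError("null distribution has no samples")
    if alternative == "observed":
        alternative = "greater" if observed >= null.mean else "less"
    if alternative == "greater":
        r = int(np.sum(s >= observed))
    elif alternative == "less":
        r = int(np.sum(s <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (r + 1) / (s.size + 1)


class PermutationNull:
    """Estimator form of :func:`permutation_null`.

    fit(X, y): X is the catalog :class:`GenotypeMatrix`; y a per-individual
    cohort-label array.  ``pop_a``/``pop_b`` name the two labels compared
    (defaults: first two labels in sorted order).  After fit: ``null_``,
    ``mean_``, ``sd_``.
    """

    def __init__(
        self,
        catalog_associations=None,
        set_size: int = 165,
        n_draws: int = 500_000,
        pop_a: str | None = None,
        pop_b: str | None = None,
        random_state: int | None = None,
    ) -> None:
        self.catalog_associations = catalog_associations
        self.set_size = set_size
        self.n_draws = n_draws
        self.pop_a = pop_a
        self.pop_b = pop_b
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "catalog_associations": self.catalog_associations,
            "set_size": self.set_size,
            "n_draws": self.n_draws,
            "pop_a": self.pop_a,
            "pop_b": self.pop_b,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "PermutationNull":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: GenotypeMatrix, y) -> "PermutationNull":
        labels = np.asarray(y)
        uniq = sorted(set(labels.tolist()))
        pop_a = self.pop_a if self.pop_a is not None else uniq[0]
        pop_b = self.pop_b if self.pop_b is not None else uniq[1]
        self.null_ = permutation_null(
            X,
            self.catalog_associations,
            self.set_size,
            labels == pop_a,
            labels == pop_b,
            n_draws=self.n_draws,
            seed=self.random_state,
        )
        self.mean_ = self.null_.mean
        self.sd_ = self.null_.sd
        return self
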