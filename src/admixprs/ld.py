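"""Windowed pairwise-r² pruning of SNP sets.

r² here is the squared Pearson correlation of genotype dosage vectors
(composite-genotype LD), computed on individuals with calls at both SNPs —
the natural statistic for unphased hard calls, as opposed to haplotype r².
Pruning is the greedy windowed procedure: within a sliding window of
``window_size`` SNPs (default 2000, stepping by half a window), whenever a
retained pair exceeds the r² threshold (default 0.1) the member with the
lower minor-allele frequency is removed, ties removing the later-position
SNP.  The scan restarts after each removal, so the retained set is the
deterministic fixed point "no remaining in-window pair exceeds the
threshold".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger("admixprs")


@dataclass
class PruneConfig:
    window_size: int = 2000
    r2_threshold: float = 0.1
    window_step: int | None = None  # default: half the window

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold outside (0, 1]")
        if self.window_step is None:
            self.window_step = max(1, self.window_size // 2)
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Computed over individuals called at both SNPs.  A monomorphic SNP
    (zero variance among complete pairs) gives 0.0; fewer than two complete
    pairs gives None (pair skipped upstream, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        logger.warning("pairwise_r2: fewer than 2 complete pairs; undefined")
        return None
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0  # monomorphic: LD undefined, treated as absent
    c = np.corrcoef(xs, ys)[0, 1]
    return float(c * c)


def _minor_allele_freq(col: np.ndarray) -> float:
    called = col != MISSING
    if not called.any():
        return 0.0
    af = col[called].mean() / 2.0
    return float(min(af, 1.0 - af))


def prune(
    matrix: GenotypeMatrix,
    snp_ids: Sequence[str] | None = None,
    config: PruneConfig | None = None,
) -> list[str]:
    """Greedy windowed r² pruning; returns retained SNP ids.

    ``snp_ids`` restricts pruning to a subset (e.g. a trait set); SNPs are
    sorted by (chrom, pos) and windows never span chromosomes.  Output is
    deterministic and invariant to input order.
    """
    config = config or PruneConfig()
    snps = matrix.snps
    if snp_ids is not None:
        keep = set(snp_ids)
        idx = [j for j, i in enumerate(snps["id"]) if i in keep]
    else:
        idx = list(range(len(snps)))
    order = sorted(
        idx, key=lambda j: (str(snps["chrom"].iloc[j]), int(snps["pos"].iloc[j]))
    )
    retained_all: list[str] = []
    chroms = snps["chrom"].astype(str)
    for chrom in dict.fromkeys(chroms.iloc[j] for j in order):
        cols = [j for j in order if chroms.iloc[j] == chrom]
        retained_all.extend(_prune_chrom(matrix, cols, config))
    # report in original table order
    keep_set = set(retained_all)
    return [i for i in snps["id"] if i in keep_set]


def _prune_chrom(
    matrix: GenotypeMatrix, cols: list[int], config: PruneConfig
) -> list[str]:
    n = len(cols)
    alive = {j: True for j in cols}
    maf = {j: _minor_allele_freq(matrix.dosages[:, j]) for j in cols}
    pos = {j: int(matrix.snps["pos"].iloc[j]) for j in cols}
    r2_cache: dict[tuple[int, int], float | None] = {}

    def r2(a: int, b: int) -> float | None:
        key = (a, b) if a < b else (b, a)
        if key not in r2_cache:
            r2_cache[key] = pairwise_r2(
                matrix.dosages[:, key[0]], matrix.dosages[:, key[1]]
            )
        return r2_cache[key]

    start = 0
    while True:
        window = [j for j in cols[start : start + config.window_size] if alive[j]]
        changed = True
        while changed:
            changed = False
            for a_i in range(len(window)):
                for b_i in range(a_i + 1, len(window)):
                    a, b = window[a_i], window[b_i]
                    r = r2(a, b)
                    if r is None or r <= config.r2_threshold:
                        continue
                    # drop the lower-MAF member; tie -> later position
                    if maf[a] < maf[b]:
                        drop = a
                    elif maf[b] < maf[a]:
                        drop = b
                    else:
                        drop = a if pos[a] > pos[b] else b
                    alive[drop] = False
                    window.remove(drop)
                    changed = True
                    break
                if changed:
                    break
        if start + config.window_size >= n:
            break
        start += config.window_step
    return [str(matrix.snps["id"].iloc[j]) for j in cols if alive[j]]


class LDPruner:
    """Feature-selection-style estimator over :func:`prune`.

    Attributes (after :meth:`fit`): ``retained_ids_`` and ``support_``
    (boolean mask over the fitted matrix's SNP columns).
    """

    def __init__(
        self,
        window_size: int = 2000,
        r2_threshold: float = 0.1,
        window_step: int | None = None,
    ) -> None:
        self.window_size = window_size
        self.r2_threshold = r2_threshold
        self.window_step = window_step

    def get_params(self, deep: bool = True) -> dict:
        return {
            "window_size": self.window_size,
            "r2_threshold": self.r2_threshold,
            "window_step": self.window_step,
        }

    def set_params(self, **params) -> "LDPruner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: GenotypeMatrix, y=None, snp_ids: Sequence[str] | None = None) -> "LDPruner":
        cfg = PruneConfig(self.window_size, self.r2_threshold, self.window_step)
        self.retained_ids_ = prune(X, snp_ids=snp_ids, config=cfg)
        retained = set(self.retained_ids_)
        self.support_ = np.array([i in retained for i in X.snps["id"]])
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "retained_ids_"):
            raise ValueError("LDPruner is not fitted")
        return X.subset_snps(self.retained_ids_)

    def fit_transform(self, X: GenotypeMatrix, y=None, **fit_params) -> GenotypeMatrix:
        return self.fit(X, y, **fit_params).transform(X)
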