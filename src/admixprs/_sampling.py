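"""Vectorized uniform sampling of many index sets without replacement.

Both null-building stages draw thousands of SNP sets; drawing each set with
``Generator.choice(..., replace=False)`` in a Python loop dominates runtime,
so sets are drawn in bulk: rows of candidate indices are sampled with
replacement and rows containing duplicates are redrawn until none remain.
Rejection over whole rows leaves every duplicate-free ordered tuple equally
likely, hence every k-subset equally likely — identical in law to repeated
``choice(..., replace=False)``.  For dense draws (k > pool/2) an
argpartition-of-uniforms route is used instead.
"""

from __future__ import annotations

import numpy as np


def _rows_with_duplicates(idx: np.ndarray) -> np.ndarray:
    if idx.shape[1] < 2:
        return np.array([], dtype=np.intp)
    s = np.sort(idx, axis=1)
    dup = (s[:, 1:] == s[:, :-1]).any(axis=1)
    return np.where(dup)[0]


def sample_index_sets(
    rng: np.random.Generator, pool_size: int, set_size: int, n_sets: int
) -> np.ndarray:
    """Draw ``n_sets`` uniform ``set_size``-subsets of ``range(pool_size)``.

    Within a row indices are distinct (without replacement); rows are
    independent (with replacement across sets).  Returns an (n_sets,
    set_size) integer array; row order within a set is arbitrary.
    """
    if set_size > pool_size:
        raise ValueError(f"set_size {set_size} exceeds pool size {pool_size}")
    if set_size == pool_size:
        return np.tile(np.arange(pool_size, dtype=np.intp), (n_sets, 1))
    if set_size > pool_size // 2:
        u = rng.random((n_sets, pool_size))
        return np.argpartition(u, set_size, axis=1)[:, :set_size].astype(np.intp)
    out = rng.integers(0, pool_size, size=(n_sets, set_size), dtype=np.intp)
    bad = _rows_with_duplicates(out)
    while bad.size:
        out[bad] = rng.integers(0, pool_size, size=(bad.size, set_size), dtype=np.intp)
        bad = bad[_rows_with_duplicates(out[bad])]
    return out
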