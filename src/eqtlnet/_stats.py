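"""Small shared statistical primitives used across the pipeline."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "pearson_pvalue", "child_rng"]

# fixed per-component offsets for master-seed expansion; stable across releases
_SEED_OFFSETS = {
    "genome": 11,
    "genotypes": 23,
    "expression": 37,
    "phenotypes": 41,
    "promoters": 53,
    "regions": 59,
    "gene_sets": 61,
    "hotspot_perm": 67,
    "overlap_perm": 71,
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component generator derived from one master seed.

    Each named pipeline component gets its own stream so that changing the
    amount of randomness consumed by one stage never perturbs another.
    """
    if component not in _SEED_OFFSETS:
        raise KeyError(f"unknown seed component {component!r}")
    return np.random.default_rng([int(seed), _SEED_OFFSETS[component]])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1. NaN p-values propagate as
    NaN (with a warning) and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any(~ok):
        warnings.warn("NaN p-values propagated through BH correction")
    if ok.sum() == 0:
        return q
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def pearson_pvalue(r, n: int) -> np.ndarray:
    """Two-sided Student asymptotic p-value for a Pearson correlation.

    Uses t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need at least 4 samples for a correlation p-value")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df)
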