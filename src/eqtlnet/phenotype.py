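"""Hotspot genotype → phenotype association by fixed-effects ANOVA.

Each hotspot anchor's genotype enters as an unordered factor (AA/AB/BB by
minor-allele count) after the fixed-effect covariates; the genotype F-test is
sequential (genotype fitted last), so its sum of squares is the drop in
residual SS from adding the genotype dummies to the covariate-only model.
BH correction is applied across the trait panel within each hotspot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .eqtl import design_matrix

__all__ = [
    "AnovaResult",
    "anova_genotype_effect",
    "fdr_across_traits",
    "adjust_phenotype",
    "associate_hotspots",
]

log = logging.getLogger(__name__)

GENOTYPE_LABELS = {0: "AA", 1: "AB", 2: "BB"}


@dataclass
class AnovaResult:
    variant_id: str
    trait: str
    f_stat: float
    p_value: float
    df_genotype: int
    df_residual: int
    q_value: float = np.nan
    exact_fit: bool = False
    dropped_levels: tuple = ()


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r), int(rank)


def anova_genotype_effect(
    trait,
    genotype,
    covariates: pd.DataFrame | None = None,
    variant_id: str = "",
    trait_name: str = "",
    min_level_n: int = 2,
) -> AnovaResult:
    """Sequential F-test for the genotype factor after covariates.

    Genotype levels observed in fewer than ``min_level_n`` samples are
    dropped (with their samples) and logged. An exact fit (zero residual SS
    in the full model) is reported with a machine-floor p-value and flagged.
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(genotype)
    levels, counts = np.unique(g, return_counts=True)
    small = [lv for lv, c in zip(levels, counts) if c < min_level_n]
    keep = ~np.isin(g, small)
    if small:
        log.warning(
            "dropping genotype levels %s with < %d observations (%d samples)",
            small, min_level_n, int((~keep).sum()),
        )
    y, g = y[keep], g[keep]
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 genotype levels with enough observations")
    if covariates is not None:
        X_cov, _ = design_matrix(covariates.iloc[np.flatnonzero(keep)])
    else:
        X_cov = np.ones((int(keep.sum()), 1))
    dummies = pd.get_dummies(pd.Series(g).astype(str), drop_first=True).to_numpy(dtype=float)
    X_full = np.column_stack([X_cov, dummies])
    sse_r, _ = _sse(X_cov, y)
    sse_f, rank_f = _sse(X_full, y)
    df_g = dummies.shape[1]
    df_res = len(y) - rank_f
    if df_res < 1:
        raise ValueError("no residual degrees of freedom for the genotype F-test")
    exact = sse_f <= 1e-12 * max(1.0, float(y @ y))
    if exact:
        f = np.inf
        p = np.nextafter(0.0, 1.0)
    else:
        f = ((sse_r - sse_f) / df_g) / (sse_f / df_res)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, df_g, df_res))
    return AnovaResult(
        variant_id=variant_id,
        trait=trait_name,
        f_stat=float(f),
        p_value=float(p),
        df_genotype=df_g,
        df_residual=df_res,
        exact_fit=bool(exact),
        dropped_levels=tuple(small),
    )


def fdr_across_traits(results: list[AnovaResult]) -> list[AnovaResult]:
    """BH q-values across one hotspot's trait panel (shared BH implementation)."""
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def adjust_phenotype(trait, covariates: pd.DataFrame) -> pd.Series:
    """Fixed-effects residualization of a trait on the covariate design.

    Samples with missing trait or covariate values are dropped (logged);
    residuals have mean ~0 by construction.
    """
    y = pd.Series(np.asarray(trait, dtype=float), index=covariates.index)
    ok = y.notna() & covariates.notna().all(axis=1)
    if (~ok).any():
        log.warning("dropping %d samples with missing trait/covariate values", int((~ok).sum()))
    cov = covariates[ok]
    X, _ = design_matrix(cov, samples=list(cov.index))
    yy = y[ok].to_numpy()
    coef, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
    return pd.Series(yy - X @ coef, index=cov.index)


def associate_hotspots(
    hotspot_anchors: list[str],
    dosage: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr_scope: str = "per_hotspot",
) -> pd.DataFrame:
    """ANOVA of every hotspot anchor against every trait.

    ``fdr_scope='per_hotspot'`` (default) applies BH across traits within
    each hotspot; ``'global'`` pools all hotspot x trait tests.
    """
    if fdr_scope not in ("per_hotspot", "global"):
        raise ValueError("fdr_scope must be 'per_hotspot' or 'global'")
    samples = list(phenotypes.index)
    rows: list[AnovaResult] = []
    for anchor in hotspot_anchors:
        geno = dosage.loc[samples, anchor].to_numpy(dtype=float)
        labels = np.array([GENOTYPE_LABELS.get(int(d), "NA") for d in np.nan_to_num(geno, nan=-1)])
        per_hotspot = []
        for trait in phenotypes.columns:
            res = anova_genotype_effect(
                phenotypes[trait].to_numpy(dtype=float),
                labels,
                covariates=covariates.loc[samples] if covariates is not None else None,
                variant_id=anchor,
                trait_name=trait,
            )
            per_hotspot.append(res)
        if fdr_scope == "per_hotspot":
            fdr_across_traits(per_hotspot)
        rows.extend(per_hotspot)
    if fdr_scope == "global":
        fdr_across_traits(rows)
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "trait": r.trait,
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "df_genotype": r.df_genotype,
                "df_residual": r.df_residual,
                "exact_fit": r.exact_fit,
            }
            for r in rows
        ]
    )
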