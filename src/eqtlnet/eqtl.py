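"""Genome-wide SNP-gene association with an additive linear model.

Every variant is tested against every gene with ordinary least squares of
expression on [intercept, dummy-coded fixed effects, age, dosage]; the
genotype enters as an additive 0/1/2 allele count. Associations are classed
cis (variant within 1 Mb of the gene span, same chromosome) or trans, and
Benjamini–Hochberg FDR is applied separately within each class.

The screening loop is blocked matrix OLS: expression and dosage are first
residualized on the covariate design, then all pairs are scored through one
correlation product. This is algebraically identical to fitting each pair's
full model (Frisch–Waugh–Lovell); the equivalence is asserted in the tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

__all__ = [
    "filter_variants",
    "design_matrix",
    "fit_additive_model",
    "classify_cis_trans",
    "gene_variant_distance",
    "inverse_normal_transform",
    "EqtlScan",
    "EqtlScanResults",
    "map_all",
]

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000  # bp; "local" variants per the 1 Mb convention
SEX_CHROMOSOMES = ("X", "Y", "chrX", "chrY")


def filter_variants(
    variant_table: pd.DataFrame,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    drop_sex_chroms: bool = True,
    sex_chromosomes=SEX_CHROMOSOMES,
    drop_unmapped: bool = True,
) -> pd.DataFrame:
    """Chip-style variant QC.

    Variants with call rate <= ``min_call_rate`` or MAF <= ``min_maf`` are
    removed (a variant exactly at the boundary is removed; strictly greater
    survives), along with sex-chromosome and unmapped variants.
    """
    vt = variant_table
    keep = (vt["call_rate"] > min_call_rate) & (vt["maf"] > min_maf)
    if drop_sex_chroms:
        keep &= ~vt["chromosome"].astype(str).isin(set(sex_chromosomes))
    if drop_unmapped:
        keep &= vt["chromosome"].notna() & (vt["chromosome"].astype(str) != "*")
        keep &= vt["position"].notna() & (vt["position"] > 0)
    out = vt[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("variant filtering removed every variant")
    return out


def design_matrix(
    covariates: pd.DataFrame | None,
    categorical=("contemporary_group", "lane"),
    numeric=("age",),
    samples=None,
):
    """Fixed-effects design [intercept | factor dummies | numeric covariates].

    Factors are dummy-coded against a reference level; collinear columns are
    dropped (and logged) so the design always has full column rank.
    Returns ``(X, column_names)``.
    """
    if covariates is None:
        n = len(samples)
        return np.ones((n, 1)), ["intercept"]
    cov = covariates.loc[samples] if samples is not None else covariates
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for factor in categorical:
        if factor not in cov.columns:
            continue
        dummies = pd.get_dummies(cov[factor].astype(str), prefix=factor, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for num in numeric:
        if num not in cov.columns:
            continue
        cols.append(cov[num].to_numpy(dtype=float))
        names.append(num)
    X = np.column_stack(cols)
    # drop collinear columns, keeping the earliest ones
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            log.warning("dropping collinear design column %s", names[j])
    return X[:, keep], [names[j] for j in keep]


def fit_additive_model(y, g, X: np.ndarray | None = None):
    """Per-pair OLS of expression on covariates plus dosage.

    Returns ``(beta, se, t_stat, p_value)`` for the dosage coefficient, with
    t = beta/se on the residual degrees of freedom and a two-sided Student p.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    if np.ptp(g) == 0:
        raise ValueError("dosage vector is constant; association undefined")
    D = np.column_stack([X, g])
    n, p = D.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} model columns")
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    df = n - rank
    sigma2 = resid @ resid / df if df > 0 else np.nan
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = float(np.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0)))
    beta = float(coef[-1])
    if se == 0.0:
        t = np.inf if beta != 0 else 0.0
    else:
        t = beta / se
    p_value = float(2.0 * stats.t.sf(abs(t), df)) if df > 0 else np.nan
    return beta, se, float(t), p_value


def gene_variant_distance(position: int, start: int, end: int) -> int:
    """bp from a variant to the nearest gene-span boundary; 0 inside the span."""
    return int(max(0, start - position, position - end))


def classify_cis_trans(
    variant_row, gene_row, window_bp: int = DEFAULT_CIS_WINDOW
) -> tuple[str, int]:
    """Classify one pair; distance to the gene span, cis iff within the window.

    A pair at exactly the window boundary is cis ("within" is inclusive);
    different chromosomes are always trans (distance reported as -1).
    """
    if variant_row["chromosome"] != gene_row["chromosome"]:
        return "trans", -1
    d = gene_variant_distance(
        int(variant_row["position"]), int(gene_row["start"]), int(gene_row["end"])
    )
    return ("cis" if d <= window_bp else "trans"), d


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets), NaN-preserving."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = ok.sum()
    ranks = stats.rankdata(x[ok])
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


@dataclass
class EqtlScanResults:
    """Full association table plus per-class FDR views."""

    records: pd.DataFrame
    fdr: float
    n_samples: int
    design_columns: list[str] = field(default_factory=list)
    dropped_variants: list[str] = field(default_factory=list)

    @property
    def cis(self) -> pd.DataFrame:
        return self.records[self.records["eqtl_class"] == "cis"]

    @property
    def trans(self) -> pd.DataFrame:
        return self.records[self.records["eqtl_class"] == "trans"]

    def significant(self, eqtl_class: str | None = None, fdr: float | None = None) -> pd.DataFrame:
        fdr = self.fdr if fdr is None else fdr
        df = self.records if eqtl_class is None else self.records[
            self.records["eqtl_class"] == eqtl_class
        ]
        return df[df["q_value"] <= fdr]

    def summary(self) -> str:
        lines = [
            "eQTL scan summary",
            "-----------------",
            f"samples:             {self.n_samples}",
            f"pairs tested:        {len(self.records)}",
            f"design columns:      {len(self.design_columns)} ({', '.join(self.design_columns)})",
            f"FDR level:           {self.fdr:g} (BH within class)",
            f"cis pairs tested:    {len(self.cis)}",
            f"trans pairs tested:  {len(self.trans)}",
            f"significant cis:     {len(self.significant('cis'))}",
            f"significant trans:   {len(self.significant('trans'))}",
        ]
        if self.dropped_variants:
            lines.append(f"dropped (constant):  {len(self.dropped_variants)}")
        return "\n".join(lines)


class EqtlScan:
    """Exhaustive variant x gene additive association scan.

    Parameters
    ----------
    expression : DataFrame, genes x samples
    dosage : DataFrame, samples x variants, values in {0,1,2} with NaN missing
        (missing dosages are mean-imputed per variant at fit time).
    variant_table, gene_table : coordinate tables (1-based inclusive spans).
    covariates : DataFrame indexed by sample, optional
        Columns ``contemporary_group`` and ``lane`` enter as fixed-effect
        factors and ``age`` as a numeric covariate when present.
    cis_window : int
        bp window around the gene span defining "local" (default 1 Mb).
    inverse_normal : bool
        Rank-inverse-normal transform each gene before testing (off by
        default; the expression scale is assumed already normalized).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        dosage: pd.DataFrame,
        variant_table: pd.DataFrame,
        gene_table: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        cis_window: int = DEFAULT_CIS_WINDOW,
        inverse_normal: bool = False,
    ) -> None:
        samples = list(expression.columns)
        missing = [s for s in samples if s not in dosage.index]
        extra = [s for s in dosage.index if s not in expression.columns]
        if missing or extra:
            raise ValueError(
                f"sample mismatch between expression and dosage; "
                f"missing from dosage: {missing[:5]}, extra in dosage: {extra[:5]}"
            )
        if covariates is not None:
            missing_cov = [s for s in samples if s not in covariates.index]
            if missing_cov:
                raise ValueError(f"samples missing from covariates: {missing_cov[:5]}")
        self.samples = samples
        self.expression = expression
        self.dosage = dosage.loc[samples]
        self.variant_table = variant_table.reset_index(drop=True)
        self.gene_table = gene_table.set_index("gene_id").loc[list(expression.index)].reset_index()
        self.covariates = covariates
        self.cis_window = int(cis_window)
        self.inverse_normal = inverse_normal

    def _distance_matrix(self):
        """(distance, is_cis) arrays of shape variants x genes; -1 = cross-chrom."""
        vpos = self.variant_table["position"].to_numpy(dtype=np.int64)[:, None]
        vchrom = self.variant_table["chromosome"].astype(str).to_numpy()[:, None]
        gstart = self.gene_table["start"].to_numpy(dtype=np.int64)[None, :]
        gend = self.gene_table["end"].to_numpy(dtype=np.int64)[None, :]
        gchrom = self.gene_table["chromosome"].astype(str).to_numpy()[None, :]
        same = vchrom == gchrom
        dist = np.maximum.reduce([gstart - vpos, vpos - gend, np.zeros_like(vpos - gend)])
        is_cis = same & (dist <= self.cis_window)
        dist = np.where(same, dist, -1)
        return dist, is_cis

    def fit(self, fdr: float = 0.05, pooled_fdr: bool = False) -> EqtlScanResults:
        """Run the scan and return the full association table.

        BH is applied separately within the cis and trans candidate classes
        unless ``pooled_fdr`` is set.
        """
        Y = self.expression.to_numpy(dtype=float)
        if self.inverse_normal:
            Y = np.apply_along_axis(inverse_normal_transform, 1, Y)
        G = self.dosage.to_numpy(dtype=float).T  # variants x samples
        # mean-impute missing dosages per variant (keeps n constant per gene)
        nan_mask = np.isnan(G)
        if nan_mask.any():
            means = np.nanmean(G, axis=1)
            G = np.where(nan_mask, means[:, None], G)
            log.info("mean-imputed %d missing dosage calls", int(nan_mask.sum()))

        variant_ids = self.variant_table["variant_id"].to_numpy()
        keep = np.ptp(G, axis=1) > 0
        dropped = [str(v) for v in variant_ids[~keep]]
        if dropped:
            log.warning("skipping %d constant variants", len(dropped))
        G = G[keep]
        vt = self.variant_table[keep].reset_index(drop=True)

        n = len(self.samples)
        X, design_columns = design_matrix(self.covariates, samples=self.samples)
        Q, _ = np.linalg.qr(X)
        rank_x = X.shape[1]
        df = n - rank_x - 1
        if df < 1:
            raise ValueError("not enough residual degrees of freedom for the scan")

        Yr = Y.T - Q @ (Q.T @ Y.T)  # samples x genes residuals
        Gr = G.T - Q @ (Q.T @ G.T)  # samples x variants residuals
        sy = np.linalg.norm(Yr, axis=0)
        sx = np.linalg.norm(Gr, axis=0)
        sy = np.where(sy == 0, np.finfo(float).tiny, sy)
        sx = np.where(sx == 0, np.finfo(float).tiny, sx)
        R = (Gr / sx).T @ (Yr / sy)  # variants x genes partial correlations
        R = np.clip(R, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = R * np.sqrt(df / np.maximum(1.0 - R * R, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        beta = R * (sy[None, :] / sx[:, None])
        se = (sy[None, :] / sx[:, None]) * np.sqrt(np.maximum(1.0 - R * R, 0.0) / df)

        # reuse the distance logic on the filtered variant table
        saved, self.variant_table = self.variant_table, vt
        try:
            dist, is_cis = self._distance_matrix()
        finally:
            self.variant_table = saved

        nv, ng = R.shape
        records = pd.DataFrame(
            {
                "variant_id": np.repeat(vt["variant_id"].to_numpy(), ng),
                "gene_id": np.tile(self.gene_table["gene_id"].to_numpy(), nv),
                "beta": beta.ravel(),
                "se": se.ravel(),
                "t_stat": t.ravel(),
                "p_value": p.ravel(),
                "eqtl_class": np.where(is_cis.ravel(), "cis", "trans"),
                "distance_bp": dist.ravel(),
            }
        )
        q = np.full(len(records), np.nan)
        if pooled_fdr:
            q = bh_fdr(records["p_value"].to_numpy())
        else:
            for cls in ("cis", "trans"):
                m = (records["eqtl_class"] == cls).to_numpy()
                if m.any():
                    q[m] = bh_fdr(records.loc[m, "p_value"].to_numpy())
        records["q_value"] = q
        return EqtlScanResults(
            records=records,
            fdr=fdr,
            n_samples=n,
            design_columns=design_columns,
            dropped_variants=dropped,
        )


def map_all(
    dosage: pd.DataFrame,
    expression: pd.DataFrame,
    gene_table: pd.DataFrame,
    variant_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
    cis_window: int = DEFAULT_CIS_WINDOW,
    pooled_fdr: bool = False,
    inverse_normal: bool = False,
) -> EqtlScanResults:
    """Functional wrapper over :class:`EqtlScan` (build, fit, return results)."""
    scan = EqtlScan(
        expression=expression,
        dosage=dosage,
        variant_table=variant_table,
        gene_table=gene_table,
        covariates=covariates,
        cis_window=cis_window,
        inverse_normal=inverse_normal,
    )
    return scan.fit(fdr=fdr, pooled_fdr=pooled_fdr)
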