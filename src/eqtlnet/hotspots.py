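"""Trans-eQTL hotspot detection.

A hotspot is a single variant associated with the expression of many genes.
The decision threshold comes from a permutation null: each significant
association is reassigned to a variant drawn uniformly (with replacement)
from all tested variants, the per-variant count of distinct target genes is
recomputed, and the per-permutation maximum is recorded; the threshold is
the ceiling of the 95th percentile of those maxima over 1000 permutations
(family-wise control of the most-hit variant). Candidates above the
threshold are then refined by linkage disequilibrium — nearby candidates in
strong LD are merged into one call — and each call gets a 4 Mb window
(2 Mb each side of the anchor).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "count_targets",
    "hotspot_threshold",
    "exact_max_count_distribution",
    "ld_r2",
    "ld_dprime",
    "refine_hotspots",
    "hotspot_window",
    "HotspotCall",
    "HotspotDetector",
    "HotspotResults",
]

HOTSPOT_HALF_WIDTH = 2_000_000  # bp each side of the anchor variant


@dataclass
class HotspotCall:
    anchor_variant: str
    n_targets: int
    threshold: int
    window: tuple[str, int, int]
    target_genes: list[str] = field(default_factory=list)
    merged_from: list[str] = field(default_factory=list)
    window_clipped: bool = False


def count_targets(significant: pd.DataFrame, scope: str = "trans") -> pd.Series:
    """Distinct associated genes per variant among significant records.

    ``scope`` restricts to trans rows (default) or keeps all classes.
    """
    if scope not in ("trans", "all"):
        raise ValueError("scope must be 'trans' or 'all'")
    df = significant
    if scope == "trans" and "eqtl_class" in df.columns:
        df = df[df["eqtl_class"] == "trans"]
    if df.empty:
        return pd.Series(dtype=int)
    return df.groupby("variant_id")["gene_id"].nunique().sort_values(ascending=False)


def _perm_stat(v_assign, gene_codes, n_variants, null):
    """Distinct-gene counts per variant for one permutation."""
    pair = v_assign.astype(np.int64) * (gene_codes.max() + 1) + gene_codes
    uniq = np.unique(pair)
    counts = np.bincount((uniq // (gene_codes.max() + 1)).astype(np.intp), minlength=n_variants)
    if null == "max":
        return counts.max()
    return counts  # pooled mode returns the full per-variant count vector


def hotspot_threshold(
    significant: pd.DataFrame,
    tested_variants,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    null: str = "max",
    scope: str = "trans",
) -> int:
    """Permutation threshold on the per-variant distinct-target count.

    ``null='max'`` (default) takes the per-permutation maximum count and
    returns ceil of its ``quantile`` percentile; ``null='pooled'`` pools the
    per-variant counts across permutations before taking the percentile.
    """
    if null not in ("max", "pooled"):
        raise ValueError("null must be 'max' or 'pooled'")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable {quantile:.0%} percentile")
    df = significant
    if scope == "trans" and "eqtl_class" in df.columns:
        df = df[df["eqtl_class"] == "trans"]
    if df.empty:
        raise ValueError("no significant associations; hotspot threshold undefined")
    gene_codes = pd.Categorical(df["gene_id"]).codes.astype(np.int64)
    n_var = len(tested_variants)
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_perm):
        v_assign = rng.integers(0, n_var, size=len(gene_codes))
        stats.append(_perm_stat(v_assign, gene_codes, n_var, null))
    if null == "max":
        draws = np.asarray(stats, dtype=float)
    else:
        draws = np.concatenate(stats).astype(float)
    return int(np.ceil(np.quantile(draws, quantile)))


def exact_max_count_distribution(gene_ids, n_variants: int, limit: int = 2_000_000):
    """Exhaustive null distribution of the max distinct-gene count.

    Enumerates all ``n_variants ** n_assoc`` equally likely reassignments of
    the given associations (identified by their gene ids) — feasible only for
    toy instances, used as the enumeration oracle for the sampled null.
    """
    gene_ids = list(gene_ids)
    n_assoc = len(gene_ids)
    if n_variants**n_assoc > limit:
        raise ValueError("instance too large for exhaustive enumeration")
    dist: dict[int, float] = {}
    total = n_variants**n_assoc
    for assign in itertools.product(range(n_variants), repeat=n_assoc):
        per_variant: dict[int, set] = {}
        for v, g in zip(assign, gene_ids):
            per_variant.setdefault(v, set()).add(g)
        m = max(len(s) for s in per_variant.values())
        dist[m] = dist.get(m, 0.0) + 1.0 / total
    return dict(sorted(dist.items()))


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of dosages."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) != len(g2):
        raise ValueError("dosage vectors must have equal length")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def _em_haplotype_freqs(g1, g2, max_iter: int = 100, tol: float = 1e-10):
    """EM haplotype frequency estimation from unphased biallelic genotypes.

    Only double heterozygotes are phase-ambiguous; the E step splits them
    between AB/ab and Ab/aB according to the current frequencies.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    table = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        table[int(a), int(b)] += 1
    n_hap = 2.0 * table.sum()
    # haplotypes: AB (alt1,alt2), Ab, aB, ab — counts of the *alt* allele
    p = np.array([0.25, 0.25, 0.25, 0.25])
    # unambiguous haplotype contributions
    base = np.zeros(4)
    base[0] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    base[1] = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    base[2] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base[3] = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    ndh = table[1, 1]
    for _ in range(max_iter):
        cis = p[0] * p[3]
        tr = p[1] * p[2]
        w = cis / (cis + tr) if (cis + tr) > 0 else 0.5
        counts = base + ndh * np.array([w, 1 - w, 1 - w, w])
        new = counts / n_hap
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p  # [p_AB, p_Ab, p_aB, p_ab]


def ld_dprime(g1, g2) -> float:
    """Normalized disequilibrium D' from EM-phased haplotype frequencies.

    D = p_AB - p_A p_B; D' = |D| / D_max with D_max = min(p_A p_b, p_a p_B)
    for D > 0, else min(p_A p_B, p_a p_b).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("D' undefined unless both variants are polymorphic")
    p = _em_haplotype_freqs(g1, g2)
    p_A = p[0] + p[1]
    p_B = p[0] + p[2]
    D = p[0] - p_A * p_B
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    if d_max == 0:
        return 0.0
    return float(min(abs(D) / d_max, 1.0))


def hotspot_window(
    chromosome: str,
    position: int,
    chrom_lengths: dict[str, int],
    half_width: int = HOTSPOT_HALF_WIDTH,
):
    """4 Mb window (2 Mb each side), clipped at the chromosome ends."""
    if chromosome not in chrom_lengths:
        raise ValueError(f"unknown chromosome length for {chromosome!r}")
    length = int(chrom_lengths[chromosome])
    start = position - half_width
    end = position + half_width
    clipped = start < 1 or end > length
    return (chromosome, max(1, start), min(length, end)), clipped


def refine_hotspots(
    counts: pd.Series,
    threshold: int,
    dosage: pd.DataFrame,
    variant_table: pd.DataFrame,
    significant: pd.DataFrame,
    chrom_lengths: dict[str, int],
    r2_merge: float = 0.5,
    scope: str = "trans",
) -> list[HotspotCall]:
    """Greedy LD merge of above-threshold candidates into hotspot calls.

    Candidates are visited by decreasing target count (ties broken by best
    association p, then position); each accepted anchor absorbs any remaining
    candidate whose dosage r^2 with it is at least ``r2_merge``. The anchor
    keeps its own target list; absorbed candidate ids are recorded in
    ``merged_from``.
    """
    cand = counts[counts >= threshold]
    if cand.empty:
        return []
    vt = variant_table.set_index("variant_id")
    sig = significant
    if scope == "trans" and "eqtl_class" in sig.columns:
        sig = sig[sig["eqtl_class"] == "trans"]
    best_p = sig.groupby("variant_id")["p_value"].min()
    order = pd.DataFrame(
        {
            "n": cand,
            "p": best_p.reindex(cand.index).fillna(1.0),
            "pos": vt["position"].reindex(cand.index),
        }
    ).sort_values(["n", "p", "pos"], ascending=[False, True, True])
    remaining = list(order.index)
    calls: list[HotspotCall] = []
    while remaining:
        anchor = remaining.pop(0)
        merged, keep = [], []
        a = dosage[anchor].to_numpy(dtype=float)
        for other in remaining:
            if ld_r2(a, dosage[other].to_numpy(dtype=float)) >= r2_merge:
                merged.append(other)
            else:
                keep.append(other)
        remaining = keep
        chrom = str(vt.loc[anchor, "chromosome"])
        pos = int(vt.loc[anchor, "position"])
        window, clipped = hotspot_window(chrom, pos, chrom_lengths)
        targets = sorted(sig.loc[sig["variant_id"] == anchor, "gene_id"].unique())
        calls.append(
            HotspotCall(
                anchor_variant=anchor,
                n_targets=int(cand.loc[anchor]),
                threshold=int(threshold),
                window=window,
                target_genes=targets,
                merged_from=merged,
                window_clipped=clipped,
            )
        )
    return calls


@dataclass
class HotspotResults:
    calls: list[HotspotCall]
    threshold: int
    counts: pd.Series
    n_perm: int
    quantile: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "anchor_variant": c.anchor_variant,
                "n_targets": c.n_targets,
                "threshold": c.threshold,
                "chromosome": c.window[0],
                "window_start": c.window[1],
                "window_end": c.window[2],
                "window_clipped": c.window_clipped,
                "n_merged": len(c.merged_from),
                "merged_from": ",".join(c.merged_from),
                "target_genes": ",".join(c.target_genes),
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "anchor_variant", "n_targets", "threshold", "chromosome",
                "window_start", "window_end", "window_clipped", "n_merged",
                "merged_from", "target_genes",
            ],
        )

    def summary(self) -> str:
        lines = [
            "Hotspot detection summary",
            "-------------------------",
            f"permutations:     {self.n_perm} (quantile {self.quantile:g})",
            f"count threshold:  >= {self.threshold} distinct genes",
            f"candidates:       {int((self.counts >= self.threshold).sum())}",
            f"refined calls:    {len(self.calls)}",
        ]
        for c in self.calls:
            lines.append(
                f"  {c.anchor_variant}  {c.window[0]}:{c.window[1]}-{c.window[2]}"
                f"  targets={c.n_targets}  merged={len(c.merged_from)}"
            )
        return "\n".join(lines)


class HotspotDetector:
    """Permutation-thresholded, LD-refined hotspot caller.

    Built from a fitted eQTL scan's significant associations plus the dosage
    matrix and variant coordinates; ``fit(seed)`` runs the permutation null
    and the greedy LD refinement.
    """

    def __init__(
        self,
        eqtl_results,
        dosage: pd.DataFrame,
        variant_table: pd.DataFrame,
        chrom_lengths: dict[str, int],
        scope: str = "trans",
        r2_merge: float = 0.5,
    ) -> None:
        self.significant = eqtl_results.significant() if hasattr(
            eqtl_results, "significant"
        ) else eqtl_results
        self.dosage = dosage
        self.variant_table = variant_table
        self.chrom_lengths = chrom_lengths
        self.scope = scope
        self.r2_merge = r2_merge

    def fit(
        self,
        n_perm: int = 1000,
        quantile: float = 0.95,
        seed: int = 0,
        null: str = "max",
    ) -> HotspotResults:
        counts = count_targets(self.significant, scope=self.scope)
        if counts.empty:
            return HotspotResults(
                calls=[], threshold=0, counts=counts, n_perm=n_perm, quantile=quantile
            )
        threshold = hotspot_threshold(
            self.significant,
            tested_variants=list(self.dosage.columns),
            n_perm=n_perm,
            quantile=quantile,
            seed=seed,
            null=null,
            scope=self.scope,
        )
        calls = refine_hotspots(
            counts,
            threshold,
            self.dosage,
            self.variant_table,
            self.significant,
            self.chrom_lengths,
            r2_merge=self.r2_merge,
            scope=self.scope,
        )
        return HotspotResults(
            calls=calls, threshold=threshold, counts=counts, n_perm=n_perm, quantile=quantile
        )
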