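"""Genotype-stratified weighted co-expression networks.

The construction follows the standard weighted-network recipe: an unsigned
adjacency a_ij = |cor(x_i, x_j)|^power (soft power 6 by default, chosen for
approximate scale-free topology), topological overlap similarity, average-
linkage clustering of the 1-TOM dissimilarity, adaptive tree cutting into
modules of at least ``min_module_size`` genes, module eigengenes (first
singular component of the standardized module expression), and merging of
modules whose eigengenes correlate above 1 - merge_height.

To compare networks built on genotype groups of different size, the smaller
group's TOM is power-scaled so that its 95th percentile matches the larger
group's. Module–trait relationships use Pearson correlation of eigengenes
with (covariate-adjusted) traits and Student asymptotic p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from ._stats import pearson_pvalue

__all__ = [
    "NetworkParams",
    "NetworkResults",
    "ModuleTraitCor",
    "CoexpressionNetwork",
    "split_by_genotype",
    "adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "tom",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "scale_tom",
    "module_trait_correlation",
    "gene_significance",
    "module_membership",
    "select_hub_genes",
    "select_trait_modules",
]

log = logging.getLogger(__name__)

GREY = "grey"  # reserved label for unassigned genes

_MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]

# deep_split -> fraction of the dendrogram height range at which the tree is
# cut; deeper split cuts lower, producing more and smaller branches
_DEEP_SPLIT_FRACTION = {0: 0.99, 1: 0.97, 2: 0.95, 3: 0.92, 4: 0.88}


@dataclass
class NetworkParams:
    soft_power: int = 6
    min_module_size: int = 30
    deep_split: int = 2
    merge_height: float = 0.25
    scale_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be a positive integer")
        if self.deep_split not in _DEEP_SPLIT_FRACTION:
            raise ValueError("deep_split must be an integer in 0..4")
        if not (0 < self.merge_height < 1):
            raise ValueError("merge_height must be in (0, 1)")
        if not (0 < self.scale_quantile < 1):
            raise ValueError("scale_quantile must be in (0, 1)")


def split_by_genotype(anchor_dosage: pd.Series, min_group: int = 15):
    """Partition samples into homozygous (AA) and heterozygous (AB) groups.

    Minor-allele homozygotes (dosage 2) are excluded — they are typically too
    few to support a network — with the count logged.
    """
    d = anchor_dosage.dropna()
    aa = list(d.index[d == 0])
    ab = list(d.index[d == 1])
    n_excluded = int((d == 2).sum())
    if not aa or not ab:
        raise ValueError("anchor variant is monomorphic across AA/AB classes")
    if n_excluded:
        log.info("excluding %d minor-allele homozygotes from network comparison", n_excluded)
    for name, grp in (("AA", aa), ("AB", ab)):
        if len(grp) < min_group:
            log.warning("genotype group %s has only %d samples; results flagged unstable",
                        name, len(grp))
    return {"AA": aa, "AB": ab, "n_excluded": n_excluded}


def adjacency(expression: pd.DataFrame, soft_power: int = 6) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^power with a zero diagonal."""
    X = expression.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance genes must be removed before adjacency")
    a = np.abs(np.corrcoef(X)) ** soft_power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(adj: np.ndarray, n_bins: int = 10):
    """Scale-free topology fit index.

    Bins connectivity k_i = sum_j a_ij into ``n_bins`` equal-width bins and
    returns ``(r_squared, slope)`` of log10(frequency) on log10(mean k) over
    the non-empty bins. A power-law degree distribution gives r² near 1 with
    a negative slope.
    """
    k = adj.sum(axis=1)
    if len(k) < 20:
        raise ValueError("need at least 20 genes for a meaningful fit index")
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0 and k[m].mean() > 0:
            means.append(k[m].mean())
            freqs.append(m.mean())
    if len(means) < 3:
        raise ValueError("too few occupied connectivity bins for a fit")
    fit = linregress(np.log10(means), np.log10(freqs))
    return float(fit.rvalue**2), float(fit.slope)


def pick_soft_power(expression: pd.DataFrame, powers=range(1, 21)) -> pd.DataFrame:
    """Report (not auto-select) the fit index and mean connectivity per power."""
    rows = []
    for p in powers:
        adj = adjacency(expression, soft_power=p)
        try:
            r2, slope = scale_free_fit(adj)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append((p, r2, slope, float(adj.sum(axis=1).mean())))
    return pd.DataFrame(rows, columns=["power", "fit_r2", "slope", "mean_connectivity"])


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a symmetric zero-diagonal adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    l = a @ a  # zero diagonal makes u = i, j terms vanish automatically
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def detect_modules(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
):
    """Adaptive tree cut of average-linkage clustering into module labels.

    The dendrogram is cut at a ``deep_split``-controlled fraction of its
    merge-height range; branches with at least ``min_module_size`` leaves become
    modules (numbered by decreasing size), everything else is grey (0).
    Returns ``(labels, linkage_matrix)`` with integer labels, 0 = unassigned.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    if n < min_module_size:
        log.warning("fewer genes (%d) than min_module_size (%d): all grey", n, min_module_size)
        return np.zeros(n, dtype=int), Z
    h = Z[:, 2]
    cut = h.min() + _DEEP_SPLIT_FRACTION[deep_split] * (h.max() - h.min())
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cluster_id in sizes.index:
        if sizes[cluster_id] >= min_module_size:
            labels[raw == cluster_id] = next_id
            next_id += 1
    return labels, Z


def module_eigengene(expression: pd.DataFrame, labels: np.ndarray):
    """First singular component per module over samples.

    Member genes are standardized across samples; the eigengene is the first
    right-singular vector (unit norm over samples), sign-oriented so the mean
    member correlation is positive. Returns ``(eigengenes, variance_explained)``
    with eigengenes as a modules x samples DataFrame.
    """
    rows, var_exp = {}, {}
    for mod in sorted(set(labels) - {0}):
        sub = expression.iloc[np.flatnonzero(labels == mod)].to_numpy(dtype=float)
        if len(sub) == 1:
            log.warning("module %s has a single gene; eigengene = that gene", mod)
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        ev = vt[0]
        member_cor = np.array([np.corrcoef(row, ev)[0, 1] for row in z])
        if member_cor.mean() < 0:
            ev = -ev
        rows[mod] = ev
        var_exp[mod] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(rows, index=expression.columns).T
    return eigengenes, pd.Series(var_exp)


def merge_modules(
    expression: pd.DataFrame,
    labels: np.ndarray,
    merge_height: float = 0.25,
):
    """Iteratively merge modules whose eigengenes cluster below merge_height.

    Eigengene dissimilarity 1 - cor is clustered (average linkage); clusters
    joined below the height cut are merged, eigengenes recomputed, and the
    procedure repeats to a fixed point. Returns ``(labels, merged_history)``.
    """
    labels = labels.copy()
    history: list[tuple[int, int]] = []
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig, _ = module_eigengene(expression, labels)
        me = eig.loc[mods].to_numpy()
        diss = 1.0 - np.corrcoef(me)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(Z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        for gid in set(groups):
            members = [mods[i] for i in np.flatnonzero(groups == gid)]
            if len(members) < 2:
                continue
            sizes = {m: int((labels == m).sum()) for m in members}
            target = max(sizes, key=sizes.get)
            for m in members:
                if m != target:
                    labels[labels == m] = target
                    history.append((m, target))
    return labels, history


def scale_tom(
    tom_small: np.ndarray, tom_reference: np.ndarray, scale_quantile: float = 0.95
) -> np.ndarray:
    """Power-scale a TOM so its off-diagonal quantile matches a reference.

    scaled = TOM ** (log q_ref / log q_small) applied elementwise to the
    off-diagonal; the power map on (0,1) preserves the ordering of entries.
    """
    if not (0 < scale_quantile < 1):
        raise ValueError("scale_quantile must be in (0, 1)")
    mask = ~np.eye(tom_small.shape[0], dtype=bool)
    q_small = float(np.quantile(tom_small[mask], scale_quantile))
    q_ref = float(np.quantile(tom_reference[mask], scale_quantile))
    if q_small <= 0 or q_small >= 1 or q_ref <= 0 or q_ref >= 1:
        raise ValueError("reference quantiles must lie strictly inside (0, 1)")
    exponent = np.log(q_ref) / np.log(q_small)
    scaled = tom_small.copy()
    scaled[mask] = tom_small[mask] ** exponent
    return scaled


@dataclass
class ModuleTraitCor:
    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame
    n: int

    def summary(self) -> str:
        lines = ["Module-trait correlations (r, p)", "-" * 32]
        for mod in self.r.index:
            cells = "  ".join(
                f"{t}: {self.r.loc[mod, t]:+.2f} (p={self.p.loc[mod, t]:.2g})"
                for t in self.r.columns
            )
            lines.append(f"{mod}: {cells}")
        return "\n".join(lines)


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> ModuleTraitCor:
    """Pearson r and Student asymptotic p per module x trait."""
    samples = list(eigengenes.columns)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples for module-trait correlation")
    T = traits.loc[samples].to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    Tz = (T - T.mean(axis=0, keepdims=True)) / T.std(axis=0, keepdims=True)
    r = Ez @ Tz / n
    p = pearson_pvalue(r, n)
    return ModuleTraitCor(
        r=pd.DataFrame(r, index=eigengenes.index, columns=traits.columns),
        p=pd.DataFrame(p, index=eigengenes.index, columns=traits.columns),
        n=n,
    )


def gene_significance(gene_expression, trait) -> float:
    """|Pearson correlation| between one gene and one trait."""
    x = np.asarray(gene_expression, dtype=float)
    y = np.asarray(trait, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("gene significance undefined for zero-variance input")
    return float(abs(np.corrcoef(x, y)[0, 1]))


def module_membership(gene_expression, eigengene) -> float:
    """Signed Pearson correlation of a gene with a module eigengene."""
    x = np.asarray(gene_expression, dtype=float)
    e = np.asarray(eigengene, dtype=float)
    if np.ptp(x) == 0 or np.ptp(e) == 0:
        raise ValueError("module membership undefined for zero-variance input")
    return float(np.corrcoef(x, e)[0, 1])


def select_hub_genes(mm_values: pd.Series, k: int = 20) -> list[str]:
    """Top-k genes by |MM| (descending), ties broken by gene id."""
    if mm_values.empty:
        raise ValueError("module has no genes")
    order = sorted(mm_values.index, key=lambda g: (-abs(mm_values[g]), g))
    return order[: min(k, len(order))]


def select_trait_modules(
    cor: ModuleTraitCor, min_traits: int = 3, p_threshold: float = 0.1
) -> list[str]:
    """Modules correlated (p < threshold) with at least ``min_traits`` traits."""
    hits = (cor.p < p_threshold).sum(axis=1)
    return [str(m) for m in hits.index if m != GREY and hits[m] >= min_traits]


@dataclass
class NetworkResults:
    """Fitted co-expression network for one sample group."""

    labels: pd.Series  # gene -> module color, grey = unassigned
    eigengenes: pd.DataFrame  # modules x samples
    variance_explained: pd.Series
    tom_matrix: np.ndarray
    linkage: np.ndarray
    params: NetworkParams
    merged_history: list = field(default_factory=list)
    scale_free_r2: float = np.nan
    scale_free_slope: float = np.nan
    dropped_genes: list = field(default_factory=list)
    expression: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def correlate_traits(self, traits: pd.DataFrame) -> ModuleTraitCor:
        return module_trait_correlation(self.eigengenes, traits)

    def module_membership_table(self) -> pd.DataFrame:
        """MM of every gene against every module eigengene."""
        X = self.expression.to_numpy(dtype=float)
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        E = self.eigengenes.to_numpy(dtype=float)
        Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
        mm = Xz @ Ez.T / X.shape[1]
        return pd.DataFrame(mm, index=self.expression.index, columns=self.eigengenes.index)

    def hub_genes(self, module: str, k: int = 20) -> list[str]:
        mm = self.module_membership_table()[module]
        return select_hub_genes(mm[self.labels == module], k=k)

    def summary(self) -> str:
        sizes = self.labels.value_counts()
        lines = [
            "Co-expression network summary",
            "-----------------------------",
            f"genes:            {len(self.labels)} ({len(self.dropped_genes)} dropped, zero variance)",
            f"samples:          {self.eigengenes.shape[1]}",
            f"soft power:       {self.params.soft_power}",
            f"scale-free fit:   R^2 = {self.scale_free_r2:.3f} (slope {self.scale_free_slope:+.2f})",
            f"modules:          {len(self.modules)} (+ grey: {int(sizes.get(GREY, 0))} genes)",
        ]
        for mod in self.modules:
            lines.append(
                f"  {mod:<14} {int(sizes.get(mod, 0)):>5} genes"
                f"  varExpl={self.variance_explained[mod]:.2f}"
            )
        return "\n".join(lines)


class CoexpressionNetwork:
    """Weighted co-expression network model for one expression matrix.

    Parameters
    ----------
    expression : DataFrame, genes x samples
        Zero-variance genes are removed (and recorded) before fitting.
    params : NetworkParams
        Soft power, tree-cut and merge settings.
    """

    def __init__(self, expression: pd.DataFrame, params: NetworkParams | None = None) -> None:
        self.params = params or NetworkParams()
        sd = expression.std(axis=1)
        self.dropped_genes = list(expression.index[sd == 0])
        if self.dropped_genes:
            log.warning("removing %d zero-variance genes", len(self.dropped_genes))
        self.expression = expression[sd > 0]

    def fit(self) -> NetworkResults:
        p = self.params
        adj = adjacency(self.expression, soft_power=p.soft_power)
        try:
            r2, slope = scale_free_fit(adj)
        except ValueError:
            r2, slope = np.nan, np.nan
        t = tom(adj)
        labels_int, Z = detect_modules(
            1.0 - t, min_module_size=p.min_module_size, deep_split=p.deep_split
        )
        if labels_int.any():
            labels_int, history = merge_modules(self.expression, labels_int, p.merge_height)
        else:
            history = []
        colors = self._color_labels(labels_int)
        eig, var_exp = module_eigengene(self.expression, labels_int)
        rename = {mod: colors[mod] for mod in eig.index}
        eig.index = [rename[m] for m in eig.index]
        var_exp.index = [rename[m] for m in var_exp.index]
        labels = pd.Series(
            [colors.get(m, GREY) for m in labels_int], index=self.expression.index
        )
        return NetworkResults(
            labels=labels,
            eigengenes=eig,
            variance_explained=var_exp,
            tom_matrix=t,
            linkage=Z,
            params=p,
            merged_history=history,
            scale_free_r2=r2,
            scale_free_slope=slope,
            dropped_genes=self.dropped_genes,
            expression=self.expression,
        )

    @staticmethod
    def _color_labels(labels_int: np.ndarray) -> dict[int, str]:
        """Stable color names assigned by decreasing module size."""
        sizes = pd.Series(labels_int[labels_int > 0]).value_counts()
        order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        names = {}
        for rank, mod in enumerate(order):
            names[mod] = (
                _MODULE_COLORS[rank] if rank < len(_MODULE_COLORS) else f"module{rank + 1}"
            )
        names[0] = GREY
        return names


def compare_genotype_networks(
    expression: pd.DataFrame,
    anchor_dosage: pd.Series,
    traits: pd.DataFrame | None = None,
    params: NetworkParams | None = None,
):
    """Fit one network per genotype group of a hotspot anchor.

    The smaller group's TOM is quantile-scaled to the larger group's so that
    topological overlap values are comparable. Returns a dict with per-group
    :class:`NetworkResults`, the scaled TOM, and (when traits are given)
    per-group module-trait correlations.
    """
    params = params or NetworkParams()
    groups = split_by_genotype(anchor_dosage)
    out = {"groups": {k: groups[k] for k in ("AA", "AB")}, "n_excluded": groups["n_excluded"]}
    results = {}
    for name in ("AA", "AB"):
        results[name] = CoexpressionNetwork(expression[groups[name]], params).fit()
    out["networks"] = results
    small, big = sorted(("AA", "AB"), key=lambda k: len(groups[k]))
    # scaling requires identical gene sets; restrict to the intersection order
    if list(results[small].labels.index) == list(results[big].labels.index):
        out["scaled_tom"] = {
            small: scale_tom(
                results[small].tom_matrix, results[big].tom_matrix, params.scale_quantile
            ),
            big: results[big].tom_matrix,
        }
    if traits is not None:
        out["module_trait"] = {
            name: results[name].correlate_traits(traits.loc[groups[name]])
            for name in ("AA", "AB")
        }
    return out
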