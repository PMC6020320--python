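"""Synthetic genotype/expression/phenotype generator with planted structure.

The generator emulates the kind of cohort the pipeline is designed for: a few
hundred animals genotyped on a dense biallelic chip, RNA-seq expression for a
few thousand genes, contemporary-group/lane/age covariates, and a panel of
fat-deposition traits. Structure is planted so that every downstream stage
has a recoverable ground truth:

* Hardy–Weinberg genotypes with first-order Markov LD along each chromosome
  (two haplotypes per sample, allele copied from the adjacent variant with
  probability ``ld_copy_prob``, summed to a 0/1/2 dosage);
* cis effects: selected genes gain ``cis_beta`` x dosage of a variant within
  1 Mb of the gene span;
* a trans hotspot: one variant drives a transcription-factor gene, whose
  expression in turn drives a set of target genes elsewhere in the genome —
  the mechanism a hotspot analysis is meant to reveal;
* traits loaded on the mean standardized expression of the planted target
  group, plus the same fixed covariate effects;
* 1500 bp promoters with motif occurrences planted in target genes.

Every generator is a pure function of (config, seed); a single master seed
expands into fixed per-component child streams (see :func:`~eqtlnet._stats.child_rng`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from ._stats import child_rng

__all__ = [
    "SimConfig",
    "TruthBundle",
    "SimulatedDataset",
    "PROMOTER_LENGTH",
    "default_pfm",
    "simulate_genome",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_promoters",
    "simulate_region_set",
    "simulate_gene_sets",
    "simulate_dataset",
    "write_dataset",
]

PROMOTER_LENGTH = 1500  # bp of upstream sequence scanned for binding sites


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort. Defaults are the study conditions.

    Units: positions/lengths in bp, age in years, expression on an arbitrary
    log-like scale (baseline N(8, 2^2)), betas in expression units per dosage
    unit.
    """

    n_samples: int = 300
    n_chromosomes: int = 4
    chrom_length_bp: int = 50_000_000
    n_variants: int = 400
    n_genes: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_copy_prob: float = 0.8
    n_cis_pairs: int = 30
    cis_beta: float = 1.0
    hotspot_n_targets: int = 50
    hotspot_beta: float = 1.0
    target_gamma: float = 0.8
    target_gamma_alt: float | None = None  # TF->target coupling for allele carriers
    noise_sd: float = 1.0
    n_contemporary_groups: int = 4
    n_lanes: int = 2
    age_range: tuple[float, float] = (1.5, 2.5)
    n_traits: int = 15
    trait_loading: float = 1.0
    motif_plant_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_chromosomes": self.n_chromosomes,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "n_contemporary_groups": self.n_contemporary_groups,
            "n_lanes": self.n_lanes,
            "n_traits": self.n_traits,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("ld_copy_prob", "motif_plant_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hotspot_n_targets > self.n_genes:
            raise ValueError("hotspot_n_targets cannot exceed n_genes")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be a valid interval")


@dataclass
class TruthBundle:
    """Everything that was planted, for recovery tests and truth-aware scoring."""

    cis_truth: list[tuple[str, str, float]] = field(default_factory=list)
    hotspot_variant: str = ""
    hotspot_targets: list[str] = field(default_factory=list)
    tf_gene: str = ""
    covariate_effects: dict = field(default_factory=dict)
    trait_loadings: dict[str, float] = field(default_factory=dict)
    trait_groups: dict[str, list[str]] = field(default_factory=dict)
    motif_placements: list[tuple[str, int, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        raw = json.loads(Path(path).read_text())
        raw["cis_truth"] = [tuple(x) for x in raw["cis_truth"]]
        raw["motif_placements"] = [tuple(x) for x in raw["motif_placements"]]
        return cls(**raw)


def _chrom_names(config: SimConfig) -> list[str]:
    return [str(i + 1) for i in range(config.n_chromosomes)]


def chrom_lengths(config: SimConfig) -> dict[str, int]:
    return {name: config.chrom_length_bp for name in _chrom_names(config)}


def _split_evenly(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _sample_positions(rng, n: int, length: int) -> np.ndarray:
    """n distinct sorted positions in [1, length] without materializing the range."""
    if n > length:
        raise ValueError(f"chromosome of {length} bp cannot hold {n} distinct positions")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=max(2 * n, n + 16)))
    while pos.size < n:
        more = rng.integers(1, length + 1, size=2 * n)
        pos = np.unique(np.concatenate([pos, more]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_genome(config: SimConfig):
    """Lay out variants and genes on the synthetic chromosomes.

    Returns ``(variant_table, gene_table)``. Variant positions are strictly
    increasing within each chromosome; gene spans are non-degenerate 1-based
    inclusive intervals.
    """
    rng = child_rng(config.seed, "genome")
    min_gene, max_gene = 2_000, 20_000
    if config.chrom_length_bp <= max_gene:
        raise ValueError(
            f"chrom_length_bp={config.chrom_length_bp} too short to place genes "
            f"(need > {max_gene} bp)"
        )
    names = _chrom_names(config)
    v_rows, g_rows = [], []
    vi = gi = 0
    for chrom, nv, ng in zip(
        names,
        _split_evenly(config.n_variants, config.n_chromosomes),
        _split_evenly(config.n_genes, config.n_chromosomes),
    ):
        if nv > config.chrom_length_bp:
            raise ValueError(
                f"chromosome {chrom} ({config.chrom_length_bp} bp) cannot hold {nv} variants"
            )
        for pos in _sample_positions(rng, nv, config.chrom_length_bp):
            vi += 1
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            v_rows.append((f"v{vi:05d}", chrom, int(pos), ref, alt))
        lengths = rng.integers(min_gene, max_gene + 1, size=ng)
        starts = rng.integers(1, config.chrom_length_bp - max_gene, size=ng)
        strands = rng.choice(["+", "-"], size=ng)
        for L, s, st in zip(lengths, starts, strands):
            gi += 1
            g_rows.append((f"g{gi:05d}", chrom, int(s), int(s + L - 1), st))
    variant_table = pd.DataFrame(
        v_rows, columns=["variant_id", "chromosome", "position", "ref", "alt"]
    )
    gene_table = pd.DataFrame(
        g_rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )
    return variant_table, gene_table


def simulate_genotypes(variant_table: pd.DataFrame, config: SimConfig):
    """HWE dosages with first-order Markov LD along each chromosome.

    Two independent haplotypes per sample; at each variant the haplotype
    either copies the allele carried at the previous variant (probability
    ``ld_copy_prob``) or draws a fresh Bernoulli(f) allele, f uniform in
    ``maf_range``. Returns ``(variant_table_with_maf, dosage)`` where dosage
    is samples x variants in {0, 1, 2}.
    """
    rng = child_rng(config.seed, "genotypes")
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    blocks = []
    for chrom in variant_table["chromosome"].unique():
        m = int((variant_table["chromosome"] == chrom).sum())
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        hap = np.empty((2 * n, m), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < freqs[0]
        for j in range(1, m):
            fresh = rng.random(2 * n) < freqs[j]
            copy = rng.random(2 * n) < config.ld_copy_prob
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        blocks.append(hap[0::2] + hap[1::2])
    dosage = pd.DataFrame(
        np.hstack(blocks).astype(float), index=samples, columns=variant_table["variant_id"]
    )
    return eio._finalize_variant_table(variant_table, dosage), dosage


def _covariate_table(rng, config: SimConfig) -> pd.DataFrame:
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "contemporary_group": [
                f"CG{k + 1}" for k in rng.integers(0, config.n_contemporary_groups, size=n)
            ],
            "lane": [f"L{k + 1}" for k in rng.integers(0, config.n_lanes, size=n)],
            "age": rng.uniform(config.age_range[0], config.age_range[1], size=n),
        },
        index=pd.Index(samples, name="sample_id"),
    )


def covariate_sample_effect(covariates: pd.DataFrame, effects: dict) -> np.ndarray:
    """Reassemble the planted per-sample covariate effect from a TruthBundle."""
    cg = covariates["contemporary_group"].map(effects["contemporary_group"]).to_numpy()
    lane = covariates["lane"].map(effects["lane"]).to_numpy()
    return cg + lane + effects["age"] * covariates["age"].to_numpy()


def simulate_expression(
    dosage: pd.DataFrame,
    variant_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    config: SimConfig,
):
    """Expression with planted cis effects and a TF-mediated trans hotspot.

    Returns ``(expression, covariates, truth)``; expression is genes x samples.
    Construction per gene class (baseline b_g ~ N(8, 2^2), e ~ N(0, noise_sd^2)):

    * cis gene:      b_g + cis_beta * dosage(v_g) + covariate effect + e
    * TF gene:       b_g + hotspot_beta * dosage(hotspot variant) + e
    * target gene:   b_g + gamma_s * TF expression + e, where gamma_s is
      ``target_gamma`` (or ``target_gamma_alt`` for samples carrying the
      hotspot allele, when set)
    * other genes:   b_g + covariate effect + e
    """
    rng = child_rng(config.seed, "expression")
    n = config.n_samples
    samples = list(dosage.index)
    genes = list(gene_table["gene_id"])

    covariates = _covariate_table(rng, config)
    cg_levels = sorted(covariates["contemporary_group"].unique())
    lane_levels = sorted(covariates["lane"].unique())
    effects = {
        "contemporary_group": {lev: float(rng.normal()) for lev in cg_levels},
        "lane": {lev: float(rng.normal()) for lev in lane_levels},
        "age": float(rng.normal()),
    }
    sample_effect = covariate_sample_effect(covariates, effects)

    # hotspot anchor: variant nearest the middle of chromosome 1
    first_chrom = gene_table["chromosome"].iloc[0]
    v1 = variant_table[variant_table["chromosome"] == first_chrom]
    mid = config.chrom_length_bp // 2
    hotspot_variant = v1.iloc[(v1["position"] - mid).abs().argmin()]["variant_id"]
    hot_pos = int(v1.set_index("variant_id").loc[hotspot_variant, "position"])

    g1 = gene_table[gene_table["chromosome"] == first_chrom]
    gene_mid = (g1["start"] + g1["end"]) // 2
    tf_gene = g1.iloc[(gene_mid - hot_pos).abs().argmin()]["gene_id"]

    away = gene_table[gene_table["chromosome"] != first_chrom]["gene_id"].to_numpy()
    if len(away) < config.hotspot_n_targets:
        raise ValueError(
            f"not enough genes off chromosome {first_chrom} for "
            f"{config.hotspot_n_targets} hotspot targets"
        )
    targets = list(rng.choice(away, size=config.hotspot_n_targets, replace=False))

    # cis pairs: nearest variant within 1 Mb of the gene span
    taken = set(targets) | {tf_gene}
    vt = variant_table.set_index("variant_id")
    pool = [g for g in genes if g not in taken]
    rng.shuffle(pool)
    cis_truth: list[tuple[str, str, float]] = []
    gt_idx = gene_table.set_index("gene_id")
    for g in pool:
        if len(cis_truth) == config.n_cis_pairs:
            break
        row = gt_idx.loc[g]
        cand = variant_table[variant_table["chromosome"] == row["chromosome"]]
        cand = cand[cand["variant_id"] != hotspot_variant]
        if cand.empty:
            continue
        d = np.maximum.reduce(
            [cand["position"] - row["end"], row["start"] - cand["position"],
             np.zeros(len(cand), dtype=int)]
        )
        j = int(np.argmin(d))
        if d[j] <= 1_000_000:
            cis_truth.append((cand.iloc[j]["variant_id"], g, float(config.cis_beta)))
    if len(cis_truth) < config.n_cis_pairs:
        raise ValueError(
            f"could only place {len(cis_truth)} of {config.n_cis_pairs} cis pairs; "
            "increase variant density or chromosome count"
        )

    baseline = rng.normal(8.0, 2.0, size=len(genes))
    expr = np.tile(baseline[:, None], (1, n)) + config.noise_sd * rng.standard_normal(
        (len(genes), n)
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    plain = np.ones(len(genes), dtype=bool)

    dos_hot = dosage[hotspot_variant].to_numpy(dtype=float)
    ti = gene_pos[tf_gene]
    expr[ti] += config.hotspot_beta * dos_hot
    plain[ti] = False

    gamma = np.full(n, config.target_gamma, dtype=float)
    if config.target_gamma_alt is not None:
        gamma[dos_hot >= 1] = config.target_gamma_alt
    tf_expr = expr[ti]
    for g in targets:
        gi = gene_pos[g]
        expr[gi] += gamma * tf_expr
        plain[gi] = False

    for vid, g, beta in cis_truth:
        gi = gene_pos[g]
        expr[gi] += beta * dosage[vid].to_numpy(dtype=float)

    # cis and background genes carry the covariate effect; TF/targets follow
    # the mechanistic construction above exactly
    expr[plain] += sample_effect[None, :]

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = TruthBundle(
        cis_truth=cis_truth,
        hotspot_variant=hotspot_variant,
        hotspot_targets=targets,
        tf_gene=tf_gene,
        covariate_effects=effects,
    )
    return expression, covariates, truth


def simulate_phenotypes(
    expression: pd.DataFrame,
    truth: TruthBundle,
    config: SimConfig,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Traits loaded on the planted target-gene group, plus covariates + noise.

    Trait t = loading_t * mean(standardized target-gene expression) +
    covariate effect + N(0, noise_sd^2); loadings alternate in sign so the
    module–trait heatmap has both directions. Pairings land in the
    TruthBundle.
    """
    rng = child_rng(config.seed, "phenotypes")
    group = truth.hotspot_targets or list(expression.index)
    sub = expression.loc[group].to_numpy(dtype=float)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
    score = z.mean(axis=0)
    sample_effect = covariate_sample_effect(covariates, truth.covariate_effects)
    traits = {}
    for t in range(config.n_traits):
        name = f"trait_{t + 1:02d}"
        loading = config.trait_loading * (1.0 if t % 2 == 0 else -1.0)
        traits[name] = (
            loading * score
            + sample_effect
            + config.noise_sd * rng.standard_normal(len(score))
        )
        truth.trait_loadings[name] = loading
        truth.trait_groups[name] = list(group)
    return pd.DataFrame(traits, index=covariates.index)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_promoters(
    gene_table: pd.DataFrame,
    pfm: np.ndarray,
    config: SimConfig,
    truth: TruthBundle,
):
    """Uniform-background 1500 bp promoters with planted motif occurrences.

    Each hotspot-target promoter independently receives one occurrence with
    probability ``motif_plant_fraction``; the site is sampled column-wise from
    the PFM probabilities and inserted on a random strand at a recorded
    offset. Returns ``(promoters, placements)`` and records placements in the
    TruthBundle.
    """
    rng = child_rng(config.seed, "promoters")
    pfm = np.asarray(pfm, dtype=float)
    L = pfm.shape[1]
    if L > PROMOTER_LENGTH:
        raise ValueError(f"motif length {L} exceeds promoter length {PROMOTER_LENGTH}")
    probs = pfm / pfm.sum(axis=0, keepdims=True)
    bases = np.array(list("ACGT"))
    targets = set(truth.hotspot_targets)
    promoters: dict[str, str] = {}
    placements: list[tuple[str, int, str]] = []
    for g in gene_table["gene_id"]:
        seq = rng.choice(bases, size=PROMOTER_LENGTH)
        if g in targets and rng.random() < config.motif_plant_fraction:
            site = "".join(bases[rng.choice(4, p=probs[:, j])] for j in range(L))
            offset = int(rng.integers(0, PROMOTER_LENGTH - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else _revcomp(site)
            seq[offset : offset + L] = list(planted)
            placements.append((g, offset, strand))
        promoters[g] = "".join(seq)
    truth.motif_placements = placements
    return promoters, placements


def default_pfm() -> np.ndarray:
    """A strong 8 bp E-box-like count matrix (consensus TCACGTGA, n=100)."""
    consensus = "TCACGTGA"
    counts = np.full((4, len(consensus)), 5.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 85.0
    return counts


def simulate_region_set(
    variant_table: pd.DataFrame,
    truth: TruthBundle,
    config: SimConfig,
    n_background: int = 12,
) -> eio.RegionSet:
    """A synthetic 'known QTL' region set: the hotspot window plus background.

    Stands in for a curated QTL database so overlap testing is exercisable.
    """
    rng = child_rng(config.seed, "regions")
    vt = variant_table.set_index("variant_id")
    rows = []
    if truth.hotspot_variant:
        chrom = vt.loc[truth.hotspot_variant, "chromosome"]
        pos = int(vt.loc[truth.hotspot_variant, "position"])
        start = max(1, pos - 2_000_000)
        rows.append((chrom, start, min(config.chrom_length_bp, pos + 2_000_000)))
    for _ in range(n_background):
        chrom = str(rng.integers(1, config.n_chromosomes + 1))
        length = int(rng.integers(1_000_000, 5_000_000))
        start = int(rng.integers(1, config.chrom_length_bp - length))
        rows.append((chrom, start, start + length - 1))
    return eio.RegionSet(
        label="known_qtl",
        intervals=pd.DataFrame(rows, columns=["chromosome", "start", "end"]),
    )


def simulate_gene_sets(
    gene_table: pd.DataFrame,
    truth: TruthBundle,
    config: SimConfig,
    n_random: int = 5,
    random_size: int = 25,
) -> dict[str, set[str]]:
    """GMT-style sets: the planted target program plus random decoys."""
    rng = child_rng(config.seed, "gene_sets")
    genes = gene_table["gene_id"].to_numpy()
    sets: dict[str, set[str]] = {}
    if truth.hotspot_targets:
        sets["planted_target_program"] = set(truth.hotspot_targets)
    for k in range(n_random):
        size = min(random_size, len(genes))
        sets[f"random_set_{k + 1}"] = set(rng.choice(genes, size=size, replace=False))
    return sets


@dataclass
class SimulatedDataset:
    """One fully simulated cohort plus its ground truth."""

    config: SimConfig
    variant_table: pd.DataFrame
    gene_table: pd.DataFrame
    dosage: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    promoters: dict[str, str]
    pfm: np.ndarray
    regions: eio.RegionSet
    gene_sets: dict[str, set[str]]
    truth: TruthBundle

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return chrom_lengths(self.config)


def simulate_dataset(config: SimConfig | None = None, pfm: np.ndarray | None = None) -> SimulatedDataset:
    """Run every generator stage in order and bundle the results."""
    config = config or SimConfig()
    pfm = default_pfm() if pfm is None else np.asarray(pfm, dtype=float)
    variant_table, gene_table = simulate_genome(config)
    variant_table, dosage = simulate_genotypes(variant_table, config)
    expression, covariates, truth = simulate_expression(
        dosage, variant_table, gene_table, config
    )
    phenotypes = simulate_phenotypes(expression, truth, config, covariates)
    promoters, _ = simulate_promoters(gene_table, pfm, config, truth)
    regions = simulate_region_set(variant_table, truth, config)
    gene_sets = simulate_gene_sets(gene_table, truth, config)
    return SimulatedDataset(
        config=config,
        variant_table=variant_table,
        gene_table=gene_table,
        dosage=dosage,
        expression=expression,
        covariates=covariates,
        phenotypes=phenotypes,
        promoters=promoters,
        pfm=pfm,
        regions=regions,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_dataset(data: SimulatedDataset, outdir) -> dict[str, str]:
    """Emit every external-format view of a simulated dataset.

    Returns a name -> path manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = data.chrom_lengths
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "dosage": outdir / "genotypes.dosage.tsv",
        "expression": outdir / "expression.tsv",
        "covariates": outdir / "covariates.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "genes_gff3": outdir / "genes.gff3",
        "genes_bed": outdir / "genes.bed",
        "promoters": outdir / "promoters.fasta",
        "pfm": outdir / "motif.pfm",
        "known_qtl": outdir / "known_qtl.bed",
        "gene_sets": outdir / "gene_sets.gmt",
        "chrom_sizes": outdir / "chrom.sizes",
        "truth": outdir / "truth.json",
    }
    eio.write_vcf(data.variant_table, data.dosage, paths["vcf"], chrom_lengths=lengths)
    eio.write_dosage_tsv(data.variant_table, data.dosage, paths["dosage"])
    eio.write_expression(data.expression, paths["expression"])
    eio.write_table(data.covariates, paths["covariates"], index_label="sample_id")
    eio.write_table(data.phenotypes, paths["phenotypes"], index_label="sample_id")
    eio.write_gene_table_gff3(data.gene_table, paths["genes_gff3"])
    eio.write_gene_table_bed(data.gene_table, paths["genes_bed"])
    eio.write_fasta(data.promoters, paths["promoters"])
    eio.write_pfm_jaspar(data.pfm, paths["pfm"])
    eio.write_regions_bed(data.regions, paths["known_qtl"])
    eio.write_gmt(data.gene_sets, paths["gene_sets"])
    eio.write_chrom_sizes(lengths, paths["chrom_sizes"])
    data.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
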