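"""Generator contracts: layout, determinism, LD behaviour, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlnet.motifs import pfm_to_pssm, scan_promoters
from eqtlnet.network import module_eigengene
from eqtlnet.simulate import (
    PROMOTER_LENGTH,
    SimConfig,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_promoters,
)


def cfg(**kw):
    base = dict(seed=1, n_samples=50, n_variants=40, n_genes=30, n_cis_pairs=3,
                hotspot_n_targets=5)
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_single_chromosome_layout(self):
        variants, genes = simulate_genome(cfg(n_chromosomes=1, n_variants=10))
        assert len(variants) == 10
        assert (variants["chromosome"] == "1").all()
        assert variants["position"].is_monotonic_increasing
        assert (genes["start"] < genes["end"]).all()

    def test_determinism(self):
        a = simulate_genome(cfg())
        b = simulate_genome(cfg())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_sizing_error(self):
        with pytest.raises(ValueError, match="cannot hold"):
            simulate_genome(cfg(n_chromosomes=1, chrom_length_bp=50_000, n_variants=60_000))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=0)
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimConfig(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimConfig(hotspot_n_targets=10_000)


class TestGenotypes:
    def test_full_copying_gives_perfect_ld(self):
        c = cfg(ld_copy_prob=1.0, n_samples=200)
        vt, genes = simulate_genome(c)
        vt, dosage = simulate_genotypes(vt, c)
        per_chrom = vt.groupby("chromosome")["variant_id"].apply(list)
        for ids in per_chrom:
            d = dosage[ids].to_numpy()
            for j in range(1, d.shape[1]):
                r = np.corrcoef(d[:, j - 1], d[:, j])[0, 1]
                assert r**2 == pytest.approx(1.0)

    def test_independent_adjacent_r2_near_one_over_n(self):
        # under independence E[r^2] ~ 1/n; Monte-Carlo over >= 200 adjacent pairs
        n = 2000
        c = cfg(ld_copy_prob=0.0, n_samples=n, n_variants=250, n_chromosomes=1,
                n_genes=30)
        vt, _ = simulate_genome(c)
        vt, dosage = simulate_genotypes(vt, c)
        d = dosage.to_numpy()
        r2 = [
            np.corrcoef(d[:, j - 1], d[:, j])[0, 1] ** 2 for j in range(1, d.shape[1])
        ]
        assert np.mean(r2) == pytest.approx(1.0 / n, rel=0.5)

    def test_fixed_maf_within_binomial_bounds(self):
        n = 400
        c = cfg(maf_range=(0.5, 0.5), ld_copy_prob=0.0, n_samples=n)
        vt, _ = simulate_genome(c)
        vt, dosage = simulate_genotypes(vt, c)
        freq = dosage.to_numpy().mean(axis=0) / 2.0
        lo, hi = stats.binom.interval(0.9999, 2 * n, 0.5)
        assert ((freq >= lo / (2 * n)) & (freq <= hi / (2 * n))).all()

    def test_dosage_alphabet(self, dataset):
        vals = np.unique(dataset.dosage.to_numpy())
        assert set(vals) <= {0.0, 1.0, 2.0}


class TestExpression:
    def test_noiseless_cis_slope_recovered(self):
        c = cfg(noise_sd=1e-9, cis_beta=2.0, n_contemporary_groups=1, n_lanes=1)
        vt, genes = simulate_genome(c)
        vt, dosage = simulate_genotypes(vt, c)
        expr, cov, truth = simulate_expression(dosage, vt, genes, c)
        vid, gid, beta = truth.cis_truth[0]
        assert beta == 2.0
        g = dosage[vid].to_numpy()
        y = expr.loc[gid].to_numpy()
        # age is the only covariate left; regress it out along with genotype
        X = np.column_stack([np.ones_like(g), cov["age"].to_numpy(), g])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        assert coef[-1] == pytest.approx(2.0, abs=1e-6)

    def test_truth_bundle_sizes(self, dataset):
        t = dataset.truth
        assert len(t.hotspot_targets) == dataset.config.hotspot_n_targets
        assert len(set(t.hotspot_targets)) == len(t.hotspot_targets)
        assert len(t.cis_truth) == dataset.config.n_cis_pairs
        gene_ids = set(dataset.gene_table["gene_id"])
        assert set(t.hotspot_targets) <= gene_ids
        assert t.tf_gene in gene_ids
        assert t.hotspot_variant in set(dataset.variant_table["variant_id"])

    def test_too_many_targets_error(self):
        with pytest.raises(ValueError, match="not enough genes"):
            c = cfg(hotspot_n_targets=30)  # all genes, incl. chromosome 1's
            vt, genes = simulate_genome(c)
            vt, dosage = simulate_genotypes(vt, c)
            simulate_expression(dosage, vt, genes, c)


class TestPhenotypes:
    def test_determinism(self, dataset):
        c = dataset.config
        other = simulate_dataset(c)
        pd.testing.assert_frame_equal(dataset.phenotypes, other.phenotypes)

    def test_zero_loading_gives_null_module_correlation(self):
        hits = 0
        reps = 8
        for seed in range(reps):
            c = cfg(seed=seed, trait_loading=0.0, n_samples=400, n_traits=3)
            d = simulate_dataset(c)
            labels = np.array(
                [1 if g in set(d.truth.hotspot_targets) else 0 for g in d.expression.index]
            )
            eig, _ = module_eigengene(d.expression, labels)
            me = eig.iloc[0].to_numpy()
            r = max(
                abs(np.corrcoef(me, d.phenotypes[t].to_numpy())[0, 1])
                for t in d.phenotypes.columns
            )
            # adjusted bound: traits still carry covariate effects, so compare
            # against the residualized trait
            from eqtlnet.phenotype import adjust_phenotype

            r_adj = max(
                abs(np.corrcoef(me, adjust_phenotype(d.phenotypes[t], d.covariates))[0, 1])
                for t in d.phenotypes.columns
            )
            if r_adj < 2.5 / np.sqrt(c.n_samples):
                hits += 1
        assert hits >= reps - 1

    def test_strong_loading_gives_high_correlation(self):
        ok = 0
        reps = 5
        for seed in range(reps):
            c = cfg(seed=100 + seed, trait_loading=5.0, n_samples=300, n_traits=2)
            d = simulate_dataset(c)
            labels = np.array(
                [1 if g in set(d.truth.hotspot_targets) else 0 for g in d.expression.index]
            )
            eig, _ = module_eigengene(d.expression, labels)
            me = eig.iloc[0].to_numpy()
            r = abs(np.corrcoef(me, d.phenotypes["trait_01"].to_numpy())[0, 1])
            if r > 0.5:
                ok += 1
        assert ok == reps


class TestPromoters:
    def test_length_and_planting(self, dataset):
        assert all(len(s) == PROMOTER_LENGTH for s in dataset.promoters.values())
        planted = {g for g, _, _ in dataset.truth.motif_placements}
        assert planted <= set(dataset.truth.hotspot_targets)

    def test_consensus_plant_found_by_scanner(self):
        consensus = np.zeros((4, 6))
        for j, b in enumerate("ACGTAC"):
            consensus["ACGT".index(b), j] = 10.0
        c = cfg(motif_plant_fraction=1.0)
        d = simulate_dataset(c, pfm=consensus)
        pssm = pfm_to_pssm(consensus, pseudocount=0.0)
        hits, _ = scan_promoters(pssm, d.promoters, p_threshold=1.0 / 4**6 + 1e-12)
        found = set(zip(hits["gene_id"], hits["offset"], hits["strand"]))
        for gene, offset, strand in d.truth.motif_placements:
            assert (gene, offset, strand) in found

    def test_zero_fraction_plants_nothing(self):
        d = simulate_dataset(cfg(motif_plant_fraction=0.0))
        assert d.truth.motif_placements == []

    def test_motif_longer_than_promoter_error(self):
        pfm = np.ones((4, PROMOTER_LENGTH + 1))
        c = cfg()
        vt, genes = simulate_genome(c)
        vt, dosage = simulate_genotypes(vt, c)
        _, _, truth = simulate_expression(dosage, vt, genes, c)
        with pytest.raises(ValueError, match="exceeds promoter length"):
            simulate_promoters(genes, pfm, c, truth)
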