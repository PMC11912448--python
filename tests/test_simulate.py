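"""Synthetic cohort generator: invariants, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from recburden import io as rio
from recburden import simulate as sim
from recburden.variants import classify_table


class TestConfigValidation:
    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            sim.SimConfig(n_genes=1)
        with pytest.raises(ValueError):
            sim.SimConfig(n_trios=-1)

    def test_f_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sim.SimConfig(f_distribution=[(0.0, 0.5), (0.01, 0.4)])

    def test_taf_range(self):
        with pytest.raises(ValueError):
            sim.SimConfig(target_attributable_fraction=1.0)

    def test_causal_gene_must_exist(self):
        cfg = sim.SimConfig(
            n_trios=5,
            n_genes=10,
            causal_genes=[("NOT_A_GENE", 1.0)],
            target_attributable_fraction=0.1,
            generate_markers=False,
        )
        panel = sim.simulate_gene_panel(cfg)
        with pytest.raises(ValueError, match="causal genes absent"):
            sim.simulate_trios(cfg, panel)


class TestGenePanel:
    def test_rare_af_invariant_and_pool_composition(self, small_cohort):
        _, panel, _ = small_cohort
        v = panel.variants
        assert (v["true_af"] < 1e-3).all()
        assert (v["af_panel1"].dropna() < 1e-3).all()
        assert (v["af_panel2"].dropna() < 1e-3).all()
        kinds = v.groupby("gene")["vkind"].agg(set)
        for got in kinds:
            assert {"LoF", "Dmis", "synonymous", "benign_missense"} <= got

    def test_af_scale_zero_kills_all_frequencies(self):
        cfg = sim.SimConfig(n_genes=20, af_scale=0.0, generate_markers=False)
        panel = sim.simulate_gene_panel(cfg)
        assert (panel.variants["true_af"] == 0).all()
        cohort = sim.simulate_trios(cfg, panel)
        assert len(cohort.genotypes) == 0

    def test_panel_determinism(self):
        cfg = sim.SimConfig(n_genes=100, seed=9, generate_markers=False)
        p1 = sim.simulate_gene_panel(cfg)
        p2 = sim.simulate_gene_panel(cfg)
        pd.testing.assert_frame_equal(p1.variants, p2.variants)
        pd.testing.assert_series_equal(p1.mutability, p2.mutability)

    def test_af_scale_doubling_doubles_damaging_sums(self):
        """Law-of-large-numbers check over 1,000 genes."""
        base = sim.simulate_gene_panel(
            sim.SimConfig(n_genes=1000, seed=10, af_scale=10.0)
        )
        doubled = sim.simulate_gene_panel(
            sim.SimConfig(n_genes=1000, seed=10, af_scale=20.0)
        )

        def mean_dam(panel):
            v = panel.variants
            return v[v["vkind"].isin(["LoF", "Dmis", "nonframeshift_indel"])].groupby(
                "gene"
            )["true_af"].sum().mean()

        ratio = mean_dam(doubled) / mean_dam(base)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestTrioCohort:
    def test_seed_determinism(self):
        cfg = sim.SimConfig(n_trios=30, n_singletons=10, n_genes=40, seed=12)
        c1 = sim.simulate_trios(cfg, sim.simulate_gene_panel(cfg))
        c2 = sim.simulate_trios(cfg, sim.simulate_gene_panel(cfg))
        pd.testing.assert_frame_equal(c1.genotypes, c2.genotypes)
        pd.testing.assert_frame_equal(c1.truth_probands, c2.truth_probands)
        assert np.array_equal(c1.marker_genotypes, c2.marker_genotypes)

    def test_mendelian_consistency(self, small_cohort):
        """Every proband allele is carried by the assigned parent."""
        _, _, cohort = small_cohort
        gt = cohort.genotypes
        dos = {(r.sample, r.variant_id): (r.hap1, r.hap2) for r in gt.itertuples(index=False)}
        trio_probands = [s for s in gt["sample"].unique() if s.endswith("-P")]
        for s in trio_probands:
            father, mother = s[:-2] + "-F", s[:-2] + "-M"
            sub = gt[gt["sample"] == s]
            for r in sub.itertuples(index=False):
                if r.hap1:  # maternal copy
                    assert sum(dos.get((mother, r.variant_id), (0, 0))) > 0
                if r.hap2:  # paternal copy
                    assert sum(dos.get((father, r.variant_id), (0, 0))) > 0

    def test_outbred_limit(self):
        cfg = sim.SimConfig(
            n_trios=0,
            n_singletons=10_000,
            n_genes=2,
            seed=13,
            f_distribution=[(0.0, 1.0)],
            generate_markers=False,
        )
        cohort = sim.simulate_trios(cfg, sim.simulate_gene_panel(cfg))
        assert cohort.truth_probands["realized_autozygous_fraction"].mean() < 1e-4

    def test_assigned_f_realized_on_average(self):
        cfg = sim.SimConfig(
            n_trios=0,
            n_singletons=300,
            n_genes=2,
            seed=14,
            f_distribution=[(0.0625, 1.0)],
            generate_markers=False,
        )
        cohort = sim.simulate_trios(cfg, sim.simulate_gene_panel(cfg))
        realized = cohort.truth_probands["realized_autozygous_fraction"].mean()
        assert realized == pytest.approx(0.0625, rel=0.15)

    def test_target_attributable_fraction_within_binomial_error(self):
        taf, n = 0.02, 5000
        cfg = sim.SimConfig(
            n_trios=n,
            n_singletons=0,
            n_genes=60,
            seed=15,
            causal_genes=[(f"GENE{i + 1:05d}", 1.0) for i in range(10)],
            target_attributable_fraction=taf,
            generate_markers=False,
        )
        cohort = sim.simulate_trios(cfg, sim.simulate_gene_panel(cfg))
        frac = cohort.truth_probands["causal"].mean()
        assert abs(frac - taf) < 3 * np.sqrt(taf * (1 - taf) / n)

    def test_causal_probands_carry_rg_in_causal_gene(self, small_cohort):
        _, panel, cohort = small_cohort
        v = classify_table(panel.variants)
        dam = v[v["damaging"]].set_index("variant_id")["gene"]
        gt = cohort.genotypes
        causal = cohort.truth_probands[cohort.truth_probands["causal"]]
        assert len(causal) > 0
        for r in causal.itertuples(index=False):
            sub = gt[(gt["sample"] == r.sample)]
            genes = sub["variant_id"].map(dam)
            in_gene = sub[genes == r.causal_gene]
            # hom or two alleles on opposite haplotypes
            assert (in_gene["dosage"] == 2).any() or (
                (in_gene["hap1"].max() > 0) and (in_gene["hap2"].max() > 0)
            )


class TestVCFRoundTrip:
    def test_allele_counts_preserved(self, small_cohort, tmp_path):
        _, panel, cohort = small_cohort
        samples = list(cohort.pedigree["sample"])
        path = str(tmp_path / "cohort.vcf")
        rio.write_vcf(cohort.genotypes, panel.variants, samples, path)
        back, back_samples = rio.read_vcf(path)
        assert back_samples == samples
        orig = cohort.genotypes.set_index(["sample", "variant_id"])["dosage"]
        got = back.set_index(["sample", "variant_id"])["dosage"]
        assert got.sort_index().equals(orig.sort_index().astype(got.dtype))


class TestCooccurrencePanel:
    def test_counts_match_brute_force(self, small_cohort):
        _, panel, _ = small_cohort
        pairs, geno = sim.simulate_cooccurrence_panel(
            panel, n_individuals=3000, seed=21, return_genotypes=True
        )
        carried = geno.groupby("individual")["variant_id"].agg(set)
        gene_of = dict(zip(panel.variants["variant_id"], panel.variants["gene"]))
        brute: dict = {}
        for vids in carried:
            vids = sorted(vids)
            for i in range(len(vids)):
                for j in range(i + 1, len(vids)):
                    if gene_of[vids[i]] == gene_of[vids[j]]:
                        key = (vids[i], vids[j])
                        brute[key] = brute.get(key, 0) + 1
        got = {
            (r.variant_a, r.variant_b): r.count for r in pairs.itertuples(index=False)
        }
        assert got == brute

    def test_cross_gene_pairs_absent(self, small_cohort):
        _, panel, _ = small_cohort
        pairs = sim.simulate_cooccurrence_panel(panel, n_individuals=2000, seed=22)
        gene_of = dict(zip(panel.variants["variant_id"], panel.variants["gene"]))
        for r in pairs.itertuples(index=False):
            assert gene_of[r.variant_a] == gene_of[r.variant_b] == r.gene

    def test_minimum_panel_size(self, small_cohort):
        _, panel, _ = small_cohort
        with pytest.raises(ValueError):
            sim.simulate_cooccurrence_panel(panel, n_individuals=0)


class TestFounderHaplotypes:
    def test_seed_determinism(self):
        a = sim.simulate_founder_haplotypes(50, 6, seed=30)
        b = sim.simulate_founder_haplotypes(50, 6, seed=30)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.breakpoints, b.breakpoints)

    def test_one_sided_lengths_are_exponential_with_mean_one_over_age(self):
        fh = sim.simulate_founder_haplotypes(40, 5000, seed=31, n_markers=10)
        mean_len = fh.breakpoints.mean()  # 10,000 one-sided draws
        assert mean_len == pytest.approx(1 / 40, rel=0.03)

    def test_old_alleles_share_almost_nothing(self):
        fh = sim.simulate_founder_haplotypes(1_000_000, 6, seed=32)
        from recburden import founder as fo

        sh = fo.max_shared_haplotype(fh.haplotypes, fh.positions, fh.focal_index)
        assert sh.length_bp <= 10 * 20_000  # a handful of markers at most
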