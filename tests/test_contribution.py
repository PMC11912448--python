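"""Attributable-fraction estimation from parental depletion."""

import numpy as np
import pandas as pd
import pytest

from recburden import contribution as ct
from tests.conftest import make_genotype, make_variant


class TestAttributableFraction:
    @pytest.mark.parametrize(
        "ep,op,epr,opr,n,expected_pct",
        [
            (1418.0, 1181, 659.1, 630, 3716, 2.2),  # damaging RGs
            (156.5, 95, 69.9, 61, 3716, 0.5),  # LoF RGs
            (4122.2, 4135, 1951.5, 1951, 3716, -0.18),  # synonymous control ~ 0
        ],
    )
    def test_published_trio_counts(self, ep, op, epr, opr, n, expected_pct):
        frac = ct.attributable_fraction(ep, op, epr, opr, n)
        assert 100 * frac == pytest.approx(expected_pct, abs=0.05)

    def test_null_identity_is_zero(self):
        # obs_probands exactly at the parental-depletion expectation
        assert ct.attributable_fraction(100, 80, 50, 50 * 0.8, 1000) == pytest.approx(0)

    def test_zero_expected_error(self):
        with pytest.raises(ValueError):
            ct.attributable_fraction(0.0, 5, 10.0, 5, 100)


def _flat_trio_cohort(n_trios=50, q_carriers=2):
    """A cohort where Q = carriers/(2*n_parents) is exact and F = 0."""
    variants = pd.DataFrame(
        [make_variant("1:100:A:T", gene="G1", consequence="stopgain", metasvm=None)]
    )
    trios = pd.DataFrame(
        {
            "proband": [f"P{i}" for i in range(n_trios)],
            "father": [f"F{i}" for i in range(n_trios)],
            "mother": [f"M{i}" for i in range(n_trios)],
        }
    )
    cols = list(make_genotype("x", "v", 1).keys())
    gt = pd.DataFrame(
        [make_genotype(f"F{i}", "1:100:A:T", 1, hap1=1, hap2=0) for i in range(q_carriers)],
        columns=cols,
    )
    samples = list(trios["proband"]) + list(trios["father"]) + list(trios["mother"])
    f_table = pd.DataFrame({"sample": samples, "F": 0.0})
    return gt, variants, trios, f_table


class TestExpectedCounts:
    def test_single_gene_closed_form(self):
        """One gene at Q = 0.01 with F = 0: expected = N * Q**2."""
        gt, variants, trios, f_table = _flat_trio_cohort(n_trios=50, q_carriers=2)
        # Q = 2 / (2 * 100 parents) = 0.01
        Q = ct.gene_frequency_sums(gt, variants, list(trios["father"]) + list(trios["mother"]))
        assert Q.loc["G1"] == pytest.approx(0.01)
        est = ct.estimate_contribution(gt, variants, trios, f_table, "damaging")
        assert est.exp_probands == pytest.approx(50 * 1e-4)
        assert est.exp_parents == pytest.approx(100 * 1e-4)
        ep, epr = ct.expected_rg_counts(gt, variants, trios, f_table, "damaging")
        assert (ep, epr) == (pytest.approx(est.exp_parents), pytest.approx(est.exp_probands))

    def test_zero_frequencies_zero_expected(self):
        gt, variants, trios, _ = _flat_trio_cohort(q_carriers=0)
        Q = ct.gene_frequency_sums(gt, variants, list(trios["father"]) + list(trios["mother"]))
        assert Q.sum() == 0.0

    def test_missing_F_error(self):
        gt, variants, trios, f_table = _flat_trio_cohort()
        with pytest.raises(ValueError, match="missing F"):
            ct.estimate_contribution(gt, variants, trios, f_table.iloc[:10], "damaging")

    def test_autozygosity_term(self):
        """With F = 1 the per-individual expectation is Q, not Q**2."""
        gt, variants, trios, f_table = _flat_trio_cohort(n_trios=50, q_carriers=2)
        f_table.loc[f_table["sample"].str.startswith("P"), "F"] = 1.0
        est = ct.estimate_contribution(gt, variants, trios, f_table, "damaging")
        assert est.exp_probands == pytest.approx(50 * 0.01)

    def test_cooccurrence_pruning_drops_rarer_member(self):
        variants = pd.DataFrame(
            [
                make_variant("1:100:A:T", gene="G1", consequence="stopgain"),
                make_variant("1:200:C:G", gene="G1", consequence="stopgain"),
            ]
        )
        # v1 has 4 carriers; v2 has 2, both of whom also carry v1 (cis-like)
        rows = [make_genotype(f"F{i}", "1:100:A:T", 1, hap1=1, hap2=0) for i in range(4)]
        rows += [make_genotype(f"F{i}", "1:200:C:G", 1, hap1=1, hap2=0) for i in range(2)]
        gt = pd.DataFrame(rows)
        parents = [f"F{i}" for i in range(20)] + [f"M{i}" for i in range(20)]
        Q = ct.gene_frequency_sums(gt, variants, parents)
        assert Q.loc["G1"] == pytest.approx(4 / 80)  # only v1 survives pruning

    def test_qc_failing_genotype_removes_variant_from_trio(self):
        gt, variants, trios, f_table = _flat_trio_cohort(n_trios=50, q_carriers=2)
        gt.loc[0, "gq"] = 5  # F0's genotype fails QC -> variant dropped for trio 0
        est = ct.estimate_contribution(gt, variants, trios, f_table, "damaging")
        assert est.exp_probands == pytest.approx(50 * (1 / 200) ** 2)


class TestBootstrap:
    def test_zero_variance_cohort_collapses_ci(self, small_cohort, trios_frame, truth_f_table):
        """Identical trios resample to identical statistics."""
        variants = pd.DataFrame(
            [make_variant("1:100:A:T", gene="G1", consequence="stopgain")]
        )
        n = 30
        trios = pd.DataFrame(
            {
                "proband": [f"P{i}" for i in range(n)],
                "father": [f"F{i}" for i in range(n)],
                "mother": [f"M{i}" for i in range(n)],
            }
        )
        rows = []
        for i in range(n):  # every trio identical: father het, transmitted
            rows.append(make_genotype(f"F{i}", "1:100:A:T", 1, hap1=1, hap2=0))
            rows.append(make_genotype(f"P{i}", "1:100:A:T", 1, hap1=0, hap2=1))
        gt = pd.DataFrame(rows)
        samples = [s for cols in (trios[c] for c in trios) for s in cols]
        f_table = pd.DataFrame({"sample": samples, "F": 0.0})
        est = ct.estimate_contribution(
            gt, variants, trios, f_table, "damaging", bootstrap=200, seed=0
        )
        assert est.ci[0] == pytest.approx(est.fraction)
        assert est.ci[1] == pytest.approx(est.fraction)

    def test_seed_determinism(self, small_cohort, trios_frame, truth_f_table):
        _, panel, cohort = small_cohort
        kwargs = dict(variant_class="damaging", bootstrap=150, seed=42)
        a = ct.estimate_contribution(
            cohort.genotypes, panel.variants, trios_frame, truth_f_table, **kwargs
        )
        b = ct.estimate_contribution(
            cohort.genotypes, panel.variants, trios_frame, truth_f_table, **kwargs
        )
        assert a.ci == b.ci
        assert a.fraction == b.fraction

    def test_b_precondition(self):
        with pytest.raises(ValueError):
            ct.bootstrap_ci(None, None, None, None, None, None, None, None, B=50)


class TestInvariances:
    def test_sample_order_and_gene_label_invariance(
        self, small_cohort, trios_frame, truth_f_table
    ):
        _, panel, cohort = small_cohort
        base = ct.estimate_contribution(
            cohort.genotypes, panel.variants, trios_frame, truth_f_table, "damaging"
        )
        shuffled = cohort.genotypes.sample(frac=1.0, random_state=0).reset_index(drop=True)
        relabel = {g: f"X_{g}" for g in panel.variants["gene"].unique()}
        v2 = panel.variants.assign(gene=panel.variants["gene"].map(relabel))
        est2 = ct.estimate_contribution(
            shuffled, v2, trios_frame, truth_f_table, "damaging"
        )
        assert est2.fraction == pytest.approx(base.fraction)
        assert est2.obs_probands == base.obs_probands
        assert est2.exp_parents == pytest.approx(base.exp_parents)


class TestStratified:
    def test_identical_strata_equal_fractions(self):
        gt, variants, trios, f_table = _flat_trio_cohort(n_trios=40, q_carriers=4)
        # make the two halves literally identical in carriage: carriers F0,F1
        # in stratum A, F2,F3 in stratum B
        gt2 = pd.concat(
            [
                gt.iloc[:2],
                gt.iloc[:2].assign(sample=["F20", "F21"]),
            ]
        ).reset_index(drop=True)
        strata = pd.Series(
            ["A"] * 20 + ["B"] * 20, index=[f"P{i}" for i in range(40)]
        )
        out = ct.stratified_contribution(
            gt2, variants, trios, f_table, strata, "damaging"
        )
        assert out["A"].fraction == pytest.approx(out["B"].fraction)

    def test_whole_cohort_is_weighted_combination_under_shared_frequencies(
        self, small_cohort, trios_frame, truth_f_table
    ):
        _, panel, cohort = small_cohort
        rng = np.random.default_rng(0)
        strata = pd.Series(
            rng.choice(["x", "y"], size=len(trios_frame)),
            index=trios_frame["proband"],
        )
        whole = ct.estimate_contribution(
            cohort.genotypes, panel.variants, trios_frame, truth_f_table, "damaging"
        )
        parts = ct.stratified_contribution(
            cohort.genotypes,
            panel.variants,
            trios_frame,
            truth_f_table,
            strata,
            "damaging",
            shared_frequencies=True,
            shared_parent_ratio=True,
        )
        combined = sum(p.fraction * p.n_probands for p in parts.values()) / sum(
            p.n_probands for p in parts.values()
        )
        assert combined == pytest.approx(whole.fraction, abs=1e-12)

    def test_small_stratum_flagged(self):
        gt, variants, trios, f_table = _flat_trio_cohort(n_trios=16, q_carriers=2)
        # carriers in both strata so per-stratum expectations stay positive
        gt = pd.concat(
            [gt, gt.assign(sample=["F6", "F7"])], ignore_index=True
        )
        strata = pd.Series(
            ["tiny"] * 5 + ["rest"] * 11, index=[f"P{i}" for i in range(16)]
        )
        out = ct.stratified_contribution(gt, variants, trios, f_table, strata, "damaging")
        assert out["tiny"].n_warning
        assert not out["rest"].n_warning
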