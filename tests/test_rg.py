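"""Recessive-genotype calling: homozygotes, trio comphets, singleton ICHs."""

import numpy as np
import pandas as pd
import pytest

from recburden import rg
from tests.conftest import make_genotype, make_variant, random_trio_genotypes


@pytest.fixture
def lof_pair():
    return pd.DataFrame(
        [
            make_variant("1:100:A:T", gene="G1", consequence="stopgain", metasvm=None),
            make_variant("1:200:C:G", gene="G1", consequence="stopgain", metasvm=None),
            make_variant("1:300:G:A", gene="G1", consequence="synonymous", metasvm=None),
        ]
    )


class TestHomozygotes:
    def test_rare_lof_homozygote_called(self, lof_pair):
        gt = pd.DataFrame([make_genotype("s1", "1:100:A:T", 2)])
        out = rg.call_homozygotes(gt, lof_pair)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.rg_type, row.damaging_class, row.phase_evidence) == (
            "hom",
            "LoF_LoF",
            "homozygous",
        )

    def test_het_only_is_not_an_rg(self, lof_pair):
        gt = pd.DataFrame([make_genotype("s1", "1:100:A:T", 1)])
        assert rg.call_homozygotes(gt, lof_pair).empty

    def test_common_homozygote_fails_rarity(self):
        v = pd.DataFrame(
            [make_variant("1:100:A:T", consequence="stopgain", af1=5e-3, af2=5e-3)]
        )
        gt = pd.DataFrame([make_genotype("s1", "1:100:A:T", 2)])
        assert rg.call_homozygotes(gt, v).empty

    def test_synonymous_control_stream(self, lof_pair):
        gt = pd.DataFrame([make_genotype("s1", "1:300:G:A", 2)])
        assert rg.call_homozygotes(gt, lof_pair).empty
        out = rg.call_homozygotes(gt, lof_pair, class_filter="synonymous")
        assert len(out) == 1 and out.iloc[0].damaging_class == "synonymous"


class TestComphetTrio:
    def _gt(self, carriers):
        return pd.DataFrame(
            [make_genotype(s, vid, d) for s, vid, d in carriers]
        )

    def test_trans_pair_called(self, lof_pair):
        gt = self._gt(
            [
                ("p", "1:100:A:T", 1),
                ("p", "1:200:C:G", 1),
                ("m", "1:100:A:T", 1),
                ("f", "1:200:C:G", 1),
            ]
        )
        trios = pd.DataFrame([{"proband": "p", "father": "f", "mother": "m"}])
        out = rg.call_comphets_trios(gt, trios, lof_pair)
        assert len(out) == 1
        assert out.iloc[0].rg_type == "comphet"
        assert {out.iloc[0].variant1, out.iloc[0].variant2} == {
            "1:100:A:T",
            "1:200:C:G",
        }

    def test_cis_pair_excluded(self, lof_pair):
        gt = self._gt(
            [
                ("p", "1:100:A:T", 1),
                ("p", "1:200:C:G", 1),
                ("m", "1:100:A:T", 1),
                ("m", "1:200:C:G", 1),
            ]
        )
        trios = pd.DataFrame([{"proband": "p", "father": "f", "mother": "m"}])
        assert rg.call_comphets_trios(gt, trios, lof_pair).empty

    def test_damaging_plus_synonymous_is_not_damaging_rg(self, lof_pair):
        gt = self._gt(
            [
                ("p", "1:100:A:T", 1),
                ("p", "1:300:G:A", 1),
                ("m", "1:100:A:T", 1),
                ("f", "1:300:G:A", 1),
            ]
        )
        trios = pd.DataFrame([{"proband": "p", "father": "f", "mother": "m"}])
        assert rg.call_comphets_trios(gt, trios, lof_pair).empty

    def test_hom_takes_precedence_over_comphet(self, lof_pair):
        gt = self._gt(
            [
                ("p", "1:100:A:T", 2),
                ("p", "1:200:C:G", 1),
                ("m", "1:100:A:T", 1),
                ("f", "1:100:A:T", 1),
                ("f", "1:200:C:G", 1),
            ]
        )
        trios = pd.DataFrame([{"proband": "p", "father": "f", "mother": "m"}])
        ped = pd.DataFrame(
            [
                {"fam": "x", "sample": "p", "father": "f", "mother": "m", "sex": 1, "phenotype": 2},
                {"fam": "x", "sample": "f", "father": "0", "mother": "0", "sex": 1, "phenotype": 1},
                {"fam": "x", "sample": "m", "father": "0", "mother": "0", "sex": 2, "phenotype": 1},
            ]
        )
        out = rg.call_rgs(gt, ped, lof_pair)
        assert len(out) == 1 and out.iloc[0].rg_type == "hom"

    def test_most_damaging_pair_selected(self):
        v = pd.DataFrame(
            [
                make_variant("1:100:A:T", gene="G1", consequence="stopgain"),
                make_variant("1:200:C:G", gene="G1", consequence="missense", metasvm="D"),
                make_variant("1:300:G:A", gene="G1", consequence="stopgain"),
            ]
        )
        gt = self._gt(
            [
                ("p", "1:100:A:T", 1),
                ("p", "1:200:C:G", 1),
                ("p", "1:300:G:A", 1),
                ("m", "1:100:A:T", 1),
                ("f", "1:200:C:G", 1),
                ("f", "1:300:G:A", 1),
            ]
        )
        trios = pd.DataFrame([{"proband": "p", "father": "f", "mother": "m"}])
        out = rg.call_comphets_trios(gt, trios, v)
        assert len(out) == 1
        # LoF (maternal 1:100) pairs with paternal LoF 1:300, not the D-mis
        assert {out.iloc[0].variant1, out.iloc[0].variant2} == {
            "1:100:A:T",
            "1:300:G:A",
        }
        assert out.iloc[0].damaging_class == "LoF_LoF"


def brute_force_comphets(genotypes, trios, variants):
    """Independent oracle: exhaustive same-gene het-pair enumeration."""
    from recburden.variants import classify_table, rare_mask

    v = classify_table(variants)
    v = v[rare_mask(v) & v["damaging"]]
    dam = set(v["variant_id"])
    gene_of = v.set_index("variant_id")["gene"].to_dict()
    dos = {
        (r.sample, r.variant_id): r.dosage for r in genotypes.itertuples(index=False)
    }
    hits = set()
    for t in trios.itertuples(index=False):
        by_gene = {}
        for (s, vid), d in dos.items():
            if s == t.proband and d == 1 and vid in dam:
                by_gene.setdefault(gene_of[vid], []).append(vid)
        for gene, vids in by_gene.items():
            found = False
            for i in range(len(vids)):
                for j in range(len(vids)):
                    if i == j:
                        continue
                    a, b = vids[i], vids[j]
                    a_mat = dos.get((t.mother, a), 0) > 0 and dos.get((t.father, a), 0) == 0
                    b_pat = dos.get((t.father, b), 0) > 0 and dos.get((t.mother, b), 0) == 0
                    if a_mat and b_pat:
                        found = True
            if found:
                hits.add((t.proband, gene))
    return hits


def test_comphet_caller_matches_brute_force_enumeration():
    """Caller output equals exhaustive trans-pair enumeration on random trios."""
    rng = np.random.default_rng(3)
    genotypes, trios, variants = random_trio_genotypes(rng, n_trios=120)
    out = rg.call_comphets_trios(genotypes, trios, variants)
    assert set(zip(out["sample"], out["gene"])) == brute_force_comphets(
        genotypes, trios, variants
    )


def test_caller_order_independent():
    rng = np.random.default_rng(4)
    genotypes, trios, variants = random_trio_genotypes(rng, n_trios=40)
    out1 = rg.call_comphets_trios(genotypes, trios, variants)
    shuffled = genotypes.sample(frac=1.0, random_state=1).reset_index(drop=True)
    out2 = rg.call_comphets_trios(shuffled, trios, variants)
    key = ["sample", "gene", "variant1", "variant2"]
    pd.testing.assert_frame_equal(
        out1.sort_values(key).reset_index(drop=True)[key],
        out2.sort_values(key).reset_index(drop=True)[key],
    )


class TestSingletons:
    @pytest.fixture
    def setup(self, lof_pair):
        gt = pd.DataFrame(
            [
                make_genotype("s1", "1:100:A:T", 1),
                make_genotype("s1", "1:200:C:G", 1),
            ]
        )
        return gt, lof_pair

    def test_zero_cooccurrence_inferred_trans(self, setup):
        gt, v = setup
        out = rg.call_comphets_singletons(gt, ["s1"], v, {})
        assert len(out) == 1
        assert out.iloc[0].rg_type == "inferred_comphet"
        assert out.iloc[0].phase_evidence == "panel_absence"

    def test_observed_cooccurrence_blocks_call(self, setup):
        gt, v = setup
        cooc = {frozenset(("1:100:A:T", "1:200:C:G")): 1}
        assert rg.call_comphets_singletons(gt, ["s1"], v, cooc).empty

    def test_single_het_no_call(self, lof_pair):
        gt = pd.DataFrame([make_genotype("s1", "1:100:A:T", 1)])
        assert rg.call_comphets_singletons(gt, ["s1"], lof_pair, {}).empty


class TestRates:
    def test_cohort_rate_matches_reported_scale(self):
        """1,253 RGs over 5,424 samples is 0.23 genotypes per individual."""
        rgs = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(1253)],
                "gene": "G",
                "rg_type": ["hom"] * 648 + ["comphet"] * 605,
                "variant1": "v",
                "variant2": None,
                "damaging_class": "contains_Dmis",
                "phase_evidence": "trio",
            }
        )
        rates = rg.tabulate_rg_rates(rgs, 5424).set_index(["gene_set", "rg_type"])
        assert rates.loc[("all_genes", "total"), "count"] == 1253
        assert rates.loc[("all_genes", "total"), "rate"] == pytest.approx(0.231, abs=1e-3)
        # rates x n reproduce counts exactly
        assert np.allclose(
            rates["rate"].to_numpy() * 5424, rates["count"].to_numpy()
        )

    def test_empty_rg_list(self):
        rates = rg.tabulate_rg_rates(pd.DataFrame(columns=rg.RG_COLUMNS), 100)
        assert (rates["count"] == 0).all() and (rates["rate"] == 0).all()

    def test_gene_set_split(self):
        rgs = pd.DataFrame(
            [
                {"sample": "a", "gene": "G1", "rg_type": "hom"},
                {"sample": "b", "gene": "G2", "rg_type": "comphet"},
            ]
        )
        rates = rg.tabulate_rg_rates(rgs, 10, gene_sets={"known": {"G1"}})
        known = rates[rates["gene_set"] == "known"].set_index("rg_type")
        assert known.loc["total", "count"] == 1
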