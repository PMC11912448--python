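import numpy as np
import pandas as pd
import pytest

from recburden import simulate as sim


def make_variant(
    vid="1:100:A:T",
    gene="GENEA",
    consequence="missense",
    metasvm="D",
    cadd=None,
    af1=1e-4,
    af2=1e-4,
    segdup=False,
):
    chrom, pos, ref, alt = vid.split(":")
    return {
        "variant_id": vid,
        "chrom": chrom,
        "pos": int(pos),
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "consequence": consequence,
        "metasvm": metasvm,
        "cadd": cadd,
        "af_panel1": af1,
        "af_panel2": af2,
        "segdup": segdup,
    }


def make_genotype(sample, vid, dosage, hap1=None, hap2=None, **qc):
    if hap1 is None:
        hap1, hap2 = (1, 1) if dosage == 2 else (1, 0)
    row = {
        "sample": sample,
        "variant_id": vid,
        "hap1": hap1,
        "hap2": hap2,
        "dosage": dosage,
        "gq": 99,
        "dp": 40,
        "mq": 60.0,
        "alt_reads": 40 if dosage == 2 else 20,
    }
    row.update(qc)
    return row


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-trio cohort with planted causal genes and some consanguinity."""
    causal = [(f"GENE{i + 1:05d}", 1.0) for i in range(10)]
    cfg = sim.SimConfig(
        n_trios=150,
        n_singletons=40,
        n_genes=120,
        seed=11,
        causal_genes=causal,
        target_attributable_fraction=0.05,
        generate_markers=False,
    )
    panel = sim.simulate_gene_panel(cfg)
    cohort = sim.simulate_trios(cfg, panel)
    return cfg, panel, cohort


@pytest.fixture(scope="session")
def trios_frame(small_cohort):
    _, _, cohort = small_cohort
    ped = cohort.pedigree
    t = ped[(ped["father"] != "0") & (ped["mother"] != "0")]
    return t.rename(columns={"sample": "proband"})[
        ["proband", "father", "mother"]
    ].reset_index(drop=True)


@pytest.fixture(scope="session")
def truth_f_table(small_cohort):
    _, _, cohort = small_cohort
    ped = cohort.pedigree
    truth = cohort.truth_probands.set_index("sample")["true_F"]
    return pd.DataFrame(
        {
            "sample": ped["sample"],
            "F": ped["sample"].map(truth).fillna(0.0),
        }
    )


def random_trio_genotypes(rng, n_trios=50, n_genes=8, n_var_per_gene=4, p_carrier=0.25):
    """Dense random trio genotypes for caller-vs-oracle comparisons.

    Parental dosages are random in {0,1}; the proband is het at a site iff
    at least one parent carries it (so transmission is plausible but phase
    must be worked out by the caller).
    """
    variants = []
    for g in range(n_genes):
        for j in range(n_var_per_gene):
            variants.append(
                make_variant(
                    vid=f"1:{g * 1000 + j + 1}:A:T",
                    gene=f"G{g}",
                    consequence=rng.choice(
                        ["stopgain", "missense", "synonymous", "nonframeshift_indel"]
                    ),
                    metasvm=rng.choice(["D", "T"]),
                    cadd=float(rng.uniform(0, 45)),
                    af1=float(rng.uniform(0, 9e-4)),
                )
            )
    vdf = pd.DataFrame(variants)
    rows = []
    trios = []
    for t in range(n_trios):
        p, f, m = f"P{t}", f"F{t}", f"M{t}"
        trios.append({"proband": p, "father": f, "mother": m})
        for v in vdf["variant_id"]:
            fd = int(rng.random() < p_carrier)
            md = int(rng.random() < p_carrier)
            if fd:
                rows.append(make_genotype(f, v, fd))
            if md:
                rows.append(make_genotype(m, v, md))
            if (fd or md) and rng.random() < 0.7:
                rows.append(make_genotype(p, v, 1))
    return pd.DataFrame(rows), pd.DataFrame(trios), vdf
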