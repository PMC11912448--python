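"""Attributable-fraction estimation from parental depletion of recessive
genotypes.

Parents of affected children are (relative to mutation-frequency
expectation) depleted of damaging biallelic genotypes that cause severe
disease, while probands are enriched. Comparing observed/expected RG counts
in probands against the same ratio in their parents yields the fraction of
probands whose disease is attributable to the variant class:

    fraction = (obs_probands - exp_probands * obs_parents / exp_parents) / n_probands

Expected counts come from parental in-cohort allele frequencies: with
per-gene damaging allele-frequency sum Q_g, individual i with inbreeding
coefficient F_i expects

    sum_g (1 - F_i) * Q_g**2 + F_i * Q_g

biallelic genotypes (random mating needs two independent alleles;
autozygosity needs one). Genotypes are QC-filtered in all three trio
members, and same-gene variant pairs that nearly always co-occur in
carriers are pruned to the more common member so the Q_g sum is not
inflated by alleles on one haplotype. The synonymous class is the negative
control: its fraction should be ~0 on calibrated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from recburden import rg as rg_mod
from recburden.variants import classify_table, qc_mask, rare_mask

#: same-gene pairs co-occurring in more than this fraction of the rarer
#: member's carriers are pruned (carrier-co-occurrence stand-in for LD pruning)
PRUNE_COOCCURRENCE = 0.5


@dataclass
class ContributionEstimate:
    variant_class: str
    exp_parents: float
    obs_parents: int
    exp_probands: float
    obs_probands: int
    n_probands: int
    fraction: float
    ci: tuple[float, float] | None = None
    n_warning: bool = False


def attributable_fraction(
    exp_parents: float,
    obs_parents: float,
    exp_probands: float,
    obs_probands: float,
    n_probands: int,
) -> float:
    """Point estimate of the attributable fraction (may be negative)."""
    if exp_parents <= 0 or exp_probands <= 0:
        raise ValueError("expected counts must be positive")
    return (obs_probands - exp_probands * obs_parents / exp_parents) / n_probands


def _class_variants(variants: pd.DataFrame, variant_class: str, af_threshold: float) -> pd.DataFrame:
    v = variants if "vclass" in variants.columns else classify_table(variants)
    v = v[rare_mask(v, threshold=af_threshold)]
    if variant_class == "damaging":
        return v[v["damaging"]]
    if variant_class == "LoF":
        return v[v["vclass"] == "LoF"]
    if variant_class == "synonymous":
        return v[v["vclass"] == "synonymous"]
    raise ValueError(f"unknown variant class: {variant_class}")


def _qc_filter_trios(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    trios: pd.DataFrame,
) -> pd.DataFrame:
    """Drop a variant from a trio when any member's genotype fails QC.

    Samples without an entry at a variant are homozygous reference and pass
    trivially.
    """
    if not {"gq", "dp", "mq", "alt_reads"}.issubset(genotypes.columns):
        return genotypes
    member_to_trio = {}
    for i, row in enumerate(trios.itertuples(index=False)):
        member_to_trio[row.proband] = i
        member_to_trio[row.father] = i
        member_to_trio[row.mother] = i
    ok = qc_mask(genotypes, variants)
    trio_idx = genotypes["sample"].map(member_to_trio)
    bad = genotypes.loc[(~ok) & trio_idx.notna(), ["variant_id"]].assign(
        trio=trio_idx[(~ok) & trio_idx.notna()]
    )
    if bad.empty:
        return genotypes[ok | trio_idx.isna()]
    bad_keys = set(zip(bad["variant_id"], bad["trio"]))
    keys = list(zip(genotypes["variant_id"], trio_idx))
    keep = np.array([k not in bad_keys for k in keys])
    return genotypes[keep]


def _prune_cooccurring(
    parent_gt: pd.DataFrame,
    v: pd.DataFrame,
    threshold: float = PRUNE_COOCCURRENCE,
) -> set[str]:
    """Variant ids to drop: the rarer member of near-always co-carried pairs."""
    drop: set[str] = set()
    gt = parent_gt.merge(v[["variant_id", "gene"]], on="variant_id")
    carriers = {
        vid: set(grp["sample"]) for vid, grp in gt.groupby("variant_id", sort=False)
    }
    for _, grp in gt.groupby("gene", sort=False):
        vids = grp["variant_id"].unique()
        for i in range(len(vids)):
            for j in range(i + 1, len(vids)):
                a, b = vids[i], vids[j]
                ca, cb = carriers[a], carriers[b]
                shared = len(ca & cb)
                if shared == 0:
                    continue
                if shared > threshold * min(len(ca), len(cb)):
                    drop.add(a if len(ca) <= len(cb) else b)
    return drop


def gene_frequency_sums(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    parents: list[str],
    variant_class: str = "damaging",
    af_threshold: float = 1e-3,
    prune_threshold: float = PRUNE_COOCCURRENCE,
) -> pd.Series:
    """Per-gene allele-frequency sums Q_g from parental in-cohort frequencies."""
    v = _class_variants(variants, variant_class, af_threshold)
    parent_gt = genotypes[genotypes["sample"].isin(set(parents))]
    parent_gt = parent_gt[parent_gt["variant_id"].isin(set(v["variant_id"]))]
    drop = _prune_cooccurring(parent_gt, v, prune_threshold)
    parent_gt = parent_gt[~parent_gt["variant_id"].isin(drop)]
    denom = 2 * len(parents)
    q = parent_gt.groupby("variant_id")["dosage"].sum() / denom
    gene_of = v.set_index("variant_id")["gene"]
    return q.groupby(gene_of.reindex(q.index)).sum()


def _expected_for(F: np.ndarray, S1: float, S2: float) -> float:
    """Sum over individuals of (1-F_i)*S2 + F_i*S1 with S_k = sum_g Q_g^k."""
    F = np.asarray(F, dtype=float)
    return float(((1.0 - F) * S2 + F * S1).sum())


def _observed_parent_rgs(
    parent_gt: pd.DataFrame, v: pd.DataFrame
) -> pd.DataFrame:
    """Parental RGs from phased genotypes: hom, or alleles on both haplotypes.

    Requires hap1/hap2 columns (phase is known in simulated or
    statistically phased data); one RG per (sample, gene).
    """
    if not {"hap1", "hap2"}.issubset(parent_gt.columns):
        raise ValueError("parental comphet counting requires phased hap1/hap2 columns")
    gt = parent_gt.merge(v[["variant_id", "gene"]], on="variant_id")
    grp = gt.groupby(["sample", "gene"])[["hap1", "hap2"]].max()
    biallelic = grp[(grp["hap1"] > 0) & (grp["hap2"] > 0)]
    return biallelic.reset_index()[["sample", "gene"]]


def expected_rg_counts(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    trios: pd.DataFrame,
    f_table: pd.DataFrame,
    variant_class: str = "damaging",
    af_threshold: float = 1e-3,
    apply_qc: bool = True,
    prune_threshold: float = PRUNE_COOCCURRENCE,
) -> tuple[float, float]:
    """(expected RGs in parents, expected RGs in probands) for one class.

    Convenience around the expectation half of :func:`estimate_contribution`.
    """
    if apply_qc:
        genotypes = _qc_filter_trios(genotypes, variants, trios)
    parents = list(trios["father"]) + list(trios["mother"])
    Q = gene_frequency_sums(
        genotypes, variants, parents, variant_class, af_threshold, prune_threshold
    )
    S1, S2 = float(Q.sum()), float((Q**2).sum())
    F = f_table.set_index("sample")["F"]
    exp_parents = _expected_for(F.loc[trios["father"]].to_numpy(), S1, S2) + _expected_for(
        F.loc[trios["mother"]].to_numpy(), S1, S2
    )
    exp_probands = _expected_for(F.loc[trios["proband"]].to_numpy(), S1, S2)
    return exp_parents, exp_probands


def estimate_contribution(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    trios: pd.DataFrame,
    f_table: pd.DataFrame,
    variant_class: str = "damaging",
    af_threshold: float = 1e-3,
    apply_qc: bool = True,
    prune_threshold: float = PRUNE_COOCCURRENCE,
    bootstrap: int = 0,
    seed: int = 0,
) -> ContributionEstimate:
    """Full attributable-fraction estimate for one variant class.

    ``trios`` has columns proband, father, mother; ``f_table`` maps every
    trio member to an inbreeding coefficient (columns sample, F). With
    ``bootstrap`` > 0, a percentile CI over trio resamples is attached.
    """
    missing_f = (
        set(trios["proband"]) | set(trios["father"]) | set(trios["mother"])
    ) - set(f_table["sample"])
    if missing_f:
        raise ValueError(f"missing F for samples: {sorted(missing_f)[:5]}...")
    if apply_qc:
        genotypes = _qc_filter_trios(genotypes, variants, trios)

    v = _class_variants(variants, variant_class, af_threshold)
    parents = list(trios["father"]) + list(trios["mother"])
    probands = list(trios["proband"])
    n_trios = len(trios)

    parent_gt = genotypes[genotypes["sample"].isin(set(parents))]
    parent_gt = parent_gt[parent_gt["variant_id"].isin(set(v["variant_id"]))]
    drop = _prune_cooccurring(parent_gt, v, prune_threshold)
    kept_gt = parent_gt[~parent_gt["variant_id"].isin(drop)]

    F = f_table.set_index("sample")["F"]
    F_father = F.loc[trios["father"]].to_numpy()
    F_mother = F.loc[trios["mother"]].to_numpy()
    F_proband = F.loc[trios["proband"]].to_numpy()

    gene_of = v.set_index("variant_id")["gene"]
    q = kept_gt.groupby("variant_id")["dosage"].sum() / (2 * len(parents))
    Q = q.groupby(gene_of.reindex(q.index)).sum()
    S1, S2 = float(Q.sum()), float((Q**2).sum())

    exp_parents = _expected_for(F_father, S1, S2) + _expected_for(F_mother, S1, S2)
    exp_probands = _expected_for(F_proband, S1, S2)

    # observed: probands via trio calling, parents via phased genotypes
    cf = {"damaging": "damaging", "LoF": "LoF", "synonymous": "synonymous"}[variant_class]
    proband_gt = genotypes[genotypes["sample"].isin(set(probands))]
    hom = rg_mod.call_homozygotes(proband_gt, variants, cf, af_threshold)
    comphet = rg_mod.call_comphets_trios(
        genotypes, trios, variants, cf, af_threshold, exclude=hom
    )
    proband_rgs = pd.concat([hom, comphet], ignore_index=True)
    if variant_class == "LoF":
        proband_rgs = proband_rgs[proband_rgs["damaging_class"] == "LoF_LoF"]
    obs_probands = len(proband_rgs)
    parent_rgs = _observed_parent_rgs(parent_gt, v)
    obs_parents = len(parent_rgs)

    fraction = attributable_fraction(
        exp_parents, obs_parents, exp_probands, obs_probands, n_trios
    )
    est = ContributionEstimate(
        variant_class=variant_class,
        exp_parents=exp_parents,
        obs_parents=obs_parents,
        exp_probands=exp_probands,
        obs_probands=obs_probands,
        n_probands=n_trios,
        fraction=fraction,
        n_warning=n_trios < 10,
    )
    if bootstrap:
        est.ci = bootstrap_ci(
            kept_gt,
            gene_of,
            trios,
            F_father,
            F_mother,
            F_proband,
            proband_rgs,
            parent_rgs,
            B=bootstrap,
            seed=seed,
        )
    return est


def bootstrap_ci(
    kept_parent_gt: pd.DataFrame,
    gene_of: pd.Series,
    trios: pd.DataFrame,
    F_father: np.ndarray,
    F_mother: np.ndarray,
    F_proband: np.ndarray,
    proband_rgs: pd.DataFrame,
    parent_rgs: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric percentile CI over trio resamples.

    Trios are resampled with replacement; in-cohort allele frequencies,
    expected counts, and observed counts are all recomputed per resample
    (the co-occurrence pruning mask is held fixed).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    n_trios = len(trios)
    trio_index = {p: i for i, p in enumerate(trios["proband"])}
    for col in ("father", "mother"):
        trio_index.update({s: i for i, s in enumerate(trios[col])})

    genes = pd.Index(sorted(gene_of.unique()))
    vids = kept_parent_gt["variant_id"].unique()
    vid_index = {vid: i for i, vid in enumerate(vids)}
    gene_row = gene_of.reindex(vids).map({g: i for i, g in enumerate(genes)})

    # A[v, t] = parental allele count of variant v in trio t
    gt = kept_parent_gt
    A = sparse.coo_matrix(
        (
            gt["dosage"].to_numpy(dtype=float),
            (
                gt["variant_id"].map(vid_index).to_numpy(),
                gt["sample"].map(trio_index).to_numpy(),
            ),
        ),
        shape=(len(vids), n_trios),
    ).tocsr()
    # M[g, v] sums variants into genes
    M = sparse.coo_matrix(
        (np.ones(len(vids)), (gene_row.to_numpy(), np.arange(len(vids)))),
        shape=(len(genes), len(vids)),
    ).tocsr()

    obs_prob_per_trio = np.zeros(n_trios)
    if len(proband_rgs):
        c = proband_rgs["sample"].map(trio_index).value_counts()
        obs_prob_per_trio[c.index.to_numpy(dtype=int)] = c.to_numpy()
    obs_par_per_trio = np.zeros(n_trios)
    if len(parent_rgs):
        c = parent_rgs["sample"].map(trio_index).value_counts()
        obs_par_per_trio[c.index.to_numpy(dtype=int)] = c.to_numpy()

    rng = np.random.default_rng(seed)
    W = rng.multinomial(n_trios, np.full(n_trios, 1.0 / n_trios), size=B).T  # trios x B
    Qmat = np.asarray(M @ (A @ W)) / (2.0 * 2 * n_trios)  # genes x B
    S1 = Qmat.sum(axis=0)
    S2 = (Qmat**2).sum(axis=0)
    one_minus_F_par = (2.0 - F_father - F_mother) @ W
    F_par = (F_father + F_mother) @ W
    exp_parents = one_minus_F_par * S2 + F_par * S1
    exp_probands = ((1.0 - F_proband) @ W) * S2 + (F_proband @ W) * S1
    obs_parents = obs_par_per_trio @ W
    obs_probands = obs_prob_per_trio @ W
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (obs_probands - exp_probands * obs_parents / exp_parents) / n_trios
    frac = frac[np.isfinite(frac)]
    lo, hi = np.quantile(frac, [(1 - level) / 2, 1 - (1 - level) / 2])
    return (float(lo), float(hi))


def stratified_contribution(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    trios: pd.DataFrame,
    f_table: pd.DataFrame,
    strata: pd.Series,
    variant_class: str = "damaging",
    shared_frequencies: bool = False,
    shared_parent_ratio: bool = False,
    **kwargs,
) -> dict[str, ContributionEstimate]:
    """One attributable-fraction estimate per proband stratum.

    ``strata`` maps proband id -> stratum label (consanguinity class,
    phenotype subgroup, ancestry). By default in-cohort frequencies are
    recomputed within each stratum; ``shared_frequencies`` instead reuses
    whole-cohort frequencies, and ``shared_parent_ratio`` additionally
    applies the whole-cohort parental depletion ratio, under which the
    whole-cohort estimate is exactly the trio-weighted combination of
    stratum estimates.
    """
    results: dict[str, ContributionEstimate] = {}
    whole = None
    shared_S: tuple[float, float] | None = None
    if shared_frequencies or shared_parent_ratio:
        whole = estimate_contribution(
            genotypes, variants, trios, f_table, variant_class, **kwargs
        )
    if shared_frequencies:
        parents = list(trios["father"]) + list(trios["mother"])
        Q = gene_frequency_sums(
            _qc_filter_trios(genotypes, variants, trios)
            if kwargs.get("apply_qc", True)
            else genotypes,
            variants,
            parents,
            variant_class,
            kwargs.get("af_threshold", 1e-3),
            kwargs.get("prune_threshold", PRUNE_COOCCURRENCE),
        )
        shared_S = (float(Q.sum()), float((Q**2).sum()))

    labels = strata.reindex(trios["proband"]).to_numpy()
    for stratum, probands in trios.groupby(labels):
        sub_trios = probands.reset_index(drop=True)
        est = estimate_contribution(
            genotypes, variants, sub_trios, f_table, variant_class, **kwargs
        )
        if shared_S is not None:
            # replace in-stratum frequencies with whole-cohort ones
            S1, S2 = shared_S
            F = f_table.set_index("sample")["F"]
            est.exp_parents = _expected_for(
                F.loc[sub_trios["father"]].to_numpy(), S1, S2
            ) + _expected_for(F.loc[sub_trios["mother"]].to_numpy(), S1, S2)
            est.exp_probands = _expected_for(
                F.loc[sub_trios["proband"]].to_numpy(), S1, S2
            )
            est.fraction = attributable_fraction(
                est.exp_parents,
                est.obs_parents,
                est.exp_probands,
                est.obs_probands,
                est.n_probands,
            )
        if shared_parent_ratio and whole is not None and whole.exp_parents > 0:
            ratio = whole.obs_parents / whole.exp_parents
            est.fraction = (
                est.obs_probands - est.exp_probands * ratio
            ) / est.n_probands
        results[str(stratum)] = est
    return results
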