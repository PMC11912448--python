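"""Recessive-genotype (RG) calling.

An RG is a biallelic damaging genotype in one gene for one sample:

* ``hom`` — a rare damaging homozygote (called in every proband);
* ``comphet`` — two rare damaging heterozygotes in the same gene phased in
  trans through the parents (trio samples);
* ``inferred_comphet`` — in parentless samples, a same-gene pair predicted
  in trans because the two variants never co-occur in a reference panel.

A sample contributes at most one RG per gene: homozygotes take precedence
over compound heterozygotes, and when more than two qualifying heterozygotes
exist the single reported pair carries the two most damaging alleles
(LoF > D-mis > nonframeshift indel, ties broken by lower allele frequency
then position). Synonymous RGs are callable as a negative-control stream via
``class_filter="synonymous"``.

Genotype tables are long-form DataFrames with one row per carried allele:
columns ``sample, variant_id, dosage`` (1 or 2) and optional QC fields.
Samples absent from the table at a variant are homozygous reference.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from recburden.variants import CLASS_SEVERITY, classify_table, rare_mask

logger = logging.getLogger(__name__)

RG_COLUMNS = [
    "sample",
    "gene",
    "rg_type",
    "variant1",
    "variant2",
    "damaging_class",
    "phase_evidence",
]


def _empty_rg_table() -> pd.DataFrame:
    return pd.DataFrame(columns=RG_COLUMNS)


def _prepare_variants(
    variants: pd.DataFrame,
    class_filter: str,
    af_threshold: float,
) -> pd.DataFrame:
    """Classify (if needed), rarity-filter, and restrict to one class stream."""
    v = variants
    if "vclass" not in v.columns:
        v = classify_table(v)
    v = v[rare_mask(v, threshold=af_threshold)]
    if class_filter == "damaging":
        v = v[v["damaging"]]
    elif class_filter == "synonymous":
        v = v[v["vclass"] == "synonymous"]
    elif class_filter == "LoF":
        v = v[v["vclass"] == "LoF"]
    else:
        raise ValueError(f"unknown class_filter: {class_filter}")
    v = v.copy()
    v["severity"] = v["vclass"].map(CLASS_SEVERITY).fillna(3).astype(int)
    v["af_rank"] = (
        pd.to_numeric(v["af_panel1"], errors="coerce")
        .fillna(pd.to_numeric(v["af_panel2"], errors="coerce"))
        .fillna(0.0)
    )
    return v


def _damaging_class(vclasses: list[str], class_filter: str) -> str:
    if class_filter == "synonymous":
        return "synonymous"
    return "LoF_LoF" if all(c == "LoF" for c in vclasses) else "contains_Dmis"


def call_homozygotes(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    class_filter: str = "damaging",
    af_threshold: float = 1e-3,
) -> pd.DataFrame:
    """One ``hom`` RG per (sample, gene) with a rare qualifying homozygote."""
    v = _prepare_variants(variants, class_filter, af_threshold)
    hom = genotypes[genotypes["dosage"] == 2].merge(
        v[["variant_id", "gene", "vclass", "severity", "af_rank", "pos"]],
        on="variant_id",
    )
    if hom.empty:
        return _empty_rg_table()
    hom = hom.sort_values(["severity", "af_rank", "pos"], kind="stable")
    best = hom.groupby(["sample", "gene"], sort=False).first().reset_index()
    return pd.DataFrame(
        {
            "sample": best["sample"],
            "gene": best["gene"],
            "rg_type": "hom",
            "variant1": best["variant_id"],
            "variant2": None,
            "damaging_class": [
                _damaging_class([c, c], class_filter) for c in best["vclass"]
            ],
            "phase_evidence": "homozygous",
        }
    )


def _het_with_parental_origin(
    genotypes: pd.DataFrame,
    trios: pd.DataFrame,
    v: pd.DataFrame,
) -> pd.DataFrame:
    """Proband het rows annotated with parental origin (ambiguous excluded).

    Origin requires the carrying parent to have the allele and the other
    parent to lack it; sites carried by both parents are phase-ambiguous and
    conservatively excluded.
    """
    het = genotypes[genotypes["dosage"] == 1].merge(
        v[["variant_id", "gene", "vclass", "severity", "af_rank", "pos"]],
        on="variant_id",
    )
    het = het.merge(trios, left_on="sample", right_on="proband")
    dos = genotypes.set_index(["sample", "variant_id"])["dosage"]
    f_idx = pd.MultiIndex.from_arrays([het["father"], het["variant_id"]])
    m_idx = pd.MultiIndex.from_arrays([het["mother"], het["variant_id"]])
    het["father_dos"] = dos.reindex(f_idx).fillna(0).to_numpy()
    het["mother_dos"] = dos.reindex(m_idx).fillna(0).to_numpy()
    maternal = (het["mother_dos"] > 0) & (het["father_dos"] == 0)
    paternal = (het["father_dos"] > 0) & (het["mother_dos"] == 0)
    neither = (het["father_dos"] == 0) & (het["mother_dos"] == 0)
    if neither.any():
        logger.info(
            "%d proband het sites carried by neither parent skipped", neither.sum()
        )
    het["origin"] = np.where(maternal, "maternal", np.where(paternal, "paternal", ""))
    return het[het["origin"] != ""]


def call_comphets_trios(
    genotypes: pd.DataFrame,
    trios: pd.DataFrame,
    variants: pd.DataFrame,
    class_filter: str = "damaging",
    af_threshold: float = 1e-3,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Trio-phased compound heterozygotes for every trio in ``trios``.

    ``trios`` has columns proband, father, mother. An RG requires at least
    one qualifying allele inherited from each parent (trans); cis pairs are
    excluded. (sample, gene) pairs listed in ``exclude`` (e.g. homozygote
    calls) are skipped.
    """
    v = _prepare_variants(variants, class_filter, af_threshold)
    het = _het_with_parental_origin(genotypes, trios, v)
    if het.empty:
        return _empty_rg_table()
    if exclude is not None and len(exclude):
        key = het["sample"].astype(str) + "\x00" + het["gene"].astype(str)
        drop = set(
            exclude["sample"].astype(str) + "\x00" + exclude["gene"].astype(str)
        )
        het = het[~key.isin(drop)]
    if het.empty:
        return _empty_rg_table()
    het = het.sort_values(["severity", "af_rank", "pos"], kind="stable")
    best = (
        het.groupby(["sample", "gene", "origin"], sort=False)
        .first()
        .reset_index()
        .pivot(index=["sample", "gene"], columns="origin")
    )
    if (
        "maternal" not in best["variant_id"].columns
        or "paternal" not in best["variant_id"].columns
    ):
        return _empty_rg_table()
    both = best[
        best[("variant_id", "maternal")].notna()
        & best[("variant_id", "paternal")].notna()
    ]
    if both.empty:
        return _empty_rg_table()
    idx = both.index.to_frame(index=False)
    return pd.DataFrame(
        {
            "sample": idx["sample"],
            "gene": idx["gene"],
            "rg_type": "comphet",
            "variant1": both[("variant_id", "maternal")].to_numpy(),
            "variant2": both[("variant_id", "paternal")].to_numpy(),
            "damaging_class": [
                _damaging_class([a, b], class_filter)
                for a, b in zip(
                    both[("vclass", "maternal")], both[("vclass", "paternal")]
                )
            ],
            "phase_evidence": "trio",
        }
    )


def call_comphet_trio(
    proband_gt: pd.DataFrame,
    father_gt: pd.DataFrame,
    mother_gt: pd.DataFrame,
    variants: pd.DataFrame,
    proband: str = "proband",
    father: str = "father",
    mother: str = "mother",
    **kwargs,
) -> pd.DataFrame:
    """Single-trio convenience wrapper around :func:`call_comphets_trios`."""
    genotypes = pd.concat([proband_gt, father_gt, mother_gt], ignore_index=True)
    trios = pd.DataFrame(
        {"proband": [proband], "father": [father], "mother": [mother]}
    )
    return call_comphets_trios(genotypes, trios, variants, **kwargs)


def cooccurrence_lookup(panel: pd.DataFrame) -> dict[frozenset, int]:
    """Index a co-occurrence panel table (variant_a, variant_b, count)."""
    return {
        frozenset((a, b)): int(c)
        for a, b, c in zip(panel["variant_a"], panel["variant_b"], panel["count"])
    }


def call_comphets_singletons(
    genotypes: pd.DataFrame,
    singletons: list[str] | pd.Series,
    variants: pd.DataFrame,
    cooccurrence: pd.DataFrame | dict,
    class_filter: str = "damaging",
    af_threshold: float = 1e-3,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inferred compound heterozygotes in parentless samples.

    A same-gene rare qualifying het pair becomes an ``inferred_comphet`` iff
    its co-occurrence count in the reference panel is zero; pairs absent from
    the panel index are treated as count zero (logged).
    """
    lookup = (
        cooccurrence
        if isinstance(cooccurrence, dict)
        else cooccurrence_lookup(cooccurrence)
    )
    v = _prepare_variants(variants, class_filter, af_threshold)
    het = genotypes[
        (genotypes["dosage"] == 1) & genotypes["sample"].isin(set(singletons))
    ].merge(
        v[["variant_id", "gene", "vclass", "severity", "af_rank", "pos"]],
        on="variant_id",
    )
    excluded = set()
    if exclude is not None and len(exclude):
        excluded = set(zip(exclude["sample"], exclude["gene"]))
    rows = []
    n_unindexed = 0
    for (sample, gene), grp in het.groupby(["sample", "gene"], sort=False):
        if len(grp) < 2 or (sample, gene) in excluded:
            continue
        grp = grp.sort_values(["severity", "af_rank", "pos"], kind="stable")
        best = None
        for a, b in itertools.combinations(range(len(grp)), 2):
            ra, rb = grp.iloc[a], grp.iloc[b]
            pair = frozenset((ra["variant_id"], rb["variant_id"]))
            if pair not in lookup:
                n_unindexed += 1
            if lookup.get(pair, 0) == 0:
                best = (ra, rb)
                break  # rows pre-sorted: first zero-count pair is most damaging
        if best is not None:
            ra, rb = best
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "rg_type": "inferred_comphet",
                    "variant1": ra["variant_id"],
                    "variant2": rb["variant_id"],
                    "damaging_class": _damaging_class(
                        [ra["vclass"], rb["vclass"]], class_filter
                    ),
                    "phase_evidence": "panel_absence",
                }
            )
    if n_unindexed:
        logger.info(
            "%d candidate pairs absent from co-occurrence index (count=0 assumed)",
            n_unindexed,
        )
    return pd.DataFrame(rows, columns=RG_COLUMNS) if rows else _empty_rg_table()


def call_rgs(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    variants: pd.DataFrame,
    cooccurrence: pd.DataFrame | dict | None = None,
    class_filter: str = "damaging",
    af_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Full cohort RG calling: homozygotes, trio comphets, singleton ICHs.

    ``pedigree`` is PED-shaped with columns sample, father, mother (father
    and mother "0" for founders/singletons); only probands (samples whose
    parents are absent or listed) are called — parents are never probands
    here.
    """
    probands = pedigree[(pedigree["father"] != "0") & (pedigree["mother"] != "0")]
    trios = probands.rename(columns={"sample": "proband"})[
        ["proband", "father", "mother"]
    ]
    singleton_ids = pedigree.loc[
        (pedigree["father"] == "0")
        & (pedigree["mother"] == "0")
        & (~pedigree["sample"].isin(set(probands["father"]) | set(probands["mother"]))),
        "sample",
    ]
    proband_ids = set(trios["proband"]) | set(singleton_ids)
    proband_gt = genotypes[genotypes["sample"].isin(proband_ids)]

    hom = call_homozygotes(proband_gt, variants, class_filter, af_threshold)
    comphet = call_comphets_trios(
        genotypes, trios, variants, class_filter, af_threshold, exclude=hom
    )
    parts = [hom, comphet]
    if cooccurrence is not None and len(singleton_ids):
        parts.append(
            call_comphets_singletons(
                genotypes,
                singleton_ids,
                variants,
                cooccurrence,
                class_filter,
                af_threshold,
                exclude=hom,
            )
        )
    rgs = pd.concat(parts, ignore_index=True)
    return rgs.sort_values(["sample", "gene"], kind="stable").reset_index(drop=True)


def tabulate_rg_rates(
    rgs: pd.DataFrame,
    n_samples: int,
    gene_sets: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-cohort RG counts and per-individual rates by type and gene set.

    Rate is genotypes per individual; counts x n_samples reproduce totals
    exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    sets = {"all_genes": None}
    if gene_sets:
        sets.update(gene_sets)
    rows = []
    for set_name, genes in sets.items():
        sub = rgs if genes is None else rgs[rgs["gene"].isin(genes)]
        counts = sub["rg_type"].value_counts() if len(sub) else pd.Series(dtype=int)
        hom = int(counts.get("hom", 0))
        ch = int(counts.get("comphet", 0)) + int(counts.get("inferred_comphet", 0))
        for rg_type, n in (("hom", hom), ("comphet", ch), ("total", hom + ch)):
            rows.append(
                {
                    "gene_set": set_name,
                    "rg_type": rg_type,
                    "count": n,
                    "rate": n / n_samples,
                }
            )
    return pd.DataFrame(rows)
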