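"""Variant classification, rarity filtering, and genotype-level QC.

Variants arrive as annotated records (consequence, MetaSVM call, CADD score,
two reference-panel allele frequencies, segmental-duplication flag) and are
partitioned into five mutually exclusive classes:

* ``LoF`` — stopgain, stoploss, frameshift indel, or canonical splice site;
* ``Dmis`` — missense predicted deleterious by MetaSVM and/or CADD >= 30;
* ``nonframeshift_indel`` — in-frame indels, counted as damaging;
* ``synonymous`` — the negative-control stream;
* ``non_damaging`` — everything else (including missense failing both scores).

``damaging`` means ``LoF | Dmis | nonframeshift_indel``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: consequences that define a likely loss-of-function allele
LOF_CONSEQUENCES = frozenset(
    {"stopgain", "stoploss", "frameshift_indel", "canonical_splice"}
)

#: default rarity threshold on the reference-panel allele frequency
RARE_AF_THRESHOLD = 1e-3

#: default CADD cutoff for damaging missense
CADD_THRESHOLD = 30.0

DAMAGING_CLASSES = frozenset({"LoF", "Dmis", "nonframeshift_indel"})

#: ranking used when a single most-damaging pair must be chosen
CLASS_SEVERITY = {"LoF": 0, "Dmis": 1, "nonframeshift_indel": 2}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele (multi-allelics pre-decomposed)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    metasvm: str | None = None  # "D", "T" or None
    cadd: float | None = None
    af_panel1: float | None = None
    af_panel2: float | None = None
    segdup: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        for af in (self.af_panel1, self.af_panel2):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {af}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeEntry:
    """Per-sample genotype with the QC fields used in contribution estimation."""

    sample: str
    variant: str
    dosage: int
    gq: int = 99
    dp: int = 40
    mq: float = 60.0
    alt_reads: int = 20

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.dp if self.dp > 0 else 0.0


def classify_variant(
    consequence: str,
    metasvm: str | None = None,
    cadd: float | None = None,
    cadd_threshold: float = CADD_THRESHOLD,
) -> str:
    """Assign one of the five variant classes.

    Missing MetaSVM with CADD present: D-mis is decided by CADD alone
    (either score suffices). Nonframeshift indels are damaging
    unconditionally.
    """
    if consequence in LOF_CONSEQUENCES:
        return "LoF"
    if consequence == "missense":
        if metasvm == "D" or (cadd is not None and cadd >= cadd_threshold):
            return "Dmis"
        return "non_damaging"
    if consequence == "nonframeshift_indel":
        return "nonframeshift_indel"
    if consequence == "synonymous":
        return "synonymous"
    return "non_damaging"


def is_rare(
    af_panel1: float | None,
    af_panel2: float | None,
    threshold: float = RARE_AF_THRESHOLD,
    missing_is_rare: bool = True,
) -> bool:
    """True iff the allele frequency is below ``threshold`` in both panels.

    Absence from a reference panel is treated as evidence of rarity by
    default (``missing_is_rare``).
    """
    for af in (af_panel1, af_panel2):
        if af is None or (isinstance(af, float) and np.isnan(af)):
            if not missing_is_rare:
                return False
        elif af >= threshold:
            return False
    return True


def passes_genotype_qc(
    gq: float,
    dp: float,
    mq: float,
    alt_reads: float,
    segdup: bool,
    min_gq: float = 20,
    min_dp: float = 8,
    min_mq: float = 40,
    min_vaf: float = 0.25,
    min_alt_reads: float = 3,
) -> bool:
    """Six-criterion genotype filter used in the contribution stage.

    GQ >= 20, DP >= 8, MQ >= 40, variant allele fraction >= 25%, at least
    three supporting reads, and not in a segmental-duplication region.
    Not applied during gene-discovery RG calling.
    """
    vaf = alt_reads / dp if dp > 0 else 0.0
    return (
        gq >= min_gq
        and dp >= min_dp
        and mq >= min_mq
        and vaf >= min_vaf
        and alt_reads >= min_alt_reads
        and not segdup
    )


# ---------------------------------------------------------------------------
# vectorised table interface
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "metasvm",
    "cadd",
    "af_panel1",
    "af_panel2",
    "segdup",
]


def classify_table(
    variants: pd.DataFrame, cadd_threshold: float = CADD_THRESHOLD
) -> pd.DataFrame:
    """Add ``vclass`` (five-way class) and ``damaging`` columns to a variant table."""
    v = variants.copy()
    cons = v["consequence"]
    cadd = pd.to_numeric(v.get("cadd"), errors="coerce")
    metasvm = v.get("metasvm")

    vclass = np.full(len(v), "non_damaging", dtype=object)
    vclass[cons.isin(LOF_CONSEQUENCES).to_numpy()] = "LoF"
    dmis = (
        (cons == "missense")
        & ((metasvm == "D") | (cadd >= cadd_threshold).fillna(False))
    ).to_numpy()
    vclass[dmis] = "Dmis"
    vclass[(cons == "nonframeshift_indel").to_numpy()] = "nonframeshift_indel"
    vclass[(cons == "synonymous").to_numpy()] = "synonymous"
    v["vclass"] = vclass
    v["damaging"] = v["vclass"].isin(DAMAGING_CLASSES)
    return v


def rare_mask(
    variants: pd.DataFrame,
    threshold: float = RARE_AF_THRESHOLD,
    missing_is_rare: bool = True,
) -> pd.Series:
    """Boolean Series: rare in both reference panels (missing counts as rare)."""
    mask = pd.Series(True, index=variants.index)
    for col in ("af_panel1", "af_panel2"):
        af = pd.to_numeric(variants[col], errors="coerce")
        common = af >= threshold
        mask &= ~common
        if not missing_is_rare:
            mask &= af.notna()
    return mask


def qc_mask(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    min_gq: float = 20,
    min_dp: float = 8,
    min_mq: float = 40,
    min_vaf: float = 0.25,
    min_alt_reads: float = 3,
) -> pd.Series:
    """Vectorised genotype-QC mask for a long genotype table.

    ``genotypes`` needs columns gq, dp, mq, alt_reads, variant_id;
    the segdup flag is looked up from ``variants``.
    """
    segdup = genotypes["variant_id"].map(
        variants.set_index("variant_id")["segdup"]
    ).fillna(False).astype(bool)
    dp = genotypes["dp"].to_numpy(dtype=float)
    alt = genotypes["alt_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(dp > 0, alt / np.where(dp > 0, dp, 1), 0.0)
    ok = (
        (genotypes["gq"].to_numpy(dtype=float) >= min_gq)
        & (dp >= min_dp)
        & (genotypes["mq"].to_numpy(dtype=float) >= min_mq)
        & (vaf >= min_vaf)
        & (alt >= min_alt_reads)
        & ~segdup.to_numpy()
    )
    return pd.Series(ok, index=genotypes.index)
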