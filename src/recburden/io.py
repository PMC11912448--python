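"""Readers and writers for the standard interchange formats.

VCF v4.2 (GT:AD:DP:GQ per genotype, MQ in INFO) read through cyvcf2,
6-column PED, and the tabular TSVs (variant annotation, mutability,
gene sets, RG tables, F tables). Internally everything is a pandas
DataFrame; multi-allelic sites are decomposed to one record per alternate
allele on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

PED_COLUMNS = ["fam", "sample", "father", "mother", "sex", "phenotype"]


def write_ped(pedigree: pd.DataFrame, path: str) -> None:
    pedigree[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: str) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", header=None, names=PED_COLUMNS, dtype=str)
    ped["sex"] = ped["sex"].astype(int)
    ped["phenotype"] = ped["phenotype"].astype(int)
    return ped


def write_annotation(variants: pd.DataFrame, path: str) -> None:
    cols = [
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
    out = variants[cols].copy()
    out["segdup"] = out["segdup"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str) -> pd.DataFrame:
    v = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "metasvm": "string"},
    )
    v["segdup"] = v["segdup"].astype(bool)
    v["metasvm"] = v["metasvm"].where(v["metasvm"].notna(), None)
    return v


def write_vcf(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    samples: list[str],
    path: str,
    phased: bool = True,
) -> None:
    """Write a cohort VCF v4.2 with GT:AD:DP:GQ fields and MQ in INFO.

    ``genotypes`` is the long carrier table; samples without an entry at a
    variant are emitted as homozygous reference.
    """
    v = variants.sort_values(["chrom", "pos"], kind="stable")
    by_variant: dict[str, dict[str, tuple]] = {}
    has_phase = phased and {"hap1", "hap2"}.issubset(genotypes.columns)
    for row in genotypes.itertuples(index=False):
        gt = by_variant.setdefault(row.variant_id, {})
        if has_phase:
            g = f"{row.hap1}|{row.hap2}"
        else:
            g = "0/1" if row.dosage == 1 else "1/1"
        dp = getattr(row, "dp", 40)
        alt = getattr(row, "alt_reads", dp // 2)
        gq = getattr(row, "gq", 99)
        gt[row.sample] = (g, f"{dp - alt},{alt}", dp, gq)
    sep = "|" if has_phase else "/"
    ref_field = (f"0{sep}0", "40,0", 40, 99)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for i in range(1, 23):
            fh.write(f"##contig=<ID={i}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for row in v.itertuples(index=False):
            gt = by_variant.get(row.variant_id, {})
            cells = []
            for s in samples:
                g, ad, dp, gq = gt.get(s, ref_field)
                cells.append(f"{g}:{ad}:{dp}:{gq}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\tMQ=60.0\tGT:AD:DP:GQ\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> tuple[pd.DataFrame, list[str]]:
    """Read a VCF into the long carrier-genotype table via cyvcf2.

    Returns (genotypes, samples); only non-reference genotypes are kept.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        for alt_i, alt in enumerate(rec.ALT, start=1):
            vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            gts = rec.genotype.array()
            mq = rec.INFO.get("MQ", 60.0)
            depth = rec.format("DP")
            gq = rec.format("GQ")
            ad = rec.format("AD")
            for si, s in enumerate(samples):
                a, b = int(gts[si][0]), int(gts[si][1])
                dosage = int(a == alt_i) + int(b == alt_i)
                if dosage == 0:
                    continue
                phased = bool(gts[si][2]) if gts.shape[1] > 2 else False
                rows.append(
                    {
                        "sample": s,
                        "variant_id": vid,
                        "hap1": int(a == alt_i) if phased else np.nan,
                        "hap2": int(b == alt_i) if phased else np.nan,
                        "dosage": dosage,
                        "gq": int(gq[si][0]) if gq is not None else 99,
                        "dp": int(depth[si][0]) if depth is not None else 40,
                        "mq": float(mq),
                        "alt_reads": int(ad[si][alt_i]) if ad is not None else 20,
                    }
                )
    return pd.DataFrame(rows), samples


def write_tsv(df: pd.DataFrame, path: str, **kwargs) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, **kwargs)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_gene_set(path: str) -> set[str]:
    """One gene symbol per line (first column of a TSV)."""
    df = pd.read_csv(path, sep="\t", header=None)
    return set(df.iloc[:, 0].astype(str))


def read_segdup_bed(path: str) -> pd.DataFrame:
    """0-based half-open BED intervals, converted to 1-based inclusive."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end"], dtype={0: str}
    )
    bed["start"] = bed["start"] + 1
    return bed


def flag_segdup(variants: pd.DataFrame, segdup_bed: pd.DataFrame) -> pd.DataFrame:
    """Set the segdup flag from BED intervals (1-based inclusive after read)."""
    v = variants.copy()
    flag = np.zeros(len(v), dtype=bool)
    for chrom, grp in segdup_bed.groupby("chrom"):
        m = (v["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        pos = v.loc[m, "pos"].to_numpy()
        hit = np.zeros(m.sum(), dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            hit |= (pos >= s) & (pos <= e)
        flag[np.flatnonzero(m)] |= hit
    v["segdup"] = v["segdup"].to_numpy() | flag
    return v
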