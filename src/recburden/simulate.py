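"""Synthetic trio/singleton exome cohorts with ground truth.

The generator emulates the statistical structure the recessive-genotype
analysis assumes, at configurable scale:

* a gene panel whose per-gene damaging allele-frequency sum is proportional
  to a log-normal de novo mutability (every rare variant AF < 1e-3);
* trio transmission: parental haplotypes drawn from the allele frequencies,
  one haplotype transmitted per parent per gene;
* autozygosity as contiguous ROH segments (exponential lengths, genome-wide
  expected autozygous fraction equal to the sample's assigned F), with
  proband homozygosity and both-parent carriage inside segments;
* planted causal recessive genotypes in designated genes at a target
  attributable fraction;
* a reference co-occurrence panel for singleton comphet inference;
* founder haplotypes decaying around a focal allele at a given age;
* a marker channel (common biallelic markers on a uniform map) for
  ROH-based F estimation;
* cell-type expression matrices with planted lineage-specific genes.

All randomness flows through the config seed: identical configs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# severity classes drawn for damaging variants, with sampling weights
_DAMAGING_KINDS = ("LoF", "Dmis", "nonframeshift_indel")
_DAMAGING_WEIGHTS = (0.35, 0.50, 0.15)
_LOF_CONSEQUENCES = ("stopgain", "stoploss", "frameshift_indel", "canonical_splice")

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_trios: int = 200
    n_singletons: int = 50
    n_genes: int = 200
    seed: int = 0
    #: (F value, proportion) mixture assigned to probands
    f_distribution: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.88), (0.004, 0.06), (0.016, 0.04), (0.0625, 0.02)]
    )
    #: (gene id, penetrance) — penetrance weights causal-gene assignment
    causal_genes: list[tuple[str, float]] = field(default_factory=list)
    target_attributable_fraction: float = 0.0
    #: damaging allele-frequency sum per gene = af_scale * mutability
    af_scale: float = 25.0
    #: optional (gene id, in-subpopulation allele frequency, age in generations)
    founder: tuple[str, float, float] | None = None
    map_rate: float = 1.0  # cM per Mb
    # genome model
    n_autosomes: int = 22
    chrom_length_bp: int = 130_000_000
    marker_spacing_bp: int = 100_000
    generate_markers: bool = True
    #: mean autozygous segment length; segment count scales as F*genome/mean
    roh_mean_length_bp: float = 2.0e7
    #: fraction of genotype entries given failing QC fields
    qc_noise: float = 0.0
    #: fraction of variants flagged as segmental-duplication
    segdup_fraction: float = 0.0
    #: probability a planted causal RG is homozygous rather than comphet
    plant_hom_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_trios < 0 or self.n_singletons < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.af_scale < 0:
            raise ValueError("af_scale must be nonnegative")
        props = [p for _, p in self.f_distribution]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("f_distribution proportions must sum to 1")
        if any(not 0.0 <= f <= 1.0 for f, _ in self.f_distribution):
            raise ValueError("F values must lie in [0,1]")
        if not 0.0 <= self.target_attributable_fraction < 1.0:
            raise ValueError("target_attributable_fraction must be in [0,1)")


@dataclass
class GenePanel:
    mutability: pd.Series  # gene -> m_g
    variants: pd.DataFrame  # annotation table incl. true_af, vkind
    genes: pd.DataFrame  # gene, chrom, start, end


@dataclass
class SyntheticCohort:
    genotypes: pd.DataFrame
    pedigree: pd.DataFrame
    truth_probands: pd.DataFrame
    truth_genes: pd.DataFrame
    marker_map: pd.DataFrame | None = None
    marker_genotypes: np.ndarray | None = None  # probands x markers dosages
    marker_samples: list[str] | None = None


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------


def _variant_positions(rng, gene_start: int, k: int) -> np.ndarray:
    return gene_start + np.sort(rng.choice(50_000, size=k, replace=False))


def simulate_gene_panel(config: SimConfig) -> GenePanel:
    """Mutability table and per-gene variant pool.

    Per-gene damaging allele-frequency sum is af_scale * m_g with m_g
    log-normal; each gene's pool contains LoF, D-mis, synonymous, and
    benign-missense variants, all with AF < 1e-3.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"GENE{i + 1:05d}" for i in range(n)]
    mutability = pd.Series(
        rng.lognormal(mean=np.log(1e-5), sigma=0.6, size=n), index=genes, name="mutability"
    )
    chrom = np.array([(i % config.n_autosomes) + 1 for i in range(n)])
    per_chrom = -(-n // config.n_autosomes)
    offset = np.array([i // config.n_autosomes for i in range(n)])
    start = ((offset + 0.5) / per_chrom * (config.chrom_length_bp - 100_000)).astype(
        np.int64
    )
    gene_df = pd.DataFrame(
        {"gene": genes, "chrom": chrom.astype(str), "start": start, "end": start + 50_000}
    )

    rows = []
    for gi, g in enumerate(genes):
        q_dam = config.af_scale * mutability.iloc[gi]
        pools = (
            ("damaging", q_dam),
            ("synonymous", 1.5 * q_dam),
            ("benign_missense", 1.0 * q_dam),
        )
        ks = []
        for kind, total in pools:
            k = max(2, int(rng.poisson(4)))
            if total > 0:
                k = max(k, int(np.ceil(total / 5e-4)))
            ks.append(k)
        # one joint draw so positions are unique across the gene's pools
        all_pos = _variant_positions(rng, int(start[gi]), sum(ks))
        rng.shuffle(all_pos)
        offsets = np.cumsum([0] + ks)
        for (kind, total), k, o in zip(pools, ks, offsets):
            afs = rng.dirichlet(np.ones(k)) * total
            afs = np.minimum(afs, 9.9e-4)
            pos = np.sort(all_pos[o : o + k])
            for j in range(k):
                ref = _BASES[rng.integers(4)]
                alt = _BASES[(list(_BASES).index(ref) + 1 + rng.integers(3)) % 4]
                if kind == "damaging":
                    # first two slots guarantee one LoF and one D-mis per gene
                    if j == 0:
                        vkind = "LoF"
                    elif j == 1:
                        vkind = "Dmis"
                    else:
                        vkind = rng.choice(_DAMAGING_KINDS, p=_DAMAGING_WEIGHTS)
                    if vkind == "LoF":
                        consequence = _LOF_CONSEQUENCES[rng.integers(4)]
                        metasvm, cadd = None, None
                    elif vkind == "Dmis":
                        consequence = "missense"
                        if rng.random() < 0.5:
                            metasvm, cadd = "D", float(rng.normal(25, 4))
                        else:
                            metasvm, cadd = "T", float(rng.uniform(30, 45))
                    else:
                        consequence = "nonframeshift_indel"
                        metasvm, cadd = None, None
                        ref, alt = ref + "CAT", ref
                elif kind == "synonymous":
                    consequence, metasvm, cadd = "synonymous", None, None
                else:
                    consequence = "missense"
                    metasvm, cadd = "T", float(rng.uniform(0, 25))
                af = float(afs[j])
                noise = rng.lognormal(0, 0.15, size=2)
                af1 = min(af * noise[0], 9.9e-4)
                af2 = min(af * noise[1], 9.9e-4)
                if rng.random() < 0.05:
                    af1 = np.nan
                rows.append(
                    {
                        "variant_id": f"{chrom[gi]}:{pos[j]}:{ref}:{alt}",
                        "chrom": str(chrom[gi]),
                        "pos": int(pos[j]),
                        "ref": ref,
                        "alt": alt,
                        "gene": g,
                        "consequence": consequence,
                        "metasvm": metasvm,
                        "cadd": cadd,
                        "af_panel1": af1,
                        "af_panel2": af2,
                        "segdup": bool(rng.random() < config.segdup_fraction),
                        "true_af": af,
                        "vkind": kind if kind != "damaging" else vkind,
                    }
                )
    variants = pd.DataFrame(rows)
    if config.founder is not None:
        fgene, faf, _ = config.founder
        if fgene not in set(genes):
            raise ValueError(f"founder gene {fgene} not in panel")
        gi = genes.index(fgene)
        pos = int(start[gi]) + 60_001
        variants = pd.concat(
            [
                variants,
                pd.DataFrame(
                    [
                        {
                            "variant_id": f"{chrom[gi]}:{pos}:A:T",
                            "chrom": str(chrom[gi]),
                            "pos": pos,
                            "ref": "A",
                            "alt": "T",
                            "gene": fgene,
                            "consequence": "missense",
                            "metasvm": "D",
                            "cadd": 28.0,
                            "af_panel1": 5e-4,  # globally rare despite subpop elevation
                            "af_panel2": 5e-4,
                            "segdup": False,
                            "true_af": faf,
                            "vkind": "founder",
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return GenePanel(mutability=mutability, variants=variants, genes=gene_df)


# ---------------------------------------------------------------------------
# trio cohort
# ---------------------------------------------------------------------------


def _assign_f(rng, n: int, f_distribution) -> np.ndarray:
    values = np.array([f for f, _ in f_distribution])
    props = np.array([p for _, p in f_distribution])
    return values[rng.choice(len(values), size=n, p=props)]


def _roh_segments(rng, F: float, config: SimConfig) -> list[tuple[int, float, float]]:
    """(chrom index, start, end) autozygous segments; wraps at chromosome ends."""
    if F <= 0:
        return []
    G = config.n_autosomes * config.chrom_length_bp
    mu = config.roh_mean_length_bp
    n_seg = rng.poisson(F * G / mu)
    segments = []
    for _ in range(n_seg):
        c = int(rng.integers(config.n_autosomes))
        s = float(rng.uniform(0, config.chrom_length_bp))
        length = float(rng.exponential(mu))
        e = s + length
        if e <= config.chrom_length_bp:
            segments.append((c, s, e))
        else:  # wrap to preserve total autozygous length
            segments.append((c, s, float(config.chrom_length_bp)))
            segments.append((c, 0.0, min(e - config.chrom_length_bp, s)))
    return segments


def _merged_length(segments: list[tuple[int, float, float]]) -> float:
    total = 0.0
    by_chrom: dict[int, list[tuple[float, float]]] = {}
    for c, s, e in segments:
        by_chrom.setdefault(c, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def _genes_in_segments(
    segments: list[tuple[int, float, float]], gene_df: pd.DataFrame
) -> list[int]:
    """Indices of genes whose start falls inside an autozygous segment."""
    hits = []
    gchrom = gene_df["chrom"].to_numpy().astype(int) - 1
    gstart = gene_df["start"].to_numpy()
    for c, s, e in segments:
        m = (gchrom == c) & (gstart >= s) & (gstart < e)
        hits.extend(np.flatnonzero(m).tolist())
    return hits


def simulate_trios(config: SimConfig, panel: GenePanel) -> SyntheticCohort:
    """Genotype tables, pedigree, and ground truth for a trio/singleton cohort."""
    causal_ids = [g for g, _ in config.causal_genes]
    missing = set(causal_ids) - set(panel.mutability.index)
    if missing:
        raise ValueError(f"causal genes absent from panel: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_t, n_s = config.n_trios, config.n_singletons
    probands = [f"T{i + 1:05d}-P" for i in range(n_t)] + [
        f"S{i + 1:05d}" for i in range(n_s)
    ]
    fathers = [f"T{i + 1:05d}-F" for i in range(n_t)]
    mothers = [f"T{i + 1:05d}-M" for i in range(n_t)]

    v = panel.variants
    gene_names = list(panel.mutability.index)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    vid = v["variant_id"].to_numpy()
    vgene = v["gene"].map(gene_index).to_numpy()
    vaf = v["true_af"].to_numpy(dtype=float)
    n_var = len(v)

    founder_mask = (v["vkind"] == "founder").to_numpy()
    founder_subpop = np.zeros(n_t + n_s, dtype=bool)
    if config.founder is not None:
        # a 10% subpopulation carries the founder allele at its elevated AF
        founder_subpop = rng.random(n_t + n_s) < 0.1

    F_assigned = _assign_f(rng, n_t + n_s, config.f_distribution)

    # --- parental haplotype carriage (trios) -------------------------------
    # haplotype slots per trio: father (0,1), mother (2,3)
    entries: dict[tuple[str, str], list[int]] = {}

    def add(sample: str, variant: str, hap: int) -> None:
        rec = entries.setdefault((sample, variant), [0, 0])
        rec[hap] = 1

    transmit_f = rng.integers(0, 2, size=(n_t, config.n_genes))
    transmit_m = rng.integers(0, 2, size=(n_t, config.n_genes))

    if n_t:
        for j in range(n_var):
            q = vaf[j]
            if founder_mask[j] or q <= 0:
                continue
            # Bernoulli(q) per parental haplotype, sparse sampling
            n_haps = 4 * n_t
            k = rng.binomial(n_haps, q)
            if k == 0:
                continue
            slots = rng.choice(n_haps, size=k, replace=False)
            for slot in slots:
                t, h = divmod(int(slot), 4)
                parent = fathers[t] if h < 2 else mothers[t]
                add(parent, vid[j], h % 2)

    # --- singleton haplotypes ---------------------------------------------
    if n_s:
        for j in range(n_var):
            q = vaf[j]
            if founder_mask[j] or q <= 0:
                continue
            n_haps = 2 * n_s
            k = rng.binomial(n_haps, q)
            if k == 0:
                continue
            slots = rng.choice(n_haps, size=k, replace=False)
            for slot in slots:
                s_i, h = divmod(int(slot), 2)
                add(probands[n_t + s_i], vid[j], h)

    # --- founder variant carriage -----------------------------------------
    if config.founder is not None:
        _, faf, _ = config.founder
        fj = int(np.flatnonzero(founder_mask)[0])
        for i in range(n_t + n_s):
            af_here = faf if founder_subpop[i] else 1e-4
            if i < n_t:
                for parent in (fathers[i], mothers[i]):
                    for h in range(2):
                        if rng.random() < af_here:
                            add(parent, vid[fj], h)
            else:
                for h in range(2):
                    if rng.random() < af_here:
                        add(probands[i], vid[fj], h)

    # --- autozygosity ------------------------------------------------------
    roh_truth: list[list[tuple[int, float, float]]] = []
    autozygous_genes: list[list[int]] = []
    for i in range(n_t + n_s):
        segs = _roh_segments(rng, F_assigned[i], config)
        roh_truth.append(segs)
        autozygous_genes.append(_genes_in_segments(segs, panel.genes))

    # variants grouped by gene for ancestral draws
    var_by_gene: dict[int, np.ndarray] = {
        g: np.flatnonzero(vgene == g) for g in range(config.n_genes)
    }

    proband_hom: dict[tuple[str, str], bool] = {}
    for i in range(n_t + n_s):
        for g in autozygous_genes[i]:
            for j in var_by_gene.get(g, ()):  # ancestral haplotype content
                if founder_mask[j]:
                    continue
                if rng.random() < vaf[j]:
                    proband = probands[i]
                    proband_hom[(proband, vid[j])] = True
                    if i < n_t:
                        # transmitted haplotypes of both parents carry it
                        tf, tm = transmit_f[i, g], transmit_m[i, g]
                        prev_f = entries.get((fathers[i], vid[j]), [0, 0])
                        prev_m = entries.get((mothers[i], vid[j]), [0, 0])
                        prev_f[tf] = 1
                        prev_m[tm] = 1
                        entries[(fathers[i], vid[j])] = prev_f
                        entries[(mothers[i], vid[j])] = prev_m

    # --- causal planting ---------------------------------------------------
    taf = config.target_attributable_fraction
    causal_flags = np.zeros(n_t + n_s, dtype=bool)
    causal_gene_of = np.full(n_t + n_s, "", dtype=object)
    if taf > 0 and causal_ids:
        weights = np.array([p for _, p in config.causal_genes], dtype=float)
        weights = weights / weights.sum()
        dam_by_gene = {
            g: np.flatnonzero(
                (vgene == gene_index[g])
                & v["vkind"].isin(_DAMAGING_KINDS).to_numpy()
            )
            for g in causal_ids
        }
        for i in range(n_t):  # causal RGs planted in trios (phase known)
            if rng.random() >= taf:
                continue
            g = causal_ids[rng.choice(len(causal_ids), p=weights)]
            dam = dam_by_gene[g]
            if dam.size == 0:
                continue
            causal_flags[i] = True
            causal_gene_of[i] = g
            gi = gene_index[g]
            tf, tm = transmit_f[i, gi], transmit_m[i, gi]
            if dam.size == 1 or rng.random() < config.plant_hom_fraction:
                j = int(rng.choice(dam))
                add(fathers[i], vid[j], int(tf))
                add(mothers[i], vid[j], int(tm))
                proband_hom[(probands[i], vid[j])] = True
            else:
                j1, j2 = rng.choice(dam, size=2, replace=False)
                add(mothers[i], vid[int(j1)], int(tm))
                add(fathers[i], vid[int(j2)], int(tf))

    # --- transmission to trio probands ------------------------------------
    vid_to_gene = dict(zip(vid, vgene))
    proband_haps: dict[tuple[str, str], list[int]] = {}
    for (sample, variant), haps in entries.items():
        if sample.endswith("-F"):
            t = int(sample[1:6]) - 1
            g = vid_to_gene[variant]
            if haps[transmit_f[t, g]]:
                rec = proband_haps.setdefault((probands[t], variant), [0, 0])
                rec[1] = 1  # paternal haplotype
        elif sample.endswith("-M"):
            t = int(sample[1:6]) - 1
            g = vid_to_gene[variant]
            if haps[transmit_m[t, g]]:
                rec = proband_haps.setdefault((probands[t], variant), [0, 0])
                rec[0] = 1  # maternal haplotype
        else:  # singleton carriage recorded directly
            proband_haps[(sample, variant)] = list(haps)
    # inside autozygous segments the proband's two gene copies are identical
    # by descent: only the ancestral-haplotype content (recorded as hom) may
    # appear there, so transmitted background hets are removed
    auto_pairs = {
        (probands[i], vid[j])
        for i in range(n_t + n_s)
        for g in autozygous_genes[i]
        for j in var_by_gene.get(g, ())
    }
    for key in list(proband_haps):
        if key in auto_pairs and key not in proband_hom:
            del proband_haps[key]
    for (sample, variant) in proband_hom:
        proband_haps[(sample, variant)] = [1, 1]

    # --- assemble genotype table ------------------------------------------
    all_entries = {**{k: list(vv) for k, vv in entries.items()}, **proband_haps}
    samples_col, vids_col, hap1, hap2 = [], [], [], []
    for (sample, variant), haps in all_entries.items():
        samples_col.append(sample)
        vids_col.append(variant)
        hap1.append(haps[0])
        hap2.append(haps[1])
    genotypes = pd.DataFrame(
        {
            "sample": samples_col,
            "variant_id": vids_col,
            "hap1": np.array(hap1, dtype=np.int8),
            "hap2": np.array(hap2, dtype=np.int8),
        }
    )
    genotypes["dosage"] = (genotypes["hap1"] + genotypes["hap2"]).astype(np.int8)
    genotypes = genotypes[genotypes["dosage"] > 0].reset_index(drop=True)
    genotypes = genotypes.sort_values(["sample", "variant_id"], kind="stable").reset_index(
        drop=True
    )

    # QC fields: passing by default; qc_noise injects failures
    m = len(genotypes)
    dp = np.maximum(rng.poisson(40, size=m), 10)
    is_hom = genotypes["dosage"].to_numpy() == 2
    alt = np.where(is_hom, dp, np.maximum(rng.binomial(dp, 0.5), np.ceil(0.3 * dp)))
    genotypes["gq"] = 99
    genotypes["dp"] = dp
    genotypes["mq"] = 60.0
    genotypes["alt_reads"] = alt.astype(int)
    if config.qc_noise > 0 and m:
        bad = rng.random(m) < config.qc_noise
        which = rng.integers(0, 3, size=m)
        gq = genotypes["gq"].to_numpy(dtype=int)
        gq[bad & (which == 0)] = 10
        genotypes["gq"] = gq
        dp2 = genotypes["dp"].to_numpy()
        dp2[bad & (which == 1)] = 4
        genotypes["dp"] = dp2
        mq = genotypes["mq"].to_numpy()
        mq[bad & (which == 2)] = 20.0
        genotypes["mq"] = mq

    # --- pedigree and truth -----------------------------------------------
    ped_rows = []
    for i in range(n_t):
        fam = f"FAM{i + 1:05d}"
        ped_rows.append((fam, probands[i], fathers[i], mothers[i], 1, 2))
        ped_rows.append((fam, fathers[i], "0", "0", 1, 1))
        ped_rows.append((fam, mothers[i], "0", "0", 2, 1))
    for i in range(n_s):
        ped_rows.append((f"SFAM{i + 1:05d}", probands[n_t + i], "0", "0", 1, 2))
    pedigree = pd.DataFrame(
        ped_rows, columns=["fam", "sample", "father", "mother", "sex", "phenotype"]
    )

    G = config.n_autosomes * config.chrom_length_bp
    truth_probands = pd.DataFrame(
        {
            "sample": probands,
            "causal": causal_flags,
            "causal_gene": causal_gene_of,
            "true_F": F_assigned,
            "realized_autozygous_fraction": [
                _merged_length(s) / G for s in roh_truth
            ],
            "founder_subpop": founder_subpop,
        }
    )
    dam_af = (
        v[v["vkind"].isin(_DAMAGING_KINDS)].groupby("gene")["true_af"].sum()
    )
    truth_genes = pd.DataFrame(
        {
            "gene": gene_names,
            "mutability": panel.mutability.to_numpy(),
            "damaging_af_sum": dam_af.reindex(gene_names).fillna(0.0).to_numpy(),
        }
    )

    cohort = SyntheticCohort(
        genotypes=genotypes,
        pedigree=pedigree,
        truth_probands=truth_probands,
        truth_genes=truth_genes,
    )

    if config.generate_markers:
        marker_map, matrix = _marker_channel(rng, config, roh_truth)
        cohort.marker_map = marker_map
        cohort.marker_genotypes = matrix
        cohort.marker_samples = probands
    return cohort


def _marker_channel(
    rng, config: SimConfig, roh_truth: list[list[tuple[int, float, float]]]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Common-marker genotypes for ROH-based F estimation (probands only).

    HWE genotypes outside autozygous segments; homozygous (allele drawn by
    frequency) inside. Parental marker genotypes are not emitted.
    """
    per_chrom = config.chrom_length_bp // config.marker_spacing_bp
    chroms = np.repeat(np.arange(config.n_autosomes), per_chrom)
    pos = np.tile(
        (np.arange(per_chrom) + 1) * config.marker_spacing_bp, config.n_autosomes
    )
    maf = rng.uniform(0.1, 0.5, size=chroms.size)
    n = len(roh_truth)
    matrix = rng.binomial(2, maf[None, :].repeat(n, axis=0)).astype(np.int8)
    block = (np.arange(per_chrom) + 1) * config.marker_spacing_bp
    for i, segs in enumerate(roh_truth):
        for c, s, e in segs:
            lo = c * per_chrom + int(np.searchsorted(block, s, side="left"))
            hi = c * per_chrom + int(np.searchsorted(block, e, side="right"))
            hi = min(hi, (c + 1) * per_chrom)
            if hi > lo:
                matrix[i, lo:hi] = (
                    rng.random(hi - lo) < maf[lo:hi]
                ).astype(np.int8) * 2
    marker_map = pd.DataFrame({"chrom": (chroms + 1).astype(str), "pos": pos})
    return marker_map, matrix


# ---------------------------------------------------------------------------
# co-occurrence panel
# ---------------------------------------------------------------------------


def simulate_cooccurrence_panel(
    panel: GenePanel,
    n_individuals: int,
    seed: int = 0,
    return_genotypes: bool = False,
):
    """Per-gene variant-pair co-occurrence counts in a reference panel.

    Counts panel individuals carrying both members of each same-gene pair;
    pairs that never co-occur have no entry (treated as count zero by the
    inferred-comphet caller).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    v = panel.variants
    carriage: dict[int, set[str]] = {}
    for j, (vid_j, q) in enumerate(zip(v["variant_id"], v["true_af"])):
        if q <= 0:
            continue
        k = rng.binomial(2 * n_individuals, q)
        if k == 0:
            continue
        slots = rng.choice(2 * n_individuals, size=k, replace=False)
        for slot in slots:
            carriage.setdefault(int(slot) // 2, set()).add(vid_j)
    gene_of = dict(zip(v["variant_id"], v["gene"]))
    pair_counts: dict[tuple[str, str], int] = {}
    for vids in carriage.values():
        vids = sorted(vids)
        for a_i in range(len(vids)):
            for b_i in range(a_i + 1, len(vids)):
                a, b = vids[a_i], vids[b_i]
                if gene_of[a] != gene_of[b]:
                    continue
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    pairs = pd.DataFrame(
        [
            {"gene": gene_of[a], "variant_a": a, "variant_b": b, "count": c}
            for (a, b), c in sorted(pair_counts.items())
        ],
        columns=["gene", "variant_a", "variant_b", "count"],
    )
    if return_genotypes:
        geno = pd.DataFrame(
            [
                {"individual": ind, "variant_id": vid_j}
                for ind, vids in carriage.items()
                for vid_j in sorted(vids)
            ],
            columns=["individual", "variant_id"],
        )
        return pairs, geno
    return pairs


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------


@dataclass
class FounderHaplotypes:
    positions: np.ndarray
    haplotypes: np.ndarray  # carriers x markers, 0/1 alleles
    focal_index: int
    ancestral: np.ndarray
    breakpoints: np.ndarray  # carriers x 2 retained genetic lengths (Morgans)


def simulate_founder_haplotypes(
    age_generations: float,
    n_carrier_chromosomes: int,
    seed: int = 0,
    n_markers: int = 1500,
    marker_spacing_bp: int = 20_000,
    cm_per_mb: float = 1.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> FounderHaplotypes:
    """Carrier haplotypes around a focal founder allele of a given age.

    Each carrier retains the ancestral haplotype over one-sided genetic
    lengths drawn Exp(rate=age) (Morgans per side); off-segment marker
    alleles are resampled from their population frequencies.
    """
    if age_generations < 1:
        raise ValueError("age must be >= 1 generation")
    if n_carrier_chromosomes < 2:
        raise ValueError("need >= 2 carrier chromosomes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    m = n_carrier_chromosomes
    positions = (np.arange(n_markers) + 1) * marker_spacing_bp
    focal = n_markers // 2
    maf = rng.uniform(*maf_range, size=n_markers)
    ancestral = (rng.random(n_markers) < maf).astype(np.int8)
    ancestral[focal] = 1
    bp_per_morgan = 1e8 / cm_per_mb
    lengths = rng.exponential(1.0 / age_generations, size=(m, 2))
    H = np.empty((m, n_markers), dtype=np.int8)
    focal_pos = positions[focal]
    for i in range(m):
        left_bp = focal_pos - lengths[i, 0] * bp_per_morgan
        right_bp = focal_pos + lengths[i, 1] * bp_per_morgan
        on = (positions >= left_bp) & (positions <= right_bp)
        H[i] = np.where(on, ancestral, (rng.random(n_markers) < maf).astype(np.int8))
        H[i, focal] = 1
    return FounderHaplotypes(
        positions=positions,
        haplotypes=H,
        focal_index=focal,
        ancestral=ancestral,
        breakpoints=lengths,
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    n_genes: int,
    cell_types: list[str],
    planted_specific: dict[str, str] | None = None,
    fold: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x cell-type mean expression with planted lineage-specific genes.

    Background genes are broadly expressed (log-normal jitter around a
    gene-level mean, max/second ratios well under the fivefold rule);
    planted genes exceed every other cell type by ``fold`` in their target
    cell type.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    planted_specific = planted_specific or {}
    unknown = set(planted_specific.values()) - set(cell_types)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    genes = [f"BG{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=1.0, sigma=0.8, size=n_genes)
    M = base[:, None] * rng.lognormal(0.0, 0.3, size=(n_genes, len(cell_types)))
    df = pd.DataFrame(M, index=genes, columns=cell_types)
    for gene, ct in planted_specific.items():
        row = base.mean() * rng.lognormal(0.0, 0.3, size=len(cell_types))
        others = [c for c in cell_types if c != ct]
        row[df.columns.get_indexer([ct])[0]] = fold * 1.05 * row.max()
        s = pd.Series(row, index=cell_types)
        s[others] = np.minimum(s[others], s[ct] / (fold * 1.02))
        df.loc[gene] = s
    return df
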