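"""Inbreeding coefficients from runs of homozygosity (ROH), and
consanguinity stratification.

The inbreeding coefficient F is the probability that an individual's two
alleles at a locus are identical by descent. It is estimated here as the
autozygous genome fraction: ROH are detected by sliding windows of
consecutive homozygous marker calls (window >= 50 markers and >= 1.5 Mb,
allowing <= 2 heterozygous miscalls per window) and F = total ROH length /
covered autosome length. An individual is consanguineous when
F >= 0.0009, approximately the expectation for offspring of a fourth-cousin
union; finer strata follow configurable F bins down from the first-cousin
value of 1/16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONSANGUINITY_THRESHOLD = 0.0009

#: descending F bin edges: >=0.03 (1st/2nd cousin), [0.0078, 0.03) (~2nd-3rd),
#: [0.002, 0.0078) (~3rd-4th), [0.0009, 0.002) (~4th), < 0.0009 (outbred)
DEFAULT_BINS = (0.03, 0.0078, 0.002, 0.0009)

DEFAULT_MIN_MARKERS = 1000


@dataclass
class ConsanguinityResult:
    sample: str
    F: float
    roh_segments: list[tuple[str, int, int]] = field(default_factory=list)
    stratum: str = ""
    consanguineous: bool = False


def _roh_runs(
    het: np.ndarray,
    pos: np.ndarray,
    window: int,
    max_het: int,
    min_length_bp: float,
) -> list[tuple[int, int]]:
    """Marker-index runs covered by qualifying homozygous windows."""
    n = het.size
    if n < window:
        return []
    cs = np.concatenate([[0], np.cumsum(het)])
    win_het = cs[window:] - cs[:-window]  # het count per window start
    ok = win_het <= max_het
    covered = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(ok)
    for s in starts:
        covered[s : s + window] = True
    runs = []
    in_run = False
    for i in range(n):
        if covered[i] and not in_run:
            start = i
            in_run = True
        elif not covered[i] and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, n - 1))
    return [
        (a, b) for a, b in runs if pos[b] - pos[a] >= min_length_bp and b - a + 1 >= window
    ]


def estimate_F(
    dosages: np.ndarray,
    marker_map: pd.DataFrame,
    sample: str = "",
    window: int = 50,
    max_het_per_window: int = 2,
    min_roh_bp: float = 1.5e6,
    min_markers: int = DEFAULT_MIN_MARKERS,
    threshold: float = CONSANGUINITY_THRESHOLD,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> ConsanguinityResult:
    """ROH-based inbreeding coefficient for one sample.

    ``dosages`` is an int array of genotypes in {0,1,2} aligned with
    ``marker_map`` (columns chrom, pos). Markers are sorted by map position
    within chromosome before scanning, so marker order in the input does
    not matter.
    """
    dosages = np.asarray(dosages)
    if dosages.size != len(marker_map):
        raise ValueError("dosages and marker_map length mismatch")
    if dosages.size < min_markers:
        raise ValueError(
            f"need at least {min_markers} markers to estimate F, got {dosages.size}"
        )
    total_roh = 0.0
    total_covered = 0.0
    segments: list[tuple[str, int, int]] = []
    order = np.lexsort((marker_map["pos"].to_numpy(), marker_map["chrom"].to_numpy()))
    chrom_sorted = marker_map["chrom"].to_numpy()[order]
    pos_sorted = marker_map["pos"].to_numpy()[order]
    dos_sorted = dosages[order]
    for chrom in pd.unique(chrom_sorted):
        m = chrom_sorted == chrom
        pos = pos_sorted[m]
        het = (dos_sorted[m] == 1).astype(np.int64)
        if pos.size < 2:
            continue
        total_covered += pos[-1] - pos[0]
        for a, b in _roh_runs(het, pos, window, max_het_per_window, min_roh_bp):
            segments.append((str(chrom), int(pos[a]), int(pos[b])))
            total_roh += pos[b] - pos[a]
    F = float(total_roh / total_covered) if total_covered > 0 else 0.0
    consang, stratum = classify(F, threshold=threshold, bins=bins)
    return ConsanguinityResult(
        sample=sample,
        F=F,
        roh_segments=segments,
        stratum=stratum,
        consanguineous=consang,
    )


def estimate_F_cohort(
    genotype_matrix: np.ndarray,
    marker_map: pd.DataFrame,
    samples: list[str],
    return_segments: bool = False,
    **kwargs,
):
    """Apply :func:`estimate_F` to each row of a samples x markers matrix."""
    results = [
        estimate_F(genotype_matrix[i], marker_map, sample=s, **kwargs)
        for i, s in enumerate(samples)
    ]
    table = pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "F": [r.F for r in results],
            "n_segments": [len(r.roh_segments) for r in results],
            "stratum": [r.stratum for r in results],
            "consanguineous": [r.consanguineous for r in results],
        }
    )
    if return_segments:
        return table, {r.sample: r.roh_segments for r in results}
    return table


def classify(
    F: float,
    threshold: float = CONSANGUINITY_THRESHOLD,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> tuple[bool, str]:
    """(consanguineous, stratum label) for an inbreeding coefficient.

    Consanguineous iff F >= threshold. Strata are right-open intervals from
    descending ``bins`` edges; the top stratum is ``>=bins[0]`` and the
    bottom ``<bins[-1]``.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F out of [0,1]: {F}")
    edges = sorted(bins, reverse=True)
    stratum = f"<{edges[-1]:g}"
    for i, edge in enumerate(edges):
        if F >= edge:
            upper = edges[i - 1] if i > 0 else None
            stratum = f">={edge:g}" if upper is None else f"[{edge:g},{upper:g})"
            break
    return F >= threshold, stratum


def compare_f_distributions(
    cases_f: np.ndarray, controls_f: np.ndarray
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on F distributions."""
    cases_f = np.asarray(cases_f, dtype=float)
    controls_f = np.asarray(controls_f, dtype=float)
    if cases_f.size == 0 or controls_f.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(cases_f, controls_f, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def consanguinity_known_gene_table(
    rgs: pd.DataFrame,
    f_table: pd.DataFrame,
    known_genes: set[str],
) -> dict:
    """2x2 enrichment of known-gene RG carriers by consanguinity stratum.

    Counts probands with >= 1 RG in ``known_genes``, split consanguineous
    vs not; fold is the carrier-rate ratio and p a Fisher exact test
    (two-sided reported as ``p``, one-sided greater as ``p_one_sided``).
    """
    carriers = set(rgs.loc[rgs["gene"].isin(known_genes), "sample"])
    consang = f_table["consanguineous"].astype(bool)
    is_carrier = f_table["sample"].isin(carriers)
    a = int((consang & is_carrier).sum())  # consanguineous carriers
    b = int((consang & ~is_carrier).sum())
    c = int((~consang & is_carrier).sum())
    d = int((~consang & ~is_carrier).sum())
    table = [[a, b], [c, d]]
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        fold = float("nan")
    else:
        rate1, rate2 = a / n1, c / n2
        fold = rate1 / rate2 if rate2 > 0 else float("inf")
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_greater = stats.fisher_exact(table, alternative="greater")
    return {
        "table": table,
        "n_consanguineous": n1,
        "n_nonconsanguineous": n2,
        "carriers_consanguineous": a,
        "carriers_nonconsanguineous": c,
        "fold": fold,
        "p": float(p_two),
        "p_one_sided": float(p_greater),
    }
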