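"""Founder-variant statistics: Hardy-Weinberg deviation, shared-haplotype
extraction, and recombination-clock allele dating.

A founder allele that rose in frequency after a population bottleneck sits
on a shared ancestral haplotype that recombination erodes at a rate
proportional to its age. For ``m`` carrier chromosomes, each one-sided
shared genetic length is the minimum of ``m`` exponentials with rate ``g``
(generations), so the total two-sided shared length L (in Morgans) is
Gamma(2, rate=m*g) distributed and the moment/ML estimator of the age is

    g_hat = 2 / (m * L).

Homozygote excess relative to Hardy-Weinberg (tested with a 1-df chi-square
with Yates continuity correction) is the signature of phenotype-driven
ascertainment of recessive founder genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_alt: int
    n_het: int
    n_hom_ref: int

    def __post_init__(self) -> None:
        if min(self.n_hom_alt, self.n_het, self.n_hom_ref) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_hom_alt + self.n_het + self.n_hom_ref


@dataclass
class SharedHaplotype:
    focal_variant: str
    carriers: list[str]
    chrom: str
    start: int  # 1-based inclusive
    end: int
    length_bp: int
    length_cm: float


def allele_frequency(counts: GenotypeCounts) -> float:
    """Alternate allele frequency (2*hom_alt + het) / 2n."""
    if counts.n == 0:
        raise ValueError("no genotypes")
    return (2 * counts.n_hom_alt + counts.n_het) / (2 * counts.n)


def hwe_yates_test(counts: GenotypeCounts) -> tuple[float, float]:
    """1-df chi-square HWE test with Yates continuity correction.

    Expected classes (nq^2, 2npq, np^2) from the sample allele frequency;
    each deviation is shrunk by 0.5 and floored at 0, so tables exactly at
    HWE give chi2 = 0, p = 1. Monomorphic sites return (0, 1) by convention.
    """
    n = counts.n
    if n == 0:
        raise ValueError("no genotypes")
    q = allele_frequency(counts)
    if q in (0.0, 1.0):
        return 0.0, 1.0
    p = 1.0 - q
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([counts.n_hom_alt, counts.n_het, counts.n_hom_ref])
    chi2 = float(
        (np.maximum(np.abs(observed - expected) - 0.5, 0.0) ** 2 / expected).sum()
    )
    return chi2, float(stats.chi2.sf(chi2, df=1))


def predicted_homozygote_frequency(q: float) -> float:
    """Random-mating homozygote frequency q**2."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency out of [0,1]: {q}")
    return q * q


def _genetic_length(
    pos_start: float,
    pos_end: float,
    genetic_map: pd.DataFrame | None,
    cm_per_mb: float,
) -> float:
    if genetic_map is None:
        return (pos_end - pos_start) / 1e6 * cm_per_mb
    cm = np.interp(
        [pos_start, pos_end], genetic_map["pos"].to_numpy(), genetic_map["cm"].to_numpy()
    )
    return float(cm[1] - cm[0])


def max_shared_haplotype(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    carriers: list[str] | None = None,
    chrom: str = "1",
    focal_variant: str = "",
    genetic_map: pd.DataFrame | None = None,
    cm_per_mb: float = 1.0,
) -> SharedHaplotype:
    """Maximal interval around the focal site where all carriers agree.

    ``haplotypes`` is a carriers x markers allele matrix; every carrier must
    carry the focal allele. Scans outward from the focal marker and stops
    at the first marker where any pair of carriers differs; the result is
    symmetric in carrier order. Genetic length from an optional (pos, cm)
    map, else a uniform cM/Mb rate.
    """
    H = np.asarray(haplotypes)
    positions = np.asarray(positions)
    if H.ndim != 2 or H.shape[0] < 2:
        raise ValueError("need >= 2 carrier chromosomes")
    if H.shape[1] != positions.size:
        raise ValueError("haplotype matrix and positions length mismatch")
    names = carriers if carriers is not None else [str(i) for i in range(H.shape[0])]
    focal_alleles = H[:, focal_index]
    if not np.all(focal_alleles == focal_alleles[0]):
        bad = names[int(np.flatnonzero(focal_alleles != focal_alleles[0])[0])]
        raise ValueError(f"carrier {bad} does not carry the focal allele")
    same = np.all(H == H[0], axis=0)  # markers where all carriers agree
    left = focal_index
    while left > 0 and same[left - 1]:
        left -= 1
    right = focal_index
    while right < same.size - 1 and same[right + 1]:
        right += 1
    start, end = int(positions[left]), int(positions[right])
    return SharedHaplotype(
        focal_variant=focal_variant,
        carriers=list(names),
        chrom=chrom,
        start=start,
        end=end,
        length_bp=end - start,
        length_cm=_genetic_length(start, end, genetic_map, cm_per_mb),
    )


def estimate_allele_age(
    length_cm: float,
    m: int,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Recombination-clock age of a founder allele, in generations.

    Point estimate g_hat = 2/(m*L) with L the two-sided shared genetic
    length in Morgans. The CI comes from the exact pivot
    m*g*L ~ Gamma(shape=2, rate=1): g in [q_lo, q_hi]/(m*L) where q are
    Gamma(2,1) quantiles.
    """
    if m < 2:
        raise ValueError("need >= 2 carrier chromosomes")
    if length_cm <= 0:
        raise ValueError("shared genetic length must be positive")
    L = length_cm / 100.0
    g_hat = 2.0 / (m * L)
    alpha = 1.0 - level
    q_lo, q_hi = stats.gamma.ppf([alpha / 2, 1 - alpha / 2], a=2)
    return g_hat, (float(q_lo / (m * L)), float(q_hi / (m * L)))


def founder_report(
    counts: GenotypeCounts,
    shared: SharedHaplotype | None = None,
) -> dict:
    """JSON-ready summary for one founder variant."""
    q = allele_frequency(counts)
    chi2, p = hwe_yates_test(counts)
    report = {
        "n": counts.n,
        "n_hom_alt": counts.n_hom_alt,
        "n_het": counts.n_het,
        "allele_frequency": q,
        "predicted_homozygote_frequency": predicted_homozygote_frequency(q),
        "hwe_chi2": chi2,
        "hwe_p": p,
    }
    if shared is not None:
        m = len(shared.carriers)
        age, ci = estimate_allele_age(shared.length_cm, m)
        report.update(
            {
                "shared_haplotype_bp": shared.length_bp,
                "shared_haplotype_cm": shared.length_cm,
                "carrier_chromosomes": m,
                "allele_age_generations": age,
                "allele_age_ci": list(ci),
            }
        )
    return report
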