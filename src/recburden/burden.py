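"""Mutability-based expected RG counts and enrichment testing.

Under random mating a biallelic genotype needs two independent damaging
alleles, so its rate scales with the square of a gene's damaging allele
pool, itself proportional to the gene's de novo mutability m_g; under
autozygosity one allele suffices, giving a term linear in m_g. Expected
per-gene RG counts are therefore fitted as a degree-2 polynomial without
intercept,

    e_g = a * m_g + b * m_g**2,  a, b >= 0 (nonnegative least squares),

capturing a cohort-wide mix of consanguinity (the linear term) and random
mating (the quadratic term). Observed counts are then tested per gene or
per gene set with a one-tailed binomial test; multiplicity is controlled by
Bonferroni at the exome-wide gene count and by Benjamini-Hochberg FDR. The
excess of genes recurrently hit (>= 2 RGs) is assessed against a
multinomial permutation null with per-gene probabilities proportional to
the fitted expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

#: floor on fitted expected counts, to avoid zero-division enrichments
EXPECTED_FLOOR = 1e-6

#: exome-wide gene count for the default Bonferroni denominator
EXOME_GENE_COUNT = 19_347


@dataclass
class ExpectedModel:
    """Fitted polynomial e_g = a*m_g + b*m_g**2, floored at ``EXPECTED_FLOOR``."""

    a: float
    b: float
    expected: pd.Series  # per-gene e_g indexed by gene
    n: int  # cohort size the counts came from
    floored_genes: list[str]

    def predict(self, mutability: pd.Series) -> pd.Series:
        e = self.a * mutability + self.b * mutability**2
        return e.clip(lower=EXPECTED_FLOOR)


@dataclass
class EnrichmentResult:
    unit: str
    observed: int
    expected: float
    enrichment: float
    p: float
    q: float | None = None
    bonferroni_significant: bool | None = None


def fit_expected_model(
    observed: pd.Series,
    mutability: pd.Series,
    n_probands: int,
    degree: int = 2,
    min_genes: int = 100,
    exclude: set[str] | None = None,
) -> ExpectedModel:
    """Nonnegative least squares of per-gene RG counts on (m_g, ..., m_g^degree).

    ``observed`` and ``mutability`` are gene-indexed; genes without
    mutability are dropped. No intercept: a gene with zero mutability has
    zero expectation. Genes in ``exclude`` are held out of the fit (useful
    when a candidate gene would otherwise absorb its own signal in a small
    panel) but still receive fitted expectations.
    """
    mut = mutability.dropna()
    fit_mut = mut.drop(index=set(exclude or ()) & set(mut.index))
    if (mut <= 0).any():
        raise ValueError("mutability must be positive for all genes")
    if len(fit_mut) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes with mutability, got {len(fit_mut)}"
        )
    y = observed.reindex(fit_mut.index).fillna(0).to_numpy(dtype=float)
    m = fit_mut.to_numpy(dtype=float)
    X = np.column_stack([m**k for k in range(1, degree + 1)])
    if np.all(y == 0):
        warnings.warn("all observed counts are zero; fitted model is trivial")
        coefs = np.zeros(degree)
    else:
        coefs, _ = optimize.nnls(X, y)
    m_all = mut.to_numpy(dtype=float)
    X_all = np.column_stack([m_all**k for k in range(1, degree + 1)])
    e = pd.Series(X_all @ coefs, index=mut.index, name="expected")
    floored = e.index[e < EXPECTED_FLOOR].tolist()
    e = e.clip(lower=EXPECTED_FLOOR)
    a = float(coefs[0])
    b = float(coefs[1]) if degree >= 2 else 0.0
    return ExpectedModel(a=a, b=b, expected=e, n=n_probands, floored_genes=floored)


def binomial_gene_test(observed: int, expected: float, n: int, unit: str = "") -> EnrichmentResult:
    """One-tailed binomial test of an observed count against its expectation.

    p = P(X >= observed) with X ~ Binomial(n, expected/n).
    """
    if expected <= 0:
        raise ValueError("expected must be positive")
    if expected >= n:
        raise ValueError("expected count must be below the cohort size")
    if observed > n:
        raise ValueError("observed count cannot exceed the cohort size")
    p = float(stats.binom.sf(observed - 1, n, expected / n))
    return EnrichmentResult(
        unit=unit,
        observed=int(observed),
        expected=float(expected),
        enrichment=observed / expected,
        p=p,
    )


def test_genes(
    observed: pd.Series, model: ExpectedModel, n: int | None = None
) -> pd.DataFrame:
    """Per-gene binomial tests over every modeled gene; sorted by p."""
    n = n if n is not None else model.n
    obs = observed.reindex(model.expected.index).fillna(0).astype(int)
    e = model.expected.to_numpy()
    p = stats.binom.sf(obs.to_numpy() - 1, n, e / n)
    out = pd.DataFrame(
        {
            "gene": model.expected.index,
            "observed": obs.to_numpy(),
            "expected": e,
            "enrichment": obs.to_numpy() / e,
            "p": p,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def gene_set_test(
    genes: set[str],
    observed_in_set: int,
    model: ExpectedModel,
    n: int | None = None,
    unit: str = "gene_set",
) -> EnrichmentResult:
    """Binomial test of the summed expectation over a gene set.

    For subcohorts (phenotype classes, consanguinity strata) refit the model
    on the subset and pass the subset ``n``. A singleton set reduces exactly
    to :func:`binomial_gene_test`.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    missing = genes - set(model.expected.index)
    if missing:
        raise ValueError(f"genes absent from model: {sorted(missing)[:5]}...")
    expected = float(model.expected.loc[sorted(genes)].sum())
    n = n if n is not None else model.n
    if observed_in_set == 0:
        return EnrichmentResult(unit=unit, observed=0, expected=expected, enrichment=0.0, p=1.0)
    return binomial_gene_test(observed_in_set, expected, n, unit=unit)


def adjust_multiplicity(
    results: pd.DataFrame,
    alpha: float = 0.05,
    n_genes: int = EXOME_GENE_COUNT,
) -> pd.DataFrame:
    """Add BH ``q`` values and a Bonferroni flag at ``alpha / n_genes``.

    ``n_genes`` defaults to the exome-wide gene count, giving the
    genome-wide threshold 0.05/19,347 = 2.6e-6; BH is computed over the
    genes actually tested.
    """
    out = results.copy()
    if len(out) == 0:
        out["q"] = []
        out["bonferroni_significant"] = []
        return out
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["bonferroni_significant"] = out["p"] < alpha / n_genes
    return out


def permutation_recurrent_genes(
    total_rgs: int,
    probabilities: np.ndarray,
    observed_recurrent: int | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    min_count: int = 2,
) -> dict:
    """Permutation null for the number of genes with >= 2 RGs.

    Each permutation drops ``total_rgs`` genotypes multinomially across
    genes with the given probabilities (proportional to fitted
    expectations) and counts genes receiving >= ``min_count``. The
    empirical p uses the +1 correction: (1 + #perms >= observed)/(1 + n_perm).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if total_rgs < 0:
        raise ValueError("total_rgs must be >= 0")
    s = probabilities.sum()
    if not np.isclose(s, 1.0):
        probabilities = probabilities / s
    rng = np.random.default_rng(seed)
    if total_rgs == 0:
        stat = np.zeros(n_perm, dtype=int)
    else:
        draws = rng.multinomial(total_rgs, probabilities, size=n_perm)
        stat = (draws >= min_count).sum(axis=1)
    expected = float(stat.mean())
    out = {"expected_recurrent": expected, "null_distribution": stat}
    if observed_recurrent is not None:
        out["enrichment"] = observed_recurrent / expected if expected > 0 else float("inf")
        out["p"] = float((1 + (stat >= observed_recurrent).sum()) / (1 + n_perm))
    return out
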