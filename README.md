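# recburden

Recessive-genotype (RG) burden analysis for trio/singleton exome cohorts.

Severe early-onset diseases such as congenital heart disease (CHD) receive a
contribution from rare biallelic damaging genotypes — homozygotes and
compound heterozygotes — that is hard to quantify because individual
recessive genes are each responsible for only a handful of cases.
`recburden` implements the full analysis chain used to measure that
contribution in large parent–offspring cohorts:

* **Variant classification** — loss-of-function (stopgain, stoploss,
  frameshift indel, canonical splice), damaging missense (MetaSVM
  deleterious and/or CADD ≥ 30), in-frame indels, and a synonymous
  negative-control stream, with rarity filtering at allele frequency
  < 10⁻³ in two reference panels.
* **RG calling** — homozygotes in all probands; compound heterozygotes
  phased through parental transmission in trios; inferred compound
  heterozygotes in singletons, where a same-gene variant pair is accepted
  as *trans* only when the two alleles never co-occur in a reference panel.
* **Consanguinity** — per-sample inbreeding coefficients *F* estimated as
  the autozygous genome fraction from runs of homozygosity (sliding windows
  of ≥ 50 homozygous markers spanning ≥ 1.5 Mb, ≤ 2 heterozygous miscalls);
  consanguineous means *F* ≥ 0.0009 (≈ fourth-cousin offspring).
* **Burden testing** — per-gene expected RG counts fitted from de novo
  mutability *m*<sub>g</sub> as *e*<sub>g</sub> = *a·m*<sub>g</sub> +
  *b·m*<sub>g</sub>² (nonnegative least squares; the quadratic term is the
  random-mating two-allele rate, the linear term the autozygosity rate),
  followed by one-tailed binomial tests, Bonferroni control at
  0.05/19,347 and Benjamini–Hochberg FDR, and a multinomial permutation
  null for recurrently hit genes.
* **Attributable fraction** — the parental-depletion estimator

  ```
  fraction = (obs_probands − exp_probands · obs_parents / exp_parents) / n_probands
  ```

  with expected counts per individual Σ<sub>g</sub> (1−*F*)·*Q*<sub>g</sub>²
  + *F·Q*<sub>g</sub>, where *Q*<sub>g</sub> is the gene's damaging
  allele-frequency sum from parental in-cohort frequencies, and a
  percentile bootstrap CI over trios.
* **Founder variants** — Hardy–Weinberg deviation (1-df χ² with Yates
  continuity correction), maximal shared haplotype extraction around a
  focal allele, and a recombination-clock age estimate ĝ = 2/(*m·L*) for
  *m* carrier chromosomes sharing genetic length *L* (Morgans).
* **Lineage specificity** — ratio-of-max normalization of cell-type
  expression, the fivefold specificity rule, UPGMA clustering, and RG
  enrichment of lineage-restricted gene sets.
* **Synthetic cohorts** — a first-class generator producing trios with
  Mendelian transmission, segment-based autozygosity matching an assigned
  *F* distribution, planted causal genes at a target attributable fraction,
  co-occurrence panels, decaying founder haplotypes, and expression
  matrices — all with ground-truth tables for calibration and power
  studies.

## Worked example

```python
import pandas as pd
from recburden import simulate as sim, rg, contribution as ct, founder as fo

causal = [(f"GENE{i+1:05d}", 1.0) for i in range(10)]
cfg = sim.SimConfig(n_trios=1000, n_genes=300, seed=7,
                    causal_genes=causal, target_attributable_fraction=0.03,
                    generate_markers=False)
panel = sim.simulate_gene_panel(cfg)
cohort = sim.simulate_trios(cfg, panel)

rgs = rg.call_rgs(cohort.genotypes, cohort.pedigree, panel.variants)
print("RGs called:", len(rgs))
print(rg.tabulate_rg_rates(rgs, 1000).to_string(index=False))

ped = cohort.pedigree
trios = ped[ped.father != "0"].rename(columns={"sample": "proband"})[
    ["proband", "father", "mother"]]
truth_f = cohort.truth_probands.set_index("sample")["true_F"]
f_table = pd.DataFrame({"sample": ped["sample"],
                        "F": ped["sample"].map(truth_f).fillna(0.0)})
est = ct.estimate_contribution(cohort.genotypes, panel.variants, trios,
                               f_table, "damaging", bootstrap=1000, seed=7)
print(f"attributable fraction: {100*est.fraction:.1f}% "
      f"(CI {100*est.ci[0]:.1f}% to {100*est.ci[1]:.1f}%)")

age, ci = fo.estimate_allele_age(0.657, m=6)   # 657 kb shared by 6 carriers
print(f"founder allele age: {age:.1f} generations")
```

prints

```
RGs called: 25
 gene_set rg_type  count  rate
all_genes     hom      1 0.001
all_genes comphet     24 0.024
all_genes   total     25 0.025
attributable fraction: 2.3% (CI 1.3% to 3.3%)
founder allele age: 50.7 generations
```

Twenty-five biallelic damaging genotypes were called in 1,000 probands
(0.025 per individual); the parental-depletion estimator attributes 2.3% of
probands to recessive genotypes, matching the planted ground truth of 2.5%
within its bootstrap CI; a 657-kb haplotype shared by six carrier
chromosomes dates the founder allele to about 51 generations.

## Command line

```sh
recburden simulate --config sim.yaml --out data/ --seed 1
recburden run --config run.yaml --out results/ --seed 1
recburden report results/
```

Stage subcommands (`classify`, `call-rg`, `consang`, `burden`,
`contribution`, `founder`, `specificity`) expose individual steps. All
tables are TSV with one-line headers; a manifest records seeds, input
checksums, and stage timings.

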