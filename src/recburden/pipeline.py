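"""Stage orchestration: simulate -> classify -> call RGs -> consanguinity ->
burden -> contribution -> founder -> specificity -> report.

Each stage reads/writes plain TSV (one-line headers) plus JSON mirrors in a
run directory; a manifest records the package version, seeds, input
checksums and stage timings so any table can be reproduced from the
manifest alone. Stage failures raise with the stage name; outputs written
before the failure are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from recburden import __version__, burden, consanguinity, contribution, expression
from recburden import io as rio
from recburden import rg as rg_mod
from recburden import simulate as sim
from recburden.variants import classify_table, rare_mask

logger = logging.getLogger(__name__)

REQUIRED_SIM_KEYS = {"n_trios", "n_singletons", "n_genes"}


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_sim_config(cfg: dict) -> sim.SimConfig:
    unknown = set(cfg) - set(sim.SimConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    missing = REQUIRED_SIM_KEYS - set(cfg)
    if missing:
        raise ValueError(f"missing simulation config keys: {sorted(missing)}")
    cfg = dict(cfg)
    if "f_distribution" in cfg:
        cfg["f_distribution"] = [tuple(x) for x in cfg["f_distribution"]]
    if "causal_genes" in cfg:
        cfg["causal_genes"] = [tuple(x) for x in cfg["causal_genes"]]
    if cfg.get("founder") is not None:
        cfg["founder"] = tuple(cfg["founder"])
    return sim.SimConfig(**cfg)


def run_simulate(cfg: dict, outdir: str, seed: int | None = None) -> dict:
    os.makedirs(outdir, exist_ok=True)
    cfg = dict(cfg)
    if seed is not None:
        cfg["seed"] = seed
    n_panel = int(cfg.pop("panel_individuals", 10_000))
    config = validate_sim_config(cfg)
    panel = sim.simulate_gene_panel(config)
    cohort = sim.simulate_trios(config, panel)
    pairs = sim.simulate_cooccurrence_panel(panel, n_individuals=n_panel, seed=config.seed)
    rio.write_annotation(panel.variants, os.path.join(outdir, "annotation.tsv"))
    rio.write_tsv(
        panel.mutability.rename("mutability").rename_axis("gene").reset_index(),
        os.path.join(outdir, "mutability.tsv"),
    )
    rio.write_tsv(cohort.genotypes, os.path.join(outdir, "genotypes.tsv"))
    rio.write_ped(cohort.pedigree, os.path.join(outdir, "pedigree.ped"))
    rio.write_tsv(cohort.truth_probands, os.path.join(outdir, "truth_probands.tsv"))
    rio.write_tsv(cohort.truth_genes, os.path.join(outdir, "truth_genes.tsv"))
    rio.write_tsv(pairs, os.path.join(outdir, "cooccurrence.tsv"))
    if cohort.marker_map is not None:
        rio.write_tsv(cohort.marker_map, os.path.join(outdir, "marker_map.tsv"))
        pd.DataFrame(
            cohort.marker_genotypes, index=cohort.marker_samples
        ).to_csv(os.path.join(outdir, "marker_genotypes.tsv"), sep="\t")
    samples = list(cohort.pedigree["sample"])
    if len(samples) <= 2000:  # cohort VCF only at desk scale
        rio.write_vcf(
            cohort.genotypes,
            panel.variants,
            samples,
            os.path.join(outdir, "cohort.vcf"),
        )
    return {"config": cfg, "n_samples": len(samples)}


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run all analysis stages on a simulated (or equivalently shaped) dataset.

    ``config`` keys: ``data_dir`` (holding annotation.tsv, genotypes.tsv,
    pedigree.ped, mutability.tsv, cooccurrence.tsv, optional marker files),
    optional ``gene_sets`` (name -> TSV path), ``expression`` (TSV path),
    ``founder_variant`` (variant id), thresholds and ``seed``.
    """
    data_dir = config["data_dir"]
    for required in ("annotation.tsv", "genotypes.tsv", "pedigree.ped", "mutability.tsv"):
        path = os.path.join(data_dir, required)
        if not os.path.exists(path):
            raise FileNotFoundError(f"pipeline validation: missing input {path}")
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    af_threshold = float(config.get("af_threshold", 1e-3))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "inputs": {},
        "stages": {},
    }
    for name in sorted(os.listdir(data_dir)):
        p = os.path.join(data_dir, name)
        if os.path.isfile(p):
            manifest["inputs"][name] = _checksum(p)

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = round(time.monotonic() - t0, 3)

        return wrap

    variants = rio.read_annotation(os.path.join(data_dir, "annotation.tsv"))
    genotypes = rio.read_tsv(os.path.join(data_dir, "genotypes.tsv"))
    pedigree = rio.read_ped(os.path.join(data_dir, "pedigree.ped"))
    mutability = rio.read_tsv(os.path.join(data_dir, "mutability.tsv")).set_index(
        "gene"
    )["mutability"]

    state: dict = {}

    @stage("classify")
    def _classify():
        v = classify_table(variants)
        v["rare"] = rare_mask(v, threshold=af_threshold)
        state["variants"] = v
        rio.write_tsv(v, os.path.join(outdir, "classified.tsv"))

    @stage("call_rg")
    def _call_rg():
        cooc_path = os.path.join(data_dir, "cooccurrence.tsv")
        cooc = rio.read_tsv(cooc_path) if os.path.exists(cooc_path) else None
        rgs = rg_mod.call_rgs(
            genotypes, pedigree, state["variants"], cooc, "damaging", af_threshold
        )
        syn = rg_mod.call_rgs(
            genotypes, pedigree, state["variants"], cooc, "synonymous", af_threshold
        )
        state["rgs"], state["syn_rgs"] = rgs, syn
        rio.write_tsv(rgs, os.path.join(outdir, "rg_table.tsv"))
        rio.write_tsv(syn, os.path.join(outdir, "rg_table_synonymous.tsv"))

    @stage("consanguinity")
    def _consang():
        mm_path = os.path.join(data_dir, "marker_map.tsv")
        probands = pedigree.loc[
            (pedigree["father"] != "0") | (pedigree["phenotype"] == 2), "sample"
        ]
        segments: dict = {}
        if os.path.exists(mm_path):
            marker_map = rio.read_tsv(mm_path, dtype={"chrom": str})
            mg = pd.read_csv(
                os.path.join(data_dir, "marker_genotypes.tsv"), sep="\t", index_col=0
            )
            f_table, segments = consanguinity.estimate_F_cohort(
                mg.to_numpy(dtype=np.int8),
                marker_map,
                list(mg.index),
                return_segments=True,
            )
        else:  # no marker channel: treat cohort as outbred
            f_table = pd.DataFrame(
                {
                    "sample": probands,
                    "F": 0.0,
                    "n_segments": 0,
                    "stratum": "<0.0009",
                    "consanguineous": False,
                }
            )
        parents = pedigree.loc[
            ~pedigree["sample"].isin(set(f_table["sample"])), "sample"
        ]
        f_all = pd.concat(
            [
                f_table,
                pd.DataFrame(
                    {
                        "sample": parents,
                        "F": 0.0,
                        "n_segments": 0,
                        "stratum": "<0.0009",
                        "consanguineous": False,
                    }
                ),
            ],
            ignore_index=True,
        )
        state["f_table"] = f_all
        rio.write_tsv(f_table, os.path.join(outdir, "f_table.tsv"))
        roh_rows = [
            {"chrom": c, "start": s - 1, "end": e, "sample": sample}
            for sample, segs in segments.items()
            for c, s, e in segs
        ]
        rio.write_tsv(
            pd.DataFrame(roh_rows, columns=["chrom", "start", "end", "sample"]),
            os.path.join(outdir, "roh.bed.tsv"),
        )

    @stage("burden")
    def _burden():
        probands = _proband_ids(pedigree)
        rgs = state["rgs"]
        obs = rgs[rgs["sample"].isin(probands)].groupby("gene").size()
        model = burden.fit_expected_model(obs, mutability, n_probands=len(probands))
        results = burden.test_genes(obs, model)
        results = burden.adjust_multiplicity(results, n_genes=len(mutability))
        state["model"], state["gene_results"] = model, results
        rio.write_tsv(results, os.path.join(outdir, "burden_genes.tsv"))
        n = len(results)
        qq = pd.DataFrame(
            {
                "expected_neglog10p": -np.log10((np.arange(n) + 0.5) / n),
                "observed_neglog10p": -np.log10(
                    np.sort(results["p"].to_numpy())
                ),
            }
        )
        rio.write_tsv(qq, os.path.join(outdir, "qq_data.tsv"))
        set_rows = []
        for name, path in (config.get("gene_sets") or {}).items():
            genes = rio.read_gene_set(path) & set(model.expected.index)
            observed = int(
                rgs[rgs["sample"].isin(probands) & rgs["gene"].isin(genes)].shape[0]
            )
            res = burden.gene_set_test(genes, observed, model, unit=name)
            set_rows.append(vars(res))
        if set_rows:
            rio.write_tsv(
                pd.DataFrame(set_rows), os.path.join(outdir, "gene_set_tests.tsv")
            )
            state["gene_set_tests"] = set_rows

    @stage("contribution")
    def _contribution():
        trios = _trios(pedigree)
        if not len(trios):
            state["contribution"] = []
            return
        rows = []
        for vclass in ("synonymous", "LoF", "damaging"):
            try:
                est = contribution.estimate_contribution(
                    genotypes,
                    state["variants"],
                    trios,
                    state["f_table"],
                    variant_class=vclass,
                    af_threshold=af_threshold,
                    bootstrap=int(config.get("bootstrap", 200)),
                    seed=seed,
                )
            except ValueError as exc:
                # degenerate cohort for this class (no qualifying carriers)
                logger.warning("contribution for %s undefined: %s", vclass, exc)
                rows.append(
                    {
                        "variant_class": vclass,
                        "exp_parents": 0.0,
                        "obs_parents": 0,
                        "exp_probands": 0.0,
                        "obs_probands": 0,
                        "n_probands": len(trios),
                        "fraction": float("nan"),
                        "ci_low": None,
                        "ci_high": None,
                    }
                )
                continue
            rows.append(
                {
                    "variant_class": vclass,
                    "exp_parents": round(est.exp_parents, 1),
                    "obs_parents": est.obs_parents,
                    "exp_probands": round(est.exp_probands, 1),
                    "obs_probands": est.obs_probands,
                    "n_probands": est.n_probands,
                    "fraction": est.fraction,
                    "ci_low": est.ci[0] if est.ci else None,
                    "ci_high": est.ci[1] if est.ci else None,
                }
            )
        state["contribution"] = rows
        rio.write_tsv(pd.DataFrame(rows), os.path.join(outdir, "contribution.tsv"))

    @stage("founder")
    def _founder():
        from recburden import founder as fo

        vid = config.get("founder_variant")
        subpop_path = os.path.join(data_dir, "truth_probands.tsv")
        if vid is None or not os.path.exists(subpop_path):
            return
        truth = rio.read_tsv(subpop_path)
        if "founder_subpop" not in truth.columns or not truth["founder_subpop"].any():
            return
        subpop = set(truth.loc[truth["founder_subpop"], "sample"])
        gt = genotypes[
            (genotypes["variant_id"] == vid) & genotypes["sample"].isin(subpop)
        ]
        n_hom = int((gt["dosage"] == 2).sum())
        n_het = int((gt["dosage"] == 1).sum())
        counts = fo.GenotypeCounts(n_hom, n_het, len(subpop) - n_hom - n_het)
        report = fo.founder_report(counts)
        report["variant_id"] = vid
        state["founder"] = report
        with open(os.path.join(outdir, "founder.json"), "w") as fh:
            json.dump(report, fh, indent=2)

    @stage("specificity")
    def _specificity():
        path = config.get("expression")
        if not path:
            return
        matrix = rio.read_tsv(path, index_col=0)
        norm = expression.ratio_of_max(matrix)
        flags = expression.specific_genes(norm, fold=float(config.get("fold", 5.0)))
        Z, leaves = expression.upgma_cluster(norm)
        rio.write_tsv(
            norm.reset_index(names="gene"), os.path.join(outdir, "expression_norm.tsv")
        )
        rio.write_tsv(
            flags.reset_index(), os.path.join(outdir, "specificity_flags.tsv")
        )
        rio.write_tsv(
            pd.DataFrame(Z, columns=["left", "right", "height", "size"]),
            os.path.join(outdir, "linkage.tsv"),
        )
        state["specific_flags"] = flags

    @stage("report")
    def _report():
        summary = build_report(state, pedigree)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        rio.write_tsv(
            pd.DataFrame(summary["rg_rates"]), os.path.join(outdir, "table1_shaped.tsv")
        )
        if state.get("contribution"):
            rio.write_tsv(
                pd.DataFrame(state["contribution"]),
                os.path.join(outdir, "table2_shaped.tsv"),
            )
        top = state["gene_results"].head(30)
        rio.write_tsv(top, os.path.join(outdir, "top_genes.tsv"))

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _proband_ids(pedigree: pd.DataFrame) -> set[str]:
    trio_p = pedigree[(pedigree["father"] != "0") & (pedigree["mother"] != "0")]
    parents = set(trio_p["father"]) | set(trio_p["mother"])
    singles = pedigree[
        (pedigree["father"] == "0")
        & (pedigree["mother"] == "0")
        & ~pedigree["sample"].isin(parents)
    ]
    return set(trio_p["sample"]) | set(singles["sample"])


def _trios(pedigree: pd.DataFrame) -> pd.DataFrame:
    t = pedigree[(pedigree["father"] != "0") & (pedigree["mother"] != "0")]
    return t.rename(columns={"sample": "proband"})[["proband", "father", "mother"]].reset_index(
        drop=True
    )


def build_report(state: dict, pedigree: pd.DataFrame) -> dict:
    probands = _proband_ids(pedigree)
    rgs = state.get("rgs", pd.DataFrame(columns=rg_mod.RG_COLUMNS))
    rates = rg_mod.tabulate_rg_rates(
        rgs[rgs["sample"].isin(probands)] if len(rgs) else rgs, max(len(probands), 1)
    )
    summary = {
        "n_probands": len(probands),
        "n_rgs": int(len(rgs)),
        "rg_rates": rates.to_dict(orient="records"),
    }
    if "f_table" in state:
        f = state["f_table"]
        f = f[f["sample"].isin(probands)]
        summary["consanguinity"] = {
            "mean_F": float(f["F"].mean()) if len(f) else 0.0,
            "n_consanguineous": int(f["consanguineous"].sum()) if len(f) else 0,
            "strata": f["stratum"].value_counts().to_dict() if len(f) else {},
        }
    if state.get("gene_results") is not None:
        gr = state["gene_results"]
        summary["n_bonferroni_significant"] = int(gr["bonferroni_significant"].sum())
    if state.get("contribution"):
        summary["contribution"] = state["contribution"]
    if state.get("founder"):
        summary["founder"] = state["founder"]
    return summary
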