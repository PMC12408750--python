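"""Pipeline orchestration: config validation, stage execution, run report.

Stages run in method order — sample QC, per-contrast probe filtering
and statistics, biomarker scoring with overt-stress flagging,
concentration-response modeling (with stress-flagged concentrations
removed first), tPOD derivation, and mixture prediction — and
communicate only through persisted TSV artifacts under the output
directory, so each stage is independently re-runnable and testable.
Every numeric threshold defaults to the study value and is logged; a
run is fully determined by the input files, the configuration and the
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from copy import deepcopy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiment import CountExperiment
from .qc_filter import (
    QCThresholds,
    contrast_stats,
    qc_report_frame,
    relevance_filter,
    sample_qc,
    size_factors_median_of_ratios,
    spike_filter,
)
from .dose_response import (
    analyze_probes,
    control_sd_log2,
    fit_models,
    postfilter,
    response_matrix,
    select_best,
    trend_prefilter,
)
from .biomarker import (
    max_unflagged_conc,
    read_directional_sets,
    score_contrast,
    scores_frame,
    stress_flag,
)
from .tpod import (
    TPOD,
    bootstrap_ci,
    read_gmt,
    tpod_biomarker,
    tpod_gene25,
    tpod_lcrd,
    tpod_pathway,
    tpod_report,
)
from .mixtures import addition_frame, additivity_check, predict_bmc, read_mixtures

log = logging.getLogger("httrpod")

DEFAULT_CONFIG: dict = {
    "paths": {
        "counts": None,
        "metadata": None,
        "gene_sets": None,
        "biomarkers": None,
        "er_biomarker": None,
        "mixtures": None,
        "probe_gene_map": None,
        "out_dir": None,
    },
    "seed": 0,
    "qc": {
        "target_reads": None,
        "min_reads_fraction": 0.10,
        "gini_max": 0.95,
        "spearman_distance_max": 0.1,
        "outer_fence_k": 3.0,
    },
    "filters": {"cpm_min": 0.5, "group_fraction": 0.75, "remove_when_spiked": True},
    "contrasts": {"p_max": 0.05, "fc_min": 1.2},
    "prefilter": {"williams_alpha": 0.05, "fc_min": 1.5, "n_perm": 1000},
    "bmc": {"bmr_sd": 1.0},
    "postfilter": {"fit_p_min": 0.1, "bmc_bmcl_max": 20.0, "bmcu_bmcl_max": 40.0},
    "stress": {"min_active": 2, "exclude": ["CP"]},
    "tpod": {
        "methods": ["gene25", "pathway5pct", "lcrd"],
        "er_min_fit": 3,
        "activation_required": True,
        "bootstrap": False,
        "n_boot_per_gene": 100,
        "n_experiments": 10000,
    },
    "stages": {
        "qc": True,
        "contrasts": True,
        "biomarker": True,
        "bmc": True,
        "tpod": True,
        "mixtures": True,
    },
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def validate_config(overrides: dict) -> dict:
    """Merge a (possibly partial) config onto the defaults, rejecting
    unknown keys at any level."""
    def merge(default, given, path=""):
        if not isinstance(given, dict):
            raise ConfigError(f"expected a mapping at {path or 'top level'}")
        out = deepcopy(default)
        for key, value in given.items():
            if key not in default:
                raise ConfigError(f"unknown config key: {path}{key}")
            if isinstance(default[key], dict) and default[key]:
                out[key] = merge(default[key], value, f"{path}{key}.")
            else:
                out[key] = value
        return out

    return merge(DEFAULT_CONFIG, overrides or {})


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_probe_gene_map(path: str | Path | None, probe_ids) -> dict:
    """probe → gene map; identity when no map file is given.  Probes
    listed with several genes map to the full list (multi-mapping)."""
    if path is None:
        return {str(p): str(p) for p in probe_ids}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ConfigError("probe_gene_map TSV needs probe_id and gene_id columns")
    out: dict = {}
    for pid, grp in df.groupby("probe_id"):
        genes = sorted(set(grp["gene_id"]))
        out[pid] = genes[0] if len(genes) == 1 else genes
    return out


# ----------------------------------------------------------------------
@dataclass
class ChemicalResult:
    chemical: str
    n_probes_relevant: int
    n_probes_after_spike: int
    n_probes_prefilter: int
    n_genes_bmc: int
    max_analyzed_conc: float
    bmc_table: pd.DataFrame
    tpods: list[TPOD]


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages and return the machine-readable run
    report (also written as ``run_report.json``)."""
    config = validate_config(config)
    paths = config["paths"]
    for key in ("counts", "metadata", "out_dir"):
        if not paths[key]:
            raise ConfigError(f"paths.{key} is required")
    out_dir = Path(paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    log.info("config hash %s, seed %s", config_hash(config), config["seed"])
    for section in ("qc", "filters", "contrasts", "prefilter", "bmc", "postfilter", "stress"):
        log.info("thresholds %s: %s", section, config[section])

    report: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "stages": {},
        "chemicals": {},
    }
    stages = config["stages"]
    try:
        exp = CountExperiment.from_tsv(paths["counts"], paths["metadata"])
    except Exception as err:
        raise StageError(f"stage 'load': {err}") from err

    # ------------------------------------------------------------ QC
    if stages["qc"]:
        try:
            thresholds = QCThresholds(**config["qc"])
            reports = sample_qc(exp, thresholds)
            frame = qc_report_frame(reports)
            frame.to_csv(out_dir / "qc_report.tsv", sep="\t")
            passing = [r.sample_id for r in reports if r.pass_]
            if not passing:
                raise StageError("stage 'qc': no sample passed QC")
            exp = exp.subset_samples(passing)
            report["stages"]["qc"] = {
                "n_samples": len(reports),
                "n_pass": len(passing),
                "n_fail": len(reports) - len(passing),
            }
            log.info("qc: %d/%d samples pass", len(passing), len(reports))
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage 'qc': {err}") from err

    chemicals = sorted(
        set(exp.metadata.loc[exp.metadata["role"] == "treated", "chemical"])
    )
    biomarkers = (
        read_directional_sets(paths["biomarkers"]) if paths["biomarkers"] else {}
    )
    gene_sets = read_gmt(paths["gene_sets"]) if paths["gene_sets"] else {}
    probe_gene = load_probe_gene_map(paths["probe_gene_map"], exp.probe_ids)

    all_scores = []
    filtered: dict[str, CountExperiment] = {}
    # ------------------------------------------- contrasts + biomarker
    if stages["contrasts"]:
        (out_dir / "contrasts").mkdir(exist_ok=True)
        for chem in chemicals:
            try:
                m = exp.metadata
                treated = list(
                    m.index[(m["role"] == "treated") & (m["chemical"] == chem)]
                )
                plates = set(m.loc[treated, "plate"])
                controls = [
                    s for p in sorted(plates) for s in exp.control_samples(plate=p)
                ]
                sub = exp.subset_samples(controls + treated)
                groups = sub.metadata["concentration_uM"].astype(float)
                kept = relevance_filter(
                    sub.counts, groups,
                    cpm_min=config["filters"]["cpm_min"],
                    group_fraction=config["filters"]["group_fraction"],
                )
                n_rel = len(kept)
                kept = spike_filter(
                    sub.counts.loc[kept], groups,
                    remove_when_spiked=config["filters"]["remove_when_spiked"],
                )
                subf = sub.subset_probes(kept)
                filtered[chem] = subf
                sf = size_factors_median_of_ratios(subf.counts)
                concs = sorted(set(groups[groups > 0]))
                for conc in concs:
                    stats_df = contrast_stats(subf, chem, conc, size_factors=sf)
                    stats_df.to_csv(
                        out_dir / "contrasts" / f"{chem}_{conc:g}.tsv", sep="\t"
                    )
                    if stages["biomarker"] and biomarkers:
                        all_scores += score_contrast(
                            stats_df, biomarkers, chem, conc,
                            p_max=config["contrasts"]["p_max"],
                            fc_min=config["contrasts"]["fc_min"],
                        )
                report["chemicals"].setdefault(chem, {})
                report["chemicals"][chem]["n_probes_relevant"] = int(n_rel)
                report["chemicals"][chem]["n_probes_after_spike"] = int(len(kept))
            except Exception as err:
                raise StageError(f"stage 'contrasts' ({chem}): {err}") from err

    scores_df = scores_frame(all_scores) if all_scores else None
    flags = None
    if stages["biomarker"] and scores_df is not None:
        scores_df.to_csv(out_dir / "biomarker_scores.tsv", sep="\t", index=False)
        flags = stress_flag(
            scores_df,
            min_active=config["stress"]["min_active"],
            exclude=tuple(config["stress"]["exclude"]),
        )
        flags.to_csv(out_dir / "stress_flags.tsv", sep="\t", index=False)
        report["stages"]["biomarker"] = {
            "n_scores": len(scores_df),
            "n_flagged_conditions": int(flags["flagged"].sum()),
        }

    # ------------------------------------------------- dose-response
    results: dict[str, ChemicalResult] = {}
    fits_by_chem: dict[str, dict] = {}
    if stages["bmc"]:
        for chem in chemicals:
            try:
                subf = filtered.get(chem, exp)
                m = subf.metadata
                concs = sorted(
                    set(m.loc[m["role"] == "treated", "concentration_uM"].astype(float))
                )
                if flags is not None:
                    cap = max_unflagged_conc(flags, chem, concs)
                else:
                    cap = max(concs)
                resp, conc = response_matrix(subf, chem, max_conc=cap)
                trend = trend_prefilter(
                    resp, conc,
                    alpha=config["prefilter"]["williams_alpha"],
                    fc_min=config["prefilter"]["fc_min"],
                    n_perm=config["prefilter"]["n_perm"],
                    seed=config["seed"],
                )
                trend.to_csv(out_dir / f"trend_{chem}.tsv", sep="\t")
                passing = trend.index[trend["passes_prefilter"]]
                probe_results = analyze_probes(
                    resp, conc, probe_ids=passing, bmr_sd=config["bmc"]["bmr_sd"]
                )
                gene_table, flagged = postfilter(
                    probe_results, cap, probe_gene,
                    fit_p_min=config["postfilter"]["fit_p_min"],
                    bmc_bmcl_max=config["postfilter"]["bmc_bmcl_max"],
                    bmcu_bmcl_max=config["postfilter"]["bmcu_bmcl_max"],
                )
                flagged.to_csv(out_dir / f"bmc_probes_{chem}.tsv", sep="\t")
                gene_table.to_csv(out_dir / f"bmc_table_{chem}.tsv", sep="\t")
                results[chem] = ChemicalResult(
                    chemical=chem,
                    n_probes_relevant=report["chemicals"].get(chem, {}).get(
                        "n_probes_relevant", len(subf.probe_ids)
                    ),
                    n_probes_after_spike=len(subf.probe_ids),
                    n_probes_prefilter=int(trend["passes_prefilter"].sum()),
                    n_genes_bmc=len(gene_table),
                    max_analyzed_conc=cap,
                    bmc_table=gene_table,
                    tpods=[],
                )
                # retain fits of surviving genes for bootstrap CIs
                if config["tpod"]["bootstrap"]:
                    sds = control_sd_log2(resp, conc)
                    member_fits = {}
                    for gene, row in gene_table.iterrows():
                        pid = row["probe_id"]
                        y = resp.loc[pid].to_numpy(dtype=float)
                        best = select_best(fit_models(conc, y))
                        member_fits[gene] = (
                            best, config["bmc"]["bmr_sd"] * float(sds.loc[pid])
                        )
                    fits_by_chem[chem] = member_fits
                report["chemicals"].setdefault(chem, {})
                report["chemicals"][chem].update(
                    {
                        "n_probes_prefilter": int(trend["passes_prefilter"].sum()),
                        "n_genes_bmc": len(gene_table),
                        "max_analyzed_conc": cap,
                    }
                )
                log.info(
                    "bmc %s: %d prefilter, %d genes with BMCs",
                    chem, int(trend["passes_prefilter"].sum()), len(gene_table),
                )
            except Exception as err:
                raise StageError(f"stage 'bmc' ({chem}): {err}") from err

    # ------------------------------------------------------------ tPOD
    tpod_tables: dict[str, pd.DataFrame] = {}
    if stages["tpod"] and results:
        er_name = paths["er_biomarker"]
        er_genes = None
        if er_name and biomarkers and er_name in biomarkers:
            bm = biomarkers[er_name]
            er_genes = sorted(bm.up | bm.down)
        for chem, res in results.items():
            try:
                tpods = []
                methods = config["tpod"]["methods"]
                if "gene25" in methods:
                    tpods.append(tpod_gene25(res.bmc_table))
                if "pathway5pct" in methods and gene_sets:
                    tpods.append(tpod_pathway(res.bmc_table, gene_sets))
                if "lcrd" in methods:
                    tpods.append(tpod_lcrd(res.bmc_table))
                if er_genes:
                    act = None
                    if scores_df is not None:
                        sub = scores_df[
                            (scores_df["chemical"] == chem)
                            & (scores_df["biomarker"] == er_name)
                        ]
                        act = bool((sub["call"] == "activated").any())
                    for mode in ("fifth", "median"):
                        tpods.append(
                            tpod_biomarker(
                                res.bmc_table, er_genes, mode=mode,
                                min_fit=config["tpod"]["er_min_fit"],
                                activation_required=config["tpod"]["activation_required"],
                                activated=act,
                            )
                        )
                if config["tpod"]["bootstrap"] and chem in fits_by_chem:
                    for t in tpods:
                        if t.defined and t.method in ("er_5pct", "er_median") and er_genes:
                            member = {
                                g: fits_by_chem[chem][g]
                                for g in er_genes
                                if g in fits_by_chem[chem]
                            }
                            stat = "fifth" if t.method == "er_5pct" else "median"
                            _, lo, hi = bootstrap_ci(
                                member, res.max_analyzed_conc, statistic=stat,
                                n_boot_per_gene=config["tpod"]["n_boot_per_gene"],
                                n_experiments=config["tpod"]["n_experiments"],
                                seed=config["seed"],
                            )
                            t.lower, t.upper = lo, hi
                res.tpods = tpods
                table = tpod_report(tpods)
                table.to_csv(out_dir / f"tpod_{chem}.tsv", sep="\t")
                tpod_tables[chem] = table
                # gene-accumulation export: rank vs BMC
                acc = res.bmc_table[["bmc"]].copy().sort_values("bmc")
                acc["rank"] = np.arange(1, len(acc) + 1)
                acc.to_csv(out_dir / f"gene_accumulation_{chem}.tsv", sep="\t")
            except Exception as err:
                raise StageError(f"stage 'tpod' ({chem}): {err}") from err
        report["stages"]["tpod"] = {
            chem: {t.method: t.value for t in res.tpods} for chem, res in results.items()
        }

    # ------------------------------------------------------- mixtures
    if stages["mixtures"] and paths["mixtures"] and tpod_tables:
        try:
            mixes = read_mixtures(paths["mixtures"])
            rows = []
            for method in ("gene25", "er_5pct"):
                comp_bmcs = {
                    chem: (
                        float(tab.loc[method, "value"])
                        if method in tab.index and pd.notna(tab.loc[method, "value"])
                        else None
                    )
                    for chem, tab in tpod_tables.items()
                }
                for mix in mixes:
                    comps = [
                        (float(f), comp_bmcs.get(c))
                        for c, f in zip(mix.chemicals, mix.fractions)
                    ]
                    pred = predict_bmc(comps)
                    emp = emp_l = emp_u = None
                    if mix.name in tpod_tables and method in tpod_tables[mix.name].index:
                        row = tpod_tables[mix.name].loc[method]
                        emp = float(row["value"]) if pd.notna(row["value"]) else None
                        emp_l = float(row["lower"]) if pd.notna(row["lower"]) else None
                        emp_u = float(row["upper"]) if pd.notna(row["upper"]) else None
                    rows.append(
                        additivity_check(mix.name, method, pred, emp, emp_l, emp_u)
                    )
            frame = addition_frame(rows)
            frame.to_csv(out_dir / "mixture_predictions.tsv", sep="\t", index=False)
            report["stages"]["mixtures"] = {
                "n_predictions": len(frame),
                "n_within_interval": int((frame["within_interval"] == True).sum()),  # noqa: E712
            }
        except Exception as err:
            raise StageError(f"stage 'mixtures': {err}") from err

    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
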