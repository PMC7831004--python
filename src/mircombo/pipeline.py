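"""End-to-end orchestration: simulate -> synergy -> overlap -> dose ->
cluster -> sites -> survival, from one config and one master seed.

Every stage writes plain TSV/JSON artifacts into the output directory; the
consolidated summary records per-stage results, timings and the SHA-256 of
every file written, so a rerun with the same config can be verified
hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import dose as dose_mod
from . import overlap as overlap_mod
from . import sites as sites_mod
from . import survival as survival_mod
from . import synergy as synergy_mod
from . import synth as synth_mod

log = logging.getLogger("mircombo")

STAGES = ("simulate", "synergy", "overlap", "dose", "cluster", "sites", "survival")

# fixed per-stage seed offsets derived from the master seed
_STAGE_SEED_OFFSET = {name: 1000 + i for i, name in enumerate(STAGES)}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed * 10_007 + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


class RunConfig:
    """Validated run configuration (YAML mapping with per-stage blocks)."""

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        self.seed = int(raw.get("seed", 0))
        synth_block = dict(raw.get("synth", {}))
        synth_block.setdefault("seed", self.seed)
        self.synth = synth_mod.SynthConfig.from_dict(synth_block)
        self.synth.validate()
        self.synergy = {"endpoint_h": 120.0, "model": "all", "bootstrap": 0,
                        **raw.get("synergy", {})}
        self.overlap = {
            "direction": "down",
            "min_studies": 2,
            "coding_only": True,
            "min_mirnas": 2,
            "iters": 10_000,
            **raw.get("overlap", {}),
        }
        self.dose = {"sd_max": 0.5, **raw.get("dose", {})}
        self.cluster = {"min_targets": 1, "k": None, "n_bootstrap": 0,
                        **raw.get("cluster", {})}
        self.sites = {"types": list(sites_mod.DEFAULT_SITE_TYPES),
                      **raw.get("sites", {})}
        self.survival = {"split_quantile": 0.5, **raw.get("survival", {})}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig, outdir) -> dict:
    """Run all stages in dependency order; return the summary dict.

    The summary (also written to ``summary.json``) contains each stage's
    headline numbers, elapsed seconds and output-file hashes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {"seed": config.seed, "stages": {}}
    files: dict[str, str] = {}
    try:
        inputs = _stage(summary, "simulate", _run_simulate, config, out, files)
        _stage(summary, "synergy", _run_synergy, config, out, files, inputs)
        ov = _stage(summary, "overlap", _run_overlap, config, out, files, inputs)
        _stage(summary, "dose", _run_dose, config, out, files, inputs, ov)
        _stage(summary, "cluster", _run_cluster, config, out, files, inputs)
        _stage(summary, "sites", _run_sites, config, out, files, inputs)
        _stage(summary, "survival", _run_survival, config, out, files, inputs)
    finally:
        log.removeHandler(handler)
        handler.close()

    summary["files"] = {name: _sha256(Path(p)) for name, p in files.items()}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage(summary, name, fn, config, out, files, *args):
    t0 = time.perf_counter()
    log.info("stage %s started (seed %d)", name, stage_seed(config.seed, name))
    try:
        result, stage_files, report = fn(config, out, *args)
    except Exception:
        log.exception(
            "stage %s failed (seed %d)", name, stage_seed(config.seed, name)
        )
        raise
    elapsed = time.perf_counter() - t0
    files.update(stage_files)
    summary["stages"][name] = {"elapsed_s": round(elapsed, 3), **report}
    log.info("stage %s finished in %.2fs", name, elapsed)
    return result


def _run_simulate(config, out):
    indir = out / "inputs"
    paths = synth_mod.write_all(config.synth, indir)
    report = {"n_files": len(paths), "synth_seed": config.synth.seed}
    return paths, paths, report


def _run_synergy(config, out, inputs):
    curves = pd.read_csv(inputs["growth_curves"], sep="\t")
    endpoint = float(config.synergy["endpoint_h"])
    effects = synergy_mod.estimate_effects(curves, endpoint_h=endpoint)
    models = (
        ["linear", "bliss_paper", "bliss_canonical"]
        if config.synergy["model"] == "all"
        else [config.synergy["model"]]
    )
    rows = []
    for m in models:
        if config.synergy["bootstrap"]:
            ci = synergy_mod.bootstrap_ci(
                curves,
                m,
                endpoint_h=endpoint,
                n_boot=int(config.synergy["bootstrap"]),
                seed=stage_seed(config.seed, "synergy"),
            )
        elif m == "linear":
            ci = synergy_mod.linear_ci(effects)
        else:
            ci = synergy_mod.bliss_ci(effects, m.removeprefix("bliss_"))
        rows.append(
            {
                "model": ci.model,
                "ci": ci.ci,
                "interpretation": ci.interpretation,
                "ci_low": ci.ci_low,
                "ci_high": ci.ci_high,
            }
        )
    ci_df = pd.DataFrame(rows)
    eff_df = pd.DataFrame(
        {
            "arm": ["A", "B", "C", "ABC"],
            "effect": [effects.E_A, effects.E_B, effects.E_C, effects.E_ABC],
            "se": [effects.se_A, effects.se_B, effects.se_C, effects.se_ABC],
            "endpoint_h": effects.endpoint_h,
        }
    )
    endpoint_groups = {
        arm: synergy_mod._endpoint_values(curves, arm, endpoint)
        for arm in curves["arm"].unique()
    }
    anova = synergy_mod.endpoint_comparison(endpoint_groups)
    _save(eff_df, out / "effects.tsv")
    _save(ci_df, out / "combination_indices.tsv")
    _save(anova["tukey"], out / "tukey_pairs.tsv")
    files = {
        "effects": str(out / "effects.tsv"),
        "combination_indices": str(out / "combination_indices.tsv"),
        "tukey_pairs": str(out / "tukey_pairs.tsv"),
    }
    report = {
        "linear_ci": float(ci_df.loc[ci_df["model"] == "linear", "ci"].iloc[0])
        if "linear" in models
        else None,
        "anova_p": anova["anova_p"],
        "models": {r["model"]: r["ci"] for r in rows},
    }
    return ci_df, files, report


def _load_studies(inputs):
    return [
        pd.read_csv(inputs[f"de_study{i}"], sep="\t") for i in (1, 2, 3)
    ]


def _run_overlap(config, out, inputs):
    studies = _load_studies(inputs)
    target_map = pd.read_csv(inputs["target_map"], sep="\t")
    p = config.overlap
    ov = overlap_mod.build_overlap(
        studies,
        p["direction"],
        min_studies=int(p["min_studies"]),
        coding_only=bool(p["coding_only"]),
    )
    universe = set()
    for direction in ("up", "down"):
        o = overlap_mod.build_overlap(
            studies, direction, min_studies=1, coding_only=False
        )
        universe |= o.union
    enr = overlap_mod.permutation_enrichment(
        ov.consensus,
        universe | ov.consensus,
        target_map,
        min_mirnas=int(p["min_mirnas"]),
        iters=int(p["iters"]),
        seed=stage_seed(config.seed, "overlap"),
    )
    consensus_df = pd.DataFrame({"gene_id": sorted(ov.consensus)})
    venn_df = pd.DataFrame(
        [
            {"studies": "+".join(k), "n_genes": v}
            for k, v in sorted(ov.venn_counts.items())
        ]
    )
    _save(consensus_df, out / "consensus_genes.tsv")
    _save(venn_df, out / "venn_counts.tsv")
    enr_dict = {
        k: v for k, v in enr.__dict__.items() if k != "null_fractions"
    }
    with open(out / "enrichment.json", "w") as fh:
        json.dump(enr_dict, fh, indent=2, default=_jsonable)
    files = {
        "consensus_genes": str(out / "consensus_genes.tsv"),
        "venn_counts": str(out / "venn_counts.tsv"),
        "enrichment": str(out / "enrichment.json"),
    }
    report = {
        "consensus_size": len(ov.consensus),
        "n_conflicts_removed": len(ov.removed_conflicts),
        "observed_fraction": enr.observed_fraction,
        "empirical_p": enr.empirical_p,
        "normal_approx_p": enr.normal_approx_p,
        "z": enr.z,
    }
    return ov, files, report


def _run_dose(config, out, inputs, ov):
    studies = _load_studies(inputs)
    target_map = pd.read_csv(inputs["target_map"], sep="\t")
    by_count = dose_mod.lfc_by_targeting(studies, target_map)
    burden = dose_mod.burden_classification(
        ov.consensus if ov.direction == "down" else set(),
        studies,
        target_map,
        sd_max=float(config.dose["sd_max"]),
    )
    cat = dose_mod.site_category_test(burden)
    _save(burden.records, out / "silencing_records.tsv")
    results = {
        "by_targeting_count": by_count,
        "chi2": cat["chi2"],
        "chi2_p": cat["chi2_p"],
        "chi2_unreliable": cat["chi2_unreliable"],
        "sites_rank_sum_p": cat["sites_rank_sum_p"],
        "table": cat["table"],
        "q1": burden.q1,
        "q3": burden.q3,
        "n_excluded": burden.n_excluded,
    }
    with open(out / "dose_tests.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_jsonable)
    files = {
        "silencing_records": str(out / "silencing_records.tsv"),
        "dose_tests": str(out / "dose_tests.json"),
    }
    report = {
        "chi2_p": cat["chi2_p"],
        "rank_sum_p_by_study": {s: r["p_value"] for s, r in by_count.items()},
        "monotone": {s: r["monotone_decreasing"] for s, r in by_count.items()},
    }
    return results, files, report


def _run_cluster(config, out, inputs):
    fam_long = pd.read_csv(inputs["family_targets"], sep="\t")
    families = cluster_mod.families_from_long(fam_long)
    p = config.cluster
    kept, shared = cluster_mod.filter_families(
        families, min_targets=int(p["min_targets"])
    )
    mat = cluster_mod.shared_matrix(kept)
    k = p["k"] if p["k"] is not None else len(
        synth_mod.SynthConfig().family_group_sizes
    )
    res = cluster_mod.cluster_families(
        kept,
        k=int(k),
        n_bootstrap=int(p["n_bootstrap"]),
        seed=stage_seed(config.seed, "cluster"),
    )
    mat.counts_frame().to_csv(out / "shared_counts.tsv", sep="\t")
    mat.pct_frame().to_csv(out / "shared_pct.tsv", sep="\t")
    _save(cluster_mod.merge_table(res), out / "merges.tsv")
    (out / "dendrogram.nwk").write_text(cluster_mod.to_newick(res) + "\n")
    files = {
        "shared_counts": str(out / "shared_counts.tsv"),
        "shared_pct": str(out / "shared_pct.tsv"),
        "merges": str(out / "merges.tsv"),
        "dendrogram": str(out / "dendrogram.nwk"),
    }
    report = {
        "n_families": len(kept),
        "n_shared_genes": len(shared),
        "flat": res.flat,
        "bootstrap_support": res.bootstrap_support,
    }
    return res, files, report


def _run_sites(config, out, inputs):
    types = tuple(config.sites["types"])
    site_table = sites_mod.scan_fasta(
        inputs["sequences"], synth_mod.MIRNA_SEQUENCES, types=types
    )
    ids, counts = sites_mod.triple_targeted(
        inputs["sequences"], synth_mod.MIRNA_SEQUENCES, types=types
    )
    _save(site_table, out / "seed_sites.tsv")
    _save(pd.DataFrame({"sequence_id": ids}), out / "triple_targeted.tsv")
    files = {
        "seed_sites": str(out / "seed_sites.tsv"),
        "triple_targeted": str(out / "triple_targeted.tsv"),
    }
    report = {"n_sites": len(site_table), "n_triple_targeted": len(ids)}
    return (site_table, ids), files, report


def _run_survival(config, out, inputs):
    cohort = pd.read_csv(inputs["survival_cohort"], sep="\t")
    expr_cols = [
        c for c in cohort.columns if c not in ("patient_id", "time", "event")
    ]
    scores = survival_mod.zscore_average(cohort[expr_cols])
    km = survival_mod.km_logrank(
        cohort, scores, split_quantile=float(config.survival["split_quantile"])
    )
    r, pmat = survival_mod.pearson_matrix(cohort[expr_cols])
    scores_df = pd.DataFrame(
        {"patient_id": cohort["patient_id"], "avg_z": scores}
    )
    _save(scores_df, out / "scores.tsv")
    for name, curve in km.curves.items():
        _save(curve, out / f"km_{name}.tsv")
    r.to_csv(out / "pearson_r.tsv", sep="\t")
    results = {
        "logrank_stat": km.logrank_stat,
        "logrank_p": km.p_value,
        "threshold": km.threshold,
        "group_sizes": km.group_sizes,
        "median_survival": km.median_survival,
        "pearson_r": r.to_dict(),
        "pearson_p": pmat.to_dict(),
    }
    with open(out / "survival_tests.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_jsonable)
    files = {
        "scores": str(out / "scores.tsv"),
        "km_low": str(out / "km_low.tsv"),
        "km_high": str(out / "km_high.tsv"),
        "pearson_r": str(out / "pearson_r.tsv"),
        "survival_tests": str(out / "survival_tests.json"),
    }
    report = {
        "logrank_p": km.p_value,
        "median_survival": km.median_survival,
    }
    return results, files, report
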