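"""End-to-end orchestration: simulate/load -> connectivity -> metrics ->
null models -> group inference -> report.

Every stage reads and writes plain-text files under one output directory, so
stages can be re-run individually (and the report can be regenerated from
saved intermediates byte-for-byte).  All randomness flows from the single
``seed`` in :class:`RunConfig`; stage seeds are spawned deterministically.

Output layout::

    out_dir/
      manifest.tsv  timeseries/  behavior.tsv  truth.json     (simulate mode)
      matrices/<subject>.tsv  group_mean_<group>.tsv
      curves.tsv            tidy metric values + "auc" rows
      nodal_auc.tsv         subject x region nodal-efficiency AUCs
      normalized.tsv        tidy lambda/gamma values + "auc" rows
      comparisons.json      group tests, hubs, subsample, behaviour
      nbs.json              NBS components + exports (.node/.edge)
      report.json summary.md
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, metrics, nullmodels, synthetic
from .connectivity import (
    ConnectivityMatrix,
    group_mean_matrix,
    pearson_matrix,
    rectify_negatives,
)
from .labels import NodeLabelTable, generic_labels
from .synthetic import CohortSpec

log = logging.getLogger("funconn")

AUC_METRICS = (
    "global_efficiency",
    "local_efficiency",
    "normalized_global_efficiency",
    "normalized_local_efficiency",
)
_TIDY_NAME = {"normalized_global_efficiency": "lambda",
              "normalized_local_efficiency": "gamma"}


@dataclass
class RunConfig:
    """Flat configuration of one full analysis run."""

    mode: str = "simulate"  # simulate | timeseries_dir | matrices_dir
    input_dir: str = ""
    labels_file: str = ""
    out_dir: str = "funconn_out"
    # cohort (simulate mode)
    n_patients: int = 28
    n_controls: int = 40
    n_rois: int = 90
    n_timepoints: int = 235
    within_r: float = 0.5
    between_r: float = 0.1
    planting: str = "null"  # null | hub | component
    group_delta: float = 0.2
    n_hubs: int = 8
    component_nodes: int = 12
    component_edges: int = 40
    # analysis
    grid_start: float = 0.05
    grid_stop: float = 0.40
    grid_step: float = 0.02
    ensemble_size: int = 100
    swap_factor: int = 10
    n_perm: int = 10000
    primary_p: float = 0.01
    tail: str = "two_sided"
    alpha: float = 0.05
    n_iter_subsample: int = 10000
    subsample_n_perm: int = 1000
    run_subsample_tests: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("simulate", "timeseries_dir", "matrices_dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate":
            if not self.input_dir or not Path(self.input_dir).exists():
                raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if not 0 < self.primary_p < 1:
            raise ValueError("primary_p must lie in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be at least 1")
        if self.planting not in ("null", "hub", "component"):
            raise ValueError(f"unknown planting {self.planting!r}")
        if self.tail not in inference.TAILS:
            raise ValueError(f"unknown tail {self.tail!r}")
        if not (0 < self.grid_start < self.grid_stop <= 1):
            raise ValueError("grid bounds must satisfy 0 < start < stop <= 1")

    def grid(self) -> np.ndarray:
        g = np.round(
            np.arange(self.grid_start, self.grid_stop - 1e-9, self.grid_step), 6
        )
        if len(g) < 2:
            raise ValueError("sparsity grid must contain at least 2 points")
        return g

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: s.lower() in ("1", "true", "yes")}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = casts[types[key]](val)
        values.update(overrides)
        return cls(**values)


def _stage_seed(cfg: RunConfig, stage: str) -> np.random.Generator:
    stages = ("simulate", "nulls", "compare", "nbs")
    children = np.random.SeedSequence(cfg.seed).spawn(len(stages))
    return np.random.default_rng(children[stages.index(stage)])


def _labels_for(cfg: RunConfig) -> NodeLabelTable:
    if cfg.labels_file:
        return NodeLabelTable.from_tsv(cfg.labels_file)
    return generic_labels(cfg.n_rois)


def cohort_spec_from_config(cfg: RunConfig) -> CohortSpec:
    common = dict(
        n_patients=cfg.n_patients, n_controls=cfg.n_controls,
        n_rois=cfg.n_rois, n_timepoints=cfg.n_timepoints,
        within_r=cfg.within_r, between_r=cfg.between_r, seed=cfg.seed,
    )
    if cfg.planting == "null":
        return CohortSpec(**common)
    if cfg.planting == "hub":
        return synthetic.hub_enhanced_spec(
            delta=cfg.group_delta, n_hubs=cfg.n_hubs, **common
        )
    return synthetic.planted_component_spec(
        n_component_nodes=cfg.component_nodes,
        n_component_edges=cfg.component_edges,
        delta=cfg.group_delta, **common,
    )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    cohort = synthetic.make_cohort(cohort_spec_from_config(cfg))
    io.write_cohort(cohort, cfg.out_dir, labels)
    log.info("simulate: %d subjects written in %.1fs",
             len(cohort.panels), time.perf_counter() - t0)


def _manifest(cfg: RunConfig) -> pd.DataFrame:
    root = Path(cfg.input_dir if cfg.mode != "simulate" else cfg.out_dir)
    return pd.read_csv(root / "manifest.tsv", sep="\t")


def _load_matrices(cfg: RunConfig, labels: NodeLabelTable):
    """(subject_id, group, rectified matrix) triples from the matrices dir."""
    out = Path(cfg.out_dir)
    mdir = (Path(cfg.input_dir) if cfg.mode == "matrices_dir"
            else out / "matrices")
    manifest = _manifest(cfg)
    triples = []
    for row in manifest.itertuples():
        m = io.read_matrix_tsv(mdir / f"{row.subject_id}.tsv", labels,
                               subject_id=row.subject_id, rectified=True)
        triples.append((row.subject_id, row.group, m))
    return triples


def stage_connectivity(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    src = Path(cfg.input_dir) if cfg.mode == "timeseries_dir" else out
    if cfg.mode == "matrices_dir":
        # precomputed matrices: rectify and copy into the run directory
        manifest = pd.read_csv(Path(cfg.input_dir) / "manifest.tsv", sep="\t")
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        for row in manifest.itertuples():
            m = io.read_matrix_tsv(Path(cfg.input_dir) / f"{row.subject_id}.tsv",
                                   labels, subject_id=row.subject_id)
            io.write_matrix_tsv(rectify_negatives(m),
                                out / "matrices" / f"{row.subject_id}.tsv", labels)
    else:
        panels = io.read_cohort_dir(src, labels)
        if cfg.mode == "timeseries_dir":
            pd.read_csv(src / "manifest.tsv", sep="\t").to_csv(
                out / "manifest.tsv", sep="\t", index=False)
        for panel in panels:
            m = rectify_negatives(pearson_matrix(panel))
            io.write_matrix_tsv(m, out / "matrices" / f"{panel.subject_id}.tsv",
                                labels)
    triples = _load_matrices(cfg, labels)
    for group in ("patient", "control"):
        mats = [m for _, g, m in triples if g == group]
        if mats:
            io.write_matrix_tsv(group_mean_matrix(mats),
                                out / f"group_mean_{group}.tsv", labels)
    log.info("connectivity: %d matrices in %.1fs",
             len(triples), time.perf_counter() - t0)


def stage_metrics(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    grid = cfg.grid()
    rows, nodal_rows = [], []
    for sid, group, m in _load_matrices(cfg, labels):
        for name in ("global_efficiency", "local_efficiency"):
            curve = metrics.metric_curve(m, grid, name)
            for s, v in zip(grid, curve.values):
                rows.append(dict(subject_id=sid, group=group, metric=name,
                                 sparsity=s, value=v))
            rows.append(dict(subject_id=sid, group=group, metric=name,
                             sparsity="auc", value=metrics.auc(curve).auc))
        nodal = metrics.metric_curve(m, grid, "nodal_efficiency")
        nodal_auc = metrics.auc(nodal).auc  # (n_rois,)
        nodal_rows.append({"subject_id": sid, "group": group,
                           **dict(zip(labels.abbreviations, nodal_auc))})
    io.write_tidy_tsv(io.curves_to_frame(rows), out / "curves.tsv")
    pd.DataFrame(nodal_rows).to_csv(out / "nodal_auc.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    log.info("metrics: %d rows in %.1fs", len(rows), time.perf_counter() - t0)


def stage_nulls(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    grid = cfg.grid()
    rng = _stage_seed(cfg, "nulls")
    rows = []
    for sid, group, m in _load_matrices(cfg, labels):
        nc = nullmodels.normalize_curves(
            m, grid, ensemble_size=cfg.ensemble_size, seed=rng,
            swap_factor=cfg.swap_factor,
        )
        for tidy, curve, summary in (
            ("lambda", nc.lambda_curve, nc.lambda_auc()),
            ("gamma", nc.gamma_curve, nc.gamma_auc()),
        ):
            for s, v in zip(grid, curve):
                rows.append(dict(subject_id=sid, group=group, metric=tidy,
                                 sparsity=s, value=v))
            rows.append(dict(subject_id=sid, group=group, metric=tidy,
                             sparsity="auc", value=summary.auc))
    io.write_tidy_tsv(io.curves_to_frame(rows), out / "normalized.tsv")
    log.info("nulls: ensemble %d x %d subjects in %.1fs",
             cfg.ensemble_size, len(rows) and len({r['subject_id'] for r in rows}),
             time.perf_counter() - t0)


def _auc_table(out: Path) -> pd.DataFrame:
    """subject_id, group, one column per AUC metric (absolute + normalized)."""
    curves = io.read_tidy_tsv(out / "curves.tsv")
    normed = io.read_tidy_tsv(out / "normalized.tsv")
    tidy = pd.concat([curves, normed])
    aucs = tidy[tidy["sparsity"] == "auc"].copy()
    rename = {v: k for k, v in _TIDY_NAME.items()}
    aucs["metric"] = aucs["metric"].replace(rename)
    wide = aucs.pivot_table(index=["subject_id", "group"], columns="metric",
                            values="value").reset_index()
    return wide


def _mean_curves(out: Path, group: str) -> dict[str, np.ndarray]:
    normed = io.read_tidy_tsv(out / "normalized.tsv")
    sel = normed[(normed["group"] == group) & (normed["sparsity"] != "auc")]
    result = {}
    for tidy in ("lambda", "gamma"):
        sub = sel[sel["metric"] == tidy]
        by_s = sub.groupby(sub["sparsity"].astype(float))["value"].mean()
        result[tidy] = by_s.sort_index()
    return result


def stage_compare(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    rng = _stage_seed(cfg, "compare")
    wide = _auc_table(out)
    pat = wide[wide["group"] == "patient"]
    con = wide[wide["group"] == "control"]
    result: dict = {"auc_comparisons": {}, "n_patients": len(pat),
                    "n_controls": len(con)}

    for name in AUC_METRICS:
        a = pat[name].to_numpy(float)
        b = con[name].to_numpy(float)
        res = inference.mean_diff_permutation_test(
            a, b, n_perm=cfg.n_perm, tail=cfg.tail, seed=rng, metric_name=name)
        result["auc_comparisons"][name] = {
            "patient_mean": float(a.mean()), "patient_sd": float(a.std(ddof=1)),
            "control_mean": float(b.mean()), "control_sd": float(b.std(ddof=1)),
            "observed_diff": res.observed_diff, "p_value": res.p_value,
            "tail": res.tail, "n_perm": res.n_perm,
        }

    # nodal comparison, Bonferroni across regions
    nodal = pd.read_csv(out / "nodal_auc.tsv", sep="\t")
    abbr = labels.abbreviations
    na = nodal[nodal["group"] == "patient"][abbr].to_numpy(float)
    nb = nodal[nodal["group"] == "control"][abbr].to_numpy(float)
    nodal_res = inference.nodal_comparison(
        na, nb, n_perm=cfg.n_perm, seed=rng, tail=cfg.tail, alpha=cfg.alpha)
    sig = np.nonzero(nodal_res.significant)[0]
    result["nodal_comparison"] = {
        "n_significant": int(sig.size),
        "significant_regions": [abbr[i] for i in sig],
        "significant_directions": {
            abbr[i]: ("patient>control" if nodal_res.observed_diff[i] > 0
                      else "patient<control") for i in sig},
        "bonferroni_threshold": nodal_res.bonferroni_threshold,
    }

    # hubs per group, from nodal-efficiency AUCs
    result["hubs"] = {}
    for group, arr in (("patient", na), ("control", nb)):
        hubs = metrics.identify_hubs(arr, group=group)
        idx = hubs.hub_indices()
        result["hubs"][group] = {
            "threshold": hubs.threshold,
            "regions": [abbr[i] for i in idx],
        }
        io.write_node_file(out / f"hubs_{group}.node", labels,
                           sizes=hubs.regional_mean / max(hubs.threshold, 1e-12),
                           subset=idx)

    # balanced-subsample robustness
    result["balanced_subsample"] = {}
    for name in AUC_METRICS:
        rep = inference.balanced_subsample_analysis(
            pat[name].to_numpy(float), con[name].to_numpy(float),
            n_iter=cfg.n_iter_subsample, seed=rng, metric_name=name,
            run_tests=cfg.run_subsample_tests, n_perm=cfg.subsample_n_perm,
            tail=cfg.tail, alpha=cfg.alpha)
        result["balanced_subsample"][name] = {
            "full_sample_diff": rep.full_sample_diff,
            "ci_low": rep.ci_low, "ci_high": rep.ci_high,
            "inside_ci": rep.inside_ci, "n_iter": rep.n_iter,
            "n_significant": rep.n_significant,
        }

    # brain-behaviour correlations for metrics with significant differences
    behavior_path = out / "behavior.tsv"
    if cfg.mode != "simulate" and cfg.input_dir:
        cand = Path(cfg.input_dir) / "behavior.tsv"
        if cand.exists():
            behavior_path = cand
    result["behavior_correlations"] = []
    if behavior_path.exists():
        behav = io.read_behavior_tsv(behavior_path)
        merged = pat.merge(behav.table, on=["subject_id", "group"])
        sig_metrics = [n for n in AUC_METRICS
                       if result["auc_comparisons"][n]["p_value"] < cfg.alpha]
        if sig_metrics and len(merged) >= 3:
            corrs = inference.behavior_correlation(
                {n: merged[n].to_numpy(float) for n in sig_metrics},
                {s: merged[s].to_numpy(float) for s in behav.score_names},
            )
            result["behavior_correlations"] = [
                {"metric": c.metric_name, "score": c.score_name,
                 "r": c.r, "p": c.p, "p_fdr": c.p_fdr} for c in corrs]

    # small-world statement from group-mean normalized curves
    result["smallworld"] = {}
    for group in ("patient", "control"):
        mc = _mean_curves(out, group)
        lam = mc["lambda"].to_numpy(float)
        gam = mc["gamma"].to_numpy(float)
        lo, hi = nullmodels.LAMBDA_BAND
        flags = (gam > 1) & (lam >= lo) & (lam <= hi)
        result["smallworld"][group] = {
            "fraction_of_grid": float(flags.mean()),
            "whole_range": bool(flags.all()),
            "mean_lambda": float(np.nanmean(lam)),
            "mean_gamma": float(np.nanmean(gam)),
        }

    io.write_json(result, out / "comparisons.json")
    log.info("compare: done in %.1fs", time.perf_counter() - t0)


def stage_nbs(cfg: RunConfig, labels: NodeLabelTable) -> None:
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    rng = _stage_seed(cfg, "nbs")
    triples = _load_matrices(cfg, labels)
    pats = [m for _, g, m in triples if g == "patient"]
    cons = [m for _, g, m in triples if g == "control"]
    abbr = labels.abbreviations
    report: dict = {"primary_p": cfg.primary_p, "n_perm": cfg.n_perm,
                    "directions": {}}
    for direction, a, b, tag in (
        ("A_gt_B", pats, cons, "patient_gt_control"),
        ("B_gt_A", pats, cons, "control_gt_patient"),
    ):
        res = inference.nbs(a, b, primary_p=cfg.primary_p, n_perm=cfg.n_perm,
                            direction=direction, seed=rng)
        comps = []
        for k, c in enumerate(res.components):
            comps.append({
                "n_nodes": len(c.nodes), "n_edges": c.size,
                "corrected_p": c.corrected_p,
                "nodes": [abbr[i] for i in c.nodes],
                "edges": [[abbr[i], abbr[j]] for i, j in c.edges],
            })
            if c.corrected_p <= cfg.alpha:
                adj = np.zeros((len(labels), len(labels)))
                for i, j in c.edges:
                    adj[i, j] = adj[j, i] = 1.0
                io.write_edge_file(out / f"nbs_{tag}_comp{k + 1}.edge", adj)
                io.write_node_file(out / f"nbs_{tag}_comp{k + 1}.node", labels,
                                   subset=np.asarray(c.nodes, dtype=int))
        report["directions"][tag] = {
            "components": comps,
            "n_significant": sum(c.corrected_p <= cfg.alpha
                                 for c in res.components),
            "max_null_size_p95": float(np.percentile(res.null_max_sizes, 95))
            if cfg.n_perm > 0 else None,
        }
    io.write_json(report, out / "nbs.json")
    log.info("nbs: done in %.1fs", time.perf_counter() - t0)


def stage_report(cfg: RunConfig, labels: NodeLabelTable) -> dict:
    """Assemble report.json and summary.md from saved intermediates only."""
    out = Path(cfg.out_dir)
    comparisons = io.read_json(out / "comparisons.json")
    nbs_rep = io.read_json(out / "nbs.json")
    truth = io.read_json(out / "truth.json") if (out / "truth.json").exists() else None
    report = {
        "config": {f.name: getattr(cfg, f.name) for f in fields(RunConfig)},
        "comparisons": comparisons,
        "nbs": nbs_rep,
    }
    sig = [n for n in AUC_METRICS
           if comparisons["auc_comparisons"][n]["p_value"] < cfg.alpha]
    report["significant_metrics"] = sig
    if truth is not None:
        expected = truth.get("expected_directions", {})
        agreement = {}
        for key, want in expected.items():
            name = key.removesuffix("_auc")
            if name in comparisons["auc_comparisons"]:
                c = comparisons["auc_comparisons"][name]
                got = "patient>control" if c["observed_diff"] > 0 else "patient<control"
                agreement[key] = {"expected": want, "observed": got,
                                  "significant": c["p_value"] < cfg.alpha,
                                  "match": got == want}
        report["truth"] = {"null_cohort": truth["null_cohort"],
                           "direction_agreement": agreement}
    io.write_json(report, out / "report.json")
    _write_summary_md(out, cfg, report)
    return report


def _write_summary_md(out: Path, cfg: RunConfig, report: dict) -> None:
    lines = ["# Functional network analysis summary", ""]
    comp = report["comparisons"]
    lines.append(f"Subjects: {comp['n_patients']} patients, "
                 f"{comp['n_controls']} controls.")
    lines.append("")
    lines.append("## Small-world organization")
    for group, sw in comp["smallworld"].items():
        where = ("over the whole sparsity range" if sw["whole_range"]
                 else f"at {sw['fraction_of_grid']:.0%} of sparsity levels")
        lines.append(f"- {group}: small-world {where} "
                     f"(mean lambda {sw['mean_lambda']:.3f}, "
                     f"mean gamma {sw['mean_gamma']:.3f})")
    lines.append("")
    lines.append("## Group differences in AUC metrics")
    lines.append("| metric | patients (mean ± SD) | controls (mean ± SD) | p |")
    lines.append("|---|---|---|---|")
    for name in AUC_METRICS:
        c = comp["auc_comparisons"][name]
        lines.append(
            f"| {name} | {c['patient_mean']:.3f} ± {c['patient_sd']:.3f} "
            f"| {c['control_mean']:.3f} ± {c['control_sd']:.3f} "
            f"| {c['p_value']:.4g} |")
    if not report["significant_metrics"]:
        lines.append("")
        lines.append("No significant group differences in global AUC metrics.")
    lines.append("")
    lines.append("## Hubs")
    for group, h in comp["hubs"].items():
        lines.append(f"- {group}: {len(h['regions'])} hubs "
                     f"({', '.join(h['regions']) or 'none'})")
    lines.append("")
    lines.append("## NBS components")
    any_comp = False
    for tag, d in report["nbs"]["directions"].items():
        for c in d["components"]:
            if c["corrected_p"] <= cfg.alpha:
                any_comp = True
                lines.append(f"- {tag}: {c['n_edges']} edges over "
                             f"{c['n_nodes']} nodes, corrected p = "
                             f"{c['corrected_p']:.4g}")
    if not any_comp:
        lines.append("- no significant components")
    lines.append("")
    if comp["behavior_correlations"]:
        lines.append("## Brain-behaviour correlations (patients)")
        for c in comp["behavior_correlations"]:
            lines.append(f"- {c['metric']} vs {c['score']}: r = {c['r']:.3f}, "
                         f"p = {c['p']:.4g} (FDR p = {c['p_fdr']:.4g})")
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines))


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the assembled report."""
    cfg.validate()
    labels = _labels_for(cfg)
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    if cfg.mode == "simulate":
        stage_simulate(cfg, labels)
    stage_connectivity(cfg, labels)
    stage_metrics(cfg, labels)
    stage_nulls(cfg, labels)
    stage_compare(cfg, labels)
    stage_nbs(cfg, labels)
    return stage_report(cfg, labels)
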