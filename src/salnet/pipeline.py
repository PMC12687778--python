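"""End-to-end orchestration: simulate -> train -> saliency -> networks ->
phenotype statistics, with a reproducible run manifest.

A run is driven by a single JSON config with per-stage blocks and writes
TSV/JSON/GraphML artifacts into a run directory.  Later stages (corrnet,
networks, phenotype, report) can be recomputed from the on-disk outputs of
earlier ones without re-running the models.  The manifest records the
config snapshot, the seeds, per-stage timing and a SHA-256 digest of every
output file; two runs from the same config and seed produce identical
digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .classifiers import (
    ModelConfig,
    TrainSpec,
    build_classifier,
    classify_controls,
    compare_heads,
    hybrid_classify,
    make_split,
    to_feature_model,
    train_classifier,
)
from .core import RegionSaliencyMatrix, SalnetError, ValidationError
from .corrnet import (
    DEFAULT_THRESHOLDS,
    composition_stats,
    filter_edges,
    hub_ranking,
    pairwise_region_correlations,
    spring_layout,
    top_edges,
)
from .phenotype import (
    averaged_involvement,
    avg_std_grid,
    control_congruence,
    network_involvement,
    score_region_correlations,
)
from .saliency import (
    SaliencyVolume,
    compute_saliency,
    hemisphere_summary,
    region_mean_saliency,
)
from .synthetic import CohortConfig, generate_cohort

__all__ = ["run_pipeline", "report", "DEFAULT_CONFIG", "PipelineError",
           "global_signal_correct", "proportional_scale"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "saliency", "corrnet", "networks", "phenotype",
          "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},  # CohortConfig overrides; or "inputs" with file paths
    "model": {"depth_preset": "tiny", "width_scale": 0.25, "head": "softmax"},
    "train": {"epochs": 12, "batch_size": 16, "learning_rate": 2e-3,
              "test_size": 31, "ensemble": 3},
    "hybrid": {"feature_dim": 64, "k": 5, "restarts": 3},
    "saliency": {"mode": "gradxinput"},
    "corrnet": {"alpha": 0.01, "tau_threshold": 0.4,
                "thresholds": list(DEFAULT_THRESHOLDS), "top_edges": 500,
                "top_n": 50},
    "phenotype": {"alpha": 0.05},
    "compare_heads": False,
}


class PipelineError(SalnetError):
    """A stage failed; partial outputs are preserved in the run directory."""


def _merged_config(config):
    if isinstance(config, (str, Path)):
        config = vio.read_json(config)
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def global_signal_correct(values: np.ndarray) -> np.ndarray:
    """Regress out the per-subject global saliency factor (for correlations).

    The classifier's gradient magnitude carries a multiplicative per-subject
    scale common to every region (analogous to the global signal in
    functional connectivity).  Working in log space, each region column is
    regressed on the subject-wise global mean and replaced by its residual;
    the result is re-exponentiated so downstream statistics still see
    positive values.  Column levels are *not* preserved, so this correction
    is only appropriate for rank-correlation statistics.
    """
    if np.any(values < 0):
        raise ValidationError("saliency values must be nonnegative")
    lg = np.log(values + 1e-12)
    g = lg.mean(axis=1)
    X = np.c_[np.ones_like(g), g]
    beta = np.linalg.lstsq(X, lg, rcond=None)[0]
    resid = lg - X @ beta
    return np.exp(resid)


def proportional_scale(values: np.ndarray) -> np.ndarray:
    """Divide each subject's saliency row by its mean (for level statistics).

    Removes the per-subject global scale while preserving the *relative*
    regional saliency profile, so hemisphere means, avg/STD panels and
    group congruence compare like with like across subjects.
    """
    if np.any(values < 0):
        raise ValidationError("saliency values must be nonnegative")
    m = values.mean(axis=1, keepdims=True)
    if np.any(m == 0):
        raise ValidationError("a subject has all-zero saliency")
    return values / m


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix(matrix: RegionSaliencyMatrix, path: Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "group", list(matrix.groups))
    df.to_csv(path, sep="\t")


def _read_matrix(path: Path, regions: pd.DataFrame) -> RegionSaliencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = df.pop("group").tolist()
    return RegionSaliencyMatrix(
        values=df.to_numpy(dtype=float),
        subject_ids=list(df.index),
        region_ids=np.array([int(c) for c in df.columns]),
        groups=groups,
        regions=regions,
    )


def run_pipeline(config, out_dir, stages=None):
    """Execute the pipeline; returns the run directory path.

    ``config`` is a dict or a path to a JSON file; missing keys fall back
    to :data:`DEFAULT_CONFIG`.  ``stages`` restricts execution (later
    stages restart from the on-disk outputs of a previous run in the same
    directory).
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    if "inputs" not in cfg and cfg.get("cohort") is None:
        raise ValidationError(
            "config must name either synthetic cohort parameters or input paths "
            "(volumes/atlas/phenotypes)"
        )

    manifest = {"config": cfg, "seed": cfg["seed"], "stages": {}, "outputs": {}}
    state = {}

    def record(stage, t0):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    def run_stage(name, fn):
        if name not in stages:
            return
        t0 = time.time()
        logger.info("stage %s starting (seed %s)", name, cfg["seed"])
        try:
            fn()
        except Exception as exc:
            _finalise(out, manifest)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        record(name, t0)

    # -- simulate ----------------------------------------------------------
    def stage_simulate():
        if "inputs" in cfg:
            inp = cfg["inputs"]
            state["atlas"] = vio.read_atlas(inp["atlas_labels"], inp["atlas_table"])
            state["records"] = vio.read_phenotypes(inp["phenotypes"])
            vol_dir = Path(inp["volumes_dir"])
            state["volumes"] = [vio.read_volume(vol_dir / f"{r.subject_id}.nii.gz")
                                for r in state["records"]]
            state["truth"] = None
        else:
            ccfg = CohortConfig(**{**cfg["cohort"], "seed": cfg["seed"]})
            records, volumes, atlas, truth = generate_cohort(ccfg)
            state.update(records=records, volumes=volumes, atlas=atlas, truth=truth)
        sim = out / "simulate"
        sim.mkdir(exist_ok=True)
        vio.write_phenotypes(state["records"], sim / "phenotypes.tsv")
        vio.write_atlas(state["atlas"], sim / "atlas_labels.nii.gz",
                        sim / "atlas_regions.tsv")
        digest = hashlib.sha256()
        for v in state["volumes"]:
            digest.update(np.ascontiguousarray(v.data).tobytes())
        manifest["volume_digest"] = digest.hexdigest()

    # -- train -------------------------------------------------------------
    def stage_train():
        records, volumes = state["records"], state["volumes"]
        tr = cfg["train"]
        train_ids, test_ids = make_split(records, tr["test_size"], seed=cfg["seed"])
        mcfg = ModelConfig(dimensionality=3, seed=cfg["seed"], **cfg["model"])
        metrics = {"split": {"train": train_ids, "test": test_ids},
                   "head": mcfg.head}
        spec = TrainSpec(epochs=tr["epochs"], batch_size=tr["batch_size"],
                         learning_rate=tr["learning_rate"],
                         train_ids=train_ids, test_ids=test_ids, seed=cfg["seed"])
        if cfg.get("compare_heads"):
            heads = compare_heads(volumes, records, spec, base=mcfg)
            metrics["heads"] = {h: r.accuracy for h, r in heads.items()}
        # saliency is averaged over a small ensemble of trainings; the first
        # member is the primary model used for classification metrics
        models, accs = [], []
        for k in range(max(1, int(tr["ensemble"]))):
            seed_k = cfg["seed"] * 100 + k
            model = build_classifier(dataclasses.replace(mcfg, seed=seed_k))
            spec_k = dataclasses.replace(spec, seed=seed_k)
            model, res = train_classifier(model, volumes, records, spec_k)
            models.append(model)
            accs.append(res.accuracy)
            if k == 0:
                metrics["accuracy"] = res.accuracy
                metrics["history"] = res.history
        metrics["ensemble_accuracies"] = accs
        hy = cfg["hybrid"]
        fm = to_feature_model(models[0], hy["feature_dim"], seed=cfg["seed"])
        knn = hybrid_classify(fm, volumes, records, spec, head="knn",
                              k=hy["k"], restarts=hy["restarts"])
        svm = hybrid_classify(fm, volumes, records, spec, head="svm",
                              restarts=hy["restarts"])
        metrics["hybrid_knn"] = knn.accuracy
        metrics["hybrid_svm"] = svm.accuracy
        controls = [v for v, r in zip(volumes, records) if r.group == "control"]
        if controls:
            metrics["controls_predicted_low"] = classify_controls(models[0], controls)
        state["models"], state["spec"] = models, spec
        (out / "train").mkdir(exist_ok=True)
        vio.write_json(metrics, out / "train" / "metrics.json")
        state["train_metrics"] = metrics

    # -- saliency ----------------------------------------------------------
    def stage_saliency():
        records, volumes = state["records"], state["volumes"]
        sal_dir = out / "saliency"
        sal_dir.mkdir(exist_ok=True)
        groups = [r.group for r in records]
        acc = None
        for model in state["models"]:
            sal = np.stack([
                compute_saliency(model, v, subject_id=r.subject_id,
                                 mode=cfg["saliency"]["mode"]).data
                for v, r in zip(volumes, records)
            ])
            sal /= sal.mean()  # each member contributes on a common scale
            acc = sal if acc is None else acc + sal
        acc /= len(state["models"])
        svols = [SaliencyVolume(d, subject_id=r.subject_id)
                 for d, r in zip(acc, records)]
        mat = region_mean_saliency(svols, state["atlas"], groups)
        _write_matrix(mat, sal_dir / "region_saliency.tsv")
        hs = hemisphere_summary(_scaled(mat), state["atlas"])
        vio.write_json(dataclasses.asdict(hs), sal_dir / "hemisphere.json")
        state["matrix"] = mat

    def _scaled(mat, fn=proportional_scale):
        return RegionSaliencyMatrix(fn(mat.values), mat.subject_ids,
                                    mat.region_ids, mat.groups, mat.regions)

    def _matrix(scored_only=True, correction="gsr"):
        """The saliency matrix, optionally subset to scored subjects and
        corrected: 'gsr' for correlation statistics, 'prop' for level
        statistics, None for raw values."""
        if "matrix" not in state:
            _load_prior()
        mat = state["matrix"]
        if scored_only:
            keep = [g in ("high", "low") for g in mat.groups]
            mat = RegionSaliencyMatrix(
                mat.values[np.array(keep)],
                [s for s, k in zip(mat.subject_ids, keep) if k],
                mat.region_ids,
                [g for g, k in zip(mat.groups, keep) if k],
                mat.regions,
            )
        if correction == "gsr":
            mat = _scaled(mat, global_signal_correct)
        elif correction == "prop":
            mat = _scaled(mat, proportional_scale)
        return mat

    def _load_prior():
        sim, sal = out / "simulate", out / "saliency"
        needed = [sim / "atlas_regions.tsv", sim / "phenotypes.tsv",
                  sal / "region_saliency.tsv"]
        if not all(p.exists() for p in needed):
            raise ValidationError(
                "staged rerun requires prior simulate+saliency outputs in "
                f"{out}; missing: {[str(p) for p in needed if not p.exists()]}"
            )
        state["atlas"] = vio.read_atlas(sim / "atlas_labels.nii.gz",
                                        sim / "atlas_regions.tsv")
        state["records"] = vio.read_phenotypes(sim / "phenotypes.tsv")
        state["matrix"] = _read_matrix(sal / "region_saliency.tsv",
                                       state["atlas"].regions)

    # -- corrnet -----------------------------------------------------------
    def stage_corrnet():
        mat = _matrix()
        cn = cfg["corrnet"]
        cdir = out / "corrnet"
        cdir.mkdir(exist_ok=True)
        cort = set(mat.regions.loc[mat.regions["is_cortical"], "region_id"])
        results = {}
        for scope in ("cortical-cortical", "cortical-subcortical"):
            edges = pairwise_region_correlations(mat, scope=scope)
            tag = scope.replace("-", "_")
            graph = filter_edges(edges, alpha=cn["alpha"],
                                 tau_threshold=cn["tau_threshold"], matrix=mat)
            if scope == "cortical-cortical":
                keep = [n for n in graph.graph.nodes if n in cort]
                graph.graph = graph.graph.subgraph(keep).copy()
            vio.write_graph(graph.graph, cdir / f"{tag}.graphml",
                            cdir / f"{tag}_edges.tsv")
            top = top_edges([e for e in edges if e.p < cn["alpha"]],
                            n=cn["top_edges"])
            pd.DataFrame([dataclasses.asdict(e) for e in top]).to_csv(
                cdir / f"{tag}_top{cn['top_edges']}.tsv", sep="\t", index=False)
            comp = composition_stats(graph)
            results[tag] = {"n_edges": graph.n_edges(), "composition": comp}
            state[f"edges_{tag}"] = edges
            state[f"graph_{tag}"] = graph
        # hub ranking sweep on the cortical-cortical scope
        hubs = hub_ranking(mat, edges=state["edges_cortical_cortical"],
                           thresholds=tuple(cn["thresholds"]), top_n=cn["top_n"],
                           alpha=cn["alpha"], scope="cortical-cortical")
        serialisable = {
            "divisor": hubs["divisor"],
            "averaged": hubs["averaged"],
            "per_threshold": {str(k): v for k, v in hubs["per_threshold"].items()},
        }
        vio.write_json(serialisable, cdir / "hub_ranking.json")
        g = state["graph_cortical_cortical"]
        if g.n_edges() > 0:
            layout = spring_layout(g, seed=cfg["seed"])
            vio.write_json({str(k): v for k, v in layout.items()},
                           cdir / "spring_layout.json")
        vio.write_json(results, cdir / "composition.json")
        state["hubs"] = hubs

    # -- networks ----------------------------------------------------------
    def stage_networks():
        mat = _matrix()
        cn = cfg["corrnet"]
        ndir = out / "networks"
        ndir.mkdir(exist_ok=True)
        if "hubs" not in state:
            stage_corrnet()
        atlas = state["atlas"]
        per = {}
        for thr, rows in state["hubs"]["per_threshold"].items():
            inv = network_involvement([r["region_id"] for r in rows], atlas,
                                      threshold_label=str(thr))
            per[str(thr)] = {"counts": inv.counts, "total": inv.total,
                             "percentages": inv.percentages}
        avg = averaged_involvement(mat, atlas,
                                   thresholds=tuple(cn["thresholds"]),
                                   top_n=cn["top_n"], alpha=cn["alpha"],
                                   edges=state.get("edges_cortical_cortical"))
        vio.write_json({"per_threshold": per,
                        "averaged": {"counts": avg.counts, "total": avg.total,
                                     "percentages": avg.percentages}},
                       ndir / "involvement.json")
        state["involvement"] = {"per": per, "averaged": avg}

    # -- phenotype ---------------------------------------------------------
    def stage_phenotype():
        records = state["records"]
        pdir = out / "phenotype"
        pdir.mkdir(exist_ok=True)
        table = score_region_correlations(_matrix(correction="gsr"), records,
                                          alpha=cfg["phenotype"]["alpha"])
        table.rows.to_csv(pdir / "score_regions.tsv", sep="\t", index=False)
        vio.write_json({"hemisphere_counts": {k: list(v) for k, v in
                                              table.hemisphere_counts().items()}},
                       pdir / "score_region_counts.json")
        grid = avg_std_grid(_matrix(correction="prop"), records)
        panels = {f"{a}|{b}": v for (a, b), v in grid["panels"].items()}
        vio.write_json({"panels": {k: panels[k] for k in sorted(panels)}},
                       pdir / "avg_std_grid.json")
        mat_all = _matrix(scored_only=False, correction="prop")
        if any(g == "control" for g in mat_all.groups):
            cc = control_congruence(mat_all)
            vio.write_json(cc, pdir / "control_congruence.json")
            state["congruence"] = cc
        state["score_table"] = table

    def stage_report():
        text = report(out)
        (out / "report.txt").write_text(text)

    run_stage("simulate", stage_simulate)
    run_stage("train", stage_train)
    run_stage("saliency", stage_saliency)
    run_stage("corrnet", stage_corrnet)
    run_stage("networks", stage_networks)
    run_stage("phenotype", stage_phenotype)
    run_stage("report", stage_report)

    _finalise(out, manifest)
    return out


def _finalise(out: Path, manifest: dict) -> None:
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _digest(p)
    vio.write_json(manifest, out / "manifest.json")


# ---------------------------------------------------------------------------

def report(run_dir) -> str:
    """Human-readable summary of a completed run (from on-disk files only)."""
    out = Path(run_dir)
    missing = []
    lines = ["run summary", "===========", ""]

    def load(rel):
        p = out / rel
        if not p.exists():
            missing.append(rel)
            return None
        return vio.read_json(p) if p.suffix == ".json" else p

    metrics = load("train/metrics.json")
    lines.append("[classifier accuracies]")
    if metrics:
        if "heads" in metrics:
            for h, a in metrics["heads"].items():
                lines.append(f"  {h:<10s} {a:.4f}")
        lines.append(f"  {metrics['head']:<10s} {metrics['accuracy']:.4f} (trained head)")
        lines.append(f"  hybrid-kNN {metrics['hybrid_knn']:.4f}")
        lines.append(f"  hybrid-SVM {metrics['hybrid_svm']:.4f}")
    lines.append("")

    hemi = load("saliency/hemisphere.json")
    sal = load("saliency/region_saliency.tsv")
    lines.append("[region saliency]")
    if hemi and sal:
        df = pd.read_csv(sal, sep="\t", index_col=0).drop(columns=["group"])
        means = df.mean(axis=0).sort_values(ascending=False)
        lines.append("  top regions by mean saliency: "
                     + ", ".join(str(r) for r in means.index[:10]))
        lines.append(f"  LH mean {hemi['lh_mean']:.6f}  RH mean {hemi['rh_mean']:.6f}  "
                     f"t={hemi['t_stat']:.3f} p={hemi['p_value']:.3e} df={hemi['df']}")
    lines.append("")

    inv = load("networks/involvement.json")
    lines.append("[network involvement]")
    if inv:
        avg = inv["averaged"]
        order = sorted(avg["percentages"], key=avg["percentages"].get, reverse=True)
        for net in order:
            lines.append(f"  {net:<26s} avg count {avg['counts'][net]:6.2f}  "
                         f"avg {avg['percentages'][net]:5.1f}%")
    lines.append("")

    hubs = load("corrnet/hub_ranking.json")
    lines.append("[threshold-averaged hubs]")
    if hubs:
        for row in hubs["averaged"][:10]:
            lines.append(f"  region {row['region_id']:>4d}  "
                         f"avg connections {row['average_degree']:.2f}")
        lines.append(f"  (threshold divisor: {hubs['divisor']})")
    lines.append("")

    counts = load("phenotype/score_region_counts.json")
    lines.append("[subscore-correlated regions, LH/RH]")
    if counts:
        for s, (l, r) in counts["hemisphere_counts"].items():
            lines.append(f"  {s:<14s} {l}/{r}")
    lines.append("")

    lines.append("[control congruence]")
    cc = load("phenotype/control_congruence.json")
    if cc:
        lines.append(f"  r={cc['r']:.4f} slope={cc['slope']:.4f} "
                     f"intercept={cc['intercept']:.6f} over {cc['n_regions']} regions")
    else:
        lines.append("  absent (no control subjects in this run)")
        missing.remove("phenotype/control_congruence.json")
    lines.append("")

    if missing:
        lines.append("[incomplete run] missing stages/files: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
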