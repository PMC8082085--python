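"""End-to-end pipeline: synthesize-or-load → classify → traces → GLM →
geometry → decoding → report.

Each stage writes plain-text outputs (CSV/JSON) into the run directory
and records its wall time and child seed in ``manifest.json``.  A single
global seed is fanned out deterministically to per-stage child seeds, so
two runs from the same config produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cue_response import (
    ClassifierConfig,
    classify_session,
    sliding_auroc,
    type_proportions,
)
from .decoding import decoding_timecourse
from .glm_encoding import DesignSpec, build_design_matrix, fit_glm, glm_summary_row
from .population_geometry import (
    build_population_matrix,
    compare_weights_by_type,
    neural_weights,
    pca_subspace,
    trajectory_distance,
    trajectory_velocity,
)
from .session_io import Session, load_session, write_session
from .synthetic import GeneratorConfig, GroundTruth, generate_session

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]

log = logging.getLogger("nlot.pipeline")

STAGES = ("input", "classify", "traces", "glm", "geometry", "decoding", "report")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "session_dir"
    session_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    # stage parameters
    classify_min_trials: int = 10
    n_perm: int = 1000
    alpha: float = 0.01
    trace_window: tuple[float, float] = (0.2, 1.0)
    trace_types: tuple[str, ...] = ("I", "II")
    glm_types: tuple[str, ...] = ("I",)
    geometry_window: tuple[float, float] = (0.2, 0.6)
    decoding_sizes: tuple[int, ...] = (1, 5, 10, 25, 50, 100)
    decoding_step: float = 0.05
    decoding_span: tuple[float, float] = (-0.2, 0.8)
    decoding_resamples: int = 10
    decoding_pseudotrials: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            gen = GeneratorConfig(**gen)
        cfg = cls(generator=gen, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        })
        if cfg.mode not in ("synthetic", "session_dir"):
            raise ValueError(f"bad mode {cfg.mode!r}")
        if cfg.mode == "session_dir" and not cfg.session_dir:
            raise ValueError("session_dir mode requires a session_dir path")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"].pop("archetypes", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage_index: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages, fail-fast, and write a manifest.

    Returns the output directory.  Stage outputs:

    * ``session/`` + ``ground_truth.csv`` (synthetic mode)
    * ``classifications.csv`` — per-unit labels and auROC statistics
    * ``traces.csv`` — sliding auROC traces (long format)
    * ``glm_fits.csv`` — encoding-model summary per unit
    * ``trajectories.csv``, ``geometry.csv``, ``weights.csv``
    * ``decoding.csv``, ``decoding_summary.json``
    * ``summary.json``, ``manifest.json``
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "global_seed": config.seed,
        "stages": {},
    }
    t_all = time.time()

    def record(stage: str, t0: float, seed: int | None) -> None:
        manifest["stages"][stage] = {
            "wall_time_s": round(time.time() - t0, 3),
            "seed": seed,
        }

    # ---- input ------------------------------------------------------------
    t0 = time.time()
    seed_in = _stage_seed(config.seed, 0)
    ground_truth: GroundTruth | None = None
    if config.mode == "synthetic":
        session, ground_truth = generate_session(config.generator, seed_in)
        write_session(session, out / "session")
        pd.DataFrame(
            {
                "unit_id": list(ground_truth.labels),
                "type_label": list(ground_truth.labels.values()),
                "baseline_rate_hz": [
                    ground_truth.params[u].baseline_rate
                    for u in ground_truth.labels
                ],
            }
        ).to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    else:
        session = load_session(config.session_dir)
        gt_path = Path(config.session_dir) / "ground_truth.csv"
        if gt_path.exists():
            gt = pd.read_csv(gt_path, dtype={"unit_id": str})
            from .synthetic import GroundTruth as _GT

            ground_truth = _GT(
                labels=dict(zip(gt.unit_id, gt.type_label)), params={}, seed=-1
            )
    record("input", t0, seed_in)
    log.info("input: %d units, %d trials", len(session.units), len(session.trials))

    # ---- classify ---------------------------------------------------------
    t0 = time.time()
    seed_cls = _stage_seed(config.seed, 1)
    cls_cfg = ClassifierConfig(
        min_trials=config.classify_min_trials,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seed_cls,
    )
    classifications = classify_session(session, cls_cfg)
    rows = []
    for c in classifications:
        rows.append(
            {
                "unit_id": c.unit_id,
                "type_label": c.type_label or "unclassifiable",
                "auroc_go": c.go.auroc if c.go else np.nan,
                "p_go": c.go.p_value if c.go else np.nan,
                "auroc_nogo": c.nogo.auroc if c.nogo else np.nan,
                "p_nogo": c.nogo.p_value if c.nogo else np.nan,
                "auroc_pref": c.preference.auroc if c.preference else np.nan,
                "p_pref": c.preference.p_value if c.preference else np.nan,
            }
        )
    _write_csv(pd.DataFrame(rows), out / "classifications.csv")
    record("classify", t0, seed_cls)
    props = type_proportions(classifications)
    log.info("classify: proportions %s", {k: round(v, 3) for k, v in props.items()})

    label_of = {c.unit_id: c.type_label for c in classifications}

    # ---- traces -----------------------------------------------------------
    t0 = time.time()
    seed_tr = _stage_seed(config.seed, 2)
    trace_rows = []
    measure_rows = []
    for cond, tt, kind in (
        ("go", "go", "go-cue"),
        ("no-go", "no-go", "no-go-cue"),
    ):
        trials = session.select_trials(tt, "correct", kind)
        for c in classifications:
            if c.type_label not in config.trace_types:
                continue
            trace = sliding_auroc(
                session.unit(c.unit_id),
                trials,
                condition=cond,
                window=config.trace_window,
                n_perm=config.n_perm,
                seed=seed_tr,
                alpha=config.alpha,
            )
            d = trace.direction()
            for b in range(trace.bin_centers.size):
                trace_rows.append(
                    {
                        "unit_id": c.unit_id,
                        "condition": cond,
                        "bin_center_s": trace.bin_centers[b],
                        "auroc": trace.auroc[b],
                        "significant": bool(trace.significant[b]),
                        "direction": d[b],
                    }
                )
            measure_rows.append(
                {
                    "unit_id": c.unit_id,
                    "condition": cond,
                    "onset_s": np.nan if trace.onset_time is None else trace.onset_time,
                    "center_of_mass_s": np.nan
                    if trace.center_of_mass is None
                    else trace.center_of_mass,
                    "duration_s": trace.duration,
                }
            )
    _write_csv(pd.DataFrame(trace_rows), out / "traces.csv")
    _write_csv(pd.DataFrame(measure_rows), out / "trace_measures.csv")
    record("traces", t0, seed_tr)

    # ---- glm --------------------------------------------------------------
    t0 = time.time()
    seed_glm = _stage_seed(config.seed, 3)
    glm_rows = []
    spec = DesignSpec()
    for c in classifications:
        if c.type_label not in config.glm_types:
            continue
        try:
            design = build_design_matrix(session.unit(c.unit_id), session, spec)
        except ValueError as e:
            log.warning("glm: skipping %s (%s)", c.unit_id, e)
            continue
        fit = fit_glm(design, seed=seed_glm)
        glm_rows.append(glm_summary_row(c.unit_id, fit))
    _write_csv(pd.DataFrame(glm_rows), out / "glm_fits.csv")
    record("glm", t0, seed_glm)

    # ---- geometry ---------------------------------------------------------
    t0 = time.time()
    matrix = build_population_matrix(
        session, window=config.geometry_window,
        min_trials=config.classify_min_trials,
    )
    sub = pca_subspace(matrix, k=min(3, matrix.n_units))
    traj_rows = []
    for cond, traj in sub.trajectories.items():
        for b in range(sub.bin_centers.size):
            row = {"condition": cond, "bin_center_s": sub.bin_centers[b]}
            for k in range(traj.shape[0]):
                row[f"pc{k+1}"] = traj[k, b]
            traj_rows.append(row)
    _write_csv(pd.DataFrame(traj_rows), out / "trajectories.csv")

    geom_rows = []
    dist = trajectory_distance(matrix)
    for b in range(dist.bin_centers.size):
        geom_rows.append(
            {
                "kind": "distance",
                "condition": "",
                "bin_center_s": dist.bin_centers[b],
                "value": dist.values[b],
                "significant": bool(dist.significant[b]),
            }
        )
    for cond in matrix.conditions:
        vel = trajectory_velocity(matrix, cond)
        for b in range(vel.bin_centers.size):
            geom_rows.append(
                {
                    "kind": "velocity",
                    "condition": cond,
                    "bin_center_s": vel.bin_centers[b],
                    "value": vel.values[b],
                    "significant": bool(vel.significant[b]),
                }
            )
    _write_csv(pd.DataFrame(geom_rows), out / "geometry.csv")

    weights = neural_weights(sub, dimension=1)
    wdf = pd.DataFrame(
        {
            "unit_id": matrix.unit_ids,
            "type_label": [
                label_of.get(u, "unclassifiable") or "unclassifiable"
                for u in matrix.unit_ids
            ],
            "weight": weights,
        }
    )
    _write_csv(wdf, out / "weights.csv")
    try:
        cmp_w = compare_weights_by_type(
            weights, wdf.type_label.to_numpy()
        )
        anova = {"f": cmp_w.f_statistic, "p": cmp_w.p_value,
                 "group_means": cmp_w.group_means}
    except ValueError as e:
        anova = {"error": str(e)}
    record("geometry", t0, None)

    # ---- decoding ---------------------------------------------------------
    t0 = time.time()
    seed_dec = _stage_seed(config.seed, 5)
    curve = decoding_timecourse(
        session,
        population_sizes=config.decoding_sizes,
        step=config.decoding_step,
        span=config.decoding_span,
        n_resamples=config.decoding_resamples,
        n_pseudotrials=config.decoding_pseudotrials,
        seed=seed_dec,
    )
    _write_csv(curve.table, out / "decoding.csv")
    (out / "decoding_summary.json").write_text(
        json.dumps(
            {
                "chance": curve.chance,
                "behavioral_accuracy": curve.behavioral_accuracy,
                "min_units_reaching_behavior": {
                    f"{k:.3f}": v for k, v in
                    curve.min_units_reaching_behavior.items()
                },
            },
            indent=1,
        )
    )
    record("decoding", t0, seed_dec)

    # ---- report -----------------------------------------------------------
    t0 = time.time()
    classifiable = [c for c in classifications if c.classifiable]
    responsive = [c for c in classifiable if c.type_label != "V"]
    summary: dict[str, Any] = {
        "n_units": len(session.units),
        "n_trials": len(session.trials),
        "behavioral_accuracy": session.behavioral_accuracy(),
        "type_proportions": props,
        "responsive_fraction": (
            len(responsive) / len(classifiable) if classifiable else np.nan
        ),
        "weights_anova": anova,
        "glm_mean_contributions": (
            pd.DataFrame(glm_rows)
            .filter(like="contrib_")
            .mean()
            .round(4)
            .to_dict()
            if glm_rows
            else {}
        ),
    }
    if ground_truth is not None and ground_truth.labels:
        true = [ground_truth.labels[c.unit_id] for c in classifiable]
        pred = [c.type_label for c in classifiable]
        labels5 = ["I", "II", "III", "IV", "V"]
        cm = [
            [sum(1 for t_, p_ in zip(true, pred) if t_ == ti and p_ == pj)
             for pj in labels5]
            for ti in labels5
        ]
        agree = sum(1 for t_, p_ in zip(true, pred) if t_ == p_)
        summary["ground_truth_recovery"] = agree / len(true) if true else np.nan
        summary["confusion_matrix"] = {"labels": labels5, "counts": cm}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    record("report", t0, None)

    manifest["total_wall_time_s"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


REQUIRED_OUTPUTS = (
    "classifications.csv",
    "traces.csv",
    "glm_fits.csv",
    "geometry.csv",
    "decoding.csv",
    "summary.json",
    "manifest.json",
)


def report_summary(out_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    out = Path(out_dir)
    missing = [f for f in REQUIRED_OUTPUTS if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {out}: missing {', '.join(missing)}"
        )
    summary = json.loads((out / "summary.json").read_text())
    lines = [f"Run summary — {out}"]
    lines.append(
        f"  units: {summary['n_units']}  trials: {summary['n_trials']}  "
        f"behavioral accuracy: {summary['behavioral_accuracy']:.1%}"
    )
    props = summary["type_proportions"]
    lines.append(
        "  type proportions: "
        + "  ".join(f"{k}: {v:.1%}" for k, v in props.items())
    )
    lines.append(
        f"  responsive (≥1 cue): {summary['responsive_fraction']:.1%}"
    )
    if summary.get("glm_mean_contributions"):
        lines.append(
            "  GLM mean contributions: "
            + "  ".join(
                f"{k.removeprefix('contrib_')}: {v:.1%}"
                for k, v in summary["glm_mean_contributions"].items()
            )
        )
    dec = json.loads((out / "decoding_summary.json").read_text())
    reaching = {
        k: v for k, v in dec["min_units_reaching_behavior"].items()
        if v is not None
    }
    if reaching:
        first = min(reaching, key=float)
        lines.append(
            f"  decoding reaches behavioral accuracy "
            f"({dec['behavioral_accuracy']:.1%}) from {first} s "
            f"with {reaching[first]} units"
        )
    else:
        lines.append("  decoding never reaches behavioral accuracy")
    if "ground_truth_recovery" in summary:
        lines.append(
            f"  ground-truth recovery: {summary['ground_truth_recovery']:.1%}"
        )
        cm = summary["confusion_matrix"]
        lines.append("  confusion matrix (rows true, cols predicted "
                     + "/".join(cm["labels"]) + "):")
        for lab, row in zip(cm["labels"], cm["counts"]):
            lines.append(f"    {lab}: " + " ".join(f"{n:4d}" for n in row))
    return "\n".join(lines)
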