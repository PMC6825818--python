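"""Readers, writers and the consolidated study-design experiment runner.

Formats are deliberately plain text: tracer studies as CSV
(``time_d,fd_plasma``) with an optional JSON metadata sidecar, model
specifications as YAML with flat ``L_2_1``-style keys, and reports as
JSON.  Every run is described by a manifest holding the seeds, inputs and
outputs needed to reproduce it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (ObservedStudy, SubjectProfile, generate_dataset,
                     make_cohort)
from .duration import (AccuracyCriteria, ReferenceValues, duration_scan,
                       fixed_duration_evaluation, intake_sensitivity,
                       reference_fit)
from .model import ModelSpec, ModelValidationError, TracerCurve
from .rid import group_fas_table

__all__ = [
    "read_study",
    "write_study",
    "spec_to_dict",
    "spec_from_dict",
    "read_spec",
    "write_spec",
    "RunManifest",
    "run_experiment_suite",
]


# ---------------------------------------------------------------------------
# tracer studies

def write_study(study: ObservedStudy | TracerCurve, path: str | Path,
                sidecar: bool = True) -> None:
    """Write a study as CSV; metadata (intake datum, seed, FSD) as sidecar."""
    path = Path(path)
    if isinstance(study, TracerCurve):
        df = pd.DataFrame({"time_d": study.times, "fd_plasma": study.fd_plasma})
        meta = None
    else:
        df = pd.DataFrame({"time_d": study.times, "fd_plasma": study.fd_observed})
        meta = {"subject_id": study.subject_id, "intake_datum": study.intake_datum,
                "intake_fsd": study.intake_fsd, "noise_fsd": study.noise_fsd,
                "seed": study.seed}
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar and meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_study(path: str | Path) -> ObservedStudy:
    """Read a tracer study CSV (header ``time_d,fd_plasma``) + sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_d", "fd_plasma"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_d"].to_numpy(dtype=float)
    f = df["fd_plasma"].to_numpy(dtype=float)
    dup = np.nonzero(np.diff(t) == 0)[0]
    if dup.size:
        # +3: 1-based, header line, and the duplicate's second occurrence
        raise ValueError(f"{path}: duplicated time at row {int(dup[0]) + 3} "
                         f"(t = {t[dup[0]]})")
    if np.any(np.diff(t) < 0):
        row = int(np.nonzero(np.diff(t) < 0)[0][0]) + 2
        raise ValueError(f"{path}: times not increasing at row {row}")
    if np.any(f <= 0):
        row = int(np.nonzero(f <= 0)[0][0]) + 2
        raise ValueError(f"{path}: non-positive fd_plasma at row {row}")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ObservedStudy(
        subject_id=meta.get("subject_id", path.stem),
        times=t, fd_observed=f,
        intake_datum=meta.get("intake_datum"),
        intake_fsd=meta.get("intake_fsd", 0.05),
        noise_fsd=meta.get("noise_fsd", 0.05),
        seed=meta.get("seed"))


# ---------------------------------------------------------------------------
# model specifications

def spec_to_dict(spec: ModelSpec) -> dict:
    out = {f"L_{i}_{j}": v for (i, j), v in sorted(spec.L.items())}
    out.update(DT3=spec.DT3, M5=spec.M5, U1=spec.U1,
               absorption=spec.absorption, loss_sites=spec.loss_sites)
    return out


def spec_from_dict(d: Mapping) -> ModelSpec:
    L = {}
    rest = {}
    for key, val in d.items():
        if key.startswith("L_"):
            try:
                _, i, j = key.split("_")
                L[(int(i), int(j))] = float(val)
            except ValueError as exc:
                raise ModelValidationError(f"bad transfer key {key!r}") from exc
        else:
            rest[key] = val
    return ModelSpec(L=L, DT3=float(rest.get("DT3", 0.0)),
                     M5=float(rest["M5"]), U1=float(rest.get("U1", 0.0)),
                     absorption=float(rest.get("absorption", 0.75)),
                     loss_sites=str(rest.get("loss_sites", "6")))


def write_spec(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def read_spec(path: str | Path) -> ModelSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# consolidated experiment

@dataclass
class RunManifest:
    """Record of a run: seeds, configuration, outputs, timings."""

    seed: int
    package_version: str = __version__
    noise_fsd: float = 0.05
    steps: dict[str, float] = field(default_factory=dict)   # step -> seconds
    outputs: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_experiment_suite(
    out_dir: str | Path,
    seed: int = 0,
    fsd: float = 0.05,
    cohort: Sequence[SubjectProfile] | None = None,
) -> dict:
    """Run the full study-design experiment and write a report bundle.

    Pipeline: cohort -> noisy studies -> per-subject reference fits ->
    fixed-duration evaluation (28 d children / 56 d adults, without and
    with the intake datum) -> duration scans both ways (full-system and
    TBS-only criteria) -> intake-misspecification sensitivity -> group
    RID (FaS) table.  Per-subject failures are recorded and do not stop
    the remaining subjects.

    Returns the consolidated report (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, noise_fsd=fsd)
    report: dict = {"seed": seed, "noise_fsd": fsd}
    cohort = list(make_cohort() if cohort is None else cohort)
    rng_seeds = {s.id: seed * 1000 + k for k, s in enumerate(cohort)}

    t0 = time.perf_counter()
    studies = {s.id: generate_dataset(s, fsd=fsd, seed=rng_seeds[s.id])
               for s in cohort}
    for s in cohort:
        write_study(studies[s.id], out / f"study_{s.id}.csv")
        manifest.outputs.append(f"study_{s.id}.csv")
    report["subjects"] = {
        s.id: {"group": s.group, "tbs": s.reference.TBS,
               "intake": s.targets.intake, "m5": s.targets.m5,
               "days_of_stores": s.reference.days_of_stores,
               "noise_seed": rng_seeds[s.id]}
        for s in cohort}
    manifest.steps["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    references: dict[str, ReferenceValues] = {}
    for s in cohort:
        try:
            references[s.id] = reference_fit(studies[s.id], s)
        except Exception as exc:  # keep going for the other subjects
            manifest.errors[f"reference:{s.id}"] = str(exc)
    report["references"] = {
        sid: {"estimates": ref.estimates, **ref.steady_state.as_dict()}
        for sid, ref in references.items()}
    manifest.steps["reference_fits"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fixed = fixed_duration_evaluation(
        cohort, studies, references=references)
    report["fixed_duration"] = {
        sid: {mode: {"duration": rep.duration, "pass": rep.overall,
                     "tbs_rel_error": rep.rel_errors.get("TBS")}
              for mode, rep in reps.items()}
        for sid, reps in fixed.items()}
    manifest.steps["fixed_duration"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    full = AccuracyCriteria(mode="full")
    tbs_only = AccuracyCriteria(mode="tbs")
    scans: dict = {}
    for s in cohort:
        if s.id not in references:
            continue
        ref = references[s.id]
        st = studies[s.id]
        try:
            sw = duration_scan(st, s, with_intake=False, criteria=full,
                               stop_criteria=tbs_only, reference=ref)
            d_wo, n_wo = sw.shortest_passing()
            d_tbs, _ = sw.shortest_passing(tbs_only, ref)
            si = duration_scan(st, s, with_intake=True, criteria=full,
                               stop_criteria=tbs_only, reference=ref,
                               start_duration=d_wo)
            d_wi, n_wi = si.shortest_passing()
            d_wi_tbs, _ = si.shortest_passing(tbs_only, ref)
            decrease = (100.0 * (d_wo - d_wi) / d_wo
                        if d_wo and d_wi else None)
            scans[s.id] = {
                "without_intake": {"duration": d_wo, "n_samples": n_wo,
                                   "tbs_only_duration": d_tbs},
                "with_intake": {"duration": d_wi, "n_samples": n_wi,
                                "tbs_only_duration": d_wi_tbs},
                "percent_decrease": decrease,
            }
        except Exception as exc:
            manifest.errors[f"scan:{s.id}"] = str(exc)
    report["duration_scans"] = scans
    manifest.steps["duration_scans"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sens: dict = {}
    for s in cohort:
        info = scans.get(s.id, {})
        d_wi = info.get("with_intake", {}).get("duration")
        if not d_wi:
            continue
        try:
            ratios = intake_sensitivity(studies[s.id], s, d_wi,
                                        reference=references[s.id])
            sens[s.id] = {"duration": d_wi,
                          "tbs_ratio": {str(k): v for k, v in ratios.items()}}
        except Exception as exc:
            manifest.errors[f"sensitivity:{s.id}"] = str(exc)
    report["intake_sensitivity"] = sens
    manifest.steps["sensitivity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        fas = group_fas_table(cohort, studies, member_references=references)
        fas.to_csv(out / "fas_table.csv", index=False)
        manifest.outputs.append("fas_table.csv")
        report["rid_fas"] = fas.to_dict(orient="records")
    except Exception as exc:
        manifest.errors["rid"] = str(exc)
    manifest.steps["rid"] = time.perf_counter() - t0

    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=1))
    manifest.outputs.append("report.json")
    manifest.save(out / "manifest.json")
    return report
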