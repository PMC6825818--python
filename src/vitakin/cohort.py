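"""Synthetic cohort of theoretical subjects for retinol kinetic studies.

Twelve fixture subjects — four children, four younger adults, four older
adults — span the vitamin A status and intake ranges reported for those
groups: total body stores (TBS) of 30-1104, 203-1038 and 449-3023 umol and
intakes of 0.53-4.4, 1.2-4.0 and 1.7-3.6 umol/d respectively, with days of
stores from under 100 to over 1200 and crossover times of roughly 10-60 d.
Subjects are *designed*: state-variable targets (TBS, intake, plasma pool
M5, store split, exchange turnover) are inverted through the steady-state
relations into a fully parameterized model, so every subject's reference
solution is exact by construction.

Noisy tracer studies are generated on the standard 24-point schedule
(3, 5, 8 and 12 h; 1, 2, 4, 7, 10, 14, 21, 28, 35, 42, 49, 56, 70, 84,
114, 144, 200, 260, 310 and 365 d) with multiplicative normal error of
fractional standard deviation (FSD) 0.05, emulating the scatter of
empirical plasma tracer data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from .kinetics import DerivedKinetics, crossover_time, plasma_kinetics
from .model import ModelSpec, SteadyStateSolution, simulate_tracer, solve_steady_state

__all__ = [
    "SubjectTargets",
    "SubjectProfile",
    "ObservedStudy",
    "InfeasibleTargetsError",
    "default_schedule",
    "targets_from_turnover",
    "design_subject",
    "dual_loss_variant",
    "make_cohort",
    "generate_dataset",
    "GROUPS",
    "GROUP_RANGES",
]

GROUPS = ("child", "younger_adult", "older_adult")

#: printed per-group ranges: TBS (umol), intake (umol/d), days of stores
GROUP_RANGES = {
    "child": {"tbs": (30.0, 1104.0), "intake": (0.53, 4.4), "days_of_stores": (77.0, 716.0)},
    "younger_adult": {"tbs": (203.0, 1038.0), "intake": (1.2, 4.0), "days_of_stores": (189.0, 416.0)},
    "older_adult": {"tbs": (449.0, 3023.0), "intake": (1.7, 3.6), "days_of_stores": (303.0, 1254.0)},
}

#: absorptive-phase defaults; hepatic processing and secretion are fast
#: (hours), clearing the early curve for the post-absorptive kinetics
ABSORPTIVE_DEFAULTS = {"l_2_1": 3.0, "l_4_3": 6.0, "dt3": 0.1, "l_5_4": 3.0}

NOISE_FLOOR = 1e-12


class InfeasibleTargetsError(ValueError):
    """Raised when state-variable targets admit no nonnegative rate constants."""


def default_schedule() -> np.ndarray:
    """The 24-point sampling schedule in days (3 h = 0.125 d first, 365 d last)."""
    hours = np.array([3.0, 5.0, 8.0, 12.0]) / 24.0
    days = np.array([1, 2, 4, 7, 10, 14, 21, 28, 35, 42, 49, 56,
                     70, 84, 114, 144, 200, 260, 310, 365], dtype=float)
    return np.concatenate([hours, days])


def targets_from_turnover(
    tbs: float,
    intake: float,
    m5: float,
    store_return_days: float,
    l_5_7: float = 0.8,
    exchange_share: float = 1.0,
    **absorptive,
) -> "SubjectTargets":
    """Construct targets from physiological turnover quantities.

    ``store_return_days`` is the mean return time of the large store
    (1 / (L(5,6) + L(10,6))); ``l_5_7`` the fast pool's return rate (per
    day); ``exchange_share`` the ratio L(7,5) / L(6,5) (capped so L(7,5)
    stays <= 8/d).  The corresponding exchange coefficients and store
    split follow by fixed-point iteration of the steady-state relations.
    """
    l65 = tbs / (m5 * store_return_days)
    m7 = 0.0
    for _ in range(200):
        l75 = min(exchange_share * l65, 8.0)
        m7 = m5 * l75 / l_5_7
        l65 = max(tbs - m7, 1e-3) / (m5 * store_return_days)
    if m7 >= 0.5 * tbs:
        raise InfeasibleTargetsError(
            "fast pool would hold most of the stores; reduce exchange_share "
            "or increase l_5_7")
    return SubjectTargets(tbs=tbs, intake=intake, m5=m5,
                          store_ratio=(tbs - m7) / m7, l_6_5=l65, l_7_5=l75,
                          **absorptive)


@dataclass(frozen=True)
class SubjectTargets:
    """State-variable targets from which a subject's model is designed.

    ``store_ratio`` is M6:M7, the split of TBS between the larger and the
    smaller extravascular pool; ``l_6_5`` and ``l_7_5`` set the plasma ->
    store exchange turnover (per day).
    """

    tbs: float                 # umol
    intake: float              # umol/d
    m5: float                  # umol
    store_ratio: float = 6.0
    l_6_5: float = 2.5
    l_7_5: float = 1.0
    absorption: float = 0.75
    l_2_1: float = ABSORPTIVE_DEFAULTS["l_2_1"]
    l_4_3: float = ABSORPTIVE_DEFAULTS["l_4_3"]
    dt3: float = ABSORPTIVE_DEFAULTS["dt3"]
    l_5_4: float = ABSORPTIVE_DEFAULTS["l_5_4"]


@dataclass(frozen=True)
class SubjectProfile:
    """A designed theoretical subject with its exact reference solution."""

    id: str
    group: str
    age: str
    targets: SubjectTargets
    spec: ModelSpec
    reference: SteadyStateSolution

    def derived_kinetics(self, with_crossover: bool = True) -> DerivedKinetics:
        dk = plasma_kinetics(self.spec)
        if with_crossover:
            co = crossover_time(self.spec)
            dk = DerivedKinetics(dk.transit_time_plasma, dk.residence_time_plasma,
                                 dk.recycling_number, dk.recycling_time, co)
        return dk


@dataclass(frozen=True)
class ObservedStudy:
    """A (noisy) tracer study for one subject, plus the optional intake datum."""

    subject_id: str
    times: np.ndarray
    fd_observed: np.ndarray
    intake_datum: float | None = None
    intake_fsd: float = 0.05
    noise_fsd: float = 0.05
    seed: int | None = None
    fd_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fd_observed, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fd_observed", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fd_observed must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("fd_observed must be positive (noise floor applies)")

    def __len__(self) -> int:
        return int(self.times.size)


def design_subject(
    id: str,
    group: str,
    targets: SubjectTargets,
    age: str = "",
) -> SubjectProfile:
    """Invert state-variable targets into a fully parameterized model.

    From the steady-state relations with disposal rate
    ``DR = absorption * intake``:

    * ``L(10,6) = DR / M6``
    * ``L(5,6) = M5 * L(6,5) / M6 - L(10,6)``  (must come out positive)
    * ``L(5,7) = M5 * L(7,5) / M7``

    Raises :class:`InfeasibleTargetsError` when the implied return rate
    L(5,6) would be negative, i.e. the requested disposal exceeds what the
    plasma -> compartment-6 exchange flux can supply.
    """
    tg = targets
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if min(tg.tbs, tg.intake, tg.m5, tg.store_ratio, tg.l_6_5, tg.l_7_5) <= 0:
        raise InfeasibleTargetsError("all targets must be positive")
    dr = tg.absorption * tg.intake
    m6 = tg.tbs * tg.store_ratio / (1.0 + tg.store_ratio)
    m7 = tg.tbs / (1.0 + tg.store_ratio)
    l106 = dr / m6
    l56 = tg.m5 * tg.l_6_5 / m6 - l106
    if l56 <= 0:
        raise InfeasibleTargetsError(
            f"targets for {id!r} imply L(5,6) = {l56:.4g} <= 0: disposal rate "
            f"{dr:.3g} umol/d exceeds the plasma->store exchange flux "
            f"{tg.m5 * tg.l_6_5:.3g} umol/d that compartment 6 receives")
    l57 = tg.m5 * tg.l_7_5 / m7
    spec = ModelSpec(
        L={(2, 1): tg.l_2_1, (4, 3): tg.l_4_3, (5, 4): tg.l_5_4,
           (6, 5): tg.l_6_5, (7, 5): tg.l_7_5,
           (5, 6): l56, (5, 7): l57, (10, 6): l106},
        DT3=tg.dt3, M5=tg.m5, U1=tg.intake, absorption=tg.absorption)
    ref = solve_steady_state(spec)
    return SubjectProfile(id=id, group=group, age=age, targets=tg, spec=spec, reference=ref)


def dual_loss_variant(subject: SubjectProfile,
                      share_6: float | None = None) -> SubjectProfile:
    """Re-parameterize a subject with irreversible loss from both stores.

    The disposal rate is split ``share_6`` : ``1 - share_6`` between
    compartments 6 and 7 (as presumably occurs in vivo, where loss is not
    confined to one tissue); exchange returns are adjusted so all state
    variables (masses, TBS, DR, intake) are unchanged.  By default the
    split is mass-proportional — the same fractional catabolic rate
    ``DR / TBS`` applies to both extravascular pools.
    """
    tg = subject.targets
    ref = subject.reference
    m5, m6, m7 = ref.M[5], ref.M[6], ref.M[7]
    dr = ref.DR
    if share_6 is None:
        share_6 = m6 / (m6 + m7)
    if not (0 < share_6 < 1):
        raise ValueError("share_6 must lie in (0, 1)")
    l106 = share_6 * dr / m6
    l107 = (1.0 - share_6) * dr / m7
    l56 = m5 * tg.l_6_5 / m6 - l106
    l57 = m5 * tg.l_7_5 / m7 - l107
    if l56 <= 0 or l57 <= 0:
        raise InfeasibleTargetsError(
            "loss split exceeds the exchange flux of a store")
    L = dict(subject.spec.L)
    L.update({(5, 6): l56, (5, 7): l57, (10, 6): l106, (10, 7): l107})
    spec = replace(subject.spec, L=L, loss_sites="6+7")
    prof = SubjectProfile(id=f"{subject.id}_dual", group=subject.group,
                          age=subject.age, targets=tg, spec=spec,
                          reference=solve_steady_state(spec))
    assert abs(prof.reference.TBS / ref.TBS - 1) < 1e-9
    return prof


def _load_fixture_rows() -> list[dict]:
    text = importlib.resources.files("vitakin").joinpath("data/cohort_default.yaml").read_text()
    return yaml.safe_load(text)["subjects"]


def _profile_from_row(row: dict) -> SubjectProfile:
    keys = ("tbs", "intake", "m5", "store_ratio", "l_6_5", "l_7_5")
    extra = {k: row[k] for k in ("absorption", "l_2_1", "l_4_3", "dt3", "l_5_4") if k in row}
    tg = SubjectTargets(**{k: float(row[k]) for k in keys}, **extra)
    return design_subject(row["id"], row["group"], tg, age=str(row.get("age", "")))


def make_cohort(seed: int | None = None, n_per_group: int = 4) -> list[SubjectProfile]:
    """The 12-subject cohort.

    With ``seed=None`` (default) the shipped fixture cohort is returned:
    twelve concrete subjects whose state variables fall in the printed group
    ranges, including a low-TBS child near 30 umol and a high-TBS older
    adult near 3000 umol.  With an integer seed, a fresh cohort is sampled
    within the same ranges (deterministic for a fixed seed).
    """
    if seed is None:
        return [_profile_from_row(r) for r in _load_fixture_rows()]
    rng = np.random.default_rng(seed)
    cohort: list[SubjectProfile] = []
    for group in GROUPS:
        rr = GROUP_RANGES[group]
        made = 0
        while made < n_per_group:
            tbs = float(np.exp(rng.uniform(*np.log(rr["tbs"]))))
            # intake consistent with the group's days-of-stores range
            ds_lo, ds_hi = rr["days_of_stores"]
            in_lo = max(rr["intake"][0], tbs / (0.75 * ds_hi))
            in_hi = min(rr["intake"][1], tbs / (0.75 * ds_lo))
            if in_lo > in_hi:
                continue
            intake = float(rng.uniform(in_lo, in_hi))
            m5 = float(rng.uniform(*{"child": (0.6, 2.6),
                                     "younger_adult": (4.0, 8.0),
                                     "older_adult": (4.5, 7.5)}[group]))
            t6_range = {"child": (6.0, 22.0), "younger_adult": (8.0, 28.0),
                        "older_adult": (12.0, 50.0)}[group]
            try:
                tg = targets_from_turnover(
                    tbs, intake, m5,
                    store_return_days=float(rng.uniform(*t6_range)),
                    l_5_7=float(rng.uniform(0.5, 1.2)),
                    exchange_share=float(rng.uniform(0.5, 1.2)))
                prof = design_subject(f"{group[0].upper()}{len(cohort) + 1}", group, tg)
            except InfeasibleTargetsError:
                continue
            cohort.append(prof)
            made += 1
    return cohort


def generate_dataset(
    subject: SubjectProfile,
    schedule: Sequence[float] | None = None,
    fsd: float = 0.05,
    seed: int = 0,
    include_intake_datum: bool = True,
) -> ObservedStudy:
    """Simulate a noisy tracer study for one subject.

    Observed values are ``FD_p(t) * (1 + fsd * Z)`` with i.i.d. standard
    normal Z, clamped below at a tiny positive floor so relative (FSD)
    weighting never divides by zero.  Deterministic for a fixed seed.
    """
    if fsd < 0:
        raise ValueError("fsd must be >= 0")
    t = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    fd = simulate_tracer(subject.spec, t).fd_plasma
    rng = np.random.default_rng(seed)
    obs = fd * (1.0 + fsd * rng.standard_normal(t.size))
    obs = np.maximum(obs, NOISE_FLOOR)
    return ObservedStudy(
        subject_id=subject.id, times=t, fd_observed=obs,
        intake_datum=subject.targets.intake if include_intake_datum else None,
        intake_fsd=fsd if fsd > 0 else 0.05,
        noise_fsd=fsd, seed=seed, fd_true=fd)
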