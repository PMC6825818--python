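"""Retinol isotope dilution (RID) coefficients from super-person models.

RID estimates total body stores from a single post-dose plasma specific
activity measurement through ``TBS = FaS * M5 / FD_p(t)``, where the
composite coefficient ``FaS`` corrects for absorption/retention of the
dose (Fa) and incomplete isotope mixing (S).  Under a fitted compartmental
model the unique dimensionless coefficient that makes that identity exact
is

    FaS(t) = TBS_model * FD_p_model(t) / M5,

and the same operational definition is used for reference and truncated
fits, so ratios between them are formula-independent.

A "super-person" is a group-level model fitted to pointwise geometric-mean
tracer data from the group's subjects; its plasma pool, intake datum and
fixed absorptive parameters are the geometric means of the members'.  The
group reference is the geometric-mean data to 365 d fitted without the
intake datum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ObservedStudy, SubjectProfile
from .duration import (FIXED_DURATIONS, ReferenceValues, _start_from,
                       reference_fit, reference_from_design, truncate)
from .fitting import DEFAULT_ADJUSTABLE, FitConfig, FitResult, fit_model
from .model import simulate_tracer

__all__ = [
    "RID_DAYS",
    "geometric_mean_curve",
    "super_person",
    "compute_fas",
    "group_fas_table",
]

#: days previously applied or suggested for RID sampling
RID_DAYS: tuple[float, ...] = (4.0, 7.0, 14.0)


def geometric_mean_curve(studies: Sequence[ObservedStudy]) -> ObservedStudy:
    """Pointwise geometric mean of tracer curves sharing one schedule."""
    if not studies:
        raise ValueError("no studies given")
    times = studies[0].times
    for s in studies[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("all studies must share the sampling schedule")
    mat = np.vstack([s.fd_observed for s in studies])
    if np.any(mat <= 0):
        raise ValueError("geometric mean requires positive values")
    gm = np.exp(np.mean(np.log(mat), axis=0))
    intakes = [s.intake_datum for s in studies]
    gm_intake = (float(np.exp(np.mean(np.log(intakes))))
                 if all(i is not None for i in intakes) else None)
    return ObservedStudy(
        subject_id="super", times=times.copy(), fd_observed=gm,
        intake_datum=gm_intake, noise_fsd=studies[0].noise_fsd,
        intake_fsd=studies[0].intake_fsd)


def _gm(values: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(values))))


def super_person(members: Sequence[SubjectProfile], group: str) -> SubjectProfile:
    """A synthetic group-level subject: geometric-mean state variables.

    Supplies the fixed quantities (M5, absorptive-phase coefficients) and
    the start values for fitting the group's geometric-mean curve; its
    "reference" steady state is the design implied by the geometric-mean
    targets and is only used for start values, never as an accuracy
    reference.
    """
    from .cohort import SubjectTargets, design_subject

    if not members:
        raise ValueError("no members given")
    tg = SubjectTargets(
        tbs=_gm([m.targets.tbs for m in members]),
        intake=_gm([m.targets.intake for m in members]),
        m5=_gm([m.targets.m5 for m in members]),
        store_ratio=_gm([m.targets.store_ratio for m in members]),
        l_6_5=_gm([m.targets.l_6_5 for m in members]),
        l_7_5=_gm([m.targets.l_7_5 for m in members]),
        absorption=members[0].targets.absorption,
        l_2_1=_gm([m.targets.l_2_1 for m in members]),
        l_4_3=_gm([m.targets.l_4_3 for m in members]),
        dt3=float(np.mean([m.targets.dt3 for m in members])),
        l_5_4=_gm([m.targets.l_5_4 for m in members]))
    return design_subject(f"super_{group}", group, tg, age="group")


def compute_fas(fit: FitResult, day: float) -> float:
    """Composite RID coefficient FaS(day) from a fitted model.

    ``FaS = TBS * FD_p(day) / M5`` — dose-normalization invariant, and the
    exact correction factor for the RID identity under the fitted model.
    """
    if fit.steady_state is None:
        raise ValueError("fit has no finite steady state; FaS undefined")
    fd = float(simulate_tracer(fit.spec, [day]).fd_plasma[0])
    if fd <= 0:
        raise ValueError(f"model FD_p({day}) is zero; FaS undefined")
    return fit.steady_state.TBS * fd / fit.spec.M5


def _fit_super(study: ObservedStudy, sp: SubjectProfile, with_intake: bool,
               t_max: float | None, intake_value: float | None = None,
               start_perturbation: float = 1.3) -> FitResult:
    s = study if t_max is None else truncate(study, t_max)
    design_ref = reference_from_design(sp)
    config = FitConfig(
        base_spec=sp.spec, include_intake=with_intake,
        intake_value=(intake_value if intake_value is not None
                      else study.intake_datum) if with_intake else None,
        start=_start_from(None, design_ref, DEFAULT_ADJUSTABLE,
                          start_perturbation))
    return fit_model(s, config)


def group_fas_table(
    cohort: Sequence[SubjectProfile],
    studies: Mapping[str, ObservedStudy],
    days: Sequence[float] = RID_DAYS,
    durations: Mapping[str, float] = FIXED_DURATIONS,
    member_references: Mapping[str, ReferenceValues] | None = None,
) -> pd.DataFrame:
    """FaS per group x day x source, from super-person models.

    Sources: ``reference_365d`` (geometric-mean data to 365 d, no intake),
    ``truncated_with_intake`` and ``truncated_without_intake`` (data to the
    group's practical duration).  The truncated with-intake fit uses the
    group-mean of the members' reference intakes as the datum.  Returns a
    tidy DataFrame with columns group, day, source, fas.
    """
    rows = []
    groups = sorted({m.group for m in cohort},
                    key=lambda g: [m.group for m in cohort].index(g))
    for group in groups:
        members = [m for m in cohort if m.group == group]
        sp = super_person(members, group)
        gm_study = geometric_mean_curve([studies[m.id] for m in members])
        d = durations[group]
        if member_references is not None:
            intakes = [member_references[m.id].intake for m in members]
        else:
            intakes = [reference_fit(studies[m.id], m).intake for m in members]
        group_intake = float(np.mean(intakes))
        fits = {
            "reference_365d": _fit_super(gm_study, sp, False, None),
            "truncated_with_intake": _fit_super(gm_study, sp, True, d,
                                                intake_value=group_intake),
            "truncated_without_intake": _fit_super(gm_study, sp, False, d),
        }
        for source, fit in fits.items():
            for day in days:
                try:
                    fas = compute_fas(fit, day)
                except ValueError:
                    fas = np.nan
                rows.append({"group": group, "day": float(day),
                             "source": source, "fas": fas})
    return pd.DataFrame(rows)
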