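"""Shared fixtures: specs, cohort, studies and cached heavy computations."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from vitakin import (
    AccuracyCriteria,
    ModelSpec,
    duration_scan,
    generate_dataset,
    make_cohort,
    reference_fit,
)

FULL = AccuracyCriteria(mode="full")
TBS_ONLY = AccuracyCriteria(mode="tbs")


def simple_spec(**overrides) -> ModelSpec:
    """A small, well-conditioned seven-compartment parameterization."""
    kw = dict(
        L={(2, 1): 3.0, (4, 3): 6.0, (5, 4): 3.0, (6, 5): 2.5, (7, 5): 1.0,
           (5, 6): 0.04, (5, 7): 0.5, (10, 6): 0.01},
        DT3=0.1, M5=3.0, U1=1.0)
    kw.update(overrides)
    return ModelSpec(**kw)


def random_spec(rng: np.random.Generator, dt3: float | None = None) -> ModelSpec:
    """A random valid single-loss spec spanning wide rate scales."""
    def u(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ModelSpec(
        L={(2, 1): u(1, 6), (4, 3): u(2, 10), (5, 4): u(0.5, 5),
           (6, 5): u(0.5, 20), (7, 5): u(0.3, 8), (5, 6): u(0.005, 0.5),
           (5, 7): u(0.1, 2), (10, 6): u(5e-4, 0.05)},
        DT3=float(rng.uniform(0.05, 0.4)) if dt3 is None else dt3,
        M5=u(0.5, 10), U1=u(0.3, 5),
        absorption=0.75)


@pytest.fixture(scope="session")
def cohort():
    return make_cohort()


@pytest.fixture(scope="session")
def cohort_by_id(cohort):
    return {s.id: s for s in cohort}


@lru_cache(maxsize=None)
def _studies(seed: int, fsd: float = 0.05):
    cohort = make_cohort()
    return {s.id: generate_dataset(s, fsd=fsd, seed=seed * 1000 + k)
            for k, s in enumerate(cohort)}


@lru_cache(maxsize=None)
def _references(seed: int):
    cohort = make_cohort()
    studies = _studies(seed)
    return {s.id: reference_fit(studies[s.id], s) for s in cohort}


@lru_cache(maxsize=None)
def _scan(seed: int, subject_id: str, with_intake: bool,
          start_duration: float | None = None):
    cohort = make_cohort()
    subject = next(s for s in cohort if s.id == subject_id)
    return duration_scan(
        _studies(seed)[subject_id], subject, with_intake, FULL,
        stop_criteria=TBS_ONLY, reference=_references(seed)[subject_id],
        start_duration=start_duration)


def scan_summary(seed: int, subject_id: str):
    """(d_without, n_without, d_tbs_only, d_with, n_with) for one subject."""
    ref = _references(seed)[subject_id]
    sw = _scan(seed, subject_id, False)
    d_wo, n_wo = sw.shortest_passing()
    d_tbs, _ = sw.shortest_passing(TBS_ONLY, ref)
    si = _scan(seed, subject_id, True, d_wo)
    d_wi, n_wi = si.shortest_passing()
    return d_wo, n_wo, d_tbs, d_wi, n_wi


@pytest.fixture(scope="session")
def studies_seed0():
    return _studies(0)


@pytest.fixture(scope="session")
def references_seed0():
    return _references(0)
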