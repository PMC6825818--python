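"""Linear compartmental model of whole-body vitamin A (retinol) kinetics.

The model follows the standard seven-component description of retinol
metabolism in humans: an oral dose (tracer) and dietary vitamin A both enter
a gastrointestinal compartment 1, pass through an absorptive chain
(compartment 2, delay component 3, hepatocyte compartment 4), and retinol
bound to retinol-binding protein is then secreted into plasma (compartment
5).  Plasma retinol exchanges with two extravascular storage pools: a larger
compartment 6 and a smaller compartment 7, whose sum is the total body
store (TBS).  Irreversible loss occurs from compartment 6 (default) or from
both 6 and 7; compartment "10" denotes the out-of-system sink by
convention and holds no mass.

All first-order transfers are fractional transfer coefficients ``L(I, J)``:
the fraction of compartment J's content moved to compartment I per day.
Component 3 is a pure transport delay of ``DT3`` days. Units are days,
micromoles and micromoles per day throughout.

Tracer dynamics are solved in closed form.  Because the absorptive chain
feeds the post-absorptive block one-way, the pure delay reduces to a time
shift of the downstream response (the downstream block is linear and
time-invariant and starts empty), so the delay is handled exactly without
delay-differential integration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelSpec",
    "TracerCurve",
    "TracerSolution",
    "SteadyStateSolution",
    "ModelValidationError",
    "SteadyStateError",
    "compartmental_matrix",
    "solve_steady_state",
    "simulate_tracer",
]

#: order of the non-delay compartments in the canonical rate matrix
COMPARTMENTS: tuple[int, ...] = (1, 2, 4, 5, 6, 7)
#: sink labels: 0 (pre-absorptive, unabsorbed dose) and 10 (systemic loss)
SINKS: tuple[int, ...] = (0, 10)
DELAY_COMPONENT = 3
PLASMA = 5

_REQUIRED_KEYS = ((2, 1), (4, 3), (5, 4), (6, 5), (7, 5), (5, 6), (5, 7), (10, 6))


class ModelValidationError(ValueError):
    """Raised when a model specification violates its invariants."""


class SteadyStateError(ValueError):
    """Raised when no finite tracee steady state exists."""


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of the seven-compartment retinol model.

    Parameters
    ----------
    L : mapping of (to, from) -> float
        Fractional transfer coefficients, per day.  Required keys for the
        default topology: ``(2,1), (4,3), (5,4), (6,5), (7,5), (5,6),
        (5,7), (10,6)``; ``(10,7)`` only in the dual-loss variant.  The key
        ``(4,3)`` is the turnover of absorptive pool 2: its outflow transits
        delay component 3 and enters compartment 4 shifted by ``DT3`` days.
    DT3 : float
        Delay time of component 3, days.
    M5 : float
        Plasma retinol pool size, micromoles.  Fixed, never fitted.
    U1 : float
        Dietary vitamin A input into compartment 1, micromoles/day.
    absorption : float
        Absorption efficiency ``a`` in (0, 1]; the fraction of oral input
        that survives the gastrointestinal compartment.  Modeled as a loss
        ``L(0,1) = L(2,1) * (1 - a) / a`` so the absorbed fraction is
        exactly ``a``.
    loss_sites : str
        ``"6"`` (default, lumped output from compartment 6) or ``"6+7"``.
    """

    L: Mapping[tuple[int, int], float]
    DT3: float
    M5: float
    U1: float = 0.0
    absorption: float = 0.75
    loss_sites: str = "6"

    def __post_init__(self) -> None:
        L = dict(self.L)
        object.__setattr__(self, "L", L)
        for key, val in L.items():
            if not np.isfinite(val):
                raise ModelValidationError(f"L{key} is not finite: {val!r}")
            if val < 0:
                raise ModelValidationError(f"L{key} must be >= 0, got {val}")
        missing = [k for k in _REQUIRED_KEYS if k not in L]
        if missing:
            raise ModelValidationError(f"missing transfer coefficients: {missing}")
        if self.loss_sites not in ("6", "6+7"):
            raise ModelValidationError(f"loss_sites must be '6' or '6+7', got {self.loss_sites!r}")
        if self.loss_sites == "6" and L.get((10, 7), 0.0) > 0:
            raise ModelValidationError("L(10,7) > 0 requires loss_sites='6+7'")
        if not (0 < self.absorption <= 1):
            raise ModelValidationError(f"absorption must be in (0, 1], got {self.absorption}")
        if self.DT3 < 0:
            raise ModelValidationError(f"DT3 must be >= 0, got {self.DT3}")
        if self.M5 <= 0:
            raise ModelValidationError(f"M5 must be > 0, got {self.M5}")
        if self.U1 < 0:
            raise ModelValidationError(f"U1 must be >= 0, got {self.U1}")

    def l(self, i: int, j: int) -> float:
        """L(i, j), zero when the arrow is absent."""
        return float(self.L.get((i, j), 0.0))

    @property
    def total_loss_rate(self) -> float:
        return self.l(10, 6) + self.l(10, 7)

    def transfer_map(self) -> dict[tuple[int, int], float]:
        """All transfers including the gut loss L(0,1) implied by absorption."""
        out = {k: float(v) for k, v in self.L.items() if v != 0.0}
        a = self.absorption
        if a < 1:
            out[(0, 1)] = self.l(2, 1) * (1 - a) / a
        return out

    def with_updates(self, updates: Mapping[tuple[int, int], float]) -> "ModelSpec":
        """A copy with some L(i, j) values replaced."""
        L = dict(self.L)
        L.update(updates)
        return replace(self, L=L)


@dataclass(frozen=True)
class TracerCurve:
    """Plasma tracer observations: fraction of oral dose in compartment 5."""

    times: np.ndarray
    fd_plasma: np.ndarray
    dose: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fd_plasma, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fd_plasma", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise ModelValidationError("times and fd_plasma must be 1-D arrays of equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ModelValidationError("times must be strictly increasing and >= 0")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ModelValidationError("non-finite values in tracer curve")
        if np.any(f < 0):
            raise ModelValidationError("fd_plasma must be >= 0")
        if t.size and t[0] == 0 and f[0] != 0:
            raise ModelValidationError("fd_plasma(0) must be 0 for an oral dose")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SteadyStateSolution:
    """Tracee steady state given fixed plasma pool M(5).

    Compartments 1-3 are transient absorptive pools and carry only
    throughput; masses are reported for 4-7.
    """

    M: dict[int, float]
    DR: float
    TBS: float
    days_of_stores: float
    intake_pred: float

    def as_dict(self) -> dict[str, float]:
        d = {f"M{i}": m for i, m in sorted(self.M.items())}
        d.update(DR=self.DR, TBS=self.TBS, days_of_stores=self.days_of_stores,
                 intake_pred=self.intake_pred)
        return d


@dataclass(frozen=True)
class TracerSolution:
    """Full tracer state over time: per-compartment amounts and losses."""

    times: np.ndarray
    q: dict[int, np.ndarray]          # compartments 1..7
    loss_gut: np.ndarray              # cumulative unabsorbed loss from 1
    loss_system: np.ndarray           # cumulative irreversible loss from 6 (+7)
    dose: float

    @property
    def fd_plasma(self) -> np.ndarray:
        return self.q[PLASMA] / self.dose

    def curve(self) -> TracerCurve:
        return TracerCurve(self.times, self.fd_plasma, dose=1.0)

    def total_recovered(self) -> np.ndarray:
        """Mass in all compartments plus cumulative losses (conservation check)."""
        return sum(self.q.values()) + self.loss_gut + self.loss_system


def compartmental_matrix(
    transfers: Mapping[tuple[int, int], float],
    compartments: Sequence[int] | None = None,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Canonical rate matrix of a linear compartmental system.

    Off-diagonal entry (i, j) is L(i, j); diagonal (j, j) is minus the sum
    of all coefficients leaving j, including losses to sinks (0, 10).  The
    delay component is never part of this matrix.

    Returns the matrix and the compartment ordering of its rows/columns.
    """
    for key, val in transfers.items():
        if val < 0:
            raise ModelValidationError(f"L{key} must be >= 0, got {val}")
    if compartments is None:
        found = {c for key in transfers for c in key if c not in SINKS and c != DELAY_COMPONENT}
        compartments = tuple(sorted(found))
    comps = tuple(compartments)
    index = {c: k for k, c in enumerate(comps)}
    A = np.zeros((len(comps), len(comps)))
    for (i, j), val in transfers.items():
        if j in SINKS or j == DELAY_COMPONENT or j not in index:
            continue
        A[index[j], index[j]] -= val
        if i in index:
            A[index[i], index[j]] += val
    return A, comps


def _spec_matrix(spec: ModelSpec) -> np.ndarray:
    """6x6 canonical matrix over (1, 2, 4, 5, 6, 7) with the delay collapsed.

    The pure delay between pool 2's outflow and compartment 4 is restored
    afterwards by time-shifting the downstream rows; the coefficient L(4,3)
    appears here as a direct 2 -> 4 transfer.
    """
    t = spec.transfer_map()
    t[(4, 2)] = t.pop((4, 3), 0.0)
    A, comps = compartmental_matrix(t, COMPARTMENTS)
    assert comps == COMPARTMENTS
    return A


# ---------------------------------------------------------------------------
# linear-system propagation backends


def _eig_backend(A: np.ndarray, q0: np.ndarray, times: np.ndarray):
    """States and their running integrals via eigendecomposition.

    Returns (Y, C) with Y[:, k] = y(t_k) and C[:, k] = integral_0^{t_k} y ds,
    or None when the matrix is too close to defective for a stable solve.
    """
    lam, V = np.linalg.eig(A)
    if np.linalg.cond(V) > 1e10:
        return None
    w = np.linalg.solve(V, q0.astype(complex))
    # exp(lam * t) and its integral, columns over times
    lt = np.multiply.outer(lam, times)
    E = np.exp(lt)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = np.where(np.abs(lam)[:, None] > 1e-14, (E - 1.0) / lam[:, None], times[None, :])
    Y = V @ (w[:, None] * E)
    C = V @ (w[:, None] * I)
    if np.max(np.abs(Y.imag)) > 1e-9 * max(1.0, np.max(np.abs(Y.real))):
        return None
    return Y.real, C.real


def _expm_backend(A: np.ndarray, q0: np.ndarray, times: np.ndarray):
    """Dense fallback: augment with integral states and exponentiate per time."""
    n = A.shape[0]
    Aug = np.zeros((2 * n, 2 * n))
    Aug[:n, :n] = A
    Aug[n:, :n] = np.eye(n)
    z0 = np.concatenate([q0, np.zeros(n)])
    Y = np.empty((n, times.size))
    C = np.empty((n, times.size))
    for k, t in enumerate(times):
        z = expm(Aug * t) @ z0
        Y[:, k] = z[:n]
        C[:, k] = z[n:]
    return Y, C


def _propagate(A: np.ndarray, q0: np.ndarray, times: np.ndarray, method: str):
    if method in ("auto", "eig"):
        out = _eig_backend(A, q0, times)
        if out is not None:
            return out
        if method == "eig":
            raise np.linalg.LinAlgError("eigendecomposition too ill-conditioned")
    return _expm_backend(A, q0, times)


def _erlang_matrix(spec: ModelSpec, n_stages: int) -> tuple[np.ndarray, int]:
    """Rate matrix with the delay replaced by an n-stage Erlang chain.

    State order: 1, 2, stage_1..stage_n, 4, 5, 6, 7.  Stage rates are
    n / DT3 so the chain's mean transit equals DT3.
    """
    t = spec.transfer_map()
    k2 = t.pop((4, 3), 0.0)
    m = 2 + n_stages + 4
    A = np.zeros((m, m))
    base, _ = compartmental_matrix(
        {k: v for k, v in t.items()}, COMPARTMENTS)
    # embed: indices 0,1 -> comps 1,2 ; 2+n..5+n -> comps 4,5,6,7
    up = [0, 1]
    down = [2 + n_stages + k for k in range(4)]
    idx = up + down
    for r, rr in enumerate(idx):
        for c, cc in enumerate(idx):
            A[rr, cc] = base[r, c]
    rate = n_stages / spec.DT3
    A[1, 1] -= k2
    A[2, 1] += k2
    for s in range(n_stages):
        i = 2 + s
        A[i, i] -= rate
        A[i + 1, i] += rate  # last stage feeds compartment 4 at index 2+n
    return A, n_stages


def simulate_tracer(
    spec: ModelSpec,
    times: Iterable[float],
    dose: float = 1.0,
    dose_compartment: int = 1,
    method: str = "auto",
    delay: str = "exact",
    erlang_stages: int = 20,
) -> TracerSolution:
    """Solve the tracer system for a bolus dose.

    Parameters
    ----------
    times : array-like of days, non-decreasing, >= 0.
    dose : tracer amount placed in ``dose_compartment`` at t = 0
        (fraction-of-dose outputs are normalized by it).
    method : "auto" (eigendecomposition with dense-exponential fallback),
        "eig" or "expm".
    delay : "exact" (time-shift of the downstream block) or "erlang"
        (n-stage chain approximation, always dense-exponential).
    """
    t = np.asarray(list(times) if np.iterable(times) else [times], dtype=float)
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ModelValidationError("times must be non-decreasing and >= 0")
    if not np.isfinite(dose) or dose <= 0:
        raise ModelValidationError("dose must be positive and finite")
    if dose_compartment not in COMPARTMENTS:
        raise ModelValidationError(f"dose_compartment must be one of {COMPARTMENTS}")

    a = spec.absorption
    l01 = spec.l(2, 1) * (1 - a) / a if a < 1 else 0.0
    k2 = spec.l(4, 3)

    if delay == "erlang" and spec.DT3 > 0:
        A, n = _erlang_matrix(spec, erlang_stages)
        q0 = np.zeros(A.shape[0])
        pos = {1: 0, 2: 1, 4: 2 + n, 5: 3 + n, 6: 4 + n, 7: 5 + n}
        q0[pos[dose_compartment]] = dose
        Y, C = _expm_backend(A, q0, t)
        q = {c: Y[pos[c]] for c in COMPARTMENTS}
        q[3] = Y[2:2 + n].sum(axis=0)
        loss_gut = l01 * C[0]
        loss_sys = spec.l(10, 6) * C[pos[6]] + spec.l(10, 7) * C[pos[7]]
        return TracerSolution(t, q, loss_gut, loss_sys, dose)
    if delay not in ("exact", "erlang"):
        raise ModelValidationError(f"unknown delay representation {delay!r}")

    A = _spec_matrix(spec)
    iup = {1: 0, 2: 1}
    idown = {4: 2, 5: 3, 6: 4, 7: 5}
    td = np.clip(t - spec.DT3, 0.0, None)

    q = {c: np.zeros_like(t) for c in COMPARTMENTS}
    q[3] = np.zeros_like(t)
    loss_gut = np.zeros_like(t)
    loss_sys = np.zeros_like(t)

    if dose_compartment in iup:
        q0 = np.zeros(6)
        q0[iup[dose_compartment]] = dose
        Yt, Ct = _propagate(A, q0, t, method)
        Yd, Cd = _propagate(A, q0, td, method) if spec.DT3 > 0 else (Yt, Ct)
        for c, k in iup.items():
            q[c] += Yt[k]
        for c, k in idown.items():
            q[c] += Yd[k]
        # delay content: pool-2 outflow accumulated over (t - DT3, t]
        q[3] += k2 * (Ct[1] - Cd[1])
        loss_gut += l01 * Ct[0]
        loss_sys += spec.l(10, 6) * Cd[4] + spec.l(10, 7) * Cd[5]
    else:
        # dose starts downstream of the delay; upstream stays empty
        q0 = np.zeros(6)
        q0[idown[dose_compartment]] = dose
        Yt, Ct = _propagate(A, q0, t, method)
        for c, k in idown.items():
            q[c] += Yt[k]
        loss_sys += spec.l(10, 6) * Ct[4] + spec.l(10, 7) * Ct[5]

    for arr in q.values():
        np.clip(arr, 0.0, None, out=arr)
    return TracerSolution(t, q, loss_gut, loss_sys, dose)


def fd_plasma(spec: ModelSpec, times: Iterable[float], **kw) -> np.ndarray:
    """Fraction of an oral dose in plasma, FD_p(t)."""
    return simulate_tracer(spec, times, **kw).fd_plasma


def solve_steady_state(spec: ModelSpec) -> SteadyStateSolution:
    """Tracee steady state with the plasma pool M(5) fixed.

    Closed form from flux balance: the storage pools balance their exchange
    with plasma plus irreversible loss, and the disposal rate equals the
    absorbed dietary input.
    """
    l65, l75 = spec.l(6, 5), spec.l(7, 5)
    l56, l57 = spec.l(5, 6), spec.l(5, 7)
    l106, l107 = spec.l(10, 6), spec.l(10, 7)
    if l106 + l107 <= 0:
        raise SteadyStateError("system has no output: L(10,6) (+ L(10,7)) must be > 0")
    if l75 > 0 and l57 + l107 == 0:
        raise SteadyStateError("compartment 7 receives inflow but has no outflow")

    M5 = spec.M5
    M6 = M5 * l65 / (l56 + l106) if l65 > 0 else 0.0
    if l65 > 0 and l56 + l106 == 0:
        raise SteadyStateError("compartment 6 receives inflow but has no outflow")
    M7 = M5 * l75 / (l57 + l107) if l75 > 0 else 0.0
    DR = M6 * l106 + M7 * l107
    if DR <= 0:
        raise SteadyStateError("disposal rate is zero: no mass reaches a loss site")
    TBS = M6 + M7
    intake = DR / spec.absorption
    l54 = spec.l(5, 4)
    if l54 <= 0:
        raise SteadyStateError("L(5,4) must be > 0 for throughput")
    M4 = DR / l54
    return SteadyStateSolution(
        M={4: M4, 5: M5, 6: M6, 7: M7},
        DR=DR,
        TBS=TBS,
        days_of_stores=TBS / DR,
        intake_pred=intake,
    )


def flux_imbalance(spec: ModelSpec, ss: SteadyStateSolution) -> dict[int, float]:
    """Relative inflow-outflow imbalance per compartment at steady state.

    Throughput compartments 1-4 carry the absorbed flux DR; 5-7 balance
    exchange and loss.  All values should be ~0 for a valid solution.
    """
    M4, M5, M6, M7 = ss.M[4], ss.M[5], ss.M[6], ss.M[7]
    flux_in_4 = ss.DR  # absorbed input emerging from the delay
    rows = {
        4: (flux_in_4, M4 * spec.l(5, 4)),
        5: (M4 * spec.l(5, 4) + M6 * spec.l(5, 6) + M7 * spec.l(5, 7),
            M5 * (spec.l(6, 5) + spec.l(7, 5))),
        6: (M5 * spec.l(6, 5), M6 * (spec.l(5, 6) + spec.l(10, 6))),
        7: (M5 * spec.l(7, 5), M7 * (spec.l(5, 7) + spec.l(10, 7))),
    }
    out = {}
    for c, (fin, fout) in rows.items():
        scale = max(abs(fin), abs(fout), 1e-300)
        out[c] = (fin - fout) / scale
    return out
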