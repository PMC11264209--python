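"""Langevin dynamics for model systems.

The integrator is the BAOAB splitting with an exact Ornstein-Uhlenbeck
O-step, stable at the 1 fs default time step for the surrogate force scales.
With friction = 0 it reduces to velocity Verlet and is exactly
time-reversible, which the two-sided shooting propagation relies on in the
deterministic limit.

Backward segments of two-sided shooting are generated by forward integration
from the momentum-reversed state with *fresh* noise, then time-reversed; this
is the package's path-generation convention for stochastic dynamics (the
deterministic momentum-reversal alternative is recovered at friction = 0).

Temperature is controlled near 300 K by default with a friction coefficient
of 1 ps^-1 and a 1 fs integration time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np

from . import _kernels
from .constants import KCAL_PER_MOL_TO_INTERNAL, kT_internal
from .systems import ModelSystem

__all__ = [
    "ParticleState",
    "LangevinParams",
    "OutsideBand",
    "TrajectorySegment",
    "IntegrationBlowupError",
    "integrate",
    "propagate_until",
    "propagate_two_sided",
    "run_equilibrium_well",
    "draw_maxwell_boltzmann",
    "iter_lambda_chunks",
]


class IntegrationBlowupError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"non-finite energy/forces at integration step {step}")
        self.step = step


@dataclass
class ParticleState:
    positions: np.ndarray   # (n_coords,), A
    velocities: np.ndarray  # (n_coords,), A/fs
    time: float = 0.0       # fs

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if not np.isfinite(self.time):
            raise ValueError("time must be finite")

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.velocities.copy(),
                             self.time)

    def reversed_momenta(self) -> "ParticleState":
        """Momentum-reversal involution: applying twice restores the state."""
        return ParticleState(self.positions.copy(), -self.velocities,
                             self.time)


@dataclass
class LangevinParams:
    dt: float = 1.0          # fs
    friction: float = 1.0    # 1/ps
    temperature: float = 300.0  # K
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class TrajectorySegment:
    """Frames at dt spacing.  positions/velocities may be strided or absent
    (None) for long runs where only the lambda series is needed."""

    times: np.ndarray                 # (n_frames,), fs
    lambdas: np.ndarray               # (n_frames,), A
    positions: np.ndarray | None = None   # (n_stored, n_coords)
    velocities: np.ndarray | None = None
    position_stride: int = 1
    dt: float = 1.0

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class OutsideBand:
    """Stop rule: terminate once lambda leaves the open interval (lo, hi).

    This is the standard state-A/state-B stop rule; when the system carries a
    compiled kernel, propagation with this rule runs on the jitted path.
    """

    lo: float
    hi: float

    def __call__(self, lam: float) -> bool:
        return lam < self.lo or lam > self.hi


def _kernel_args(system: ModelSystem, params: LangevinParams):
    kind, p, anchors = system.metadata["kernel"]
    bias_k, bias_c = system.metadata.get("kernel_bias", (0.0, 0.0))
    gamma_fs = params.friction * 1e-3
    return dict(kind=kind, p=p, anchors=anchors, masses=system.masses,
                dt=params.dt, gamma_fs=gamma_fs,
                kt_int=kT_internal(params.temperature),
                f2a=KCAL_PER_MOL_TO_INTERNAL,
                bias_k=float(bias_k), bias_c=float(bias_c))


def _kernel_propagate(system, state, lo, hi, max_steps, params, rng):
    kw = _kernel_args(system, params)
    seed = int(rng.integers(2 ** 31))
    xs, vs, lams, nf, status = _kernels.propagate_kernel(
        x0=np.ascontiguousarray(state.positions, dtype=float),
        v0=np.ascontiguousarray(state.velocities, dtype=float),
        lo=lo, hi=hi, max_steps=max_steps, seed=seed, **kw)
    if status == _kernels.STATUS_BLOWUP:
        raise IntegrationBlowupError(nf)
    return xs, vs, lams, status == _kernels.STATUS_STOPPED


def _ou_coeffs(params: LangevinParams, masses: np.ndarray):
    gamma = params.friction * 1e-3  # 1/ps -> 1/fs
    c1 = np.exp(-gamma * params.dt)
    sigma = np.sqrt((1.0 - c1 * c1) * kT_internal(params.temperature) / masses)
    return c1, sigma


_F2A = KCAL_PER_MOL_TO_INTERNAL  # force (kcal/mol/A) -> acceleration*mass unit


def _steps_core(system: ModelSystem, x, v, f, n_steps, params, rng,
                on_frame: Callable[[int, np.ndarray, np.ndarray], None]):
    """Shared BAOAB loop.  x, v of shape (..., n); f is -gradient (kcal/mol/A).
    Calls on_frame(step, x, v) after each completed step.  Returns final f."""
    m = system.masses
    dt = params.dt
    half = 0.5 * dt
    c1, sigma = _ou_coeffs(params, m)
    stochastic = params.friction > 0
    inv_m = _F2A / m
    chunk = 512
    step = 0
    while step < n_steps:
        n_do = min(chunk, n_steps - step)
        if stochastic:
            noise = rng.standard_normal((n_do,) + x.shape)
        for i in range(n_do):
            v = v + half * f * inv_m
            x = x + half * v
            if stochastic:
                v = c1 * v + sigma * noise[i]
            x = x + half * v
            g = system.gradient(x)
            if not np.all(np.isfinite(g)):
                raise IntegrationBlowupError(step + i + 1)
            f = -g
            v = v + half * f * inv_m
            on_frame(step + i + 1, x, v)
        step += n_do
    return x, v, f


def integrate(system: ModelSystem, state: ParticleState, n_steps: int,
              params: LangevinParams,
              rng: np.random.Generator | None = None) -> TrajectorySegment:
    """Propagate and return all n_steps+1 frames at dt spacing.

    Deterministic given (state, params.seed): an explicit generator may be
    passed to continue an existing noise stream.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if "kernel" in system.metadata and _kernels.HAVE_NUMBA:
        X, V, lams, _ = _kernel_propagate(system, state, -np.inf, np.inf,
                                          n_steps, params, rng)
        times = state.time + params.dt * np.arange(n_steps + 1)
        return TrajectorySegment(times=times, lambdas=lams, positions=X,
                                 velocities=V, dt=params.dt)
    n = system.n_coords
    X = np.empty((n_steps + 1, n))
    V = np.empty((n_steps + 1, n))
    X[0] = state.positions
    V[0] = state.velocities

    def on_frame(i, x, v):
        X[i] = x
        V[i] = v

    f0 = -system.gradient(state.positions)
    if not np.all(np.isfinite(f0)):
        raise IntegrationBlowupError(0)
    _steps_core(system, state.positions.copy(), state.velocities.copy(),
                f0, n_steps, params, rng, on_frame)
    times = state.time + params.dt * np.arange(n_steps + 1)
    return TrajectorySegment(times=times, lambdas=system.lambda_of(X),
                             positions=X, velocities=V, dt=params.dt)


def propagate_until(system: ModelSystem, state: ParticleState,
                    stop_rule: Callable[[float], bool], max_steps: int,
                    params: LangevinParams, rng: np.random.Generator):
    """Propagate until stop_rule(lambda) is true or max_steps is exhausted.

    Returns (positions, velocities, lambdas, committed) where committed is
    False when max_steps was hit first.  The initial frame is included; the
    stop rule is not applied to it.
    """
    if (isinstance(stop_rule, OutsideBand) and "kernel" in system.metadata
            and _kernels.HAVE_NUMBA):
        return _kernel_propagate(system, state, stop_rule.lo, stop_rule.hi,
                                 max_steps, params, rng)
    xs = [state.positions.copy()]
    vs = [state.velocities.copy()]
    lam0 = float(system.lambda_of(state.positions))
    lams = [lam0]
    committed = False

    class _Stop(Exception):
        pass

    def on_frame(i, x, v):
        nonlocal committed
        xs.append(x.copy())
        vs.append(v.copy())
        lam = float(system.lambda_of(x))
        lams.append(lam)
        if stop_rule(lam):
            committed = True
            raise _Stop

    f0 = -system.gradient(state.positions)
    if not np.all(np.isfinite(f0)):
        raise IntegrationBlowupError(0)
    try:
        _steps_core(system, state.positions.copy(), state.velocities.copy(),
                    f0, max_steps, params, rng, on_frame)
    except _Stop:
        pass
    return (np.array(xs), np.array(vs), np.array(lams), committed)


def propagate_two_sided(system: ModelSystem, state: ParticleState,
                        stop_rule: Callable[[float], bool], max_steps: int,
                        params: LangevinParams,
                        rng: np.random.Generator | None = None):
    """Two-sided propagation for shooting moves.

    The backward segment is produced by forward integration from the
    momentum-reversed state (fresh noise), time-reversed (velocities negated,
    order flipped), and concatenated with the forward segment so the shared
    midpoint appears once.  If the starting state already satisfies the stop
    rule, each segment has length 1 (the path is the single frame, degenerate).

    Returns a dict with keys positions, velocities, times, lambdas, committed
    (True only when both sides terminated by the stop rule).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lam0 = float(system.lambda_of(state.positions))
    if stop_rule(lam0):
        return {
            "positions": state.positions[None, :].copy(),
            "velocities": state.velocities[None, :].copy(),
            "times": np.array([0.0]),
            "lambdas": np.array([lam0]),
            "committed": True,
        }
    bx, bv, blam, bcom = propagate_until(
        system, state.reversed_momenta(), stop_rule, max_steps, params, rng)
    fx, fv, flam, fcom = propagate_until(
        system, state, stop_rule, max_steps, params, rng)
    # time-reverse the backward segment; drop its copy of the midpoint
    positions = np.concatenate([bx[::-1][:-1], fx])
    velocities = np.concatenate([-bv[::-1][:-1], fv])
    lambdas = np.concatenate([blam[::-1][:-1], flam])
    n_b = len(bx) - 1
    times = params.dt * (np.arange(len(positions)) - n_b)
    return {
        "positions": positions,
        "velocities": velocities,
        "times": times,
        "lambdas": lambdas,
        "committed": bool(bcom and fcom),
    }


# ---------------------------------------------------------------------------
# Batched propagation (replicas / umbrella windows / brute-force counting)
# ---------------------------------------------------------------------------

def _batch_steps(system: ModelSystem, X, V, n_steps, params, rng,
                 record_lambda=True, position_stride=0):
    """Vectorized BAOAB over a batch of walkers X, V of shape (m, n).

    Returns (X, V, lambdas (m, n_steps+1) or None, positions at stride)."""
    m_arr = system.masses
    dt = params.dt
    half = 0.5 * dt
    c1, sigma = _ou_coeffs(params, m_arr)
    stochastic = params.friction > 0
    inv_m = _F2A / m_arr
    f = -system.gradient(X)
    lams = None
    if record_lambda:
        lams = np.empty((X.shape[0], n_steps + 1))
        lams[:, 0] = system.lambda_of(X)
    pos_frames = []
    if position_stride:
        pos_frames.append(X.copy())
    chunk = 256
    step = 0
    while step < n_steps:
        n_do = min(chunk, n_steps - step)
        if stochastic:
            noise = rng.standard_normal((n_do,) + X.shape)
        for i in range(n_do):
            V = V + half * f * inv_m
            X = X + half * V
            if stochastic:
                V = c1 * V + sigma * noise[i]
            X = X + half * V
            g = system.gradient(X)
            if not np.all(np.isfinite(g)):
                raise IntegrationBlowupError(step + i + 1)
            f = -g
            V = V + half * f * inv_m
            k = step + i + 1
            if record_lambda:
                lams[:, k] = system.lambda_of(X)
            if position_stride and k % position_stride == 0:
                pos_frames.append(X.copy())
        step += n_do
    P = np.array(pos_frames) if position_stride else None
    return X, V, lams, P


def iter_lambda_chunks(system: ModelSystem, X, V, n_steps, params, rng,
                       chunk_steps: int = 4096) -> Iterator[np.ndarray]:
    """Stream lambda series of a batch in chunks of shape (m, <=chunk+1).

    Consecutive chunks overlap by one frame (each chunk starts with the last
    frame of the previous one) so crossing counters see every transition.
    """
    done = 0
    while done < n_steps:
        n_do = min(chunk_steps, n_steps - done)
        X, V, lams, _ = _batch_steps(system, X, V, n_do, params, rng)
        yield lams
        done += n_do


def draw_maxwell_boltzmann(system: ModelSystem, rng: np.random.Generator,
                           temperature: float | None = None,
                           size: int | None = None) -> np.ndarray:
    """Velocities (A/fs) from the Maxwell-Boltzmann distribution."""
    T = system.temperature if temperature is None else temperature
    scale = np.sqrt(kT_internal(T) / system.masses)
    if size is None:
        return rng.standard_normal(system.n_coords) * scale
    return rng.standard_normal((size, system.n_coords)) * scale


def run_equilibrium_well(system: ModelSystem, duration_ps: float,
                         n_replicas: int, params: LangevinParams,
                         initial_state: ParticleState | None = None,
                         well_lambda_max: float = -0.8,
                         position_stride: int = 0,
                         burn_in_ps: float = 1.0) -> list[TrajectorySegment]:
    """Independent reactant-well replicas (distinct sub-seeds), in one batch.

    Replicas start from ``initial_state`` (default: the system's rest
    geometry, which must lie inside the well, lambda < ``well_lambda_max``)
    with independently drawn Maxwell-Boltzmann velocities, and are decorrelated
    with a short burn-in before recording.
    """
    n_steps = max(1, int(round(duration_ps * 1000.0 / params.dt)))
    rng = np.random.default_rng(params.seed)
    if initial_state is None:
        rest = system.metadata.get("rest_positions")
        if rest is None:
            raise ValueError("no initial state and no rest geometry")
        x0 = np.asarray(rest, dtype=float)
    else:
        x0 = initial_state.positions
    if float(system.lambda_of(x0)) >= well_lambda_max:
        raise ValueError("initial state is outside the reactant well")
    X = np.tile(x0, (n_replicas, 1))
    V = draw_maxwell_boltzmann(system, rng, size=n_replicas)
    n_burn = int(round(burn_in_ps * 1000.0 / params.dt))
    if n_burn:
        X, V, _, _ = _batch_steps(system, X, V, n_burn, params, rng,
                                  record_lambda=False)
    X, V, lams, P = _batch_steps(system, X, V, n_steps, params, rng,
                                 position_stride=position_stride)
    times = params.dt * np.arange(n_steps + 1)
    segs = []
    for r in range(n_replicas):
        pos = P[:, r, :] if P is not None else None
        segs.append(TrajectorySegment(
            times=times.copy(), lambdas=lams[r], positions=pos,
            position_stride=position_stride or 1, dt=params.dt))
    return segs
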