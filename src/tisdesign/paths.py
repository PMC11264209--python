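"""TIS/TPS path sampling: seed discovery, shooting-move Monte Carlo,
interface and pathway-type ensembles, time alignment, window sampling.

Conventions
-----------
* State A is lambda < -0.8 A (reactant well), state B is lambda > 0.8 A
  (product well); a lambda exactly at a threshold is "neither" (strict
  inequalities).  Thresholds are configurable.
* Paths terminate on first entry into A or B.  Interface-ensemble paths that
  reach B are retained and count as crossing every higher interface.
* Shooting moves select a frame uniformly from the current path, perturb the
  momenta with a Gaussian kernel at fixed kinetic energy, redraw the kinetic
  energy from its equilibrium (gamma) marginal, and regenerate the trial path
  by two-sided propagation.  Acceptance = condition indicator times
  min(1, L_old / L_new), the flexible-path-length factor for uniform
  shooting-point selection; the direction kernel is symmetric and the KE
  redraw samples the exact stationary marginal, so both contribute unit
  Metropolis factors.  Rejected moves increment the current path's
  multiplicity.
* Non-committal trial paths (max_steps exhausted) are rejected, never
  truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import kT_internal
from .dynamics import (LangevinParams, OutsideBand, ParticleState,
                       draw_maxwell_boltzmann, propagate_two_sided)
from .systems import ModelSystem

logger = logging.getLogger(__name__)

__all__ = [
    "LAMBDA_A",
    "LAMBDA_B",
    "NR_THRESHOLD",
    "Path",
    "PathEnsemble",
    "ShootParams",
    "SeedFailureError",
    "AlignmentError",
    "classify_endpoint",
    "generate_seed_path",
    "shooting_move",
    "sample_interface_ensemble",
    "sample_pathway_ensembles",
    "align_time_zero",
    "sample_window_frames",
    "WeightedFrames",
]

LAMBDA_A = -0.8   # A; reactant-well boundary
LAMBDA_B = 0.8    # A; product-well boundary
NR_THRESHOLD = -0.4  # A; minimum progress for a nonreactive (NR) path


class SeedFailureError(RuntimeError):
    def __init__(self, attempts):
        super().__init__(f"no A<->B seed path found in {attempts} attempts")
        self.attempts = attempts


class AlignmentError(RuntimeError):
    pass


def classify_endpoint(lambda_value: float, lambda_a: float = LAMBDA_A,
                      lambda_b: float = LAMBDA_B) -> str:
    """'A' iff lambda < lambda_a, 'B' iff lambda > lambda_b, else 'neither'."""
    if not np.isfinite(lambda_value):
        raise ValueError("lambda must be finite")
    if lambda_value < lambda_a:
        return "A"
    if lambda_value > lambda_b:
        return "B"
    return "neither"


@dataclass
class Path:
    """A time-ordered trajectory with its lambda series and MC multiplicity.

    positions/velocities may be None for slim storage (lambda series kept)."""

    times: np.ndarray
    lambdas: np.ndarray
    positions: np.ndarray | None
    velocities: np.ndarray | None
    endpoints: tuple[str, str]
    multiplicity: int = 1
    path_id: int = 0

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self):
        return len(self.lambdas)

    @property
    def lambda_max(self) -> float:
        return float(np.max(self.lambdas))

    def slim(self) -> "Path":
        """Copy without coordinate frames (for interface-ensemble storage)."""
        return replace(self, positions=None, velocities=None)

    def breaking_distance_series(self, system: ModelSystem) -> np.ndarray:
        if self.positions is None:
            return self.lambdas  # scalar-coordinate systems
        return system.breaking_distance(self.positions)


def _make_path(raw: dict, lambda_a: float, lambda_b: float,
               keep_velocities: bool = True) -> Path:
    ep = (classify_endpoint(raw["lambdas"][0], lambda_a, lambda_b),
          classify_endpoint(raw["lambdas"][-1], lambda_a, lambda_b))
    return Path(times=raw["times"], lambdas=raw["lambdas"],
                positions=raw["positions"],
                velocities=raw["velocities"] if keep_velocities else None,
                endpoints=ep)


@dataclass
class ShootParams:
    """Shooting-move proposal parameters.

    sigma_p is the dimensionless momentum-perturbation scale: each velocity
    component receives sigma_p * sqrt(kT/m) Gaussian noise before the
    fixed-KE rescale.  The default lands near the ~25% acceptance band on the
    bundled surrogates.
    """

    sigma_p: float = 0.35
    ke_redraw: bool = True
    max_steps: int = 20000
    lambda_a: float = LAMBDA_A
    lambda_b: float = LAMBDA_B

    @property
    def band(self) -> OutsideBand:
        return OutsideBand(self.lambda_a, self.lambda_b)


@dataclass
class PathEnsemble:
    """Weighted collection of paths sharing a sampling condition."""

    condition: dict            # e.g. {"kind": "interface", "lambda_i": -0.6}
    entries: list[Path] = field(default_factory=list)
    n_attempted: int = 0
    n_accepted: int = 0
    seed_lineage: str = ""

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0

    @property
    def total_multiplicity(self) -> int:
        return sum(p.multiplicity for p in self.entries)

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def lambda_max_values(self) -> np.ndarray:
        return np.array([p.lambda_max for p in self.entries])

    def multiplicities(self) -> np.ndarray:
        return np.array([p.multiplicity for p in self.entries], dtype=float)

    def weighted_fraction(self, predicate) -> float:
        w = self.multiplicities()
        hits = np.array([bool(predicate(p)) for p in self.entries])
        return float(w[hits].sum() / w.sum())


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------

def _interface_condition(path: Path, lambda_i: float) -> bool:
    return path.endpoints[0] == "A" and path.lambda_max >= lambda_i


def _pathway_condition(path: Path, path_type: str, nr_threshold: float) -> bool:
    if path_type == "R":
        return path.endpoints == ("A", "B")
    if path_type == "NR":
        return path.endpoints == ("A", "A") and path.lambda_max >= nr_threshold
    raise ValueError(f"unknown pathway type {path_type!r}")


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def generate_seed_path(system: ModelSystem, barrier_states, params: LangevinParams,
                       max_attempts: int = 200,
                       rng: np.random.Generator | None = None,
                       shoot: ShootParams | None = None,
                       path_type: str = "R",
                       nr_threshold: float = NR_THRESHOLD) -> Path:
    """Find a first path of the requested type by shooting from barrier states.

    ``barrier_states`` are positions near lambda ~ 0 for R seeds (e.g. drawn
    from umbrella windows) or, for NR seeds, positions with lambda between the
    NR threshold and the barrier top.  Velocities are drawn fresh from the
    Maxwell-Boltzmann distribution on every attempt; reconstructed (B, A)
    pathways are time-reversed into (A, B).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shoot = shoot or ShootParams()
    barrier_states = np.atleast_2d(np.asarray(barrier_states, dtype=float))
    for attempt in range(max_attempts):
        x0 = barrier_states[attempt % len(barrier_states)]
        v0 = draw_maxwell_boltzmann(system, rng)
        raw = propagate_two_sided(system, ParticleState(x0.copy(), v0),
                                  shoot.band, shoot.max_steps, params, rng)
        if not raw["committed"]:
            continue
        path = _make_path(raw, shoot.lambda_a, shoot.lambda_b)
        if path_type == "R":
            if path.endpoints == ("B", "A"):
                path = Path(times=path.times,
                            lambdas=path.lambdas[::-1].copy(),
                            positions=path.positions[::-1].copy(),
                            velocities=-path.velocities[::-1],
                            endpoints=("A", "B"))
            if path.endpoints == ("A", "B"):
                return path
        else:
            if _pathway_condition(path, "NR", nr_threshold):
                return path
    raise SeedFailureError(max_attempts)


# ---------------------------------------------------------------------------
# shooting move
# ---------------------------------------------------------------------------

def _perturb_velocities(system: ModelSystem, v: np.ndarray, shoot: ShootParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Direction kick at fixed KE, then KE redraw from the gamma marginal."""
    m = system.masses
    kt = kT_internal(system.temperature)
    if shoot.sigma_p > 0:
        dv = shoot.sigma_p * np.sqrt(kt / m) * rng.standard_normal(len(v))
        vt = v + dv
        ke_old = 0.5 * np.sum(m * v * v)
        ke_new = 0.5 * np.sum(m * vt * vt)
        if ke_new > 0 and ke_old > 0:
            vt *= np.sqrt(ke_old / ke_new)
        v = vt
    if shoot.ke_redraw:
        n_dof = len(v)
        ke_target = rng.gamma(shape=0.5 * n_dof, scale=kt)
        ke_cur = 0.5 * np.sum(m * v * v)
        if ke_cur > 0:
            v = v * np.sqrt(ke_target / ke_cur)
    return v


def shooting_move(current: Path, system: ModelSystem, shoot: ShootParams,
                  params: LangevinParams, rng: np.random.Generator,
                  condition) -> tuple[Path, bool]:
    """One shooting-move proposal.  Returns (path, accepted): the candidate
    when accepted, else ``current`` with its multiplicity incremented."""
    if current.positions is None:
        raise ValueError("current path carries no frames to shoot from")
    idx = int(rng.integers(len(current)))
    x = current.positions[idx].copy()
    v = _perturb_velocities(system, current.velocities[idx].copy(), shoot, rng)
    raw = propagate_two_sided(system, ParticleState(x, v), shoot.band,
                              shoot.max_steps, params, rng)
    accepted = False
    if raw["committed"]:
        candidate = _make_path(raw, shoot.lambda_a, shoot.lambda_b)
        if condition(candidate):
            p_len = min(1.0, len(current) / len(candidate))
            if rng.random() < p_len:
                accepted = True
    if accepted:
        return candidate, True
    current.multiplicity += 1
    return current, False


def _run_chain(seed_path: Path, system, shoot, params, rng, condition,
               n_moves: int, n_equil: int, ensemble: PathEnsemble,
               keep_frames: bool):
    """Drive a shooting-move chain, recording post-equilibration paths."""
    current = replace(seed_path, multiplicity=1)
    next_id = 0
    stored_current = None
    for move in range(n_moves):
        cand, accepted = shooting_move(current, system, shoot, params, rng,
                                       condition)
        ensemble.n_attempted += 1
        if accepted:
            ensemble.n_accepted += 1
            cand.multiplicity = 1
            current = cand
            stored_current = None
        if move >= n_equil:
            if stored_current is None:
                stored_current = current if keep_frames else current.slim()
                stored_current = replace(stored_current, multiplicity=1,
                                         path_id=next_id)
                next_id += 1
                ensemble.entries.append(stored_current)
            else:
                stored_current.multiplicity += 1
    return current


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def sample_interface_ensemble(system: ModelSystem, seed_path: Path,
                              lambda_i: float, n_moves: int = 6000,
                              n_equil: int = 3000,
                              shoot: ShootParams | None = None,
                              params: LangevinParams | None = None,
                              rng: np.random.Generator | None = None,
                              keep_frames: bool = False) -> PathEnsemble:
    """Sample the ensemble of A-originating paths that cross lambda_i.

    Only post-equilibration paths are recorded; the stored multiplicities sum
    to ``n_moves - n_equil``.
    """
    if n_equil >= n_moves:
        raise ValueError("n_equil must be < n_moves")
    shoot = shoot or ShootParams()
    params = params or LangevinParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if not _interface_condition(seed_path, lambda_i):
        raise ValueError("seed path does not satisfy the interface condition")

    ens = PathEnsemble(condition={"kind": "interface", "lambda_i": lambda_i})
    _run_chain(seed_path, system, shoot, params, rng,
               lambda p: _interface_condition(p, lambda_i),
               n_moves, n_equil, ens, keep_frames)
    return ens


def sample_pathway_ensembles(system: ModelSystem, seed_paths: list[Path],
                             path_type: str, nr_threshold: float = NR_THRESHOLD,
                             n_moves: int = 1000, n_equil: int = 200,
                             n_ensembles: int | None = None,
                             shoot: ShootParams | None = None,
                             params: LangevinParams | None = None,
                             rng: np.random.Generator | None = None) -> list[PathEnsemble]:
    """Sample pathway-type ensembles (R, or NR reaching ``nr_threshold``).

    Ensembles are distributed round-robin across the supplied seed paths
    (defaults to one ensemble per seed).  R seeds must end in B; NR seeds must
    reach the threshold and end in A.
    """
    shoot = shoot or ShootParams()
    params = params or LangevinParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    for sp in seed_paths:
        if not _pathway_condition(sp, path_type, nr_threshold):
            raise ValueError(f"seed path does not satisfy the {path_type} condition")
    n_ensembles = n_ensembles or len(seed_paths)
    out = []
    for e in range(n_ensembles):
        seed = seed_paths[e % len(seed_paths)]
        ens = PathEnsemble(
            condition={"kind": "pathway", "type": path_type,
                       "nr_threshold": nr_threshold if path_type == "NR" else None},
            seed_lineage=f"seed{e % len(seed_paths)}")
        _run_chain(seed, system, shoot, params, rng,
                   lambda p: _pathway_condition(p, path_type, nr_threshold),
                   n_moves, n_equil, ens, keep_frames=True)
        out.append(ens)
    return out


# ---------------------------------------------------------------------------
# time alignment and window sampling
# ---------------------------------------------------------------------------

def _local_minima(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series)
    if len(s) < 3:
        return np.array([], dtype=int)
    interior = np.where((s[1:-1] < s[:-2]) & (s[1:-1] <= s[2:]))[0] + 1
    return interior


def align_time_zero(path: Path, system: ModelSystem) -> Path:
    """Shift times so t = 0 is the trough of the last compression of the
    breaking bond before the final barrier passage.

    The anchor search runs up to the final rupture (last frame with
    lambda < 0, for reactive paths) or up to lambda_max (nonreactive paths).
    Idempotent; raises :class:`AlignmentError` when the breaking-bond series
    has no interior local minimum in that span (e.g. monotone series).
    """
    d = path.breaking_distance_series(system)
    if path.endpoints == ("A", "B"):
        below = np.where(path.lambdas < 0.0)[0]
        end = int(below[-1]) if len(below) else len(d) - 1
    else:
        end = int(np.argmax(path.lambdas))
    minima = _local_minima(d[:end + 1])
    if len(minima) == 0:
        raise AlignmentError("no compression trough before the anchor event")
    t0 = path.times[minima[-1]]
    return replace(path, times=path.times - t0)


@dataclass
class WeightedFrames:
    """Frames with TIS path-count weights (and provenance)."""

    positions: np.ndarray     # (m, n_coords)
    weights: np.ndarray       # (m,)
    times: np.ndarray         # (m,), aligned fs
    path_ids: np.ndarray      # (m,)
    labels: np.ndarray | None = None   # optional 'R'/'NR' per frame

    def __len__(self):
        return len(self.weights)


def sample_window_frames(ensembles: list[PathEnsemble],
                         window: tuple[float, float],
                         frames_per_path: int = 1,
                         rng: np.random.Generator | None = None,
                         label: str | None = None) -> WeightedFrames:
    """Draw frames uniformly from the half-open time window [t_lo, t_hi).

    One (or ``frames_per_path``) frames per unique path, each carrying the
    path's TIS multiplicity as weight.  Paths with no frame in the window are
    skipped with a logged warning.  Paths must be time-aligned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t_lo, t_hi = window
    pos, wts, tts, pids = [], [], [], []
    skipped = 0
    gid = 0
    for ens in ensembles:
        for path in ens.entries:
            gid += 1
            if path.positions is None:
                raise ValueError("ensemble paths carry no frames")
            mask = (path.times >= t_lo) & (path.times < t_hi)
            idx = np.where(mask)[0]
            if len(idx) == 0:
                skipped += 1
                continue
            pick = rng.choice(idx, size=min(frames_per_path, len(idx)),
                              replace=False)
            for i in pick:
                pos.append(path.positions[i])
                wts.append(path.multiplicity)
                tts.append(path.times[i])
                pids.append(gid)
    if skipped:
        logger.warning("sample_window_frames: %d paths had no frame in [%g, %g)",
                       skipped, t_lo, t_hi)
    labels = np.array([label] * len(wts)) if label is not None else None
    return WeightedFrames(positions=np.array(pos), weights=np.array(wts, dtype=float),
                          times=np.array(tts), path_ids=np.array(pids),
                          labels=labels)
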