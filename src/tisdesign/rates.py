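"""Rate-constant assembly and decomposition.

The TIS rate constant is the effective positive flux through the reactant
boundary times the product of conditional interface-crossing probabilities:

    k = Phi_A * P(lambda_B | lambda_A)
      = Phi_A * P(lambda_B | lambda_n) * prod_i P(lambda_{i+1} | lambda_i)

The default interface grid mirrors the reference protocol: 29 steps (30
interfaces) from -0.8 to 0 A.  All rates are reported in 1/s; times entering
the flux factor are fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL, KB_SI, PLANCK_SI
from .dynamics import TrajectorySegment

__all__ = [
    "CrossingProbabilities",
    "RateEstimate",
    "RateDecomposition",
    "default_interface_grid",
    "count_effective_crossings",
    "compute_flux_factor",
    "estimate_conditionals",
    "assemble_rate",
    "crossing_profiles",
    "decompose_rate",
    "aggregate_replicates",
    "eyring_rate",
    "eyring_ratio",
]

FS_PER_S = 1e15


def default_interface_grid(n_interfaces: int = 30, start: float = -0.8,
                           stop: float = 0.0) -> np.ndarray:
    """30 interfaces (29 conditional steps) from -0.8 to 0 A by default."""
    if n_interfaces < 2:
        raise ValueError("need at least two interfaces")
    return np.linspace(start, stop, n_interfaces)


@dataclass
class CrossingProbabilities:
    interfaces: np.ndarray      # strictly increasing lambda grid (A)
    conditionals: np.ndarray    # P(lambda_{i+1} | lambda_i), length n-1

    def __post_init__(self):
        self.interfaces = np.asarray(self.interfaces, dtype=float)
        self.conditionals = np.asarray(self.conditionals, dtype=float)
        if np.any(np.diff(self.interfaces) <= 0):
            raise ValueError("interface grid must be strictly increasing")
        if len(self.conditionals) != len(self.interfaces) - 1:
            raise ValueError("need one conditional per interface step")
        if np.any(self.conditionals <= 0) or np.any(self.conditionals > 1):
            raise ValueError("conditionals must lie in (0, 1]")

    @property
    def total_probability(self) -> float:
        return float(np.prod(self.conditionals))

    def cumulative(self) -> np.ndarray:
        """P(lambda_i | lambda_A) at every interface (nonincreasing)."""
        return np.concatenate([[1.0], np.cumprod(self.conditionals)])


@dataclass
class RateEstimate:
    flux: float                 # 1/s
    total_probability: float
    k: float                    # 1/s
    replicates: list = field(default_factory=list)
    sem: float = 0.0


@dataclass
class RateDecomposition:
    flux: float
    p_to_bottleneck: float      # P(lambda = split | lambda_A)
    p_from_bottleneck: float    # P(lambda_B | lambda = split), incl. final leg
    split: float
    total_probability: float


# ---------------------------------------------------------------------------
# flux factor
# ---------------------------------------------------------------------------

def count_effective_crossings(lambdas: np.ndarray, lambda_a: float,
                              lambda_b: float | None = None) -> tuple[int, int]:
    """Effective positive crossings of lambda_a and frames assigned to A.

    The trajectory must start in A (lambda < lambda_a).  Each upward crossing
    of lambda_a counts once per excursion from A.  Assignment is history
    based: the system belongs to A from each entry into the A region until it
    first enters B (if ``lambda_b`` is given); time beyond that is unassigned
    until A is re-entered.
    """
    lam = np.asarray(lambdas)
    in_a_region = lam < lambda_a
    if lambda_b is not None and lam[0] > lambda_b:
        raise ValueError("trajectory starts inside B, not the A basin")
    if lambda_b is None:
        # never leaves the A basin: every upward boundary crossing counts
        up = np.sum(in_a_region[:-1] & ~in_a_region[1:])
        return int(up), len(lam)
    assigned = np.empty(len(lam), dtype=bool)
    state = True
    crossings = 0
    prev_in_a = lam[0] < lambda_a
    for i, x in enumerate(lam):
        in_a = x < lambda_a
        if i > 0 and prev_in_a and not in_a and state:
            crossings += 1          # left the A region while assigned to A
        if in_a:
            state = True
        elif x > lambda_b:
            state = False
        assigned[i] = state
        prev_in_a = in_a
    return int(crossings), int(np.sum(assigned))


def compute_flux_factor(well_trajectories: list[TrajectorySegment],
                        lambda_a: float = -0.8,
                        lambda_b: float | None = None) -> tuple[float, float]:
    """Effective flux factor Phi_A (1/s) with SEM across trajectories."""
    fluxes = []
    total_time = 0.0
    for seg in well_trajectories:
        n_cross, n_frames = count_effective_crossings(seg.lambdas, lambda_a,
                                                      lambda_b)
        t_a = n_frames * seg.dt  # fs
        total_time += t_a
        if t_a == 0:
            raise ValueError("trajectory spends no time assigned to A")
        fluxes.append(n_cross / t_a * FS_PER_S)
    fluxes = np.asarray(fluxes)
    mean = float(fluxes.mean())
    sem_ = float(fluxes.std(ddof=1) / np.sqrt(len(fluxes))) if len(fluxes) > 1 else 0.0
    return mean, sem_


# ---------------------------------------------------------------------------
# conditionals and assembly
# ---------------------------------------------------------------------------

def estimate_conditionals(ensembles, grid: np.ndarray) -> CrossingProbabilities:
    """P(lambda_{i+1} | lambda_i) from one interface ensemble per grid step.

    ``ensembles[i]`` must be the ensemble conditioned on crossing ``grid[i]``
    (one per step, i.e. len(grid) - 1 ensembles); the conditional is the
    multiplicity-weighted fraction of its paths with lambda_max >= grid[i+1].
    """
    grid = np.asarray(grid, dtype=float)
    if len(ensembles) != len(grid) - 1:
        raise ValueError("need one ensemble per interface step")
    conds = []
    for i, ens in enumerate(ensembles):
        if not ens.entries:
            raise ValueError(f"empty ensemble at interface {grid[i]:g}")
        nxt = grid[i + 1]
        conds.append(ens.weighted_fraction(lambda p: p.lambda_max >= nxt))
    conds = np.asarray(conds)
    if np.any(conds <= 0):
        bad = grid[:-1][conds <= 0]
        raise ValueError(f"no path reached the next interface from {bad}")
    return CrossingProbabilities(interfaces=grid, conditionals=conds)


def assemble_rate(flux: float, probs: CrossingProbabilities,
                  final_leg: float = 1.0) -> RateEstimate:
    """k = flux * P(lambda_B | lambda_n) * prod P(lambda_{i+1} | lambda_i)."""
    if flux <= 0:
        raise ValueError("flux must be positive")
    if not 0 < final_leg <= 1:
        raise ValueError("final_leg must lie in (0, 1]")
    total = probs.total_probability * final_leg
    return RateEstimate(flux=flux, total_probability=total, k=flux * total)


def crossing_profiles(probs: CrossingProbabilities, delta: float = 0.05):
    """Cumulative and incremental crossing-probability curves.

    Returns (lam_grid, cumulative P(lambda|lambda_A), incremental
    P(lambda+delta|lambda), bottleneck lambda*).  The cumulative curve is
    resampled onto a delta-spaced grid by interpolating log P; the bottleneck
    is the argmin of the incremental curve, ties broken toward smaller
    lambda.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    lam = probs.interfaces
    logc = np.log(probs.cumulative())
    grid = np.arange(lam[0], lam[-1] + 1e-12, delta)
    logc_g = np.interp(grid, lam, logc)
    cumulative = np.exp(logc_g)
    incremental = np.exp(logc_g[1:] - logc_g[:-1])
    bottleneck = float(grid[:-1][np.argmin(incremental)])
    return grid, cumulative, incremental, bottleneck


def decompose_rate(probs: CrossingProbabilities, split: float = -0.4,
                   flux: float = 1.0, final_leg: float = 1.0) -> RateDecomposition:
    """Split the probability factor at the bottleneck interface.

    p_to = P(split | lambda_A), p_from = P(lambda_B | split) including the
    final leg; their product reconstructs the total to floating precision.
    """
    lam = probs.interfaces
    i_split = np.where(np.isclose(lam, split, atol=1e-9))[0]
    if len(i_split) == 0:
        raise ValueError(f"split {split} is not on the interface grid")
    i = int(i_split[0])
    p_to = float(np.prod(probs.conditionals[:i]))
    p_from = float(np.prod(probs.conditionals[i:])) * final_leg
    return RateDecomposition(flux=flux, p_to_bottleneck=p_to,
                             p_from_bottleneck=p_from, split=split,
                             total_probability=p_to * p_from)


def aggregate_replicates(ks) -> tuple[float, float]:
    """Mean and SEM (sample SD / sqrt(n)) over replicate rate estimates."""
    ks = np.asarray(ks, dtype=float)
    if len(ks) < 2:
        raise ValueError("SEM requires at least two replicates")
    return float(ks.mean()), float(ks.std(ddof=1) / np.sqrt(len(ks)))


# ---------------------------------------------------------------------------
# Eyring
# ---------------------------------------------------------------------------

def eyring_rate(delta_g: float, temperature: float = 300.0) -> float:
    """k = (k_B T / h) exp(-dG_act / RT), dG_act in kcal/mol, k in 1/s."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    prefactor = KB_SI * temperature / PLANCK_SI
    return prefactor * np.exp(-delta_g / (KB_KCAL * temperature))


def eyring_ratio(dg_mut: float, dg_wt: float, temperature: float = 300.0) -> float:
    """Fold change k_mut / k_wt = exp(-(dG_mut - dG_wt) / RT)."""
    return float(np.exp(-(dg_mut - dg_wt) / (KB_KCAL * temperature)))
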