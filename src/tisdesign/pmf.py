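"""Umbrella sampling along lambda with WHAM unbiasing.

The harmonic restraint is ``V_bias = k_f (lambda - center)^2`` with
k_f = 200.0 kcal/(mol*A^2) by default and *no* 1/2 factor (the convention of
the reference restraint module); a config switch restores the 1/2 convention.

Two modes: "screening" (fast, 5 ps per window, no equilibration discard) and
"detailed" (100 ps per window, first 50 ps discarded), both configurable.
Window centers span -1.2 to 1.2 A, spaced 0.0325 A apart for |lambda| < 0.5
and 0.0975 A outside.  Per-window initial states are walked out sequentially
from the neighboring window's final state; production then runs all windows
as one batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import KB_KCAL
from .dynamics import LangevinParams, _batch_steps, draw_maxwell_boltzmann
from .systems import ModelSystem

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "DisconnectedHistogramError",
    "WHAMConvergenceError",
    "generate_window_centers",
    "biased_system",
    "run_umbrella_window",
    "run_umbrella_series",
    "solve_wham",
    "estimate_barrier",
    "compute_pmf",
    "MODES",
]

DEFAULT_FORCE_CONSTANT = 200.0  # kcal/(mol*A^2)
INNER_SPACING = 0.0325          # A, |lambda| < 0.5
OUTER_SPACING = 0.0975          # A, outside
INNER_BOUND = 0.5
MODES = {
    # (duration_ps, discard_ps, replicates)
    "screening": (5.0, 0.0, 1),
    "detailed": (100.0, 50.0, 3),
}


class DisconnectedHistogramError(RuntimeError):
    def __init__(self, gaps):
        super().__init__(f"window histograms leave uncovered lambda gaps: {gaps}")
        self.gaps = gaps


class WHAMConvergenceError(RuntimeError):
    def __init__(self, residual, max_iter):
        super().__init__(f"WHAM not converged after {max_iter} iterations "
                         f"(residual {residual:.3g})")
        self.residual = residual


@dataclass
class UmbrellaWindow:
    center: float               # A
    force_constant: float       # kcal/(mol*A^2), no-1/2 convention
    samples: np.ndarray         # lambda series after discard
    equilibration_discard_ps: float = 0.0
    half_factor: bool = False

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("window has no samples after discard")

    def bias(self, lam: np.ndarray) -> np.ndarray:
        pref = 0.5 if self.half_factor else 1.0
        return pref * self.force_constant * (np.asarray(lam) - self.center) ** 2


@dataclass
class PMFProfile:
    grid: np.ndarray            # bin centers (A)
    free_energy: np.ndarray     # kcal/mol, min anchored to 0
    mode: str = "detailed"
    replicates: int = 1
    barrier: float | None = None
    barrier_sem: float | None = None


def generate_window_centers(lam_range: tuple[float, float] = (-1.2, 1.2),
                            inner_spacing: float = INNER_SPACING,
                            outer_spacing: float = OUTER_SPACING,
                            inner_bound: float = INNER_BOUND) -> np.ndarray:
    """Window centers: dense inside |lambda| < inner_bound, coarse outside,
    symmetric about 0, covering the range (endpoints included)."""
    lo, hi = lam_range
    if inner_spacing <= 0 or outer_spacing <= 0:
        raise ValueError("spacings must be positive")
    if hi - lo < min(inner_spacing, outer_spacing):
        raise ValueError("range narrower than one window spacing")
    inner = list(np.arange(0.0, inner_bound, inner_spacing))
    pos = list(inner)
    c = inner[-1]
    while c < hi - 1e-9:
        c = min(c + outer_spacing, hi)
        pos.append(c)
    centers = sorted(set([-p for p in pos if -p >= lo - 1e-9] + [p for p in pos if p <= hi + 1e-9]))
    return np.array(centers)


def biased_system(system: ModelSystem, center: float, force_constant: float,
                  half_factor: bool = False) -> ModelSystem:
    """System with the harmonic lambda restraint folded into V and its force."""
    pref = 0.5 if half_factor else 1.0

    base_pot, base_grad = system.potential, system.gradient

    def potential(x):
        lam = system.lambda_of(x)
        return base_pot(x) + pref * force_constant * (lam - center) ** 2

    def gradient(x):
        lam = system.lambda_of(x)
        dlam = system.lambda_gradient(x)
        return base_grad(x) + (2.0 * pref * force_constant
                               * (lam - center))[..., None] * dlam

    md = dict(system.metadata)
    if "kernel" in md:
        md["kernel_bias"] = (pref * force_constant, center)
    return replace(system, potential=potential, gradient=gradient, metadata=md)


def _mode_settings(mode, duration_ps, discard_ps):
    if duration_ps is None or discard_ps is None:
        try:
            d, disc, _ = MODES[mode]
        except KeyError:
            raise ValueError(f"unknown mode {mode!r}") from None
        duration_ps = d if duration_ps is None else duration_ps
        discard_ps = disc if discard_ps is None else discard_ps
    return duration_ps, discard_ps


def run_umbrella_window(system: ModelSystem, center: float,
                        force_constant: float = DEFAULT_FORCE_CONSTANT,
                        mode: str = "screening",
                        params: LangevinParams | None = None,
                        initial_positions: np.ndarray | None = None,
                        duration_ps: float | None = None,
                        discard_ps: float | None = None,
                        half_factor: bool = False,
                        rng: np.random.Generator | None = None) -> UmbrellaWindow:
    """Run one biased window; samples are recorded every step after discard."""
    params = params or LangevinParams()
    duration_ps, discard_ps = _mode_settings(mode, duration_ps, discard_ps)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bsys = biased_system(system, center, force_constant, half_factor)
    if initial_positions is None:
        initial_positions = np.asarray(
            system.metadata.get("rest_positions"), dtype=float).copy()
    X = initial_positions[None, :].copy()
    V = draw_maxwell_boltzmann(system, rng, size=1)
    n_steps = int(round(duration_ps * 1000.0 / params.dt))
    n_disc = int(round(discard_ps * 1000.0 / params.dt))
    X, V, lams, _ = _batch_steps(bsys, X, V, n_steps, params, rng)
    return UmbrellaWindow(center=center, force_constant=force_constant,
                          samples=lams[0, n_disc + 1:],
                          equilibration_discard_ps=discard_ps,
                          half_factor=half_factor)


def run_umbrella_series(system: ModelSystem, centers: np.ndarray,
                        force_constant: float = DEFAULT_FORCE_CONSTANT,
                        mode: str = "screening",
                        params: LangevinParams | None = None,
                        duration_ps: float | None = None,
                        discard_ps: float | None = None,
                        half_factor: bool = False,
                        walkout_steps: int = 400,
                        rng: np.random.Generator | None = None) -> list[UmbrellaWindow]:
    """All windows of a PMF calculation.

    Initialization: starting from the system rest geometry at the nearest
    center, each window's initial state is walked out sequentially from its
    neighbor's final state under that window's bias; production then runs all
    windows as one batch.
    """
    params = params or LangevinParams()
    duration_ps, discard_ps = _mode_settings(mode, duration_ps, discard_ps)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    centers = np.asarray(centers, dtype=float)
    rest = np.asarray(system.metadata.get("rest_positions"), dtype=float)
    lam_rest = float(system.lambda_of(rest))
    i_start = int(np.argmin(np.abs(centers - lam_rest)))

    n_win = len(centers)
    inits = np.empty((n_win, system.n_coords))

    def walk(order):
        x = rest.copy()
        for i in order:
            bsys = biased_system(system, centers[i], force_constant, half_factor)
            v = draw_maxwell_boltzmann(system, rng)
            X, V, _, _ = _batch_steps(bsys, x[None, :], v[None, :],
                                      walkout_steps, params, rng,
                                      record_lambda=False)
            x = X[0]
            inits[i] = x

    walk(range(i_start, n_win))
    walk(range(i_start, -1, -1))

    # batched production with per-window bias via a vectorized wrapper
    base_grad = system.gradient
    k_pref = (0.5 if half_factor else 1.0) * force_constant

    def gradient(x):
        lam = system.lambda_of(x)
        dlam = system.lambda_gradient(x)
        return base_grad(x) + (2.0 * k_pref * (lam - centers))[..., None] * dlam

    def potential(x):
        return system.potential(x) + k_pref * (system.lambda_of(x) - centers) ** 2

    md = {k: v for k, v in system.metadata.items() if k != "kernel"}
    bsys = replace(system, potential=potential, gradient=gradient, metadata=md)
    V = draw_maxwell_boltzmann(system, rng, size=n_win)
    n_steps = int(round(duration_ps * 1000.0 / params.dt))
    n_disc = int(round(discard_ps * 1000.0 / params.dt))
    _, _, lams, _ = _batch_steps(bsys, inits, V, n_steps, params, rng)
    return [UmbrellaWindow(center=c, force_constant=force_constant,
                           samples=lams[i, n_disc + 1:],
                           equilibration_discard_ps=discard_ps,
                           half_factor=half_factor)
            for i, c in enumerate(centers)]


def solve_wham(windows: list[UmbrellaWindow], n_bins: int | None = None,
               temperature: float = 300.0, tol: float = 1e-7,
               max_iter: int = 100000, mode: str = "detailed") -> PMFProfile:
    """Self-consistent WHAM over the window histograms.

    Iterates the window free energies until the maximum change is below
    ``tol`` (kcal/mol scale, relative to kT).  Default bin width is half the
    inner window spacing.  Raises on non-overlapping histograms or
    non-convergence.
    """
    kt = KB_KCAL * temperature
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    if n_bins is None:
        n_bins = max(10, int(np.ceil((hi - lo) / (INNER_SPACING / 2.0))))
    edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    K = len(windows)
    counts = np.empty((K, n_bins))
    N = np.empty(K)
    for k, w in enumerate(windows):
        counts[k], _ = np.histogram(w.samples, bins=edges)
        N[k] = len(w.samples)
    total = counts.sum(axis=0)
    occupied = total > 0
    # connectivity: occupied bins must be contiguous
    occ_idx = np.where(occupied)[0]
    gaps = []
    if len(occ_idx):
        holes = np.where(np.diff(occ_idx) > 1)[0]
        for h in holes:
            gaps.append((float(mids[occ_idx[h]]), float(mids[occ_idx[h + 1]])))
    if gaps:
        raise DisconnectedHistogramError(gaps)

    bias = np.stack([w.bias(mids) for w in windows])  # (K, n_bins)
    boltz = np.exp(-bias / kt)
    f = np.zeros(K)  # window free energies, kcal/mol
    for _ in range(int(max_iter)):
        denom = np.einsum("k,k,kb->b", N, np.exp(f / kt), boltz)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, total / denom, 0.0)
        z = boltz[:, occupied] @ p[occupied]
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        resid = np.max(np.abs(f_new - f))
        f = f_new
        if resid < tol:
            break
    else:
        raise WHAMConvergenceError(resid, max_iter)
    with np.errstate(divide="ignore"):
        F = -kt * np.log(np.where(occupied, p, np.nan))
    F = F[occupied] - np.nanmin(F[occupied])
    return PMFProfile(grid=mids[occupied], free_energy=F, mode=mode)


def estimate_barrier(profiles, reactant_region: tuple[float, float] = (-1.2, -0.6),
                     barrier_region: tuple[float, float] = (-0.3, 0.3)):
    """dG_act = max F over the barrier region minus min F over the reactant
    region; mean with SEM across replicate profiles when several are given."""
    if isinstance(profiles, PMFProfile):
        profiles = [profiles]
    vals = []
    for prof in profiles:
        g, F = prof.grid, prof.free_energy
        rmask = (g >= reactant_region[0]) & (g <= reactant_region[1])
        bmask = (g >= barrier_region[0]) & (g <= barrier_region[1])
        if not rmask.any() or not bmask.any():
            raise ValueError("empty reactant or barrier region on the grid")
        vals.append(float(F[bmask].max() - F[rmask].min()))
    if len(vals) == 1:
        return vals[0], 0.0
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def compute_pmf(system: ModelSystem, mode: str = "screening",
                centers: np.ndarray | None = None,
                force_constant: float = DEFAULT_FORCE_CONSTANT,
                params: LangevinParams | None = None,
                n_replicates: int | None = None,
                seed: int = 0, **kwargs) -> tuple[PMFProfile, list[PMFProfile]]:
    """End-to-end PMF: windows, WHAM, barrier, over replicate calculations.

    Returns (profile with barrier attached, per-replicate profiles).  The
    reported profile is the first replicate; the barrier carries the
    replicate mean and SEM.
    """
    if centers is None:
        centers = generate_window_centers()
    if n_replicates is None:
        n_replicates = MODES[mode][2]
    if params is None:
        # the stiff restraint (200 kcal/mol/A^2) on light surrogate particles
        # needs a finer step than the unbiased dynamics default
        params = LangevinParams(dt=0.5)
    profiles = []
    for r in range(n_replicates):
        params_r = replace(params, seed=seed + 7919 * r)
        windows = run_umbrella_series(system, centers, force_constant,
                                      mode=mode, params=params_r, **kwargs)
        profiles.append(solve_wham(windows, mode=mode,
                                   temperature=params_r.temperature))
    barrier, sem = estimate_barrier(profiles)
    main = replace(profiles[0], barrier=barrier, barrier_sem=sem,
                   replicates=n_replicates)
    return main, profiles
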