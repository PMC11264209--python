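"""Desk-scale surrogate model systems for rare-event sampling.

The pipeline is system-agnostic: every downstream module (dynamics, path
sampling, rate assembly, umbrella sampling) interacts with a
:class:`ModelSystem` only through its potential, gradient, and order
parameter.  The surrogates here expose the same interfaces a QM/MM enzyme
Hamiltonian would, at a scale where exhaustive / brute-force oracles are
feasible:

* :func:`make_double_well` -- a bistable scalar reaction coordinate with
  harmonically coupled environment coordinates; the workhorse for validating
  rate constants and free-energy profiles against closed forms.
* :func:`make_migration_mimic` -- a 3D group-transfer mimic (donor D,
  migrating group M, acceptor A) whose order parameter is
  lambda = d(D-M) - d(M-A), with a planted "gate" environment particle that
  modulates the instantaneous barrier.  Reactive and nonreactive barrier
  approaches are therefore statistically distinguishable from prereaction
  geometry, which is the signal the classifiers must recover.
* :func:`make_toy_design_space` -- a small sequence space with a reproducible
  additive+pairwise mutation-effect table, standing in for a side-chain
  design space.

Units: kcal/mol, Angstrom, fs, amu, K throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from . import _kernels
from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "ModelSystem",
    "ToyDesignSpace",
    "make_double_well",
    "make_harmonic_well",
    "make_migration_mimic",
    "make_toy_design_space",
    "system_to_config",
    "system_from_config",
]


class ParameterError(ValueError):
    """Invalid model-system parameter."""


@dataclass
class ModelSystem:
    """A dynamical system with a scalar order parameter lambda.

    Attributes
    ----------
    masses : (n_coords,) array, amu per coordinate.
    potential : callable, positions ``(..., n_coords) -> (...)`` in kcal/mol.
    gradient : callable, positions ``(..., n_coords) -> (..., n_coords)``,
        dV/dx in kcal/(mol*A).
    lambda_spec : either ``("coordinate", index)`` designating one coordinate
        as lambda, or ``("pairs", (i, j), (k, l))`` with *particle* indices so
        that lambda = d(i,j) - d(k,l) with particles laid out as consecutive
        xyz triples.
    """

    name: str
    n_coords: int
    masses: np.ndarray
    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    lambda_spec: tuple
    temperature: float = DEFAULT_TEMPERATURE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.n_coords,):
            raise ParameterError("masses must have one entry per coordinate")
        if np.any(self.masses <= 0):
            raise ParameterError("masses must be positive")
        self._validate_lambda_spec()

    def _validate_lambda_spec(self):
        kind = self.lambda_spec[0]
        if kind == "coordinate":
            idx = self.lambda_spec[1]
            if not 0 <= idx < self.n_coords:
                raise ParameterError("lambda coordinate index out of range")
        elif kind == "pairs":
            _, breaking, forming = self.lambda_spec
            n_particles = self.n_coords // 3
            for (a, b) in (breaking, forming):
                if a == b:
                    raise ParameterError("lambda pair indices must be distinct")
                if not (0 <= a < n_particles and 0 <= b < n_particles):
                    raise ParameterError("lambda pair index out of range")
        else:
            raise ParameterError(f"unknown lambda_spec kind {kind!r}")

    # -- order parameter ---------------------------------------------------
    def lambda_of(self, x: np.ndarray) -> np.ndarray:
        """Evaluate lambda for positions of shape (..., n_coords)."""
        x = np.asarray(x)
        if self.lambda_spec[0] == "coordinate":
            return x[..., self.lambda_spec[1]]
        _, (i, j), (k, l) = self.lambda_spec
        d_break = _pair_distance(x, i, j)
        d_form = _pair_distance(x, k, l)
        return d_break - d_form

    def lambda_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(lambda)/dx, shape (..., n_coords)."""
        x = np.asarray(x)
        g = np.zeros_like(x, dtype=float)
        if self.lambda_spec[0] == "coordinate":
            g[..., self.lambda_spec[1]] = 1.0
            return g
        _, (i, j), (k, l) = self.lambda_spec
        _add_distance_gradient(g, x, i, j, +1.0)
        _add_distance_gradient(g, x, k, l, -1.0)
        return g

    def breaking_distance(self, x: np.ndarray) -> np.ndarray:
        """Breaking-bond length; for scalar-coordinate systems this is lambda
        itself (its compression troughs play the same role)."""
        if self.lambda_spec[0] == "coordinate":
            return self.lambda_of(x)
        _, (i, j), _ = self.lambda_spec
        return _pair_distance(np.asarray(x), i, j)


def _pair_distance(x: np.ndarray, i: int, j: int) -> np.ndarray:
    d = x[..., 3 * i:3 * i + 3] - x[..., 3 * j:3 * j + 3]
    r = np.sqrt(np.sum(d * d, axis=-1))
    return r


def _add_distance_gradient(g, x, i, j, scale):
    d = x[..., 3 * i:3 * i + 3] - x[..., 3 * j:3 * j + 3]
    r = np.sqrt(np.sum(d * d, axis=-1, keepdims=True))
    if np.any(r == 0):
        raise FloatingPointError("coincident atoms in distance gradient")
    u = scale * d / r
    g[..., 3 * i:3 * i + 3] += u
    g[..., 3 * j:3 * j + 3] -= u


# ---------------------------------------------------------------------------
# Double well
# ---------------------------------------------------------------------------

def make_double_well(barrier_height: float = 4.0,
                     well_centers: tuple[float, float] = (-1.0, 1.0),
                     n_env: int = 1,
                     coupling: float = 0.0,
                     seed: int = 0,
                     k_env: float = 2.0,
                     temperature: float = DEFAULT_TEMPERATURE) -> ModelSystem:
    """Quartic double well along coordinate 0 plus harmonic environment.

    V(x) = h * ((u^2 - c^2)^2 / c^4) + sum_i k_env/2 (x_i - coupling*u)^2
    with u = x0 - midpoint and c = half the well separation, so the minima sit
    exactly at ``well_centers`` and the barrier top (env relaxed) is
    ``barrier_height`` kcal/mol above them.
    """
    if barrier_height <= 0:
        raise ParameterError("barrier_height must be positive")
    l1, l2 = well_centers
    if l1 == l2:
        raise ParameterError("well centers must be distinct")
    if n_env < 0:
        raise ParameterError("n_env must be >= 0")
    mid = 0.5 * (l1 + l2)
    c = 0.5 * abs(l2 - l1)
    h = float(barrier_height)
    n = 1 + n_env

    def potential(x):
        x = np.asarray(x, dtype=float)
        u = x[..., 0] - mid
        v = h * (u * u - c * c) ** 2 / c ** 4
        if n_env:
            env = x[..., 1:] - coupling * u[..., None]
            v = v + 0.5 * k_env * np.sum(env * env, axis=-1)
        return v

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        u = x[..., 0] - mid
        g[..., 0] = 4.0 * h * u * (u * u - c * c) / c ** 4
        if n_env:
            env = x[..., 1:] - coupling * u[..., None]
            g[..., 1:] = k_env * env
            g[..., 0] -= coupling * k_env * np.sum(env, axis=-1)
        return g

    rest = np.zeros(n)
    rest[0] = l1
    return ModelSystem(
        name="double_well",
        n_coords=n,
        masses=np.ones(n),
        potential=potential,
        gradient=gradient,
        lambda_spec=("coordinate", 0),
        temperature=temperature,
        metadata={
            "config": {
                "kind": "double_well",
                "barrier_height": barrier_height,
                "well_centers": list(well_centers),
                "n_env": n_env,
                "coupling": coupling,
                "seed": seed,
                "k_env": k_env,
                "temperature": temperature,
            },
            "kernel": _kernels.kernel_params_double_well(
                h, (l1, l2), coupling, k_env),
            "well_centers": (l1, l2),
            "barrier_height": h,
            "k_env": k_env,
            "rest_positions": rest,
            "particle_labels": ["lambda"] + [f"env{i}" for i in range(n_env)],
        },
    )


def make_harmonic_well(k_lambda: float = 10.0,
                       center: float = 0.0,
                       n_env: int = 0,
                       k_env: float = 2.0,
                       temperature: float = DEFAULT_TEMPERATURE) -> ModelSystem:
    """Single harmonic well along the scalar order parameter.

    Its free-energy profile equals the potential itself (decoupled
    environment), making it the analytic reference for umbrella/WHAM checks.
    """
    if k_lambda <= 0:
        raise ParameterError("k_lambda must be positive")
    n = 1 + n_env

    def potential(x):
        x = np.asarray(x, dtype=float)
        u = x[..., 0] - center
        v = 0.5 * k_lambda * u * u
        if n_env:
            v = v + 0.5 * k_env * np.sum(x[..., 1:] ** 2, axis=-1)
        return v

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        g[..., 0] = k_lambda * (x[..., 0] - center)
        if n_env:
            g[..., 1:] = k_env * x[..., 1:]
        return g

    rest = np.zeros(n)
    rest[0] = center
    return ModelSystem(
        name="harmonic_well",
        n_coords=n,
        masses=np.ones(n),
        potential=potential,
        gradient=gradient,
        lambda_spec=("coordinate", 0),
        temperature=temperature,
        metadata={
            "config": {"kind": "harmonic_well", "k_lambda": k_lambda,
                       "center": center, "n_env": n_env, "k_env": k_env,
                       "temperature": temperature},
            "k_lambda": k_lambda,
            "rest_positions": rest,
        },
    )


# ---------------------------------------------------------------------------
# Migration mimic
# ---------------------------------------------------------------------------

def make_migration_mimic(n_env: int = 4,
                         gate_strength: float = 3.0,
                         seed: int = 0,
                         barrier_height: float = 7.0,
                         bond_length_sum: float = 4.0,
                         k_bond: float = 300.0,
                         gate_rest: float = 2.0,
                         gate_ref: float = 2.0,
                         gate_width: float = 0.8,
                         gate_bump_width: float = 0.2,
                         gate2_strength: float = 3.0,
                         gate2_rest: float = 2.0,
                         k_gate: float = 4.0,
                         k_env: float = 4.0,
                         k_center: float = 5.0,
                         gate_mass: float = 12.0,
                         temperature: float = DEFAULT_TEMPERATURE) -> ModelSystem:
    """3D group-transfer mimic with planted gate coordinates.

    Particles (xyz triples, in order): donor D, migrating group M, acceptor A,
    gate particle G (plus, when ``n_env >= 2``, a second gate particle G2),
    then distractor particles, each tethered to M by a harmonic distance
    restraint (so their distances to M are pure class-free noise rather than
    proxies of the molecule's displacement).  lambda = d(D-M) - d(M-A); a
    stiff restraint keeps d(D-M) + d(M-A) near ``bond_length_sum`` so the
    bonds exchange over a quartic barrier in lambda of height
    ``barrier_height``.

    Each gate particle is tethered to M at its rest distance; the
    instantaneous barrier is modulated by a bounded function of the gate
    distance g = d(G-M):

        V += strength * tanh((g - gate_ref)/gate_width) * exp(-lambda^2 / (2 w^2))

    so configurations with g below ``gate_ref`` see a lower barrier.  This is
    the planted ground truth (recorded in metadata): reactive barrier
    approaches carry statistically recoverable gate signatures in prereaction
    windows, while distractor-particle distances carry none.  A single
    bounded modulation saturates and caps the linear separability of the two
    pathway classes; the second, independent gate restores a strong combined
    signal while each individual barrier excursion stays rare.  Setting
    ``gate2_strength = 0`` makes G2 an inert tethered particle.

    Variants ("mutants") are emulated by shifting ``gate_rest`` relative to
    the fixed ``gate_ref``: a smaller rest distance biases the gate toward its
    barrier-lowering side without changing the modulation rule itself.
    """
    if n_env < 1:
        raise ParameterError("n_env must be >= 1")
    if barrier_height <= 0:
        raise ParameterError("barrier_height must be positive")
    rng = np.random.default_rng(seed)
    n_particles = 3 + n_env
    n = 3 * n_particles
    n_gates = 2 if n_env >= 2 else 1
    # light donor/acceptor make the bond vibration (the compression clock
    # used for t = 0 alignment) several times faster than barrier passage
    masses = np.full(n, 12.0)
    masses[0:3] = 3.0    # D
    masses[6:9] = 3.0    # A
    # the gate mass sets a gate's oscillation period, i.e. how long a gate
    # configuration persists relative to one barrier approach (~100 fs):
    # heavy = slowly varying environment (strong prereaction predictability),
    # light = faster-mixing environment
    masses[9:9 + 3 * n_gates] = float(gate_mass)
    # distractors are light so the uninformative noise they emulate mixes
    # within a single path-sampling chain (a slow uninformative coordinate
    # would turn into a spurious chain-identity marker in few-chain studies)
    masses[9 + 3 * n_gates:] = 2.0
    c = 1.0          # wells of the lambda double well at +/- 1 A
    h = float(barrier_height)
    L = float(bond_length_sum)
    w2 = gate_bump_width ** 2
    gates = [(3, float(gate_strength), float(gate_rest))]
    if n_gates == 2:
        gates.append((4, float(gate2_strength), float(gate2_rest)))
    n_distract = n_env - n_gates

    # distractor tether rest distances (to M) and initial directions
    distractor_rests = 3.0 + 1.5 * rng.random(max(n_distract, 0))
    dirs = rng.normal(size=(max(n_distract, 0), 3))
    if n_distract > 0:
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    D, M, A = 0, 1, 2
    first_distract = 3 + n_gates

    def _pairvec(x, i):
        return x[..., 3 * i:3 * i + 3] - x[..., 3 * M:3 * M + 3]

    def potential(x):
        x = np.asarray(x, dtype=float)
        dDM = x[..., 3 * D:3 * D + 3] - x[..., 3 * M:3 * M + 3]
        dMA = x[..., 3 * M:3 * M + 3] - x[..., 3 * A:3 * A + 3]
        rDM = np.sqrt(np.sum(dDM * dDM, axis=-1))
        rMA = np.sqrt(np.sum(dMA * dMA, axis=-1))
        lam = rDM - rMA
        s = rDM + rMA - L
        v = 0.5 * k_bond * s * s
        v = v + h * (lam * lam - c * c) ** 2 / c ** 4
        bump = np.exp(-lam * lam / (2.0 * w2))
        for (gp, strength, rest) in gates:
            g = np.sqrt(np.sum(_pairvec(x, gp) ** 2, axis=-1))
            v = v + strength * np.tanh((g - gate_ref) / gate_width) * bump
            v = v + 0.5 * k_gate * (g - rest) ** 2
        xM = x[..., 3 * M:3 * M + 3]
        v = v + 0.5 * k_center * np.sum(xM * xM, axis=-1)
        for e in range(n_distract):
            de = _pairvec(x, first_distract + e)
            r = np.sqrt(np.sum(de * de, axis=-1))
            v = v + 0.5 * k_env * (r - distractor_rests[e]) ** 2
        return v

    def gradient(x):
        x = np.asarray(x, dtype=float)
        grad = np.zeros_like(x)
        dDM = x[..., 3 * D:3 * D + 3] - x[..., 3 * M:3 * M + 3]
        dMA = x[..., 3 * M:3 * M + 3] - x[..., 3 * A:3 * A + 3]
        rDM = np.sqrt(np.sum(dDM * dDM, axis=-1))
        rMA = np.sqrt(np.sum(dMA * dMA, axis=-1))
        lam = rDM - rMA
        s = rDM + rMA - L
        uDM = dDM / rDM[..., None]
        uMA = dMA / rMA[..., None]
        bump = np.exp(-lam * lam / (2.0 * w2))
        # lambda-derivative of the quartic plus every gate bump
        dV_dlam = 4.0 * h * lam * (lam * lam - c * c) / c ** 4
        gate_geoms = []
        for (gp, strength, rest) in gates:
            dG = _pairvec(x, gp)
            g = np.sqrt(np.sum(dG * dG, axis=-1))
            th = np.tanh((g - gate_ref) / gate_width)
            gate_geoms.append((gp, strength, rest, dG, g, th))
            dV_dlam = dV_dlam + strength * th * bump * (-lam / w2)
        dV_drDM = k_bond * s + dV_dlam
        dV_drMA = k_bond * s - dV_dlam
        grad[..., 3 * D:3 * D + 3] += dV_drDM[..., None] * uDM
        grad[..., 3 * M:3 * M + 3] -= dV_drDM[..., None] * uDM
        grad[..., 3 * M:3 * M + 3] += dV_drMA[..., None] * uMA
        grad[..., 3 * A:3 * A + 3] -= dV_drMA[..., None] * uMA
        for (gp, strength, rest, dG, g, th) in gate_geoms:
            uG = dG / g[..., None]
            dV_dg = strength * (1.0 - th ** 2) / gate_width * bump \
                + k_gate * (g - rest)
            grad[..., 3 * gp:3 * gp + 3] += dV_dg[..., None] * uG
            grad[..., 3 * M:3 * M + 3] -= dV_dg[..., None] * uG
        xM = x[..., 3 * M:3 * M + 3]
        grad[..., 3 * M:3 * M + 3] += k_center * xM
        for e in range(n_distract):
            p = first_distract + e
            de = _pairvec(x, p)
            r = np.sqrt(np.sum(de * de, axis=-1, keepdims=True))
            dV = k_env * (r - distractor_rests[e])
            grad[..., 3 * p:3 * p + 3] += dV * de / r
            grad[..., 3 * M:3 * M + 3] -= dV * de / r
        return grad

    # rest geometry: reactant well (lambda = -1): rDM = 1.5, rMA = 2.5,
    # molecule along +x axis, gates along +/-y at their rest distances
    rest = np.zeros(n)
    rest[3 * D:3 * D + 3] = (1.5, 0.0, 0.0)
    rest[3 * M:3 * M + 3] = (0.0, 0.0, 0.0)
    rest[3 * A:3 * A + 3] = (-2.5, 0.0, 0.0)
    rest[9:12] = (0.0, gates[0][2], 0.0)
    if n_gates == 2:
        rest[12:15] = (0.0, -gates[1][2], 0.0)
    for e in range(n_distract):
        base = 3 * (first_distract + e)
        rest[base:base + 3] = distractor_rests[e] * dirs[e]

    labels = ["D", "M", "A", "gate"] + (["gate2"] if n_gates == 2 else []) \
        + [f"env{i}" for i in range(n_distract)]
    return ModelSystem(
        name="migration_mimic",
        n_coords=n,
        masses=masses,
        potential=potential,
        gradient=gradient,
        lambda_spec=("pairs", (D, M), (M, A)),
        temperature=temperature,
        metadata={
            "config": {
                "kind": "migration_mimic", "n_env": n_env,
                "gate_strength": gate_strength, "seed": seed,
                "barrier_height": barrier_height,
                "bond_length_sum": bond_length_sum, "k_bond": k_bond,
                "gate_rest": gate_rest, "gate_ref": gate_ref,
                "gate_width": gate_width, "gate_bump_width": gate_bump_width,
                "gate2_strength": gate2_strength, "gate2_rest": gate2_rest,
                "k_gate": k_gate, "k_env": k_env, "k_center": k_center,
                "gate_mass": gate_mass, "temperature": temperature,
            },
            "kernel": _kernels.kernel_params_migration_mimic(
                h, L, k_bond, gate_strength, gate_ref, gate_width,
                gate_bump_width, k_gate, gate_rest, k_center, k_env,
                distractor_rests, n_gates, gate2_strength, gate2_rest),
            "particle_labels": labels,
            "gate_particle": 3,
            "gate_particles": [gp for (gp, _, _) in gates],
            "gate_truth": {
                "description": "barrier modulated by tanh((d(G,M)-gate_ref)/gate_width) per gate",
                "gate_strengths": [s for (_, s, _) in gates],
                "gate_ref": gate_ref,
                "favorable_direction": "small d(G,M)",
            },
            "rest_positions": rest,
            "distractor_rests": distractor_rests,
        },
    )


# ---------------------------------------------------------------------------
# Toy design space
# ---------------------------------------------------------------------------

@dataclass
class ToyDesignSpace:
    """Finite sequence space with a deterministic conformation-energy model.

    ``energy_model(sequence, conformation)`` returns kcal/mol; conformations
    are opaque hashable identifiers (here: integers indexing planted tables,
    or coordinate arrays for potential-backed spaces).
    """

    sites: list
    alphabet: list            # allowed tokens per site
    wt_sequence: tuple
    energy_model: Callable[[tuple, object], float]
    # optional tabular structure enabling branch-and-bound search
    additive: np.ndarray | None = None   # (n_sites, n_tokens, n_conf)
    pairwise: np.ndarray | None = None   # (n_sites, n_tokens, n_sites, n_tokens)
    n_conformations: int = 0

    def sequences(self):
        import itertools
        return itertools.product(*[self.alphabet for _ in self.sites])

    @property
    def size(self) -> int:
        return len(self.alphabet) ** len(self.sites)


def make_toy_design_space(n_sites: int = 3,
                          alphabet_size: int = 4,
                          effect_table_seed: int = 0,
                          n_conformations: int = 6,
                          additive_scale: float = 2.0,
                          pairwise_scale: float = 0.5) -> ToyDesignSpace:
    """Sequence space with reproducible random additive+pairwise effects.

    WT is token 0 at every site with all its effects zeroed, so mutation
    effects read directly off the tables: E(s, conf) - E(WT, conf) equals the
    sum of the planted per-site and pairwise entries of s.
    """
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    if alphabet_size < 2:
        raise ParameterError("alphabet_size must be >= 2")
    rng = np.random.default_rng(effect_table_seed)
    add = rng.normal(scale=additive_scale,
                     size=(n_sites, alphabet_size, n_conformations))
    add[:, 0, :] = 0.0
    pair = rng.normal(scale=pairwise_scale,
                      size=(n_sites, alphabet_size, n_sites, alphabet_size))
    # symmetrize, zero diagonal blocks and WT-token couplings
    pair = 0.5 * (pair + pair.transpose(2, 3, 0, 1))
    for i in range(n_sites):
        pair[i, :, i, :] = 0.0
    pair[:, 0, :, :] = 0.0
    pair[:, :, :, 0] = 0.0
    base = rng.normal(scale=1.0, size=n_conformations)

    wt = tuple(0 for _ in range(n_sites))

    def energy_model(sequence, conformation):
        s = tuple(sequence)
        conf = int(conformation)
        e = base[conf]
        for i, t in enumerate(s):
            e += add[i, t, conf]
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                e += pair[i, s[i], j, s[j]]
        return float(e)

    return ToyDesignSpace(
        sites=list(range(n_sites)),
        alphabet=list(range(alphabet_size)),
        wt_sequence=wt,
        energy_model=energy_model,
        additive=add,
        pairwise=pair,
        n_conformations=n_conformations,
    )


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

_FACTORIES = {
    "double_well": make_double_well,
    "harmonic_well": make_harmonic_well,
    "migration_mimic": make_migration_mimic,
}


def system_to_config(system: ModelSystem) -> str:
    """Serialize a factory-built system to a YAML string."""
    cfg = system.metadata.get("config")
    if cfg is None:
        raise ParameterError("system carries no factory config")
    return yaml.safe_dump({"system": cfg}, sort_keys=False)


def system_from_config(text: str) -> ModelSystem:
    """Rebuild a system from :func:`system_to_config` output."""
    data = yaml.safe_load(io.StringIO(text))
    cfg = dict(data["system"])
    kind = cfg.pop("kind")
    try:
        factory = _FACTORIES[kind]
    except KeyError:
        raise ParameterError(f"unknown system kind {kind!r}") from None
    return factory(**cfg)
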