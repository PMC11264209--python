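"""Multistate sequence design over reactive/nonreactive structure sets.

The design objective for a sequence s is

    f(s) = sum_i E_R,i(s) - sum_i E_NR,i(s)

over N_R reactive and N_NR nonreactive representative structures (three of
each by default), reported relative to the starting sequence: score =
f(s) - f(WT), so the WT score is 0 by construction.  Designs are collected
within a 20 kcal/mol window of the best feasible sequence, under the
stability constraint that the redesigned reactive structures are no more
than 5 kcal/mol less stable than WT's (applied to the sum of reactive
energies by default, mirroring the objective; a per-structure variant is
available).

The search runs exhaustively on small spaces, or by depth-first
branch-and-bound with an admissible additive+pairwise lower bound on spaces
built by :func:`tisdesign.systems.make_toy_design_space`; both return
identical result sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .classify import TrainedModel, reactive_fraction
from .geometry import FeatureSchema
from .paths import WeightedFrames
from .systems import ToyDesignSpace

__all__ = [
    "DesignObjectiveSpec",
    "DesignResult",
    "ScreeningRecord",
    "OBJECTIVE_WINDOW",
    "STABILITY_BOUND",
    "select_representative_structures",
    "score_objective",
    "search_designs",
    "screen_candidate",
    "prioritize",
]

OBJECTIVE_WINDOW = 20.0   # kcal/mol around the optimal sequence
STABILITY_BOUND = 5.0     # kcal/mol destabilization allowed on reactive set


class SelectionError(RuntimeError):
    pass


@dataclass
class DesignObjectiveSpec:
    reactive_structures: list          # conformations (ids or coordinates)
    nonreactive_structures: list
    energy_model: "callable"           # (sequence, conformation) -> kcal/mol
    wt_sequence: tuple

    def __post_init__(self):
        if not self.reactive_structures or not self.nonreactive_structures:
            raise ValueError("need at least one structure per class")

    def f(self, sequence) -> float:
        s = tuple(sequence)
        return (sum(self.energy_model(s, c) for c in self.reactive_structures)
                - sum(self.energy_model(s, c) for c in self.nonreactive_structures))

    def reactive_sum(self, sequence) -> float:
        s = tuple(sequence)
        return sum(self.energy_model(s, c) for c in self.reactive_structures)


@dataclass
class DesignResult:
    sequence: tuple
    score: float               # f(s) - f(WT), kcal/mol
    stability_ok: bool
    within_window: bool | None = None
    rank: int | None = None


@dataclass
class ScreeningRecord:
    sequence: tuple
    objective_score: float | None = None
    lr_fraction: float | None = None
    nn_fraction: float | None = None
    lr_fraction_normalized: float | None = None
    nn_fraction_normalized: float | None = None
    screening_barrier: float | None = None
    failure_reason: str | None = None
    priority_tier: int | None = None


# ---------------------------------------------------------------------------
# structure selection
# ---------------------------------------------------------------------------

def select_representative_structures(frames: WeightedFrames,
                                     lr: TrainedModel, nn: TrainedModel,
                                     schema: FeatureSchema,
                                     n_per_class: int = 3):
    """Pick the most confidently classified frames of each true class.

    Confidence is the mean of the LR and NN reactive probabilities; the
    reactive set is the top ``n_per_class`` truly reactive frames by that
    confidence, the nonreactive set the top truly nonreactive frames by
    (1 - confidence).  Deterministic: ties break by frame position.
    Returns (reactive positions, nonreactive positions) as arrays.
    """
    if frames.labels is None:
        raise SelectionError("frames carry no true pathway labels")
    p = 0.5 * (lr.predict_proba_frames(frames.positions, schema)
               + nn.predict_proba_frames(frames.positions, schema))
    out = []
    for label, conf in (("R", p), ("NR", 1.0 - p)):
        mask = frames.labels == label
        idx = np.where(mask)[0]
        if len(idx) < n_per_class:
            raise SelectionError(
                f"only {len(idx)} {label} frames available, need {n_per_class}")
        order = idx[np.argsort(-conf[idx], kind="stable")]
        out.append(frames.positions[order[:n_per_class]].copy())
    return out[0], out[1]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def score_objective(sequence, spec: DesignObjectiveSpec,
                    stability_bound: float = STABILITY_BOUND,
                    stability_per_structure: bool = False) -> DesignResult:
    """f(s) - f(WT) with the reactive-stability constraint flag."""
    s = tuple(sequence)
    score = spec.f(s) - spec.f(spec.wt_sequence)
    if stability_per_structure:
        ok = all(spec.energy_model(s, c)
                 <= spec.energy_model(spec.wt_sequence, c) + stability_bound
                 for c in spec.reactive_structures)
    else:
        ok = spec.reactive_sum(s) <= spec.reactive_sum(spec.wt_sequence) + stability_bound
    return DesignResult(sequence=s, score=float(score), stability_ok=bool(ok))


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _rank_and_filter(results, window):
    feasible = [r for r in results if r.stability_ok]
    if not feasible:
        return []
    f_min = min(r.score for r in feasible)
    keep = [r for r in feasible if r.score <= f_min + window]
    keep.sort(key=lambda r: (r.score, r.sequence))
    for i, r in enumerate(keep):
        r.within_window = True
        r.rank = i + 1
    return keep


def _tables_apply(space, spec):
    """The planted tables describe the objective only when the spec scores
    with the space's own energy model on integer conformation ids."""
    return (space.additive is not None
            and spec.energy_model is space.energy_model
            and _tabular_confs(spec) is not None)


def _search_exhaustive(space, spec, window, stability, per_structure):
    if _tables_apply(space, spec) and not per_structure:
        return _search_exhaustive_tabular(space, spec, window, stability)
    results = [score_objective(s, spec, stability, per_structure)
               for s in space.sequences()]
    return _rank_and_filter(results, window)


def _tabular_confs(spec):
    try:
        r = [int(c) for c in spec.reactive_structures]
        nr = [int(c) for c in spec.nonreactive_structures]
    except (TypeError, ValueError):
        return None
    return r, nr


def _search_exhaustive_tabular(space, spec, window, stability):
    """Plain enumeration, vectorized over all sequences via the planted
    tables (no pruning; the independent reference for branch-and-bound)."""
    a_obj, p_obj, a_stab, p_stab = _reduced_tables(space, spec)
    n_sites, n_tok = a_obj.shape[0], a_obj.shape[1]
    seqs = np.indices((n_tok,) * n_sites).reshape(n_sites, -1).T
    f = np.zeros(len(seqs))
    stab = np.zeros(len(seqs))
    for i in range(n_sites):
        f += a_obj[i, seqs[:, i]]
        stab += a_stab[i, seqs[:, i]]
        for j in range(i + 1, n_sites):
            f += p_obj[i, seqs[:, i], j, seqs[:, j]]
            stab += p_stab[i, seqs[:, i], j, seqs[:, j]]
    wt = np.array(space.wt_sequence)
    i_wt = int(np.ravel_multi_index(wt, (n_tok,) * n_sites))
    scores = f - f[i_wt]
    feasible = stab <= stab[i_wt] + stability
    if not feasible.any():
        return []
    f_min = scores[feasible].min()
    keep = feasible & (scores <= f_min + window)
    results = [DesignResult(sequence=tuple(int(t) for t in seqs[i]),
                            score=float(scores[i]), stability_ok=True)
               for i in np.where(keep)[0]]
    return _rank_and_filter(results, window)


def _reduced_tables(space: ToyDesignSpace, spec: DesignObjectiveSpec):
    """Collapse the space's planted tables onto the objective's structures."""
    r_ids = [int(c) for c in spec.reactive_structures]
    nr_ids = [int(c) for c in spec.nonreactive_structures]
    add = space.additive
    pair = space.pairwise
    a_obj = add[:, :, r_ids].sum(axis=2) - add[:, :, nr_ids].sum(axis=2)
    a_stab = add[:, :, r_ids].sum(axis=2)
    p_obj = (len(r_ids) - len(nr_ids)) * pair
    p_stab = len(r_ids) * pair
    return a_obj, p_obj, a_stab, p_stab


def _search_branch_and_bound(space, spec, window, stability, per_structure):
    if per_structure or not _tables_apply(space, spec):
        # no admissible tabular bound available; plain enumeration
        return _search_exhaustive(space, spec, window, stability, per_structure)
    a_obj, p_obj, a_stab, p_stab = _reduced_tables(space, spec)
    n_sites = len(space.sites)
    tokens = list(range(len(space.alphabet)))
    wt = space.wt_sequence
    f_wt_extra = sum(a_obj[i, wt[i]] for i in range(n_sites)) + sum(
        p_obj[i, wt[i], j, wt[j]] for i in range(n_sites) for j in range(i + 1, n_sites))
    stab_wt = sum(a_stab[i, wt[i]] for i in range(n_sites)) + sum(
        p_stab[i, wt[i], j, wt[j]] for i in range(n_sites) for j in range(i + 1, n_sites))
    # pairwise minima for unassigned-unassigned bound terms
    pair_min = p_obj.min(axis=(1, 3))  # (n_sites, n_sites)

    best = [np.inf]
    leaves = []

    def bound(prefix):
        k = len(prefix)
        val = sum(a_obj[i, prefix[i]] for i in range(k))
        val += sum(p_obj[i, prefix[i], j, prefix[j]]
                   for i in range(k) for j in range(i + 1, k))
        for u in range(k, n_sites):
            per_tok = a_obj[u, :].copy()
            for i in range(k):
                per_tok = per_tok + p_obj[i, prefix[i], u, :]
            val += per_tok.min()
        for u in range(k, n_sites):
            for v in range(u + 1, n_sites):
                val += pair_min[u, v]
        return val

    def dfs(prefix):
        if len(prefix) == n_sites:
            val = bound(prefix)
            stab = sum(a_stab[i, prefix[i]] for i in range(n_sites)) + sum(
                p_stab[i, prefix[i], j, prefix[j]]
                for i in range(n_sites) for j in range(i + 1, n_sites))
            ok = stab <= stab_wt + stability
            leaves.append((tuple(prefix), val, ok))
            if ok and val < best[0]:
                best[0] = val
            return
        if bound(prefix) > best[0] + window:
            return
        for t in tokens:
            dfs(prefix + [t])

    dfs([])
    results = [DesignResult(sequence=s, score=float(v - f_wt_extra),
                            stability_ok=ok) for s, v, ok in leaves]
    return _rank_and_filter(results, window)


def search_designs(space: ToyDesignSpace, spec: DesignObjectiveSpec,
                   window: float = OBJECTIVE_WINDOW,
                   stability: float = STABILITY_BOUND,
                   mode: str = "exhaustive",
                   stability_per_structure: bool = False) -> list[DesignResult]:
    """All stability-feasible sequences within ``window`` of the best one,
    ranked ascending by score (ties by sequence)."""
    if mode == "exhaustive":
        return _search_exhaustive(space, spec, window, stability,
                                  stability_per_structure)
    if mode == "branch_and_bound":
        return _search_branch_and_bound(space, spec, window, stability,
                                        stability_per_structure)
    raise ValueError(f"unknown search mode {mode!r}")


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_candidate(sequence, system_factory, lr: TrainedModel,
                     nn: TrainedModel, schema: FeatureSchema,
                     objective_score: float | None = None,
                     reference: ScreeningRecord | None = None,
                     equilibrium_ps: float = 40.0, n_replicas: int = 8,
                     position_stride: int = 25,
                     pmf_kwargs: dict | None = None,
                     seed: int = 0) -> ScreeningRecord:
    """Characterize one candidate: reactant-well reactive-like fractions
    (LR and NN) and a screening-mode barrier estimate.

    Failures in either stage are recorded on the record (reason string), not
    raised, so a screening campaign survives individual bad candidates.
    """
    from .dynamics import LangevinParams, run_equilibrium_well
    from .paths import WeightedFrames as WF
    from .pmf import compute_pmf

    rec = ScreeningRecord(sequence=tuple(sequence),
                          objective_score=objective_score)
    system = system_factory(tuple(sequence))
    try:
        segs = run_equilibrium_well(system, equilibrium_ps, n_replicas,
                                    LangevinParams(seed=seed),
                                    position_stride=position_stride)
        pos = np.concatenate([s.positions for s in segs])
        frames = WF(positions=pos, weights=np.ones(len(pos)),
                    times=np.zeros(len(pos)), path_ids=np.arange(len(pos)))
        rec.lr_fraction = reactive_fraction(lr, frames, schema)
        rec.nn_fraction = reactive_fraction(nn, frames, schema)
        if reference is not None and reference.lr_fraction:
            rec.lr_fraction_normalized = rec.lr_fraction / reference.lr_fraction
        if reference is not None and reference.nn_fraction:
            rec.nn_fraction_normalized = rec.nn_fraction / reference.nn_fraction
    except Exception as exc:  # recorded, not raised
        rec.failure_reason = f"equilibrium tracking failed: {exc}"
    try:
        prof, _ = compute_pmf(system, mode="screening", seed=seed,
                              **(pmf_kwargs or {}))
        rec.screening_barrier = prof.barrier
    except Exception as exc:
        reason = f"screening PMF failed: {exc}"
        rec.failure_reason = (rec.failure_reason + "; " + reason
                              if rec.failure_reason else reason)
    return rec


def prioritize(records: list[ScreeningRecord],
               reference: ScreeningRecord) -> list[ScreeningRecord]:
    """Rank candidates into tiers by the joint criterion.

    Tier 1: negative objective score AND increased reactive-like population
    under both models AND screening barrier <= reference.  Tier 2: any two of
    the three.  Tier 3: the rest.  Stable sort by objective score in tier.
    """
    ranked = []
    for rec in records:
        hits = 0
        if rec.objective_score is not None and rec.objective_score < 0:
            hits += 1
        if (rec.lr_fraction_normalized is not None
                and rec.nn_fraction_normalized is not None
                and rec.lr_fraction_normalized > 1.0
                and rec.nn_fraction_normalized > 1.0):
            hits += 1
        if (rec.screening_barrier is not None
                and reference.screening_barrier is not None
                and rec.screening_barrier <= reference.screening_barrier):
            hits += 1
        rec.priority_tier = 1 if hits == 3 else (2 if hits == 2 else 3)
        ranked.append(rec)
    ranked.sort(key=lambda r: (r.priority_tier,
                               r.objective_score if r.objective_score is not None else np.inf))
    return ranked
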