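"""Design objective, constraint handling, search equivalence, prioritization."""

import numpy as np
import pytest

from tisdesign.design import (DesignObjectiveSpec, ScreeningRecord,
                              SelectionError, prioritize, score_objective,
                              search_designs, select_representative_structures)
from tisdesign.paths import WeightedFrames
from tisdesign.systems import make_toy_design_space


def make_spec(space, r_confs=(0, 1, 2), nr_confs=(3, 4, 5)):
    return DesignObjectiveSpec(
        reactive_structures=list(r_confs),
        nonreactive_structures=list(nr_confs),
        energy_model=space.energy_model,
        wt_sequence=space.wt_sequence)


class TestObjective:
    def test_wt_score_exactly_zero(self, toy_space):
        res = score_objective(toy_space.wt_sequence, make_spec(toy_space))
        assert res.score == 0.0
        assert res.stability_ok

    def test_planted_arithmetic(self):
        """A mutant lowering each reactive structure by 1 kcal/mol with NR
        unchanged scores -3 and passes stability."""
        energies = {}

        def em(seq, conf):
            base = 10.0
            if seq == (1,) and conf in (0, 1, 2):
                return base - 1.0
            return base

        spec = DesignObjectiveSpec(reactive_structures=[0, 1, 2],
                                   nonreactive_structures=[3, 4, 5],
                                   energy_model=em, wt_sequence=(0,))
        res = score_objective((1,), spec)
        assert res.score == pytest.approx(-3.0)
        assert res.stability_ok

    def test_stability_sum_vs_per_structure(self):
        """A +6 rise concentrated on one reactive structure violates both
        readings; spread as +2 each it violates only the sum bound at 5."""
        def em_concentrated(seq, conf):
            return 6.0 if (seq == (1,) and conf == 0) else 0.0

        spec = DesignObjectiveSpec(reactive_structures=[0, 1, 2],
                                   nonreactive_structures=[3],
                                   energy_model=em_concentrated,
                                   wt_sequence=(0,))
        assert not score_objective((1,), spec).stability_ok
        assert not score_objective((1,), spec,
                                   stability_per_structure=True).stability_ok

        def em_spread(seq, conf):
            return 2.0 if (seq == (1,) and conf in (0, 1, 2)) else 0.0

        spec2 = DesignObjectiveSpec(reactive_structures=[0, 1, 2],
                                    nonreactive_structures=[3],
                                    energy_model=em_spread, wt_sequence=(0,))
        assert not score_objective((1,), spec2).stability_ok          # sum +6
        assert score_objective((1,), spec2,
                               stability_per_structure=True).stability_ok

    def test_objective_invariant_to_constant_shift(self, toy_space):
        spec = make_spec(toy_space)
        shifted = DesignObjectiveSpec(
            reactive_structures=spec.reactive_structures,
            nonreactive_structures=spec.nonreactive_structures,
            energy_model=lambda s, c: spec.energy_model(s, c) + 100.0,
            wt_sequence=spec.wt_sequence)
        for seq in [(1, 0, 0), (2, 3, 1)]:
            assert (score_objective(seq, spec).score
                    == pytest.approx(score_objective(seq, shifted).score))

    def test_lowering_reactive_energy_never_worsens_score(self, toy_space):
        spec = make_spec(toy_space)
        seq = (1, 2, 0)
        base = score_objective(seq, spec).score

        def em_better(s, c):
            e = spec.energy_model(s, c)
            if tuple(s) == seq and c in spec.reactive_structures:
                e -= 0.7
            return e

        better = DesignObjectiveSpec(spec.reactive_structures,
                                     spec.nonreactive_structures,
                                     em_better, spec.wt_sequence)
        assert score_objective(seq, better).score <= base


class TestSearch:
    def test_window_zero_returns_only_optima(self, toy_space):
        spec = make_spec(toy_space)
        res = search_designs(toy_space, spec, window=0.0)
        assert len(res) >= 1
        assert all(r.score == res[0].score for r in res)

    def test_single_site_planted_best(self):
        space = make_toy_design_space(n_sites=1, alphabet_size=2,
                                      effect_table_seed=3)
        spec = make_spec(space, r_confs=(0,), nr_confs=(1,))
        res = search_designs(space, spec, window=100.0, stability=1e6)
        brute = sorted(space.sequences(), key=lambda s: spec.f(s) - spec.f((0,)))
        assert res[0].sequence == brute[0]

    @pytest.mark.parametrize("n_sites,alphabet", [(3, 4), (4, 3), (5, 4)])
    def test_branch_and_bound_matches_exhaustive(self, n_sites, alphabet):
        space = make_toy_design_space(n_sites=n_sites, alphabet_size=alphabet,
                                      effect_table_seed=n_sites)
        spec = make_spec(space)
        ex = search_designs(space, spec, mode="exhaustive")
        bb = search_designs(space, spec, mode="branch_and_bound")
        assert [r.sequence for r in ex] == [r.sequence for r in bb]
        assert np.allclose([r.score for r in ex], [r.score for r in bb],
                           atol=1e-9)

    def test_window_and_stability_enforced(self):
        space = make_toy_design_space(n_sites=2, alphabet_size=3,
                                      effect_table_seed=11)
        spec = make_spec(space)
        res = search_designs(space, spec, window=2.0, stability=1.0)
        f_min = res[0].score if res else 0.0
        for r in res:
            assert r.score <= f_min + 2.0 + 1e-9
            assert r.stability_ok
        # compare against direct filtering
        all_res = [score_objective(s, spec, stability_bound=1.0)
                   for s in space.sequences()]
        feasible = [r for r in all_res if r.stability_ok]
        best = min(r.score for r in feasible)
        expected = sorted([r.sequence for r in feasible
                           if r.score <= best + 2.0])
        assert sorted(r.sequence for r in res) == expected

    def test_ranked_ascending(self, toy_space):
        res = search_designs(toy_space, make_spec(toy_space), window=50.0)
        scores = [r.score for r in res]
        assert scores == sorted(scores)
        assert [r.rank for r in res] == list(range(1, len(res) + 1))


class TestPrioritize:
    def _rec(self, seq, obj, lr, nn, dg):
        return ScreeningRecord(sequence=seq, objective_score=obj,
                               lr_fraction_normalized=lr,
                               nn_fraction_normalized=nn,
                               screening_barrier=dg)

    REF = ScreeningRecord(sequence=(0,), objective_score=0.0,
                          screening_barrier=5.0)

    def test_all_three_tier1(self):
        recs = prioritize([self._rec((1,), -2.0, 1.5, 1.4, 4.5)], self.REF)
        assert recs[0].priority_tier == 1

    def test_none_tier3(self):
        recs = prioritize([self._rec((1,), 2.0, 0.8, 0.9, 6.0)], self.REF)
        assert recs[0].priority_tier == 3

    def test_two_of_three_tier2(self):
        recs = prioritize([self._rec((1,), -2.0, 1.5, 1.4, 6.0)], self.REF)
        assert recs[0].priority_tier == 2

    def test_equal_tier_sorted_by_score(self):
        a = self._rec((1,), -1.0, 1.5, 1.4, 4.5)
        b = self._rec((2,), -3.0, 1.5, 1.4, 4.5)
        recs = prioritize([a, b], self.REF)
        assert [r.sequence for r in recs] == [(2,), (1,)]


class TestStructureSelection:
    def _frames_and_models(self):
        """Frames whose single feature separates perfectly; LR/NN trained on
        matching synthetic data so confidence is monotone in the feature."""
        from tests.test_classify import make_synthetic_dataset
        from tisdesign.classify import train_lr, train_nn
        from tisdesign.geometry import FeatureDef, FeatureSchema

        ds = make_synthetic_dataset(n_per_class=50, n_features=1,
                                    informative=(0,), separation=4.0, seed=2)
        lr = train_lr(ds, seed=0)
        nn = train_nn(ds, seed=0)
        schema = FeatureSchema([FeatureDef("f0", "distance", (0, 1))])
        # positions: atom 1 at distance f0 from atom 0
        dists = np.array([9.0, 8.0, 7.0, 1.0, 0.9, 0.8, 0.7, 0.6])
        positions = np.zeros((8, 6))
        positions[:, 3] = dists
        labels = np.array(["R"] * 3 + ["NR"] * 5)
        frames = WeightedFrames(positions=positions, weights=np.ones(8),
                                times=np.zeros(8), path_ids=np.arange(8),
                                labels=labels)
        return frames, lr, nn, schema

    def test_extreme_frames_selected(self):
        frames, lr, nn, schema = self._frames_and_models()
        react, nonreact = select_representative_structures(frames, lr, nn,
                                                           schema,
                                                           n_per_class=3)
        assert react.shape == (3, 6)
        # the reactive picks are exactly the truly-R frames (largest f0)
        assert sorted(react[:, 3].tolist()) == [7.0, 8.0, 9.0]
        assert all(v <= 1.0 for v in nonreact[:, 3])

    def test_too_few_frames_errors(self):
        frames, lr, nn, schema = self._frames_and_models()
        with pytest.raises(SelectionError):
            select_representative_structures(frames, lr, nn, schema,
                                             n_per_class=4)
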