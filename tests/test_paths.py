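"""Path sampling: endpoint rules, shooting moves, ensembles, alignment."""

import numpy as np
import pytest

from tisdesign.dynamics import (LangevinParams, OutsideBand, ParticleState,
                                draw_maxwell_boltzmann)
from tisdesign.paths import (AlignmentError, Path, SeedFailureError,
                             ShootParams, align_time_zero, classify_endpoint,
                             generate_seed_path, sample_interface_ensemble,
                             sample_pathway_ensembles, sample_window_frames,
                             shooting_move)


class TestClassifyEndpoint:
    @pytest.mark.parametrize("lam,expected", [
        (-0.9, "A"), (0.0, "neither"), (0.9, "B"),
        (-0.8, "neither"), (0.8, "neither"),      # strict boundaries
    ])
    def test_default_thresholds(self, lam, expected):
        assert classify_endpoint(lam) == expected

    def test_configurable_thresholds(self):
        assert classify_endpoint(-0.55, lambda_a=-0.5, lambda_b=0.5) == "A"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_endpoint(float("nan"))


def _make_path(lambdas, times=None, positions=None, mult=1):
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(lambdas)
    if times is None:
        times = np.arange(n, dtype=float)
    if positions is None:
        positions = lambdas[:, None]
    ep = (classify_endpoint(lambdas[0]), classify_endpoint(lambdas[-1]))
    return Path(times=np.asarray(times, dtype=float), lambdas=lambdas,
                positions=np.asarray(positions, dtype=float),
                velocities=np.zeros_like(positions, dtype=float),
                endpoints=ep, multiplicity=mult)


class TestSeedGeneration:
    def test_seed_from_barrier_top(self, double_well, params, rng):
        states = np.zeros((4, 2))
        path = generate_seed_path(double_well, states, params, rng=rng)
        assert path.endpoints == ("A", "B")
        assert classify_endpoint(path.lambdas[0]) == "A"
        assert classify_endpoint(path.lambdas[-1]) == "B"

    def test_states_deep_in_A_fail(self, double_well, params, rng):
        """Shots from deep inside the reactant well reconstruct (A, A) paths
        only; seed search exhausts its attempts."""
        states = np.tile([-1.0, 0.0], (2, 1))
        with pytest.raises(SeedFailureError) as exc:
            generate_seed_path(double_well, states, params, max_attempts=5,
                               rng=rng)
        assert exc.value.attempts == 5


class TestShootingMove:
    def test_identity_case_deterministic(self, double_well):
        """sigma_p = 0 with frictionless (deterministic, time-reversible)
        dynamics regenerates the same path, which is accepted."""
        params = LangevinParams(friction=0.0, seed=4)
        rng = np.random.default_rng(4)
        state = ParticleState(np.array([0.0, 0.0]),
                              draw_maxwell_boltzmann(double_well, rng))
        from tisdesign.dynamics import propagate_two_sided
        shoot = ShootParams(sigma_p=0.0, ke_redraw=False)
        raw = propagate_two_sided(double_well, state, shoot.band, 20000,
                                  params, rng)
        assert raw["committed"]
        current = _make_path(raw["lambdas"], raw["times"], raw["positions"])
        current.velocities = raw["velocities"]
        cand, accepted = shooting_move(current, double_well, shoot, params,
                                       rng, condition=lambda p: True)
        assert accepted
        assert len(cand) == len(current)
        assert np.allclose(cand.lambdas, current.lambdas, atol=1e-8)

    def test_rejection_increments_multiplicity(self, double_well, params, rng):
        raw_path = _make_path([-0.85, 0.0, -0.85])
        raw_path.velocities = np.zeros((3, 1))
        # impossible condition: every proposal is rejected
        path2 = _make_path(np.array([-0.85, -0.5, -0.85]))
        path2.positions = np.tile([[-0.9, 0.0]], (3, 1))
        path2.velocities = np.zeros((3, 2))
        out, accepted = shooting_move(path2, double_well, ShootParams(),
                                      params, rng, condition=lambda p: False)
        assert not accepted
        assert out is path2
        assert out.multiplicity == 2


@pytest.fixture(scope="module")
def ensemble(double_well):
    params = LangevinParams(seed=21)
    rng = np.random.default_rng(21)
    seed = generate_seed_path(double_well, np.zeros((4, 2)), params, rng=rng)
    return sample_interface_ensemble(double_well, seed, lambda_i=-0.4,
                                     n_moves=300, n_equil=100,
                                     params=params, rng=rng)


class TestInterfaceEnsemble:
    def test_multiplicities_sum_to_counted_moves(self, ensemble):
        assert ensemble.total_multiplicity == 200

    def test_all_paths_satisfy_condition(self, ensemble):
        for p in ensemble.entries:
            assert p.endpoints[0] == "A"
            assert p.lambda_max >= -0.4

    def test_acceptance_rate_in_unit_interval(self, ensemble):
        assert 0.0 < ensemble.acceptance_rate <= 1.0
        assert ensemble.n_unique <= ensemble.n_accepted + 1

    def test_single_counted_move(self, double_well):
        params = LangevinParams(seed=3)
        rng = np.random.default_rng(3)
        seed = generate_seed_path(double_well, np.zeros((4, 2)), params,
                                  rng=rng)
        ens = sample_interface_ensemble(double_well, seed, lambda_i=-0.6,
                                        n_moves=6, n_equil=5, params=params,
                                        rng=rng)
        assert ens.total_multiplicity == 1

    def test_seed_violating_condition_rejected(self, double_well, params, rng):
        bad = _make_path([-0.85, -0.7, -0.85])
        bad.positions = np.column_stack([bad.lambdas, np.zeros(3)])
        bad.velocities = np.zeros((3, 2))
        with pytest.raises(ValueError):
            sample_interface_ensemble(double_well, bad, lambda_i=-0.2,
                                      n_moves=10, n_equil=2, params=params,
                                      rng=rng)
        with pytest.raises(ValueError):
            sample_interface_ensemble(double_well, bad, lambda_i=-0.75,
                                      n_moves=10, n_equil=10, params=params,
                                      rng=rng)


class TestPathwayEnsembles:
    def test_nr_default_threshold_and_conditions(self, double_well):
        params = LangevinParams(seed=33)
        rng = np.random.default_rng(33)
        seed = generate_seed_path(double_well, np.zeros((4, 2)), params,
                                  rng=rng, path_type="NR")
        enss = sample_pathway_ensembles(double_well, [seed], "NR",
                                        n_moves=120, n_equil=40,
                                        params=params, rng=rng)
        assert len(enss) == 1
        assert enss[0].condition["nr_threshold"] == -0.4
        for p in enss[0].entries:
            assert p.endpoints == ("A", "A")
            assert p.lambda_max >= -0.4

    def test_reactive_seed_rejected_for_nr(self, double_well, params, rng):
        r_path = _make_path([-0.85, 0.0, 0.85])
        with pytest.raises(ValueError):
            sample_pathway_ensembles(double_well, [r_path], "NR",
                                     n_moves=10, n_equil=2, params=params,
                                     rng=rng)


class TestAlignment:
    def _system(self, double_well):
        return double_well

    def test_last_trough_selected(self, double_well):
        """Synthetic reactive path: breaking-distance troughs at indices 5
        and 9 before rupture -> t = 0 assigned to the later one."""
        lam = np.full(20, -0.5)
        lam[0] = -0.85
        lam[5] = -0.7
        lam[9] = -0.72
        lam[12:] = np.linspace(0.0, 0.9, 8)
        lam[-1] = 0.85
        path = _make_path(lam)
        aligned = align_time_zero(path, double_well)
        assert aligned.times[9] == 0.0

    def test_alignment_idempotent(self, double_well):
        lam = np.array([-0.85, -0.5, -0.7, -0.3, 0.2, 0.85])
        a1 = align_time_zero(_make_path(lam), double_well)
        a2 = align_time_zero(a1, double_well)
        assert np.array_equal(a1.times, a2.times)

    def test_monotone_series_errors(self, double_well):
        lam = np.linspace(-0.85, 0.85, 10)
        with pytest.raises(AlignmentError):
            align_time_zero(_make_path(lam), double_well)

    def test_nr_anchor_precedes_lambda_max(self, double_well):
        lam = np.array([-0.85, -0.6, -0.75, -0.5, -0.35, -0.6, -0.85])
        aligned = align_time_zero(_make_path(lam), double_well)
        # trough at index 2 is the last minimum before the peak at index 4
        assert aligned.times[2] == 0.0


class TestWindowSampling:
    def _ensemble(self):
        from tisdesign.paths import PathEnsemble
        ens = PathEnsemble(condition={"kind": "pathway", "type": "R"})
        p1 = _make_path(np.linspace(-0.85, 0.85, 11),
                        times=np.arange(-5.0, 6.0), mult=4)
        p2 = _make_path(np.linspace(-0.85, 0.85, 11),
                        times=np.arange(-15.0, -4.0), mult=2)
        ens.entries = [p1, p2]
        return ens

    def test_weights_carry_multiplicity(self, rng):
        wf = sample_window_frames([self._ensemble()], (-5.0, 1.0), rng=rng)
        assert len(wf) == 2
        assert sorted(wf.weights.tolist()) == [2.0, 4.0]

    def test_half_open_window(self, rng):
        # [-6, -5): p2's t = -6 qualifies, its t = -5 and p1's start at -5
        # are excluded by the half-open upper edge
        wf = sample_window_frames([self._ensemble()], (-6.0, -5.0), rng=rng)
        assert len(wf) == 1
        assert wf.weights[0] == 2.0
        assert wf.times[0] == -6.0

    def test_at_most_one_frame_per_path(self, rng):
        wf = sample_window_frames([self._ensemble()], (-20.0, 20.0),
                                  frames_per_path=1, rng=rng)
        assert len(wf) == 2
        assert len(np.unique(wf.path_ids)) == 2
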