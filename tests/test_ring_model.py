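"""Ring-model units: initial condition, right-hand sides, latch, Euler
integration, the anterior-half cut, and streak-arc detection."""

import numpy as np
import pytest

from mzring import (
    ModelParams,
    RingState,
    ScenarioConfig,
    SimulationRecord,
    apply_anterior_half_cut,
    dB_dt,
    dC_dt,
    dV_dt,
    detect_streak_segments,
    euler_step,
    init_intact_state,
    simulate,
    transmission_speed_bound,
    update_latch,
)


def uniform_state(n, B=1.0, C=0.0, V=0.0, A=0, topology="periodic"):
    return RingState(t=0.0, B=np.full(n, float(B)), C=np.full(n, float(C)),
                     V=np.full(n, float(V)), A=np.full(n, A, dtype=np.int8),
                     topology=topology)


class TestParams:
    def test_defaults_are_valid(self):
        p = ModelParams()
        assert p.n_cells == 100 and p.dt == pytest.approx(1e-4)
        assert p.beta_V > p.beta_C

    @pytest.mark.parametrize("kwargs", [
        {"k_B": -1.0},
        {"beta_C": 0.5, "beta_V": 0.5},
        {"dt": 0.0},
        {"D": 4800.0, "dt": 2e-4},     # violates dt <= dx^2 / (2 D)
        {"production_mode": "logistic"},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


class TestInitialCondition:
    def test_gradient_anchors_and_symmetry(self):
        state = init_intact_state(ModelParams())
        assert state.B[0] == pytest.approx(1.1)
        assert state.B[99] == pytest.approx(1.1)
        assert state.B[49] == pytest.approx(2.2)
        assert state.B[50] == pytest.approx(2.2)
        # linear and non-decreasing towards the anterior pole
        assert (np.diff(state.B[:50]) >= 0).all()
        # mirror-symmetric about the posterior pole
        assert state.B == pytest.approx(state.B[::-1])
        assert not state.C.any() and not state.V.any() and not state.A.any()


class TestRates:
    def test_bmp4_decay_only_below_activity_threshold(self):
        p = ModelParams()
        s = uniform_state(4, B=1.0, C=0.0, V=0.0)
        assert dB_dt(s, p) == pytest.approx(np.full(4, -p.gamma0))

    def test_bmp4_production_on_at_threshold_boundary(self):
        p = ModelParams()
        s = uniform_state(4, B=0.0, C=p.alpha)
        assert dB_dt(s, p) == pytest.approx(np.full(4, p.k_B))

    def test_bmp4_rate_hand_computed(self):
        # k_B=1, alpha=0.1, C=0.2, gamma0=0.5, gamma_C=1, gamma_V=2,
        # V=0.25, B=2  ->  1 - (0.5 + 0.2 + 0.5) * 2 = -1.4
        p = ModelParams(k_B=1.0, alpha=0.1, gamma0=0.5, gamma_C=1.0,
                        gamma_V=2.0, D=100.0)
        s = uniform_state(3, B=2.0, C=0.2, V=0.25)
        assert dB_dt(s, p) == pytest.approx(np.full(3, -1.4))

    def test_calcium_uniform_decays_at_lambda(self):
        p = ModelParams()
        s = uniform_state(6, C=2.0)
        assert dC_dt(s, p) == pytest.approx(np.full(6, -p.lambda_ * 2.0))

    def test_transmission_conserves_on_ring(self):
        p = ModelParams()
        rng = np.random.default_rng(0)
        s = uniform_state(100)
        s.C = rng.uniform(0.0, 5.0, 100)
        transmission = dC_dt(s, p) - p.k_C * s.A + p.lambda_ * s.C
        assert abs(transmission.sum()) < 1e-10 * np.abs(transmission).sum()

    def test_single_streak_cell_sources_only_itself(self):
        p = ModelParams(D=0.0)
        s = uniform_state(5)
        s.A[2] = 1
        rate = dC_dt(s, p)
        assert rate[2] == pytest.approx(p.k_C)
        assert rate[[0, 1, 3, 4]] == pytest.approx(np.zeros(4))

    def test_cvg1_decays_above_threshold(self):
        p = ModelParams()
        s = uniform_state(3, B=p.beta_V + 0.5, V=1.0)
        assert dV_dt(s, p) == pytest.approx(np.full(3, -p.mu))

    def test_cvg1_production_on_at_boundary(self):
        p = ModelParams()
        s = uniform_state(3, B=p.beta_V, V=0.0)
        assert dV_dt(s, p) == pytest.approx(np.full(3, p.k_V))

    def test_hill_mode_cvg1_production_at_twice_threshold(self):
        p = ModelParams(production_mode="hill")
        s = uniform_state(3, B=2.0 * p.beta_V, V=0.0)
        # beta^4 / (beta^4 + 16 beta^4) = 1/17
        assert dV_dt(s, p) == pytest.approx(np.full(3, p.k_V / 17.0))


class TestLatch:
    def test_commits_at_threshold_boundary(self):
        p = ModelParams()
        s = uniform_state(3, B=p.beta_C)
        update_latch(s, p)
        assert s.A.tolist() == [1, 1, 1]

    def test_never_resets(self):
        p = ModelParams()
        s = uniform_state(3, B=p.beta_C - 0.1)
        update_latch(s, p)
        s.B[:] = p.beta_C + 1.0
        update_latch(s, p)
        assert s.A.tolist() == [1, 1, 1]

    def test_stays_zero_above_threshold(self):
        p = ModelParams()
        s = uniform_state(3, B=p.beta_C + 0.01)
        update_latch(s, p)
        assert not s.A.any()


class TestEuler:
    def test_fixed_point_only_advances_time(self):
        p = ModelParams(k_B=0.0, k_C=0.0, k_V=0.0)
        s = uniform_state(5, B=0.0, C=0.0, V=0.0)
        out = euler_step(s, p)
        assert out.t == pytest.approx(p.dt)
        assert not out.B.any() and not out.C.any() and not out.V.any()

    def test_single_cell_calcium_matches_closed_form(self):
        # dC/dt = k_C - lambda C with C(0)=0: C(t) = k_C/lambda (1 - e^-lt)
        p = ModelParams(D=0.0, dt=1e-3)
        s = uniform_state(3, B=10.0)
        s.A[:] = 1
        n_steps = 500
        for _ in range(n_steps):
            euler_step(s, p)
        t = n_steps * p.dt
        exact = p.k_C / p.lambda_ * (1.0 - np.exp(-p.lambda_ * t))
        assert s.C == pytest.approx(np.full(3, exact), rel=5e-3)

    def test_first_order_convergence(self):
        # smooth (Hill) variant so threshold crossings do not mask the
        # truncation order; error vs a dt/20 reference halves with dt
        def run(dt, n_cells=12, T=0.1):
            p = ModelParams(production_mode="hill", D=40.0, dt=dt,
                            n_cells=n_cells)
            s = init_intact_state(p)
            s.C[:] = np.linspace(0.5, 1.5, n_cells)
            s.V[:] = 0.2
            for _ in range(int(round(T / dt))):
                euler_step(s, p)
            return np.concatenate([s.B, s.C, s.V])

        ref = run(1e-5)
        e1 = np.abs(run(2e-3) - ref).max()
        e2 = np.abs(run(1e-3) - ref).max()
        order = np.log2(e1 / e2)
        assert 0.8 <= order <= 1.2

    def test_nonfinite_aborts(self):
        p = ModelParams()
        s = uniform_state(3, B=np.nan)
        with pytest.raises(FloatingPointError):
            euler_step(s, p)


class TestCut:
    def test_symmetric_cut_has_equal_edge_gradient(self):
        p = ModelParams()
        s = init_intact_state(p)
        cfg = ScenarioConfig(scenario="intact", obliquity_offset=0)
        cut = apply_anterior_half_cut(s, cfg)
        assert cut.topology == "segment"
        assert cut.cells[0] == 10 and cut.cells[-1] == 89
        assert cut.B[0] == pytest.approx(cut.B[-1])

    def test_oblique_cut_biases_right_edge(self):
        p = ModelParams()
        s = init_intact_state(p)
        cfg = ScenarioConfig(scenario="anterior_half", obliquity_offset=2)
        cut = apply_anterior_half_cut(s, cfg)
        assert cut.cells[0] == 8 and cut.cells[-1] == 87
        assert cut.B[0] < cut.B[-1]

    def test_cut_must_cover_streak_cells(self):
        p = ModelParams()
        s = init_intact_state(p)
        s.A[30] = 1    # streak cell outside the default removal arc
        cfg = ScenarioConfig(scenario="anterior_half", obliquity_offset=2)
        with pytest.raises(ValueError, match="streak"):
            apply_anterior_half_cut(s, cfg)

    def test_cut_defines_time_zero(self):
        s = init_intact_state(ModelParams())
        s.t = -1.5
        cut = apply_anterior_half_cut(
            s, ScenarioConfig(scenario="anterior_half", obliquity_offset=1))
        assert cut.t == 0.0

    def test_sourceless_segment_calcium_decays_at_lambda(self):
        # no-flux edges conserve the transmission term, so total activity
        # follows dC/dt = -lambda C exactly
        p = ModelParams(dt=1e-4)
        s = uniform_state(20, B=10.0, topology="segment")
        s.C = np.linspace(0.5, 2.0, 20)
        total0 = s.C.sum()
        n_steps = 2000
        for _ in range(n_steps):
            euler_step(s, p)
        expect = total0 * np.exp(-p.lambda_ * n_steps * p.dt)
        assert s.C.sum() == pytest.approx(expect, rel=1e-3)


class TestStreakSegments:
    @staticmethod
    def record_with_A(A, topology="periodic"):
        n = len(A)
        s = uniform_state(n, B=1.0, topology=topology)
        s.A = np.array(A, dtype=np.int8)
        rec = SimulationRecord(snapshots=[s])
        return rec

    def test_empty(self):
        assert detect_streak_segments(self.record_with_A([0] * 10)) == []

    def test_wraps_across_index_seam(self):
        A = [0] * 100
        for i in (98, 99, 0, 1):
            A[i] = 1
        segs = detect_streak_segments(self.record_with_A(A))
        assert len(segs) == 1 and segs[0]["span"] == 4
        assert sorted(segs[0]["cells"]) == [0, 1, 98, 99]

    def test_two_runs(self):
        A = [0] * 20
        for i in (3, 4, 5, 10, 11):
            A[i] = 1
        segs = detect_streak_segments(self.record_with_A(A))
        assert sorted(s["span"] for s in segs) == [2, 3]

    def test_matches_brute_force_oracle(self):
        def oracle(A):
            """Circular run lengths: rotate to start at a zero, count runs."""
            n = len(A)
            if all(A):
                return [n]
            if not any(A):
                return []
            z = A.index(0)
            rotated = A[z:] + A[:z]
            spans, cur = [], 0
            for v in rotated + [0]:
                if v:
                    cur += 1
                elif cur:
                    spans.append(cur)
                    cur = 0
            return sorted(spans)

        rng = np.random.default_rng(42)
        for _ in range(50):
            A = (rng.random(rng.integers(4, 30)) < 0.4).astype(int).tolist()
            segs = detect_streak_segments(self.record_with_A(A))
            assert sorted(s["span"] for s in segs) == oracle(A)


class TestScenarios:
    def test_intact_single_posterior_arc(self, intact_records):
        for mode, rec in intact_records.items():
            segs = rec.streak_segments
            assert len(segs) == 1, mode
            d = [min(c + 0.5, 100 - c - 0.5) for c in segs[0]["cells"]]
            assert max(d) <= 3.5, mode   # hugging the posterior pole

    def test_intact_run_is_mirror_symmetric(self, intact_records):
        rec = intact_records["heaviside"]
        for snap in rec.snapshots:
            for arr in (snap.B, snap.C, snap.V):
                assert np.abs(arr - arr[::-1]).max() < 1e-8

    def test_latch_monotone_and_state_nonnegative(self, intact_records,
                                                  half_records):
        for rec in [intact_records["heaviside"], half_records[("hill", 2)]]:
            prev = None
            for snap in rec.snapshots:
                assert (snap.B >= 0).all() and (snap.C >= 0).all() \
                    and (snap.V >= 0).all()
                if prev is not None and prev.size == snap.A.size:
                    assert (snap.A >= prev).all()
                prev = snap.A

    def test_determinism(self):
        p = ModelParams(D=50.0, dt=1e-3)
        cfg = ScenarioConfig(scenario="intact", pre_cut_duration=0.5)
        a = simulate(cfg, p)
        b = simulate(cfg, p)
        assert np.array_equal(a.final.B, b.final.B)
        assert a.events == b.events

    def test_no_calcium_source_decouples(self):
        p = ModelParams(k_C=0.0)
        cfg = ScenarioConfig(scenario="anterior_half", pre_cut_duration=0.5,
                             post_cut_duration=0.5, obliquity_offset=2)
        rec = simulate(cfg, p)
        assert not rec.final.C.any()


def test_transmission_speed_bound_matches_printed_arithmetic():
    out = transmission_speed_bound(diameter_cells=240.0, window_h=5.0)
    assert out["half_circumference_cells"] == pytest.approx(
        np.pi * 120.0)
    assert out["half_circumference_rounded"] == 380.0
    assert round(out["min_speed_cells_per_min"], 2) == 1.27
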