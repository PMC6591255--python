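import numpy as np
import pytest

import thalcort as tc


DT = 0.001


class TestDominantFrequency:
    def test_pure_sine(self):
        t = np.arange(0, 20, DT)
        y = np.sin(2 * np.pi * 3.0 * t)
        assert tc.dominant_frequency(y, DT) == pytest.approx(3.0, abs=0.06)

    def test_constant_series_is_steady(self):
        assert tc.dominant_frequency(np.full(8000, 0.3), DT) == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            tc.dominant_frequency(np.sin(np.arange(0, 2, DT)), DT)

    def test_spike_wave_discharge_near_3hz(self, swd_window):
        fd = tc.dominant_frequency(swd_window, DT)
        assert fd == pytest.approx(3.0, abs=0.3)


class TestFundamentalFrequency:
    def test_matches_sine_frequency(self):
        t = np.arange(0, 10, DT)
        assert tc.fundamental_frequency(np.sin(2 * np.pi * 2.0 * t), DT) == pytest.approx(
            2.0, rel=0.02
        )

    def test_recovers_cycle_rate_despite_dominant_harmonic(self):
        # spiky waveform whose FFT peak is the 5th harmonic
        t = np.arange(0, 10, DT)
        y = 0.5 * np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 5.0 * t)
        assert tc.fundamental_frequency(y, DT) == pytest.approx(1.0, rel=0.02)
        assert tc.dominant_frequency(y, DT) == pytest.approx(5.0, abs=0.2)


class TestSignalExtrema:
    def test_constant(self):
        np.testing.assert_allclose(tc.signal_extrema(np.full(5000, 1.7)), [1.7])

    def test_sine_levels(self):
        t = np.arange(0, 5, DT)
        ext = tc.signal_extrema(2.0 * np.sin(2 * np.pi * 2 * t))
        assert ext.min() == pytest.approx(-2.0, abs=1e-4)
        assert ext.max() == pytest.approx(2.0, abs=1e-4)

    def test_spike_wave_has_multiple_levels(self, swd_window):
        ext = tc.signal_extrema(swd_window)
        # spike max, wave shoulder and trough structure: >= 3 distinct levels
        assert len(np.unique(np.round(ext, 2))) >= 3


class TestCountSpikesPerCycle:
    def test_sine_has_one_maximum(self):
        t = np.arange(0, 10, DT)
        y = np.sin(2 * np.pi * 1.0 * t)
        assert tc.count_spikes_per_cycle(y, DT, 1.0, narrow_width_frac=0.6) == 1

    def test_harmonic_mixture_counts_fast_peaks(self):
        t = np.arange(0, 10, DT)
        y = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 5.0 * t)
        # wide ceiling: the crest maximum of this smooth mixture is broad,
        # unlike the sharp spikes of the model's discharges
        assert tc.count_spikes_per_cycle(
            y, DT, 1.0, prominence=0.01, narrow_width_frac=0.6
        ) == 5

    def test_needs_three_cycles(self):
        t = np.arange(0, 2, DT)
        with pytest.raises(ValueError):
            tc.count_spikes_per_cycle(np.sin(2 * np.pi * t), DT, 1.0)

    def test_requires_positive_fundamental(self):
        with pytest.raises(ValueError):
            tc.count_spikes_per_cycle(np.zeros(5000), DT, 0.0)


class TestClassifyState:
    @pytest.mark.parametrize(
        "c_tr, c_te, expected",
        [(0.15, 1.0, "TO"), (0.15, 2.3, "LS"), (0.15, 3.0, "HS")],
    )
    def test_steady_and_tonic_anchors(self, params, c_tr, c_te, expected):
        traj = tc.simulate(params.replace(c_tr=c_tr, c_te=c_te), np.zeros(4), 16.0)
        label = tc.classify_state(traj, tc.ClassificationConfig(transient_discard=8.0))
        assert label.kind == expected

    def test_multi_spike_wave_anchor(self, params):
        traj = tc.simulate(params.replace(c_tr=0.15, c_te=2.65), np.zeros(4), 24.0)
        label = tc.classify_state(traj, tc.ClassificationConfig(transient_discard=14.0))
        assert label.kind == "SWD" and label.m == 2

    def test_deterministic(self, swd_trajectory):
        cfg = tc.ClassificationConfig()
        assert tc.classify_state(swd_trajectory, cfg) == tc.classify_state(
            swd_trajectory, cfg
        )

    def test_dying_oscillation_is_unresolved(self):
        t = np.arange(0, 12, DT)
        y = np.exp(-0.5 * t) * np.sin(2 * np.pi * 3 * t)
        cfg = tc.ClassificationConfig(transient_discard=0.001)
        assert tc.classify_series(y, DT, cfg).kind == "UNRESOLVED"

    def test_label_invariants(self):
        with pytest.raises(ValueError):
            tc.StateLabel(kind="LS", m=2)
        with pytest.raises(ValueError):
            tc.StateLabel(kind="SWD")
        assert str(tc.StateLabel(kind="SWD", m=3)) == "3-SWD"


class TestEquilibria:
    def test_decoupled_equilibrium_is_offset_vector(self):
        p = tc.ModelParameters(
            **{k: 0.0 for k in ("c_ee", "c_ei", "c_et", "c_ie", "c_te",
                                "c_tr", "c_re", "c_rt", "c_rr")}
        )
        eqs = tc.find_equilibria(p)
        assert len(eqs) == 1
        x, stable = eqs[0]
        np.testing.assert_allclose(x, [p.h_e, p.h_i, p.h_t, p.h_r], atol=1e-9)
        assert stable

    def test_inhibitory_line_identity(self, params, ls_equilibrium):
        # at equilibrium IN = h_i + c_ie f[PY] exactly
        expected = params.h_i + params.c_ie * tc.sigmoid_activation(
            ls_equilibrium[0], params.epsilon
        )
        assert ls_equilibrium[1] == pytest.approx(expected, abs=1e-10)

    def test_residual_tolerance(self, params, ls_equilibrium):
        assert np.linalg.norm(tc.model_rhs(ls_equilibrium, params)) < 1e-10

    def test_nonconvergence_raises(self, params):
        with pytest.raises((RuntimeError, ValueError)):
            tc.find_equilibrium(params, np.array([np.nan, 0, 0, 0]))


class TestContinuation:
    def test_decoupled_branch_is_constant(self):
        p = tc.ModelParameters(
            **{k: 0.0 for k in ("c_ee", "c_ei", "c_et", "c_ie", "c_te",
                                "c_tr", "c_re", "c_rt", "c_rr")}
        )
        br = tc.continue_equilibria(p, "c_te", (0.0, 1.0), step=0.1)
        # closed form: PY, IN, RE stay at their offsets; TC picks up the
        # axis parameter through c_te * f[h_e]
        f_he = tc.sigmoid_activation(p.h_e, p.epsilon)
        for v, x in zip(br.parameter_values, br.states):
            expected = np.array([p.h_e, p.h_i, p.h_t + v * f_he, p.h_r])
            np.testing.assert_allclose(x, expected, atol=1e-8)
        assert br.stable.all()

    def test_branch_points_are_equilibria(self, params):
        pp = params.replace(c_tr=0.15)
        br = tc.continue_equilibria(pp, "c_te", (2.2, 2.8), step=0.05)
        for v, x in zip(br.parameter_values[::5], br.states[::5]):
            res = tc.model_rhs(x, pp.replace(c_te=float(v)))
            assert np.linalg.norm(res) < 1e-8

    def test_stability_flip_matches_eigenvalues(self, params):
        pp = params.replace(c_tr=0.15)
        br = tc.continue_equilibria(pp, "c_te", (2.2, 2.8), step=0.02)
        flips = np.nonzero(np.diff(br.stable.astype(int)))[0]
        assert len(flips) >= 1
        for i in flips:
            re_lo = br.eigenvalues[i].real.max()
            re_hi = br.eigenvalues[i + 1].real.max()
            assert re_lo * re_hi < 0


class TestDetectHopf:
    @staticmethod
    def _normal_form_branch(omega=2.0, n=10):
        mus = np.linspace(-0.5, 0.5, n)   # even n: no grid point exactly at 0

        def eig_solver(mu, x_guess):
            return x_guess, np.array(
                [mu + 1j * omega, mu - 1j * omega, -1.0 + 0j, -2.0 + 0j]
            )

        branch = tc.EquilibriumBranch(
            axis="mu",
            parameter_values=mus,
            states=np.zeros((n, 4)),
            eigenvalues=np.array([eig_solver(m, None)[1] for m in mus]),
            stable=mus < 0,
        )
        return branch, eig_solver, omega

    def test_normal_form_crossing_location_and_frequency(self):
        branch, solver, omega = self._normal_form_branch()
        pts = tc.detect_hopf(branch, eig_solver=solver)
        hbs = [b for b in pts if b.kind == "HB"]
        assert len(hbs) == 1
        assert hbs[0].parameter_value == pytest.approx(0.0, abs=1e-4)
        assert hbs[0].frequency == pytest.approx(omega / (2 * np.pi), rel=1e-3)

    def test_uniformly_stable_branch_has_no_crossing(self):
        branch, solver, _ = self._normal_form_branch()
        shifted = tc.EquilibriumBranch(
            axis="mu",
            parameter_values=branch.parameter_values,
            states=branch.states,
            eigenvalues=branch.eigenvalues - 1.0,   # all real parts < 0
            stable=np.ones(len(branch.parameter_values), dtype=bool),
        )
        assert tc.detect_hopf(shifted, eig_solver=solver) == []

    def test_model_hopf_confirmed_by_eigenvalues(self, params):
        # the background equilibrium destabilises via a Hopf as the cortical
        # drive to TC grows at weak feedforward inhibition; each stability
        # flip of the branch has an HB at it, confirmed by a direct
        # eigenvalue evaluation on either side
        pp = params.replace(c_tr=0.15)
        br = tc.continue_equilibria(pp, "c_te", (2.2, 2.8), step=0.02)
        hbs = [b for b in tc.detect_hopf(br, params=pp) if b.kind == "HB"]
        assert len(hbs) >= 1
        flips = np.nonzero(np.diff(br.stable.astype(int)))[0]
        assert len(flips) >= 1
        for i in flips:
            near = min(hbs, key=lambda b: abs(b.parameter_value - br.parameter_values[i]))
            assert abs(near.parameter_value - br.parameter_values[i]) < 0.02
            lo = pp.replace(c_te=near.parameter_value - 2e-3)
            hi = pp.replace(c_te=near.parameter_value + 2e-3)
            x_lo = tc.find_equilibrium(lo, br.states[i])
            x_hi = tc.find_equilibrium(hi, br.states[i])
            mu_lo = max(np.linalg.eigvals(tc.jacobian(x_lo, lo)).real)
            mu_hi = max(np.linalg.eigvals(tc.jacobian(x_hi, hi)).real)
            assert mu_lo * mu_hi < 0
            assert near.frequency is not None and near.frequency > 0


class TestMultistability:
    def test_monostable_tonic_cell(self, params):
        pr = tc.multistability_probe(
            params.replace(c_tr=0.15, c_te=1.0), n_initials=12, seed=4, kick=False,
            duration=16.0, window=6.0,
        )
        assert len(pr) == 1
        assert pr.labels[0].kind == "TO"

    def test_monotone_discovery(self, params):
        pp = params.replace(c_tr=0.45, c_te=3.0)
        small = tc.multistability_probe(pp, n_initials=10, seed=9, kick=False)
        large = tc.multistability_probe(pp, n_initials=20, seed=9, kick=False)
        assert {str(l) for l in small.labels} <= {str(l) for l in large.labels}


class TestRegionMap:
    def test_single_cell_is_one_region(self, params):
        rm = tc.two_param_map(
            params, [0.15], [1.0], n_initials=3, seed=0, duration=16.0, window=5.0
        )
        assert rm.n_regions == 1

    def test_tonic_row_at_weak_cortical_drive(self, params):
        # weak cortical drive to TC: tonic oscillations everywhere (at large
        # c_tr a small-basin background state coexists)
        rm = tc.two_param_map(
            params, [0.2, 0.5, 0.8], [1.0], n_initials=3, seed=0,
            duration=16.0, window=5.0,
        )
        for i in range(3):
            kinds = {l.kind for l in rm.cell_labels[i][0]}
            assert "TO" in kinds

    def test_export_schema(self, params, tmp_path):
        rm = tc.two_param_map(
            params, [0.15], [1.0, 2.3], n_initials=2, seed=0,
            duration=16.0, window=5.0,
        )
        path = tmp_path / "regions.csv"
        rm.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "c_tr", "c_te", "labels", "dominant_frequency", "region_id"
        ]
        assert len(df) == 2


class TestOneParamScan:
    def test_empty_values(self, params):
        assert tc.one_param_scan(params, "c_te", []) == []

    def test_transition_sequence_along_cortical_drive(self, params):
        # increasing PY->TC drive at weak inhibition: TO -> LS -> SWD -> HS
        pts = tc.one_param_scan(
            params.replace(c_tr=0.15), "c_te", [1.0, 2.3, 2.55, 3.0],
            probe_initials=[np.zeros(4)], duration=24.0, window=8.0,
        )
        dominant = [
            {l.kind for l in pt.labels} for pt in pts
        ]
        assert "TO" in dominant[0]
        assert "LS" in dominant[1]
        assert "SWD" in dominant[2]
        assert "HS" in dominant[3]
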