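"""Generator behaviour: design enumeration, closed-form limits, determinism."""

import json

import numpy as np
import pytest

from pamflux.errors import ProtocolError, ValidationError
from pamflux.protocols import kautsky_protocol, light_curve_protocol
from pamflux.simulate import (
    GroupFactor,
    GroupTruth,
    SimulationParams,
    default_group_truth,
    kautsky_model_for,
    make_design,
    retr_response,
    fit_retr_response,
    simulate_kautsky,
    simulate_light_curve,
    simulate_ojip,
    simulate_study,
)


class TestDesign:
    def test_balanced_design_size(self):
        design = make_design(n_per_cell=5, seed=0)
        assert len(design) == 4 * 2 * 5
        assert len({pid for pid, _ in design}) == len(design)

    def test_unbalanced_map_respects_cell_sizes(self):
        sizes = {}
        n = 3
        for cyto in ("2x", "4x", "6x_29", "6x_35"):
            for pp in (10.0, 16.5):
                sizes[(cyto, pp)] = n
                n = 3 + (n - 2) % 9  # walk through 3..11
        design = make_design(sizes, seed=1)
        for (cyto, pp), want in sizes.items():
            got = sum(1 for _, g in design
                      if g.cytotype == cyto and g.photoperiod_h == pp)
            assert got == want and 3 <= got <= 11

    def test_zero_plants_rejected(self):
        with pytest.raises(ValidationError):
            make_design(n_per_cell=0, seed=0)

    def test_invalid_factor_levels_rejected(self):
        with pytest.raises(ValidationError):
            GroupFactor("3x", 10.0)
        with pytest.raises(ValidationError):
            GroupFactor("2x", 12.0)


class TestOjipSimulator:
    def test_saturates_at_model_asymptote(self, noisefree_params, group_2x):
        # FM = F0/(1-phi); with phi=0.8, f0=500 the asymptote is 2500
        tr = simulate_ojip(noisefree_params, group_2x)
        assert tr.fluorescence.max() == pytest.approx(2500.0, rel=2e-3)

    def test_forced_variable_fluorescence(self):
        params = SimulationParams(noise_cv=0.0)
        g = GroupFactor("4x", 10.0)
        tr = simulate_ojip(params, g, t_max_s=5.0)
        fm = tr.fluorescence.max()  # saturated asymptote
        assert (fm - params.f0_base) / fm == pytest.approx(
            params.truth_for(g).phi_max_true, rel=1e-3)

    def test_noise_free_transient_is_monotone(self, noisefree_params, group_2x):
        tr = simulate_ojip(noisefree_params, group_2x)
        assert np.all(np.diff(tr.fluorescence) >= 0)

    def test_seed_determinism(self, group_2x):
        params = SimulationParams(noise_cv=0.05)
        a = simulate_ojip(params, group_2x, seed=11, plant_id="p1")
        b = simulate_ojip(params, group_2x, seed=11, plant_id="p1")
        c = simulate_ojip(params, group_2x, seed=12, plant_id="p1")
        assert np.array_equal(a.fluorescence, b.fluorescence)
        assert not np.array_equal(a.fluorescence, c.fluorescence)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValidationError):
            GroupTruth(phi_max_true=1.0)

    def test_sampling_grid(self, noisefree_params, group_2x):
        tr = simulate_ojip(noisefree_params, group_2x)
        assert len(tr) >= 60
        assert tr.time_s[0] == pytest.approx(1e-5)
        assert tr.time_s[-1] == pytest.approx(2.0)


class TestKautskySimulator:
    def test_no_quenching_pulses_all_reach_fm(self):
        """npq_ss = 0 means every pulse reports the dark-adapted FM."""
        truth = GroupTruth(npq_ss=0.0, closed_frac_ss=0.0)
        g = GroupFactor("2x", 10.0)
        params = SimulationParams(groups={GroupFactor(c, p): truth
                                          for c in ("2x", "4x", "6x_29", "6x_35")
                                          for p in (10.0, 16.5)},
                                  noise_cv=0.0)
        tr = simulate_kautsky(params, g)
        fm = params.f0_base / (1 - truth.phi_max_true)
        pulse_vals = tr.fluorescence[tr.pulse_flag]
        assert np.allclose(pulse_vals, fm, rtol=1e-9)

    def test_fm_prime_at_steady_state_pulse(self):
        """Hand evaluation of the NPQ rise law: npq_ss=1, tau=10 s, pulse at
        55 s after light-on gives FM'/FM = 1/(1 + (1-e^-5.5))."""
        truth = GroupTruth(npq_ss=1.0)
        g = GroupFactor("2x", 10.0)
        params = SimulationParams(groups={g: truth}, noise_cv=0.0)
        model = kautsky_model_for(params, g)
        ratio = model.fm_prime(np.array([model.t_on + 55.0]))[0] / model.fm
        assert 0.500 < ratio < 0.503

    def test_dark_relaxation_recovers_fm(self):
        """With no sustained quenching, FM'' at 63 s after light-off has
        relaxed to within 1% of FM (6.3 relaxation times)."""
        truth = GroupTruth(npq_ss=1.0, qi_frac=0.0)
        g = GroupFactor("2x", 10.0)
        params = SimulationParams(groups={g: truth}, noise_cv=0.0)
        model = kautsky_model_for(params, g)
        fmpp = model.fm_prime(np.array([model.t_off + 63.0]))[0]
        assert abs(fmpp - model.fm) / model.fm < 0.01

    def test_protocol_phase_check(self, noisefree_params, group_2x):
        from pamflux.protocols import Phase, ProtocolSpec

        broken = ProtocolSpec("KC", (Phase("dark", 5.0, 0.0, (2.0,)),
                                     Phase("actinic", 60.0, 300.0, (7.0,))))
        with pytest.raises(ProtocolError):
            simulate_kautsky(noisefree_params, group_2x, protocol=broken)

    def test_determinism(self, group_2x):
        params = SimulationParams(noise_cv=0.03)
        a = simulate_kautsky(params, group_2x, seed=5, plant_id="x")
        b = simulate_kautsky(params, group_2x, seed=5, plant_id="x")
        assert a == b


class TestLightCurveSimulator:
    def test_retr_plateaus_at_retr_max(self):
        truth = GroupTruth(retr_max=40.0)
        assert retr_response(1e5, 40.0, 0.4) == pytest.approx(40.0, rel=1e-6)
        assert retr_response(500.0, truth.retr_max, 0.4) == pytest.approx(
            40.0, rel=1e-2)

    def test_linear_low_light_limit(self):
        # alpha*I << retr_max: response is alpha*I within 2%
        assert retr_response(1.0, 40.0, 0.4) == pytest.approx(0.4, rel=0.02)

    def test_default_steps_give_six_pulse_windows(self, noisefree_params, group_2x):
        tr = simulate_light_curve(noisefree_params, group_2x)
        # pulse windows: 1 dark + 6 steps
        edges = np.diff(tr.pulse_flag.astype(int))
        assert (edges == 1).sum() == 7

    def test_decreasing_steps_rejected(self, noisefree_params, group_2x):
        with pytest.raises(ProtocolError):
            simulate_light_curve(noisefree_params, group_2x,
                                 steps=(100.0, 50.0))

    def test_fit_recovers_generating_curve(self):
        ppfd = np.array([10, 20, 50, 100, 300, 500], float)
        retr = retr_response(ppfd, 40.0, 0.4)
        rm, a = fit_retr_response(ppfd, retr)
        assert rm == pytest.approx(40.0, rel=1e-6)
        assert a == pytest.approx(0.4, rel=1e-6)


class TestStudySimulation:
    def test_trace_and_ground_truth_counts(self):
        params = SimulationParams(n_per_cell=3, noise_cv=0.0)
        study = simulate_study(params, seed=1)
        assert len(study.design) == 24
        assert sum(len(v) for v in study.traces.values()) == 72
        assert study.ground_truth["plant_id"].nunique() == 24

    def test_ground_truth_invariant_to_seed(self):
        params = SimulationParams(n_per_cell=2, noise_cv=0.05)
        a = simulate_study(params, seed=1)
        b = simulate_study(params, seed=2)
        assert a.ground_truth.equals(b.ground_truth)
        pid = a.design[0][0]
        assert not np.array_equal(a.traces[pid]["KC"].fluorescence,
                                  b.traces[pid]["KC"].fluorescence)

    def test_weights_survive_config_round_trip(self):
        truth = GroupTruth(ojip_weights=(1 / 3, 1 / 3, 1 / 3))
        blob = json.dumps(truth.ojip_weights)
        back = GroupTruth(ojip_weights=tuple(json.loads(blob)))
        assert abs(sum(back.ojip_weights) - 1.0) <= 1e-9

    def test_preset_covers_all_cells(self):
        preset = default_group_truth()
        assert len(preset) == 8
        phi_35 = preset[GroupFactor("6x_35", 16.5)].phi_max_true
        others = [t.phi_max_true for g, t in preset.items()
                  if g.cytotype != "6x_35"]
        assert all(phi_35 < p for p in others)
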