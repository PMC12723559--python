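"""Surrogate microcircuit: construction, determinism, dynamics sanity."""

import numpy as np
import pytest

from agecircuit.aging_parameters import make_profile
from agecircuit.microcircuit import (
    CircuitConfig,
    OUDrive,
    SynapseKinetics,
    _build_stim_events,
    brief_stimulus,
    build_circuit,
    replay_dipole,
    simulate,
    strong_stimulus,
)


@pytest.fixture(scope="module")
def small_cfg():
    return CircuitConfig(n_total=200)


@pytest.fixture(scope="module")
def middle_circuit(small_cfg):
    return build_circuit(small_cfg, make_profile("middle_age"), seed=3)


class TestBuild:
    def test_default_population_counts(self):
        c = build_circuit(CircuitConfig(n_total=1000), make_profile("middle_age"), seed=0)
        assert c.counts == {"Pyr": 800, "SST": 50, "PV": 70, "VIP": 80}

    def test_aged_interneuron_counts_round_half_up(self):
        c = build_circuit(CircuitConfig(n_total=1000), make_profile("older"), seed=0)
        assert c.counts["SST"] == 38  # round(50 x 0.758)
        assert c.counts["VIP"] == round(80 * 0.824)
        assert c.counts["Pyr"] == 800

    def test_connectivity_deterministic_in_seed(self, small_cfg):
        a = build_circuit(small_cfg, make_profile("older"), seed=11)
        b = build_circuit(small_cfg, make_profile("older"), seed=11)
        assert np.array_equal(a.W_ampa, b.W_ampa)
        assert np.array_equal(a.W_gabaA, b.W_gabaA)

    def test_connectivity_motif(self, middle_circuit):
        c = middle_circuit
        pyr = c.neurons_of("Pyr")
        sst = c.neurons_of("SST")
        vip = c.neurons_of("VIP")
        pv = c.neurons_of("PV")
        # SST inhibits only Pyr (apical channel); VIP inhibits SST and PV
        assert c.W_gabaA[np.ix_(sst, pyr)].sum() > 0
        assert c.W_gabaA[np.ix_(vip, pyr)].sum() == 0
        assert c.W_gabaB[np.ix_(vip, sst)].sum() > 0
        assert c.W_gabaB[np.ix_(vip, pyr)].sum() == 0
        assert c.W_gabaB[np.ix_(pyr, pyr)].sum() == 0
        # interneurons make no glutamatergic synapses
        assert c.W_ampa[np.ix_(pv, pyr)].sum() == 0

    def test_nmda_multiplier_scales_only_pyr_targets(self, small_cfg):
        mid = build_circuit(small_cfg, make_profile("middle_age"), seed=5)
        nm = build_circuit(small_cfg, make_profile("nmda_loss"), seed=5)
        pyr = mid.neurons_of("Pyr")
        pv = mid.neurons_of("PV")
        w_mid = mid.W_nmda[np.ix_(pyr, pyr)]
        w_nm = nm.W_nmda[np.ix_(pyr, pyr)]
        nz = w_mid > 0
        assert np.allclose(w_nm[nz] / w_mid[nz], 0.5)
        assert np.array_equal(mid.W_nmda[np.ix_(pyr, pv)], nm.W_nmda[np.ix_(pyr, pv)])

    def test_passive_multiplier_scales_pyr_membrane(self, small_cfg):
        mid = build_circuit(small_cfg, make_profile("middle_age"), seed=5)
        sp = build_circuit(small_cfg, make_profile("spine_loss"), seed=5)
        pyr = mid.neurons_of("Pyr")
        ratio = sp.g_leak[pyr] / mid.g_leak[pyr]
        assert np.allclose(ratio, sp.profile.passive_multiplier)

    def test_tiny_population_floored_with_warning(self):
        cfg = CircuitConfig(n_total=10, proportions=(0.90, 0.02, 0.04, 0.04))
        with pytest.warns(UserWarning):
            c = build_circuit(cfg, make_profile("middle_age"), seed=0)
        assert c.counts["SST"] >= 1


class TestKineticsValidation:
    def test_rise_must_be_below_decay(self):
        with pytest.raises(ValueError):
            SynapseKinetics(ampa_rise=5.0, ampa_decay=3.0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CircuitConfig(proportions=(0.5, 0.2, 0.2, 0.2))


class TestSimulate:
    def test_no_drive_no_spikes(self, small_cfg):
        quiet = CircuitConfig(
            n_total=200,
            ou=(OUDrive(0, 0), OUDrive(0, 0), OUDrive(0, 0), OUDrive(0, 0)),
            alpha_gain=0.0,
        )
        c = build_circuit(quiet, make_profile("middle_age"), seed=1)
        spikes, dip = simulate(c, 500.0, seed=2)
        assert spikes.times_ms.size == 0
        assert np.allclose(dip.values, 0.0)

    def test_bitwise_deterministic_under_seed(self, middle_circuit):
        s1, d1 = simulate(middle_circuit, 800.0, seed=9)
        s2, d2 = simulate(middle_circuit, 800.0, seed=9)
        assert np.array_equal(s1.times_ms, s2.times_ms)
        assert np.array_equal(s1.neuron_ids, s2.neuron_ids)
        assert np.array_equal(d1.values, d2.values)

    def test_seed_changes_realization(self, middle_circuit):
        s1, _ = simulate(middle_circuit, 800.0, seed=9)
        s2, _ = simulate(middle_circuit, 800.0, seed=10)
        assert not np.array_equal(s1.times_ms, s2.times_ms)

    def test_baseline_regime_irregular_low_rate(self):
        c = build_circuit(CircuitConfig(n_total=400), make_profile("middle_age"), seed=4)
        spikes, _ = simulate(c, 4000.0, seed=12)
        rate = spikes.population_rate("Pyr", 500.0)
        assert 0.1 <= rate <= 10.0
        assert spikes.isi_cv("Pyr") > 0.5

    def test_spike_times_within_duration_and_sorted(self, middle_circuit):
        spikes, _ = simulate(middle_circuit, 800.0, seed=9)
        assert np.all(spikes.times_ms >= 0)
        assert np.all(spikes.times_ms <= 800.0)
        assert np.all(np.diff(spikes.times_ms) >= 0)

    def test_invalid_duration_rejected(self, middle_circuit):
        with pytest.raises(ValueError):
            simulate(middle_circuit, -5.0)

    def test_disinhibition_increases_pyr_rate(self):
        cfg = CircuitConfig(n_total=300)
        c = build_circuit(cfg, make_profile("middle_age"), seed=6)
        intact, _ = simulate(c, 2500.0, seed=21)
        c.W_gabaA = np.zeros_like(c.W_gabaA)
        c.W_gabaB = np.zeros_like(c.W_gabaB)
        released, _ = simulate(c, 2500.0, seed=21, max_rate_hz=500.0)
        assert released.population_rate("Pyr", 500.0) > intact.population_rate(
            "Pyr", 500.0
        )

    def test_dipole_output_rate(self, middle_circuit):
        _, dip = simulate(middle_circuit, 1000.0, seed=9)
        assert dip.fs == middle_circuit.config.dipole_fs
        assert dip.values.size == int(1000.0 / 1000.0 * dip.fs)


class TestStimuli:
    def test_brief_stimulus_protocol(self):
        spec = brief_stimulus()
        pyr = spec.entry_for("Pyr")
        assert (pyr.n_targets, pyr.delay_ms, pyr.gmax_ns) == (55, (2.0, 4.0), 4.0)
        late = spec.entry_for("VIP_late")
        assert (late.n_targets, late.delay_ms, late.gmax_ns) == (80, (7.0, 12.0), 2.2)
        assert spec.entry_for("PV").gmax_ns == 2.0

    def test_strong_stimulus_protocol(self):
        spec = strong_stimulus()
        assert spec.entry_for("PV") is None  # feedforward inhibition removed
        pyr = spec.entry_for("Pyr")
        assert (pyr.n_targets, pyr.delay_ms, pyr.gmax_ns, pyr.n_syn) == (
            55,
            (2.0, 22.0),
            2.0,
            2,
        )
        assert spec.entry_for("VIP_early").gmax_ns == 5.6
        assert spec.entry_for("VIP_late").gmax_ns == 4.4

    def test_targets_capped_at_available_population(self, small_cfg):
        # n_total=200 -> 16 VIP cells < the 80 requested late targets
        c = build_circuit(small_cfg, make_profile("middle_age"), seed=3)
        rng = np.random.default_rng(0)
        steps, neurons, ga, gn = _build_stim_events(
            c, brief_stimulus(), np.array([100.0]), rng, c.config.dt
        )
        vip = set(c.neurons_of("VIP"))
        vip_events = [n for n in neurons if n in vip]
        # early group capped at 16, late group capped at 16
        assert len(vip_events) == 32

    def test_stimulus_evokes_response(self):
        cfg = CircuitConfig(n_total=300)
        c = build_circuit(cfg, make_profile("middle_age"), seed=8)
        spikes, _ = simulate(
            c,
            4600.0,
            stimulus=brief_stimulus(),
            n_trials=2,
            stim_start_ms=3600.0,
            stim_interval_ms=500.0,
            seed=30,
        )
        base = spikes.population_rate("Pyr", 500.0, 3600.0)
        resp = np.mean(
            [
                spikes.population_rate("Pyr", t + 2.0, t + 50.0)
                for t in spikes.stim_times_ms
            ]
        )
        assert resp > base

    def test_duration_too_short_for_trials_rejected(self, middle_circuit):
        with pytest.raises(ValueError):
            simulate(
                middle_circuit,
                1000.0,
                stimulus=brief_stimulus(),
                n_trials=20,
                stim_start_ms=500.0,
            )


class TestReplayDipole:
    def test_dipole_linear_in_synaptic_weights(self, middle_circuit):
        spikes, _ = simulate(middle_circuit, 1500.0, seed=14)
        d1 = replay_dipole(middle_circuit, spikes, weight_scale=1.0)
        d2 = replay_dipole(middle_circuit, spikes, weight_scale=2.0)
        assert np.allclose(d2.values, 2.0 * d1.values, rtol=1e-12, atol=1e-300)

    def test_replay_tracks_population_activity(self, middle_circuit):
        spikes, _ = simulate(middle_circuit, 1500.0, seed=14)
        d = replay_dipole(middle_circuit, spikes)
        assert d.values.size == int(1500.0 / 1000.0 * middle_circuit.config.dipole_fs)
        assert np.all(np.isfinite(d.values))
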