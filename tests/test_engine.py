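"""Closed-loop engine: determinism, controls, probes, bump dynamics.

Short bespoke runs cover controls and determinism; the session-scoped
300-s desk run supplies the dynamical invariants (bump clustering,
excitation->inhibition causality, firing-rate sanity).
"""

import numpy as np
import pytest

from gridcan.engine import (
    CA1,
    CONJUNCTIVE,
    IN_TYPES,
    STELLATE,
    Network,
    SimConfig,
    run_simulation,
)
from gridcan.errors import ConfigurationError
from gridcan.params import load_tables
from gridcan.rhythms import population_rate
from gridcan.stimulus import synthesize_trajectory
from gridcan.topology import torus_distance


def short_traj(duration=5.0, seed=3):
    return synthesize_trajectory(duration, seed=seed)


def silent_tables():
    """All synaptic gains and drives zeroed: every population must rest."""
    tables = load_tables()
    pr = tables.presets["desk"]
    pr["gain"] = {k: 0.0 for k in pr["gain"]}
    pr["drive"].update({"I0": 0.0, "alpha": 0.0, "A_place": 0.0})
    pr["noise_sigma"] = 0.0
    return tables


class TestControls:
    def test_silent_network_produces_no_spikes(self):
        cfg = SimConfig(preset="desk", seed=0, settle_pulse_pA=0.0, tables=silent_tables())
        res = run_simulation(cfg, short_traj())
        assert res.spikes.total() == 0

    def test_silent_network_numpy_backend_agrees(self):
        cfg = SimConfig(
            preset="desk", seed=0, backend="numpy",
            settle_pulse_pA=0.0, tables=silent_tables(),
        )
        res = run_simulation(cfg, short_traj(2.0))
        assert res.spikes.total() == 0

    def test_probed_neuron_in_silent_network_sits_at_rest(self, tables):
        cfg = SimConfig(
            preset="desk", seed=0, settle_pulse_pA=0.0,
            probes=[(STELLATE, 2, 1)], tables=silent_tables(),
        )
        res = run_simulation(cfg, short_traj(2.0))
        trace = res.probes[0]
        vr = tables.neuron(STELLATE).Vr
        # initial-phase jitter relaxes back toward rest; the last half must
        # hug Vr
        assert np.allclose(trace.v[len(trace.v) // 2 :], vr, atol=1.5)

    def test_unknown_backend_rejected(self):
        cfg = SimConfig(preset="desk", backend="fortran")
        with pytest.raises(ConfigurationError, match="backend"):
            run_simulation(cfg, short_traj(1.0))


class TestDeterminism:
    @pytest.mark.parametrize("backend", ["numba", "numpy"])
    def test_identical_runs_are_bit_identical(self, backend):
        traj = short_traj(3.0)
        results = []
        for _ in range(2):
            cfg = SimConfig(preset="desk", seed=11, backend=backend)
            results.append(run_simulation(cfg, traj))
        a, b = results
        for pop in a.spikes.times_ms:
            np.testing.assert_array_equal(a.spikes.times_ms[pop], b.spikes.times_ms[pop])
            np.testing.assert_array_equal(a.spikes.indices[pop], b.spikes.indices[pop])

    def test_backends_agree_statistically(self):
        """With independent noise streams the two backends must produce the
        same population rates to within sampling error."""
        traj = short_traj(6.0)
        rates = {}
        for backend in ("numba", "numpy"):
            cfg = SimConfig(preset="desk", seed=4, backend=backend)
            res = run_simulation(cfg, traj)
            rates[backend] = {
                p: res.spikes.rate(p, n) for p, n in res.manifest["populations"].items()
            }
        for pop in rates["numba"]:
            a, b = rates["numba"][pop], rates["numpy"][pop]
            assert a == pytest.approx(b, rel=0.25, abs=0.5), pop


class TestProbes:
    def test_probe_traces_have_ms_resolution_and_five_sources(self, desk_run, desk_config):
        trace = desk_run.probes[0]
        n_ms = int((desk_config.settle_s + 300.0) * 1000)
        assert trace.v.size == n_ms
        sources = {key.split("/")[0] for key in trace.currents}
        assert sources == {CONJUNCTIVE, CA1, *IN_TYPES}
        # each source contributes a fast and a slow channel
        assert len(trace.currents) == 10

    def test_probe_current_signs_follow_channel_type(self, desk_run):
        """Below the excitatory reversal (0 mV) excitatory currents are
        non-negative; above the GABA_A reversal inhibitory currents are
        non-positive."""
        trace = desk_run.probes[0]
        sub_exc = trace.v < -1.0
        above_inh = trace.v > -69.0
        for key, arr in trace.currents.items():
            if "exc" in key:
                assert arr[sub_exc].min() > -1e-9, key
            elif "fast_inh" in key:
                assert arr[above_inh].max() < 1e-9, key

    def test_out_of_range_probe_rejected(self):
        cfg = SimConfig(preset="desk", probes=[(STELLATE, 99, 0)])
        with pytest.raises(ConfigurationError):
            run_simulation(cfg, short_traj(1.0))


class TestDynamics:
    def test_stellate_rates_in_low_single_digits(self, desk_run, desk_network):
        n = desk_network.layouts[STELLATE].count
        rate = desk_run.spikes.rate(STELLATE, n)
        assert 0.5 < rate < 5.0

    def test_activity_is_bump_lattice_structured(self, desk_run, desk_network):
        """Instantaneous stellate activity projects strongly onto the bump
        lattice's reciprocal vectors, far above an index-shuffled control
        (whose order parameter is ~n^-1/2)."""
        layout = desk_network.layouts[STELLATE]
        lam = desk_network.preset.bump_lattice
        k1 = (2 * np.pi / lam) * np.array([1.0, -1.0 / np.sqrt(3)])
        pos = layout.positions()
        idx, t_ms = desk_run.spikes.of(STELLATE)
        k2 = (2 * np.pi / lam) * np.array([0.0, 2.0 / np.sqrt(3)])
        rng = np.random.default_rng(0)
        observed, shuffled = [], []
        for w0 in np.arange(5_000.0, 295_000.0, 10_000.0):
            m = (t_ms >= w0) & (t_ms < w0 + 100.0)
            spikes_pos = pos[idx[m]]
            if spikes_pos.shape[0] < 10:
                continue
            fake = pos[rng.integers(0, layout.count, size=spikes_pos.shape[0])]
            for k in (k1, k2):
                observed.append(abs(np.exp(1j * spikes_pos @ k).mean()))
                shuffled.append(abs(np.exp(1j * fake @ k).mean()))
        assert len(observed) >= 20
        assert np.mean(observed) > 1.5 * np.mean(shuffled)

    def test_interneurons_lag_stellates(self, desk_run):
        """Cross-correlation of IN rate against stellate rate peaks at a
        positive lag within a few milliseconds (spikes propagate through
        the 1-ms conduction delay)."""
        st = population_rate(
            {STELLATE: desk_run.spikes.times_ms[STELLATE]},
            bin_ms=1.0, t_start_ms=0.0, t_stop_ms=60_000.0,
        ).counts.astype(float)
        inh = population_rate(
            {p: desk_run.spikes.times_ms[p] for p in IN_TYPES},
            populations=list(IN_TYPES),
            bin_ms=1.0, t_start_ms=0.0, t_stop_ms=60_000.0,
        ).counts.astype(float)
        st -= st.mean()
        inh -= inh.mean()
        lags = np.arange(-10, 11)
        xc = [np.dot(st[10:-10], inh[10 + lag : inh.size - 10 + lag]) for lag in lags]
        best = lags[int(np.argmax(xc))]
        # conduction delay (1 ms) plus synaptic rise and integration time
        assert 0 < best <= 8

    def test_manifest_records_parameters(self, desk_run):
        m = desk_run.manifest
        assert m["preset"] == "desk"
        assert m["seed"] == 1
        assert m["populations"][STELLATE] == 400
        assert all(n > 0 for n in m["n_edges"].values())
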