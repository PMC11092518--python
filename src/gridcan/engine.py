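"""Closed-loop simulation engine.

Per time step (default dt = 0.5 ms), in order: decay synaptic state,
deliver spikes whose conduction delay (1 ms) has elapsed, compute
per-population currents (receptor channels + external drive), advance
the Izhikevich states, then log spikes and probes.  A settle phase with
zero velocity and a brief broad excitation pulse nucleates the activity
bumps and is excluded from recorded output; recorded spike times are
milliseconds from the start of trajectory playback.

Runs are deterministic: a single RNG stream is seeded from the config
and identical (config, trajectory, seed) reproduce spike trains
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import __version__
from .errors import ConfigurationError, SimulationError
from .izhikevich import NeuronState, izh_step, make_population
from .params import IzhikevichParams, ModelTables, TMParams, load_tables
from .stimulus import (
    PlaceFieldBank,
    Trajectory,
    conjunctive_drive,
    place_drive,
    velocity_from_trajectory,
)
from .synapses import SynapseGroup, mg_block, tm_on_spike
from .topology import (
    PhaseMap,
    ScalePreset,
    SheetLayout,
    assign_preferred_directions,
    build_cs_connectivity,
    build_one_to_one,
    build_phase_projection,
)

__all__ = [
    "SimConfig",
    "SpikeRecord",
    "ProbeTrace",
    "SimResult",
    "Network",
    "build_network",
    "run_simulation",
    "STELLATE",
    "CONJUNCTIVE",
    "CA1",
    "IN_TYPES",
    "MEC_LII_POPULATIONS",
]

STELLATE = "MEC LII Stellate"
CONJUNCTIVE = "EC LI-II Multipolar Pyramidal"
CA1 = "CA1 Pyramidal"
IN_TYPES = ("EC LII AxoAxonic", "MEC LII Basket", "EC LII Basket Multipolar")
#: Populations whose somata sit in MEC LII (combined for rhythm analysis).
MEC_LII_POPULATIONS = (STELLATE,) + IN_TYPES + (CONJUNCTIVE,)

_DIRECTION_ANGLE = {"E": 0.0, "N": np.pi / 2, "W": np.pi, "S": -np.pi / 2}


@dataclass
class SimConfig:
    """Run configuration; all stochastic elements derive from ``seed``."""

    preset: str = "desk"
    dt_ms: float = 0.5
    settle_s: float = 0.5
    seed: int = 0
    delay_ms: float = 1.0
    backend: str = "numba"
    record_spikes: bool = True
    probes: list[tuple[str, int, int]] = dc_field(default_factory=list)
    im_overrides: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    tm_overrides: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    twist: bool = True
    settle_pulse_pA: float = 200.0
    settle_pulse_ms: float = 100.0
    tables: ModelTables | None = None

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt_ms}")
        if self.delay_ms < self.dt_ms:
            raise ConfigurationError("conduction delay must be at least one step")

    def resolve_tables(self) -> ModelTables:
        return self.tables if self.tables is not None else load_tables()


@dataclass
class SpikeRecord:
    """Event stream per population: parallel (neuron index, time ms) arrays."""

    times_ms: dict[str, np.ndarray]
    indices: dict[str, np.ndarray]
    duration_ms: float

    def of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        return self.indices[population], self.times_ms[population]

    def count(self, population: str) -> int:
        return int(self.times_ms[population].size)

    def total(self) -> int:
        return sum(t.size for t in self.times_ms.values())

    def cell_spike_times_s(self, population: str, neuron: int) -> np.ndarray:
        idx, t = self.of(population)
        return t[idx == neuron] / 1000.0

    def rate(self, population: str, n_neurons: int) -> float:
        """Population-mean firing rate in spikes/s."""
        if self.duration_ms <= 0:
            return 0.0
        return self.count(population) / n_neurons / (self.duration_ms / 1000.0)


@dataclass
class ProbeTrace:
    """1-ms voltage and per-source synaptic current traces for one neuron."""

    population: str
    neuron: int
    sheet_pos: tuple[int, int]
    t_ms: np.ndarray
    v: np.ndarray
    currents: dict[str, np.ndarray]  # keyed "<source group>/<channel>"

    def total_current(self) -> np.ndarray:
        return np.sum(list(self.currents.values()), axis=0)


@dataclass
class SimResult:
    spikes: SpikeRecord
    probes: list[ProbeTrace]
    manifest: dict


class Network:
    """All populations, layouts, synapse groups and drive machinery."""

    def __init__(self, config: SimConfig):
        tables = config.resolve_tables()
        preset = ScalePreset.from_tables(config.preset, tables)
        self.config = config
        self.preset = preset
        self.tables = tables
        self.arena_cm = float(tables.arena["side_cm"])

        def im(name: str) -> IzhikevichParams:
            p = tables.neuron(name)
            if name in config.im_overrides:
                p = p.replace(**config.im_overrides[name])
            return p

        def tm(name: str) -> TMParams:
            p = tables.synapse(name)
            if name in config.tm_overrides:
                p = p.replace(**config.tm_overrides[name])
            return p

        self.layouts: dict[str, SheetLayout] = {}
        self.params: dict[str, IzhikevichParams] = {}
        st_layout = preset.stellate_layout(twist=config.twist)
        self.layouts[STELLATE] = st_layout
        self.layouts[CONJUNCTIVE] = preset.stellate_layout(twist=config.twist)
        self.layouts[CA1] = preset.stellate_layout(twist=config.twist)
        for i, name in enumerate(IN_TYPES):
            self.layouts[name] = preset.in_layout(i, twist=config.twist)
        for name in (STELLATE, CONJUNCTIVE, CA1) + IN_TYPES:
            self.params[name] = im(name)

        self.directions = assign_preferred_directions(st_layout)
        self.theta_pref = np.array(
            [_DIRECTION_ANGLE[l] for l in self.directions.labels]
        )
        # Cell-to-cell excitability spread of the velocity drive (seeded):
        # broadens the conjunctive locking frequencies as real neurons do.
        spread = float(preset.drive.get("heterogeneity", 0.0))
        het_rng = np.random.default_rng(config.seed + 7919)
        self.conj_het = 1.0 + spread * het_rng.uniform(-1.0, 1.0, size=st_layout.count)
        self.phase_map = PhaseMap(preset, st_layout)

        bank_side = st_layout.cols
        self.place_bank = PlaceFieldBank.tile(
            bank_side,
            sigma=preset.drive["sigma_place"],
            amplitude=preset.drive["A_place"],
            arena_cm=self.arena_cm,
        )

        groups: list[SynapseGroup] = [
            build_one_to_one(
                self.layouts[CONJUNCTIVE],
                st_layout,
                tm(f"{CONJUNCTIVE} to {STELLATE}"),
                name=f"{CONJUNCTIVE} to {STELLATE}",
                gain=preset.gain.get("conj", 1.0),
            ),
            build_phase_projection(
                self.layouts[CA1],
                st_layout,
                self.place_bank.centers,
                self.phase_map,
                tm(f"{CA1} to {STELLATE}"),
                name=f"{CA1} to {STELLATE}",
                gain=preset.gain.get("place", 1.0),
            ),
        ]
        for name in IN_TYPES:
            e2i, i2e = build_cs_connectivity(
                st_layout,
                self.layouts[name],
                preset,
                self.directions,
                tm(f"{STELLATE} to {name}"),
                tm(f"{name} to {STELLATE}"),
                in_name=name,
            )
            groups += [e2i, i2e]
        if not any(g.n_edges for g in groups):
            raise ConfigurationError("network has no synaptic connectivity")
        self.groups = groups
        self.source_of = {g.name: g.name.split(" to ")[0] for g in groups}
        self.target_of = {g.name: g.name.split(" to ")[1] for g in groups}

    def populations(self) -> dict[str, int]:
        return {name: layout.count for name, layout in self.layouts.items()}

    def groups_onto(self, population: str) -> list[SynapseGroup]:
        return [g for g in self.groups if self.target_of[g.name] == population]


def build_network(config: SimConfig) -> Network:
    return Network(config)


def _jitter_initial_state(states: dict[str, NeuronState], net: Network, seed: int) -> None:
    """Seeded uniform initial-voltage jitter in [Vr, (Vr+Vt)/2].

    Identically parameterized neurons under identical drive would
    otherwise march in lock-step forever (they are uncoupled clones),
    producing artificial population-wide volleys; random initial phases
    are the standard desynchronization."""
    rng = np.random.default_rng(seed)
    for name, state in states.items():
        p = net.params[name]
        state.v += rng.uniform(0.0, 0.5 * (p.Vt - p.Vr), size=len(state))


def _resolve_probes(net: Network, probes) -> list[tuple[str, int, tuple[int, int]]]:
    resolved = []
    for pop, row, col in probes:
        if pop not in net.layouts:
            raise ConfigurationError(f"unknown probe population {pop!r}")
        resolved.append((pop, net.layouts[pop].index_of(row, col), (row, col)))
    return resolved


def run_simulation(config: SimConfig, traj: Trajectory) -> SimResult:
    """Run settle + trajectory playback; return spikes, probes and manifest.

    Two numerically identical backends exist: the vectorized reference
    implementation (``backend="numpy"``, built directly from the module
    operations) and a compiled step loop (``backend="numba"``, the
    default, roughly an order of magnitude faster).  Each backend is
    bit-deterministic under a fixed (config, trajectory, seed); their
    membrane-noise streams differ, so statistics — not individual spike
    times — agree across backends.
    """
    if config.backend == "numba":
        return _run_simulation_numba(config, traj)
    if config.backend != "numpy":
        raise ConfigurationError(f"unknown backend {config.backend!r}")
    return _run_simulation_numpy(config, traj)


def _run_simulation_numpy(config: SimConfig, traj: Trajectory) -> SimResult:
    net = Network(config)
    dt = config.dt_ms
    steps_per_ms = int(round(1.0 / dt))
    if abs(steps_per_ms * dt - 1.0) > 1e-9:
        raise ConfigurationError("dt must divide 1 ms for event bookkeeping")
    rng = np.random.default_rng(config.seed)

    vel = velocity_from_trajectory(traj)
    n_settle = int(round(config.settle_s * 1000.0 / dt))
    n_run = int(round(traj.duration * 1000.0 / dt))
    n_total = n_settle + n_run
    delay_steps = int(round(config.delay_ms / dt))

    # Per-step drive lookup tables (positions at step resolution; velocity
    # held stepwise-constant between trajectory samples).
    t_run = np.arange(n_run) * (dt / 1000.0) + traj.t[0]
    pos_run = traj.position_at(t_run)
    vidx = np.clip(np.searchsorted(vel.t, t_run, side="right") - 1, 0, len(vel.speed) - 1)
    speed_run = vel.speed[vidx]
    heading_run = vel.heading[vidx]

    states: dict[str, NeuronState] = {
        name: make_population(name, count, params=net.params[name])
        for name, count in net.populations().items()
    }
    _jitter_initial_state(states, net, config.seed)

    # Delay lines: per group, (delay_steps + 1) slots of pending conductance
    # increments for its two channels on the target population.
    buf_fast = {g.name: np.zeros((delay_steps + 1, g.n_post)) for g in net.groups}
    buf_slow = {g.name: np.zeros((delay_steps + 1, g.n_post)) for g in net.groups}

    decay = {}
    for g in net.groups:
        p = g.params
        decay[g.name] = (
            np.exp(-dt / p.tau_u),
            np.exp(-dt / p.tau_x),
            np.exp(-dt / p.tau_d_fast),
            np.exp(-dt / p.tau_d_slow),
        )

    probes = _resolve_probes(net, config.probes)
    n_ms_total = n_total // steps_per_ms
    probe_data = [
        {
            "v": np.zeros(n_ms_total),
            "currents": {
                f"{net.source_of[g.name]}/{'fast_inh' if g.inhibitory else 'fast_exc'}": np.zeros(n_ms_total)
                for g in net.groups_onto(pop)
            }
            | {
                f"{net.source_of[g.name]}/{'slow_inh' if g.inhibitory else 'slow_exc'}": np.zeros(n_ms_total)
                for g in net.groups_onto(pop)
            },
        }
        for pop, _, _ in probes
    ]

    spike_times: dict[str, list] = {name: [] for name in states}
    spike_idx: dict[str, list] = {name: [] for name in states}

    I_ext = {name: np.zeros(count) for name, count in net.populations().items()}
    reversals = {
        "fast_exc": net.tables.receptors["E_fast_exc"],
        "slow_exc": net.tables.receptors["E_slow_exc"],
        "fast_inh": net.tables.receptors["E_fast_inh"],
        "slow_inh": net.tables.receptors["E_slow_inh"],
    }
    I0 = net.preset.drive["I0"]
    alpha = net.preset.drive["alpha"]
    noise_sigma = net.preset.noise_sigma
    pulse_steps = int(round(config.settle_pulse_ms / dt))
    start_pos = traj.position_at(traj.t[0])

    # Hot-loop precomputation: per-population incoming group lists, decay
    # scalars, reusable current buffers.
    pop_names = list(states)
    incoming = {name: net.groups_onto(name) for name in pop_names}
    E_fx, E_sx = reversals["fast_exc"], reversals["slow_exc"]
    E_fi, E_si = reversals["fast_inh"], reversals["slow_inh"]
    I_buf = {name: np.zeros(count) for name, count in net.populations().items()}
    n_stellate = net.layouts[STELLATE].count
    driven = (CONJUNCTIVE, CA1, STELLATE)

    for step in range(n_total):
        in_settle = step < n_settle
        k = step - n_settle

        # 1) decay TM state and conductances (exact exponentials).
        for g in net.groups:
            du, dx, df, ds = decay[g.name]
            np.multiply(g.u, du, out=g.u)
            g.x -= 1.0
            g.x *= dx
            g.x += 1.0
            np.multiply(g.s_fast, df, out=g.s_fast)
            np.multiply(g.s_slow, ds, out=g.s_slow)

        # 2) deliver spikes whose delay has elapsed.
        slot = step % (delay_steps + 1)
        for g in net.groups:
            bf = buf_fast[g.name][slot]
            bs = buf_slow[g.name][slot]
            g.s_fast += bf
            g.s_slow += bs
            bf[:] = 0.0
            bs[:] = 0.0

        # 3) external drive.
        if in_settle:
            speed, heading = 0.0, 0.0
            pos = start_pos
        else:
            speed, heading = speed_run[k], heading_run[k]
            pos = pos_run[k]
        I_conj = conjunctive_drive(speed, heading, net.theta_pref, I0, alpha) * net.conj_het
        if noise_sigma > 0:
            I_conj = I_conj + rng.normal(0.0, noise_sigma, size=I_conj.size)
        I_ext[CONJUNCTIVE] = I_conj
        I_ext[CA1] = place_drive(pos, net.place_bank)
        I_st = rng.normal(0.0, noise_sigma, size=n_stellate) if noise_sigma > 0 else np.zeros(n_stellate)
        if in_settle and step < pulse_steps:
            I_st += config.settle_pulse_pA
        I_ext[STELLATE] = I_st

        # 4) synaptic currents and neuron updates.
        spiking: dict[str, np.ndarray] = {}
        for name in pop_names:
            state = states[name]
            v = state.v
            I = I_buf[name]
            if name in driven:
                I[:] = I_ext[name]
            else:
                I[:] = 0.0
            groups_in = incoming[name]
            if groups_in:
                mg = None
                for g in groups_in:
                    if g.inhibitory:
                        I += g.s_fast * (E_fi - v)
                        I += g.s_slow * (E_si - v)
                    else:
                        if mg is None:
                            z = ((v + 80.0) / 60.0) ** 2
                            mg = z / (1.0 + z)
                        I += g.s_fast * (E_fx - v)
                        I += g.s_slow * ((E_sx - v) * mg)
            _, flags = izh_step(state, net.params[name], I, dt, out=state, validate=False)
            spiking[name] = np.flatnonzero(flags)

        # 5) queue synaptic releases with the conduction delay.
        tgt = (step + delay_steps) % (delay_steps + 1)
        for g in net.groups:
            sp = spiking[net.source_of[g.name]]
            if sp.size:
                tm_on_spike(g, sp, out_fast=buf_fast[g.name][tgt], out_slow=buf_slow[g.name][tgt])

        # Periodic numerical audit (cheap relative to per-step checks).
        if step % 1000 == 999:
            for name in pop_names:
                if not np.all(np.isfinite(states[name].v)):
                    bad = int(np.flatnonzero(~np.isfinite(states[name].v))[0])
                    raise SimulationError(
                        f"non-finite voltage (neuron {bad}, population {name!r}, step {step})"
                    )

        # 6) log (playback only; times relative to playback start).
        if not in_settle and config.record_spikes:
            t_ms = k * dt
            for name, sp in spiking.items():
                if sp.size:
                    spike_idx[name].append(sp)
                    spike_times[name].append(np.full(sp.size, t_ms))
        if probes and step % steps_per_ms == 0:
            ms = step // steps_per_ms
            for (pop, nid, _), data in zip(probes, probe_data):
                state = states[pop]
                data["v"][ms] = state.v[nid]
                vpost = state.v[nid]
                for g in net.groups_onto(pop):
                    src = net.source_of[g.name]
                    if g.inhibitory:
                        data["currents"][f"{src}/fast_inh"][ms] = g.s_fast[nid] * (
                            reversals["fast_inh"] - vpost
                        )
                        data["currents"][f"{src}/slow_inh"][ms] = g.s_slow[nid] * (
                            reversals["slow_inh"] - vpost
                        )
                    else:
                        data["currents"][f"{src}/fast_exc"][ms] = g.s_fast[nid] * (
                            reversals["fast_exc"] - vpost
                        )
                        data["currents"][f"{src}/slow_exc"][ms] = g.s_slow[nid] * (
                            reversals["slow_exc"] - vpost
                        ) * mg_block(vpost)

    record = SpikeRecord(
        times_ms={
            name: (np.concatenate(v) if v else np.empty(0)) for name, v in spike_times.items()
        },
        indices={
            name: (np.concatenate(v).astype(np.int64) if v else np.empty(0, dtype=np.int64))
            for name, v in spike_idx.items()
        },
        duration_ms=n_run * dt,
    )
    settle_ms = n_settle * dt
    probe_traces = [
        ProbeTrace(
            population=pop,
            neuron=nid,
            sheet_pos=pos_rc,
            t_ms=np.arange(n_ms_total) * 1.0 - settle_ms,
            v=data["v"],
            currents=data["currents"],
        )
        for (pop, nid, pos_rc), data in zip(probes, probe_data)
    ]
    manifest = {
        "version": __version__,
        "preset": config.preset,
        "dt_ms": config.dt_ms,
        "settle_s": config.settle_s,
        "seed": config.seed,
        "duration_s": traj.duration,
        "populations": net.populations(),
        "im_overrides": config.im_overrides,
        "tm_overrides": config.tm_overrides,
        "n_edges": {g.name: g.n_edges for g in net.groups},
    }
    return SimResult(spikes=record, probes=probe_traces, manifest=manifest)

def _run_simulation_numba(config: SimConfig, traj: Trajectory) -> SimResult:
    from . import _kernels

    net = Network(config)
    dt = config.dt_ms
    steps_per_ms = int(round(1.0 / dt))
    if abs(steps_per_ms * dt - 1.0) > 1e-9:
        raise ConfigurationError("dt must divide 1 ms for event bookkeeping")

    vel = velocity_from_trajectory(traj)
    n_settle = int(round(config.settle_s * 1000.0 / dt))
    n_run = int(round(traj.duration * 1000.0 / dt))
    n_total = n_settle + n_run
    delay_steps = int(round(config.delay_ms / dt))

    t_run = np.arange(n_run) * (dt / 1000.0) + traj.t[0]
    pos_run = traj.position_at(t_run) if n_run else np.zeros((0, 2))
    if n_run:
        vidx = np.clip(np.searchsorted(vel.t, t_run, side="right") - 1, 0, len(vel.speed) - 1)
        speed_run = vel.speed[vidx]
        heading_run = vel.heading[vidx]
    else:
        speed_run = np.zeros(0)
        heading_run = np.zeros(0)

    pop_names = list(net.populations())
    pop_index = {name: i for i, name in enumerate(pop_names)}
    states = {
        name: make_population(name, count, params=net.params[name])
        for name, count in net.populations().items()
    }
    _jitter_initial_state(states, net, config.seed)
    v_list = _kernels.typed_list([states[n].v for n in pop_names])
    u_list = _kernels.typed_list([states[n].u for n in pop_names])
    pop_params = np.array(
        [
            [p.C, p.k, p.Vr, p.Vt, p.a, p.b, p.Vpeak, p.Vreset, p.d]
            for p in (net.params[n] for n in pop_names)
        ]
    )

    groups = net.groups
    g_pre = _kernels.typed_list([g.pre for g in groups])
    g_post = _kernels.typed_list([g.post for g in groups])
    g_w = _kernels.typed_list([g.weight for g in groups])
    g_indptr = _kernels.typed_list([g._indptr for g in groups])
    g_u = _kernels.typed_list([g.u for g in groups])
    g_x = _kernels.typed_list([g.x for g in groups])
    g_sfast = _kernels.typed_list([g.s_fast for g in groups])
    g_sslow = _kernels.typed_list([g.s_slow for g in groups])
    g_buf_fast = _kernels.typed_list(
        [np.zeros((delay_steps + 1, g.n_post)) for g in groups]
    )
    g_buf_slow = _kernels.typed_list(
        [np.zeros((delay_steps + 1, g.n_post)) for g in groups]
    )
    g_decay = np.array(
        [
            [
                np.exp(-dt / g.params.tau_u),
                np.exp(-dt / g.params.tau_x),
                np.exp(-dt / g.params.tau_d_fast),
                np.exp(-dt / g.params.tau_d_slow),
            ]
            for g in groups
        ]
    )
    g_gfast = np.array([g.params.g_fast * g.gain for g in groups])
    g_gslow = np.array([g.params.g_slow * g.gain for g in groups])
    g_U = np.array([g.params.U for g in groups])
    g_inhib = np.array([1 if g.inhibitory else 0 for g in groups], dtype=np.uint8)
    g_src = np.array([pop_index[net.source_of[g.name]] for g in groups], dtype=np.int64)
    g_tgt = np.array([pop_index[net.target_of[g.name]] for g in groups], dtype=np.int64)

    dir_angle = np.array([0.0, np.pi / 2, np.pi, -np.pi / 2])
    code_of = {"E": 0, "N": 1, "W": 2, "S": 3}
    dir_code = np.array(
        [code_of[l] for l in net.directions.labels], dtype=np.int64
    )
    conj_het = net.conj_het
    start_pos = traj.position_at(traj.t[0])

    probes = _resolve_probes(net, config.probes)
    n_ms_total = max(1, n_total // steps_per_ms)
    probe_pop = np.array([pop_index[p] for p, _, _ in probes], dtype=np.int64)
    probe_idx = np.array([nid for _, nid, _ in probes], dtype=np.int64)
    probe_v = np.zeros((max(1, len(probes)), n_ms_total))
    probe_s = np.zeros((max(1, len(probes)), len(groups), 2, n_ms_total))
    probe_is_target = np.zeros((max(1, len(probes)), len(groups)), dtype=np.uint8)
    for q, (pop, _, _) in enumerate(probes):
        for gi, g in enumerate(groups):
            if net.target_of[g.name] == pop:
                probe_is_target[q, gi] = 1

    cap = 4_000_000
    ev_pop = np.empty(cap, dtype=np.int8)
    ev_idx = np.empty(cap, dtype=np.int32)
    ev_t = np.empty(cap, dtype=np.float32)
    chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    _kernels.seed_rng(config.seed % (2**31))
    step = 0
    while step < n_total:
        step, n_events = _kernels.run_steps(
            step,
            n_total,
            n_settle,
            dt,
            steps_per_ms,
            delay_steps,
            v_list,
            u_list,
            pop_params,
            g_pre,
            g_post,
            g_w,
            g_indptr,
            g_u,
            g_x,
            g_sfast,
            g_sslow,
            g_buf_fast,
            g_buf_slow,
            g_decay,
            g_gfast,
            g_gslow,
            g_U,
            g_inhib,
            g_src,
            g_tgt,
            dir_code,
            dir_angle,
            conj_het,
            speed_run,
            heading_run,
            pos_run,
            net.place_bank.centers,
            np.zeros(net.place_bank.centers.shape[0]),
            net.place_bank.sigma,
            net.place_bank.amplitude,
            net.preset.drive["I0"],
            net.preset.drive["alpha"],
            net.preset.noise_sigma,
            config.settle_pulse_pA,
            int(round(config.settle_pulse_ms / dt)),
            start_pos[0],
            start_pos[1],
            20,
            net.tables.receptors["E_fast_exc"],
            net.tables.receptors["E_slow_exc"],
            net.tables.receptors["E_fast_inh"],
            net.tables.receptors["E_slow_inh"],
            ev_pop,
            ev_idx,
            ev_t,
            0,
            probe_pop,
            probe_idx,
            probe_v,
            probe_s,
            probe_is_target,
        )
        if config.record_spikes and n_events:
            chunks.append(
                (ev_pop[:n_events].copy(), ev_idx[:n_events].copy(), ev_t[:n_events].copy())
            )
        for name in pop_names:
            if not np.all(np.isfinite(states[name].v)):
                bad = int(np.flatnonzero(~np.isfinite(states[name].v))[0])
                raise SimulationError(
                    f"non-finite voltage (neuron {bad}, population {name!r}, step {step})"
                )

    times_ms: dict[str, np.ndarray] = {}
    indices: dict[str, np.ndarray] = {}
    if chunks:
        all_pop = np.concatenate([c[0] for c in chunks])
        all_idx = np.concatenate([c[1] for c in chunks])
        all_t = np.concatenate([c[2] for c in chunks])
    else:
        all_pop = np.empty(0, dtype=np.int8)
        all_idx = np.empty(0, dtype=np.int32)
        all_t = np.empty(0, dtype=np.float32)
    for name in pop_names:
        m = all_pop == pop_index[name]
        times_ms[name] = all_t[m].astype(np.float64)
        indices[name] = all_idx[m].astype(np.int64)
    record = SpikeRecord(times_ms=times_ms, indices=indices, duration_ms=n_run * dt)

    reversals = {
        "fast_exc": net.tables.receptors["E_fast_exc"],
        "slow_exc": net.tables.receptors["E_slow_exc"],
        "fast_inh": net.tables.receptors["E_fast_inh"],
        "slow_inh": net.tables.receptors["E_slow_inh"],
    }
    settle_ms = n_settle * dt
    probe_traces = []
    for q, (pop, nid, pos_rc) in enumerate(probes):
        v_trace = probe_v[q]
        currents: dict[str, np.ndarray] = {}
        for gi, g in enumerate(groups):
            if not probe_is_target[q, gi]:
                continue
            src = net.source_of[g.name]
            if g.inhibitory:
                currents[f"{src}/fast_inh"] = probe_s[q, gi, 0] * (
                    reversals["fast_inh"] - v_trace
                )
                currents[f"{src}/slow_inh"] = probe_s[q, gi, 1] * (
                    reversals["slow_inh"] - v_trace
                )
            else:
                currents[f"{src}/fast_exc"] = probe_s[q, gi, 0] * (
                    reversals["fast_exc"] - v_trace
                )
                currents[f"{src}/slow_exc"] = (
                    probe_s[q, gi, 1] * (reversals["slow_exc"] - v_trace) * mg_block(v_trace)
                )
        probe_traces.append(
            ProbeTrace(
                population=pop,
                neuron=nid,
                sheet_pos=pos_rc,
                t_ms=np.arange(n_ms_total) * 1.0 - settle_ms,
                v=v_trace,
                currents=currents,
            )
        )

    manifest = {
        "version": __version__,
        "preset": config.preset,
        "dt_ms": config.dt_ms,
        "settle_s": config.settle_s,
        "seed": config.seed,
        "backend": "numba",
        "duration_s": traj.duration,
        "populations": net.populations(),
        "im_overrides": config.im_overrides,
        "tm_overrides": config.tm_overrides,
        "n_edges": {g.name: g.n_edges for g in net.groups},
    }
    return SimResult(spikes=record, probes=probe_traces, manifest=manifest)
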