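"""Tsodyks-Markram conductance synapses with short-term plasticity.

Each connection group couples one presynaptic to one postsynaptic
population through a fast and a slow conductance channel (AMPA/NMDA for
excitatory groups, GABA_A/GABA_B for inhibitory ones).  On a presynaptic
spike the classical release update is applied,

    u <- u + U (1 - u),   R = u x,   x <- x - R,

and each receptor conductance of the targeted neurons is incremented by
``g * gain * weight * R``.  Between spikes the state relaxes with exact
exponential updates: u -> 0, x -> 1, s -> 0.

Because every edge of a presynaptic neuron shares that neuron's spike
history and the group's TM constants, the (u, x) pair is stored once per
presynaptic neuron; per-edge values are exposed through ``edge_u``/
``edge_x``.  Conductances are accumulated per postsynaptic neuron per
channel, which is what the membrane current needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .params import TMParams

__all__ = [
    "SynapseGroup",
    "tm_on_spike",
    "tm_decay",
    "synaptic_current",
    "mg_block",
    "DEFAULT_REVERSALS",
]

#: Reversal potentials (mV) per channel, simulator-default convention.
DEFAULT_REVERSALS = {
    "fast_exc": 0.0,
    "slow_exc": 0.0,
    "fast_inh": -70.0,
    "slow_inh": -90.0,
}


@dataclass
class SynapseGroup:
    """Sparse edge list with TM state and per-target conductances."""

    name: str
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    n_pre: int
    n_post: int
    params: TMParams
    inhibitory: bool = False
    gain: float = 1.0
    delay_ms: float = 1.0
    u: np.ndarray = field(init=False)
    x: np.ndarray = field(init=False)
    s_fast: np.ndarray = field(init=False)
    s_slow: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (self.pre.shape == self.post.shape == self.weight.shape):
            raise ConfigurationError(f"{self.name}: edge arrays must share one shape")
        if self.pre.size and (self.pre.min() < 0 or self.pre.max() >= self.n_pre):
            raise ConfigurationError(f"{self.name}: presynaptic index out of range")
        if self.post.size and (self.post.min() < 0 or self.post.max() >= self.n_post):
            raise ConfigurationError(f"{self.name}: postsynaptic index out of range")
        if np.any(self.weight < 0):
            raise ConfigurationError(f"{self.name}: weights must be non-negative")
        # CSR-like grouping of edges by presynaptic neuron.
        order = np.argsort(self.pre, kind="stable")
        self.pre = self.pre[order]
        self.post = self.post[order]
        self.weight = self.weight[order]
        self._indptr = np.searchsorted(self.pre, np.arange(self.n_pre + 1))
        self.u = np.zeros(self.n_pre)
        self.x = np.ones(self.n_pre)
        self.s_fast = np.zeros(self.n_post)
        self.s_slow = np.zeros(self.n_post)

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    @property
    def edge_u(self) -> np.ndarray:
        """Release state viewed per edge (edges inherit their source's u)."""
        return self.u[self.pre]

    @property
    def edge_x(self) -> np.ndarray:
        return self.x[self.pre]

    def edges_of(self, pre_indices: np.ndarray) -> np.ndarray:
        """Flat edge indices originating from the given presynaptic neurons."""
        chunks = [
            np.arange(self._indptr[i], self._indptr[i + 1]) for i in np.atleast_1d(pre_indices)
        ]
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)


def tm_on_spike(
    group: SynapseGroup,
    spiking_pre: np.ndarray,
    out_fast: np.ndarray | None = None,
    out_slow: np.ndarray | None = None,
) -> SynapseGroup:
    """Apply the TM release update for the given spiking presynaptic neurons.

    Conductance increments are added to the group's own channels, or to
    ``out_fast``/``out_slow`` when provided (the engine passes delay-line
    slots so that increments arrive after the conduction delay).
    """
    spiking_pre = np.atleast_1d(np.asarray(spiking_pre, dtype=np.int64))
    if spiking_pre.size == 0:
        return group
    if spiking_pre.min() < 0 or spiking_pre.max() >= group.n_pre:
        raise ConfigurationError(f"{group.name}: spiking index out of range")
    p = group.params
    u = group.u[spiking_pre]
    u += p.U * (1.0 - u)
    release = u * group.x[spiking_pre]
    group.u[spiking_pre] = u
    group.x[spiking_pre] -= release

    edges = group.edges_of(spiking_pre)
    if edges.size == 0:
        return group
    # Map each edge back to its source's release amount.
    rel_per_pre = np.zeros(group.n_pre)
    rel_per_pre[spiking_pre] = release
    amount = rel_per_pre[group.pre[edges]] * group.weight[edges] * group.gain
    posts = group.post[edges]
    tgt_fast = group.s_fast if out_fast is None else out_fast
    tgt_slow = group.s_slow if out_slow is None else out_slow
    np.add.at(tgt_fast, posts, p.g_fast * amount)
    np.add.at(tgt_slow, posts, p.g_slow * amount)
    return group


def tm_decay(group: SynapseGroup, dt: float) -> SynapseGroup:
    """Relax TM state and conductances over ``dt`` ms (exact exponentials)."""
    if dt <= 0:
        raise ConfigurationError(f"decay interval must be positive, got {dt}")
    p = group.params
    group.u *= np.exp(-dt / p.tau_u)
    group.x = 1.0 - (1.0 - group.x) * np.exp(-dt / p.tau_x)
    group.s_fast *= np.exp(-dt / p.tau_d_fast)
    group.s_slow *= np.exp(-dt / p.tau_d_slow)
    return group


def mg_block(v: np.ndarray | float) -> np.ndarray | float:
    """Voltage-dependent magnesium unblock factor for the NMDA channel."""
    z = ((np.asarray(v) + 80.0) / 60.0) ** 2
    return z / (1.0 + z)


def synaptic_current(
    conductances: dict[str, np.ndarray],
    v_post: np.ndarray | float,
    reversals: dict[str, float] | None = None,
) -> np.ndarray:
    """Total receptor current (pA): I = sum_channels s * (E_rev - v).

    ``conductances`` maps channel names (``fast_exc``, ``slow_exc``,
    ``fast_inh``, ``slow_inh``) to per-neuron conductance arrays in nS.
    The slow excitatory channel is scaled by the magnesium-block factor.
    """
    if reversals is None:
        reversals = DEFAULT_REVERSALS
    unknown = set(conductances) - set(DEFAULT_REVERSALS)
    if unknown:
        raise ConfigurationError(f"unknown synaptic channels: {sorted(unknown)}")
    v = np.asarray(v_post, dtype=np.float64)
    I = np.zeros_like(v, dtype=np.float64)
    for channel, s in conductances.items():
        drive = reversals[channel] - v
        if channel == "slow_exc":
            drive = drive * mg_block(v)
        I = I + np.asarray(s) * drive
    return I
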