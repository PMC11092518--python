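"""Izhikevich neuron dynamics for all populations of the network.

The nine-parameter formulation is integrated with forward Euler; the
voltage equation is advanced in two half-steps per time step (the common
SNN-engine practice) which keeps spike onsets stable at dt = 0.5 ms:

    C dv/dt = k (v - Vr)(v - Vt) - u + I
      du/dt = a (b (v - Vr) - u)

with the reset rule v >= Vpeak  ->  v <- Vreset, u <- u + d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SimulationError
from .params import IzhikevichParams, ModelTables, load_tables

__all__ = ["NeuronState", "izh_step", "make_population", "V_FLOOR"]

#: Hyperpolarization floor (mV) guarding forward-Euler stability.
V_FLOOR = -100.0


@dataclass
class NeuronState:
    """Membrane voltage ``v`` (mV) and recovery variable ``u`` (pA) arrays."""

    v: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.v.shape != self.u.shape:
            raise ConfigurationError("v and u must have identical shapes")

    def __len__(self) -> int:
        return self.v.size

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy())


def izh_step(
    state: NeuronState,
    params: IzhikevichParams,
    I_input: np.ndarray | float,
    dt: float,
    out: NeuronState | None = None,
    validate: bool = True,
) -> tuple[NeuronState, np.ndarray]:
    """Advance the population one time step; return (new state, spike flags).

    ``I_input`` is the total injected current per neuron in pA.  Neurons
    whose voltage reaches ``Vpeak`` during the step are flagged and reset.
    Pass ``out=state`` to update in place (used by the simulation engine,
    which also sets ``validate=False`` and audits finiteness periodically
    instead of every step).
    """
    if not 0.0 < dt <= 1.0:
        raise ConfigurationError(f"dt must lie in (0, 1] ms, got {dt}")
    I = np.broadcast_to(np.asarray(I_input, dtype=np.float64), state.v.shape)
    if validate:
        if not np.all(np.isfinite(I)):
            bad = int(np.flatnonzero(~np.isfinite(I))[0])
            raise SimulationError(f"non-finite input current at neuron index {bad}")
        if not (np.all(np.isfinite(state.v)) and np.all(np.isfinite(state.u))):
            bad = int(np.flatnonzero(~(np.isfinite(state.v) & np.isfinite(state.u)))[0])
            raise SimulationError(f"non-finite membrane state at neuron index {bad}")

    if out is None:
        out = state.copy()
    elif out is not state:
        out.v[:] = state.v
        out.u[:] = state.u
    v, u = out.v, out.u

    # Neurons already at or beyond the cutoff spike immediately: reset
    # without integrating (their dynamics past Vpeak are not defined).
    pre_spiked = v >= params.Vpeak
    u_entry = u[pre_spiked]

    half = 0.5 * dt / params.C
    # Two half-steps for v with u frozen, then one full step for u.  The
    # voltage is clamped to [V_FLOOR, Vpeak]: no receptor reversal lies
    # below -90 mV, so the floor only guards the quadratic term against
    # Euler overshoot under extreme hyperpolarizing conductance.
    for _ in range(2):
        dv = params.k * (v - params.Vr) * (v - params.Vt) - u + I
        v += half * dv
        np.clip(v, V_FLOOR, params.Vpeak, out=v)
    u += dt * params.a * (params.b * (v - params.Vr) - u)

    spiked = v >= params.Vpeak
    if spiked.any():
        v[spiked] = params.Vreset
        u[spiked] += params.d
    if pre_spiked.any():
        u[pre_spiked] = u_entry + params.d
    return out, spiked


def make_population(
    name: str,
    count: int,
    params: IzhikevichParams | None = None,
    tables: ModelTables | None = None,
) -> NeuronState:
    """Create ``count`` neurons of type ``name`` at the resting fixed point.

    When ``params`` is omitted the packaged table row for ``name`` is used;
    an unknown name is a configuration error.
    """
    if count <= 0:
        raise ConfigurationError(f"population size must be positive, got {count}")
    if params is None:
        tables = tables or load_tables()
        params = tables.neuron(name)
    v = np.full(count, params.Vr, dtype=np.float64)
    u = np.zeros(count, dtype=np.float64)
    return NeuronState(v, u)
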