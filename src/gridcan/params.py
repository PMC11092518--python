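"""Parameter tables: Izhikevich neuron and Tsodyks-Markram synapse constants.

All quantities use the pF / mV / pA / nS / ms unit system, so the packaged
table values are consumed verbatim with no conversion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = [
    "IzhikevichParams",
    "TMParams",
    "ModelTables",
    "load_tables",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Nine-parameter Izhikevich excitability model for one neuron type.

    ``C`` capacitance (pF); ``k`` voltage-curvature gain (nS/mV);
    ``Vr``/``Vt`` resting and threshold voltages (mV); ``a`` recovery
    rate (1/ms); ``b`` recovery coupling (nS); ``Vpeak`` spike cutoff
    (mV); ``Vreset`` post-spike reset voltage (mV); ``d`` post-spike
    recovery increment (pA).
    """

    C: float
    k: float
    Vr: float
    Vt: float
    a: float
    b: float
    Vpeak: float
    Vreset: float
    d: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError(f"capacitance must be positive, got C={self.C}")
        if not (self.Vr < self.Vt < self.Vpeak):
            raise ConfigurationError(
                f"require Vr < Vt < Vpeak, got {self.Vr}, {self.Vt}, {self.Vpeak}"
            )
        if self.Vreset >= self.Vpeak:
            raise ConfigurationError("post-spike reset must lie below the spike cutoff")
        if self.a < 0:
            raise ConfigurationError(f"recovery rate a must be >= 0, got {self.a}")

    def replace(self, **kwargs: float) -> "IzhikevichParams":
        values = {f: getattr(self, f) for f in self.__dataclass_fields__}
        values.update(kwargs)
        return IzhikevichParams(**values)


@dataclass(frozen=True)
class TMParams:
    """Tsodyks-Markram short-term-plasticity synapse constants.

    Fast channels are AMPA/GABA_A (``g_fast``, ``tau_d_fast``); slow
    channels are NMDA/GABA_B (``g_slow``, ``tau_d_slow``).  ``U`` is the
    baseline release fraction, ``tau_u`` the facilitation decay and
    ``tau_x`` the depression-recovery time constant.
    """

    g_fast: float
    tau_d_fast: float
    U: float
    tau_u: float
    tau_x: float
    g_slow: float
    tau_d_slow: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= 1.0:
            raise ConfigurationError(f"release fraction U must be in [0, 1], got {self.U}")
        for name in ("tau_d_fast", "tau_u", "tau_x", "tau_d_slow"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.g_fast < 0 or self.g_slow < 0:
            raise ConfigurationError("conductance gains must be non-negative")

    def replace(self, **kwargs: float) -> "TMParams":
        values = {f: getattr(self, f) for f in self.__dataclass_fields__}
        values.update(kwargs)
        return TMParams(**values)


@dataclass
class ModelTables:
    """Packaged parameter tables plus scale presets and receptor constants."""

    populations: dict[str, IzhikevichParams]
    counts: dict[str, int]
    connections: dict[str, TMParams]
    receptors: dict[str, float]
    arena: dict[str, float]
    presets: dict[str, dict]
    realism_bounds: dict[str, float] = field(default_factory=dict)

    def neuron(self, name: str) -> IzhikevichParams:
        try:
            return self.populations[name]
        except KeyError:
            raise ConfigurationError(f"unknown population {name!r}") from None

    def synapse(self, name: str) -> TMParams:
        try:
            return self.connections[name]
        except KeyError:
            raise ConfigurationError(f"unknown connection {name!r}") from None

    def preset(self, name: str) -> dict:
        try:
            return copy.deepcopy(self.presets[name])
        except KeyError:
            raise ConfigurationError(f"unknown scale preset {name!r}") from None


def load_tables(path: str | Path | None = None) -> ModelTables:
    """Load the parameter tables from the packaged YAML (or a user file)."""
    if path is None:
        text = resources.files("gridcan.data").joinpath("tables.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    populations: dict[str, IzhikevichParams] = {}
    counts: dict[str, int] = {}
    for name, row in raw["populations"].items():
        row = dict(row)
        counts[name] = int(row.pop("count"))
        populations[name] = IzhikevichParams(**row)
    connections = {name: TMParams(**row) for name, row in raw["connections"].items()}
    return ModelTables(
        populations=populations,
        counts=counts,
        connections=connections,
        receptors=dict(raw["receptors"]),
        arena=dict(raw["arena"]),
        presets=dict(raw["presets"]),
        realism_bounds=dict(raw.get("realism_bounds", {})),
    )
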