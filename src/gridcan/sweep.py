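"""Parameter-robustness sweeps: grid score over 9 x 9 parameter grids.

Reproduces the robustness analysis: vary a pair of stellate Izhikevich
parameters (e.g. b and d) or stellate->interneuron TM parameters (g,
tau_d, tau_u, tau_x — applied jointly to all three glutamatergic
stellate->IN connections), run a reduced simulation for every grid
point, and score a probed stellate.  Three region masks summarize the
result: grid score above the 0.2 acceptability threshold, biologically
realistic parameter windows, and their intersection.

The realism windows are shipped configuration constants (relative
half-widths around the table values); the experimental firing-pattern
fits behind them are not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import STELLATE, IN_TYPES, SimConfig, run_simulation
from .errors import ConfigurationError
from .params import ModelTables, load_tables
from .spatial import GRID_SCORE_THRESHOLD, grid_metrics
from .stimulus import Trajectory, synthesize_trajectory
from .topology import ScalePreset

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "threshold_region",
    "IM_PARAMS",
    "TM_PARAMS",
]

IM_PARAMS = ("C", "k", "Vr", "Vt", "a", "b", "Vpeak", "Vreset", "d")
TM_PARAMS = ("g_fast", "tau_d_fast", "U", "tau_u", "tau_x", "g_slow")

#: The reset voltage appears in robustness plots under the name "V_min";
#: both names address the same parameter.
IM_ALIASES = {"Vmin": "Vreset", "V_min": "Vreset", "c": "Vreset", "g": "g_fast", "tau_d": "tau_d_fast"}

STELLATE_TO_IN = tuple(f"{STELLATE} to {name}" for name in IN_TYPES)


def _canonical(name: str) -> str:
    return IM_ALIASES.get(name, name)


@dataclass
class SweepSpec:
    """A 9 x 9 sweep over two parameters around their table values.

    Each parameter is either a stellate Izhikevich parameter or a TM
    parameter of the stellate->IN connections (varied jointly across the
    three IN types).  ``rel_range`` sets the sweep half-width relative
    to the base value; ``n_values`` per axis defaults to nine, with the
    base value always included.
    """

    params: tuple[str, str]
    n_values: int = 9
    rel_range: float = 0.5
    preset: str = "desk"
    duration_s: float = 180.0
    seed: int = 0
    traj_seed: int = 1
    probe: tuple[int, int] | None = None
    tables: ModelTables | None = None

    def __post_init__(self) -> None:
        self.params = tuple(_canonical(p) for p in self.params)
        for p in self.params:
            if p not in IM_PARAMS and p not in TM_PARAMS:
                raise ConfigurationError(f"unknown sweep parameter {p!r}")
        if self.n_values < 2 or self.n_values % 2 == 0:
            raise ConfigurationError(
                "n_values must be odd (>= 3) so the base value is on the grid"
            )

    def resolve_tables(self) -> ModelTables:
        return self.tables if self.tables is not None else load_tables()

    def kind(self, param: str) -> str:
        return "im" if param in IM_PARAMS else "tm"

    def base_value(self, param: str) -> float:
        tables = self.resolve_tables()
        if self.kind(param) == "im":
            return getattr(tables.neuron(STELLATE), param)
        return getattr(tables.synapse(STELLATE_TO_IN[0]), param)

    def axis_values(self, param: str) -> np.ndarray:
        """Nine values spanning base * (1 -/+ rel_range), base included."""
        base = self.base_value(param)
        if base == 0.0:
            # Zero-valued base (e.g. stellate d): sweep an absolute range
            # derived from the recovery-increment scale of Table 1.
            span = 100.0
            return np.linspace(0.0, span, self.n_values)
        return base * np.linspace(1 - self.rel_range, 1 + self.rel_range, self.n_values)

    def realism_window(self, param: str) -> tuple[float, float]:
        tables = self.resolve_tables()
        rel = tables.realism_bounds.get(
            "im_rel" if self.kind(param) == "im" else "tm_rel", 0.25
        )
        base = self.base_value(param)
        if base == 0.0:
            return (0.0, 50.0)
        lo, hi = base * (1 - rel), base * (1 + rel)
        return (min(lo, hi), max(lo, hi))


@dataclass
class SweepResult:
    spec_params: tuple[str, str]
    values_x: np.ndarray
    values_y: np.ndarray
    scores: np.ndarray  # (ny, nx), NaN where the run failed or undefined
    threshold_mask: np.ndarray
    realism_mask: np.ndarray
    intersection_mask: np.ndarray
    threshold: float = GRID_SCORE_THRESHOLD


def threshold_region(scores: np.ndarray, threshold: float = GRID_SCORE_THRESHOLD) -> np.ndarray:
    """Boolean mask of grid scores at or above the acceptability threshold.

    Missing (NaN) entries are excluded from the region.
    """
    scores = np.asarray(scores, dtype=np.float64)
    return np.isfinite(scores) & (scores >= threshold)


def _default_runner(spec: SweepSpec, traj: Trajectory) -> Callable[[dict, dict], float]:
    def runner(im_over: dict, tm_over: dict) -> float:
        cfg = SimConfig(
            preset=spec.preset,
            seed=spec.seed,
            im_overrides={STELLATE: im_over} if im_over else {},
            tm_overrides={name: tm_over for name in STELLATE_TO_IN} if tm_over else {},
            tables=spec.tables,
        )
        res = run_simulation(cfg, traj)
        from .engine import Network

        layout = Network(cfg).layouts[STELLATE]
        r, c = spec.probe if spec.probe else (layout.rows // 2, layout.cols // 2)
        spikes = res.spikes.cell_spike_times_s(STELLATE, layout.index_of(r, c))
        return grid_metrics(spikes, traj).score

    return runner


def run_sweep(
    spec: SweepSpec,
    traj: Trajectory | None = None,
    score_fn: Callable[[dict, dict], float] | None = None,
) -> SweepResult:
    """Run the 81 reduced simulations of a two-parameter sweep.

    Every grid point reuses the same trajectory and seed, so score
    differences reflect only the parameter changes.  ``score_fn`` may
    replace the simulation+scoring pipeline (used for fast mask logic
    tests); it receives (im_overrides, tm_overrides) and returns a
    score.  Failed runs are recorded as NaN, never as silent zeros.
    """
    if traj is None:
        traj = synthesize_trajectory(spec.duration_s, seed=spec.traj_seed)
    if score_fn is None:
        score_fn = _default_runner(spec, traj)
    px, py = spec.params
    xs = spec.axis_values(px)
    ys = spec.axis_values(py)
    scores = np.full((ys.size, xs.size), np.nan)
    for iy, vy in enumerate(ys):
        for ix, vx in enumerate(xs):
            im_over: dict[str, float] = {}
            tm_over: dict[str, float] = {}
            for param, value in ((px, vx), (py, vy)):
                (im_over if spec.kind(param) == "im" else tm_over)[param] = float(value)
            try:
                scores[iy, ix] = score_fn(im_over, tm_over)
            except Exception:
                scores[iy, ix] = np.nan
    t_mask = threshold_region(scores)
    rx = spec.realism_window(px)
    ry = spec.realism_window(py)
    realism = (
        ((xs >= rx[0]) & (xs <= rx[1]))[None, :]
        & ((ys >= ry[0]) & (ys <= ry[1]))[:, None]
    )
    return SweepResult(
        spec_params=spec.params,
        values_x=xs,
        values_y=ys,
        scores=scores,
        threshold_mask=t_mask,
        realism_mask=realism,
        intersection_mask=t_mask & realism,
    )
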