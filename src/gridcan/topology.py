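"""Neural-sheet layouts and center-surround (CS) connectivity.

Populations live on 2-D sheets with periodic boundaries.  The stellate
(grid-cell) sheet uses a *twisted* torus: with ``rows = cols = N`` the
wrap vectors are e1 = (N, 0) and e2 = (N/2, N*sqrt(3)/2), which are equal
in length and 60 degrees apart.  The quotient lattice is therefore
hexagonal, so a linear arena-to-sheet phase map turns each cell's firing
locations into an equilateral triangular (hexagonal) grid in the arena —
the standard construction for single/multi-bump attractor sheets.  A
plain square torus is available via ``twist=False``.

Bump creation and movement follow the classic inhibitory-CAN recipe:
stellates excite interneurons (INs) inside a small disc displaced by the
stellate's preferred-direction offset, and each IN inhibits all stellates
in an annulus around its own mapped position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .params import ModelTables, TMParams, load_tables
from .synapses import SynapseGroup

__all__ = [
    "SheetLayout",
    "DirectionAssignment",
    "ScalePreset",
    "PhaseMap",
    "assign_preferred_directions",
    "build_cs_connectivity",
    "build_one_to_one",
    "build_phase_projection",
    "connectivity_stats",
    "torus_displacement",
    "torus_distance",
]

DIRECTION_VECTORS = {
    "N": np.array([0.0, 1.0]),
    "E": np.array([1.0, 0.0]),
    "S": np.array([0.0, -1.0]),
    "W": np.array([-1.0, 0.0]),
}

_ROW_HEIGHT_TWISTED = np.sqrt(3.0) / 2.0


@dataclass
class SheetLayout:
    """A population arranged row-major on a ``rows`` x ``cols`` grid.

    ``count`` may be smaller than ``rows * cols`` (the grid is filled
    row-major and the last row may be partial), which accommodates
    census-derived population sizes such as 834.  ``span`` is the
    physical sheet width in stellate sheet units; layouts of different
    populations are mapped into common coordinates by uniform scaling.
    """

    rows: int
    cols: int
    count: int | None = None
    span: float | None = None
    twist: bool = True

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ConfigurationError("sheet dimensions must be positive")
        if self.count is None:
            self.count = self.rows * self.cols
        if self.count <= 0 or self.count > self.rows * self.cols:
            raise ConfigurationError(
                f"count {self.count} does not fit a {self.rows}x{self.cols} sheet"
            )
        if self.span is None:
            self.span = float(self.cols)

    @classmethod
    def for_count(
        cls, count: int, span: float | None = None, twist: bool = True
    ) -> "SheetLayout":
        """Near-square layout for an arbitrary population size."""
        rows = int(np.floor(np.sqrt(count)))
        cols = int(np.ceil(count / rows))
        return cls(rows=rows, cols=cols, count=count, span=span, twist=twist)

    @property
    def row_height(self) -> float:
        return _ROW_HEIGHT_TWISTED if self.twist else 1.0

    @property
    def grid_coords(self) -> np.ndarray:
        """Integer (row, col) sheet coordinates, shape (count, 2)."""
        idx = np.arange(self.count)
        return np.stack([idx // self.cols, idx % self.cols], axis=1)

    def positions(self) -> np.ndarray:
        """Physical (x, y) positions in common sheet units, shape (count, 2)."""
        rc = self.grid_coords
        x = (rc[:, 1] + 0.5) * (self.span / self.cols)
        y = (rc[:, 0] + 0.5) * (self.span / self.rows) * self.row_height
        return np.stack([x, y], axis=1)

    def wrap_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Lattice vectors identifying opposite sheet edges."""
        width = self.span
        height = self.rows * (self.span / self.rows) * self.row_height
        if self.twist:
            return np.array([width, 0.0]), np.array([width / 2.0, height])
        return np.array([width, 0.0]), np.array([0.0, height])

    def index_of(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ConfigurationError(f"sheet coordinate ({row}, {col}) out of range")
        idx = row * self.cols + col
        if idx >= self.count:
            raise ConfigurationError(f"sheet coordinate ({row}, {col}) is unpopulated")
        return idx

    def center_index(self) -> int:
        return self.index_of(self.rows // 2, self.cols // 2)


def torus_displacement(
    p: np.ndarray, q: np.ndarray, layout: SheetLayout
) -> np.ndarray:
    """Minimal-image displacement q - p on the (possibly twisted) torus."""
    e1, e2 = layout.wrap_vectors()
    d = np.asarray(q, dtype=np.float64) - np.asarray(p, dtype=np.float64)
    best = None
    best_norm = None
    # The twisted torus shifts x by half a width on every y-wrap, so the
    # minimal image can need two x-wraps when combined with k2 = +/-1.
    for k1 in (-2, -1, 0, 1, 2):
        for k2 in (-1, 0, 1):
            cand = d + k1 * e1 + k2 * e2
            norm = np.sum(cand**2, axis=-1)
            if best is None:
                best, best_norm = cand.copy(), norm
            else:
                better = norm < best_norm
                best = np.where(better[..., None], cand, best)
                best_norm = np.minimum(norm, best_norm)
    return best


def torus_distance(p: np.ndarray, q: np.ndarray, layout: SheetLayout) -> np.ndarray:
    return np.sqrt(np.sum(torus_displacement(p, q, layout) ** 2, axis=-1))


@dataclass
class DirectionAssignment:
    """Cardinal preferred direction per grid cell."""

    labels: np.ndarray  # array of 'N' / 'E' / 'S' / 'W'
    vectors: np.ndarray  # (count, 2) unit vectors

    def counts(self) -> dict[str, int]:
        labels, n = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))


def assign_preferred_directions(layout: SheetLayout) -> DirectionAssignment:
    """Deterministic 2x2 tiling of preferred directions (N,E / W,S).

    Each cardinal direction covers exactly a quarter of the sheet; the
    vector sum over any 2x2 tile vanishes, so the assignment injects no
    net directional bias.
    """
    if layout.rows % 2 or layout.cols % 2:
        raise ConfigurationError("direction tiling requires even sheet dimensions")
    rc = layout.grid_coords
    tile = np.array([["N", "E"], ["W", "S"]])
    labels = tile[rc[:, 0] % 2, rc[:, 1] % 2]
    vectors = np.stack([DIRECTION_VECTORS[l] for l in labels])
    return DirectionAssignment(labels=labels, vectors=vectors)


@dataclass
class ScalePreset:
    """Grid-scale preset: CS geometry, drive gains and the arena phase map."""

    name: str
    stellate_sheet: tuple[int, int]
    in_counts: tuple[int, int, int]
    bump_lattice: float
    cs_inner: float
    cs_outer: float
    cs_disc_radius: float
    direction_offset: float
    spacing_cm: float
    orientation_deg: float
    gain: dict[str, float]
    drive: dict[str, float]
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.cs_inner < self.cs_outer:
            raise ConfigurationError(
                f"preset {self.name!r}: require 0 <= inner < outer annulus radii, "
                f"got [{self.cs_inner}, {self.cs_outer})"
            )
        if self.direction_offset < 0:
            raise ConfigurationError(f"preset {self.name!r}: offset must be >= 0")

    @classmethod
    def from_tables(cls, name: str, tables: ModelTables | None = None) -> "ScalePreset":
        tables = tables or load_tables()
        raw = tables.preset(name)
        return cls(
            name=name,
            stellate_sheet=tuple(raw.pop("stellate_sheet")),
            in_counts=tuple(raw.pop("in_counts")),
            **raw,
        )

    def stellate_layout(self, twist: bool = True) -> SheetLayout:
        rows, cols = self.stellate_sheet
        return SheetLayout(rows=rows, cols=cols, twist=twist)

    def in_layout(self, which: int = 0, twist: bool = True) -> SheetLayout:
        return SheetLayout.for_count(
            self.in_counts[which], span=float(self.stellate_sheet[1]), twist=twist
        )


class PhaseMap:
    """Linear arena-to-sheet map fixing grid spacing and orientation.

    Arena position (cm) maps to sheet phase via ``phi = s R(theta) pos``
    with ``s = bump_lattice / spacing_cm``; a displacement of one arena
    grid spacing moves the sheet pattern by exactly one bump-lattice
    period, so each cell fires on a hexagonal arena lattice with the
    preset's spacing and orientation.
    """

    def __init__(self, preset: ScalePreset, layout: SheetLayout):
        self.layout = layout
        s = preset.bump_lattice / preset.spacing_cm
        th = np.deg2rad(preset.orientation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        self.matrix = s * rot

    def to_sheet(self, pos_cm: np.ndarray) -> np.ndarray:
        """Map arena positions (cm) to physical sheet coordinates."""
        return np.asarray(pos_cm, dtype=np.float64) @ self.matrix.T

    def sheet_velocity(self, vel_cm_s: np.ndarray) -> np.ndarray:
        return self.to_sheet(vel_cm_s)


def build_cs_connectivity(
    grid_layout: SheetLayout,
    in_layout: SheetLayout,
    preset: ScalePreset,
    directions: DirectionAssignment,
    e2i_params: TMParams,
    i2e_params: TMParams,
    in_name: str = "IN",
) -> tuple[SynapseGroup, SynapseGroup]:
    """Build the stellate->IN disc and IN->stellate annulus groups.

    Stellate ``i`` (preferred direction e_i) targets every IN whose mapped
    sheet position lies within ``cs_disc_radius`` of the stellate's
    position displaced by ``direction_offset * e_i``; each IN inhibits
    all stellates at torus distance in ``[cs_inner, cs_outer)``.  Weights
    are uniform (1.0); distances use the twisted-torus metric of the
    stellate sheet.
    """
    if preset.cs_inner >= preset.cs_outer:
        raise ConfigurationError(
            f"preset {preset.name!r}: empty CS annulus [{preset.cs_inner}, {preset.cs_outer})"
        )
    sp = grid_layout.positions()
    ip = in_layout.positions()

    centers = sp + preset.direction_offset * directions.vectors
    # Distances snapped to 1e-9: boundary ties (lattice distances landing
    # exactly on a radius) must not break on float rounding, which would
    # make geometrically equivalent cells differ in degree.
    d_e2i = np.round(torus_distance(centers[:, None, :], ip[None, :, :], grid_layout), 9)
    pre_e, post_e = np.nonzero(d_e2i <= preset.cs_disc_radius)
    e2i = SynapseGroup(
        name=f"MEC LII Stellate to {in_name}",
        pre=pre_e,
        post=post_e,
        weight=np.ones(pre_e.size),
        n_pre=grid_layout.count,
        n_post=in_layout.count,
        params=e2i_params,
        inhibitory=False,
        gain=preset.gain.get("e2i", 1.0),
    )

    d_i2e = np.round(torus_distance(ip[:, None, :], sp[None, :, :], grid_layout), 9)
    pre_i, post_i = np.nonzero((d_i2e >= preset.cs_inner) & (d_i2e < preset.cs_outer))
    if pre_i.size == 0:
        raise ConfigurationError(
            f"preset {preset.name!r}: CS annulus produced no IN->stellate edges"
        )
    i2e = SynapseGroup(
        name=f"{in_name} to MEC LII Stellate",
        pre=pre_i,
        post=post_i,
        weight=np.ones(pre_i.size),
        n_pre=in_layout.count,
        n_post=grid_layout.count,
        params=i2e_params,
        inhibitory=True,
        gain=preset.gain.get("i2e", 1.0),
    )
    return e2i, i2e


def build_one_to_one(
    src_layout: SheetLayout,
    dst_layout: SheetLayout,
    params: TMParams,
    name: str = "one-to-one",
    gain: float = 1.0,
) -> SynapseGroup:
    """Bijective index-matched projection (every in/out-degree exactly 1)."""
    if src_layout.count != dst_layout.count:
        raise ConfigurationError(
            f"{name}: one-to-one requires equal sizes, got "
            f"{src_layout.count} vs {dst_layout.count}"
        )
    idx = np.arange(src_layout.count)
    return SynapseGroup(
        name=name,
        pre=idx,
        post=idx.copy(),
        weight=np.ones(idx.size),
        n_pre=src_layout.count,
        n_post=dst_layout.count,
        params=params,
        inhibitory=False,
        gain=gain,
    )


def build_phase_projection(
    src_layout: SheetLayout,
    grid_layout: SheetLayout,
    centers_cm: np.ndarray,
    phase_map: PhaseMap,
    params: TMParams,
    name: str = "CA1 Pyramidal to MEC LII Stellate",
    gain: float = 1.0,
) -> SynapseGroup:
    """Wire each source cell to a stellate at the phase of its arena anchor.

    Used for the place-cell (CA1) drift-correction pathway: place cell j
    with field center c_j excites the stellate whose sheet position is
    nearest (torus metric) to ``phase_map.to_sheet(c_j)``.  Presets pair
    the phase-map gain with the sheet span so the arena image wraps the
    whole sheet: every stellate then receives direct pinning input when
    the animal crosses the matching part of the arena.  Out-degree is
    exactly 1; in-degree varies with the wrapping of the phase map.
    """
    if centers_cm.shape[0] != src_layout.count:
        raise ConfigurationError(f"{name}: one anchor per source cell required")
    phases = phase_map.to_sheet(centers_cm)
    d = torus_distance(phases[:, None, :], grid_layout.positions()[None, :, :], grid_layout)
    post = np.argmin(d, axis=1)
    pre = np.arange(src_layout.count)
    return SynapseGroup(
        name=name,
        pre=pre,
        post=post,
        weight=np.ones(pre.size),
        n_pre=src_layout.count,
        n_post=grid_layout.count,
        params=params,
        inhibitory=False,
        gain=gain,
    )


@dataclass
class ConnectivityStats:
    out_mean: float
    out_sd: float
    in_mean: float
    in_sd: float
    n_edges: int


def connectivity_stats(group: SynapseGroup) -> ConnectivityStats:
    """Mean and SD of out-degree (per source) and in-degree (per target)."""
    if group.n_edges == 0:
        raise ConfigurationError(f"{group.name}: empty synapse group")
    out_deg = np.bincount(group.pre, minlength=group.n_pre)
    in_deg = np.bincount(group.post, minlength=group.n_post)
    return ConnectivityStats(
        out_mean=float(out_deg.mean()),
        out_sd=float(out_deg.std()),
        in_mean=float(in_deg.mean()),
        in_sd=float(in_deg.std()),
        n_edges=group.n_edges,
    )
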