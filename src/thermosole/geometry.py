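"""Voxelized foot-insole-shoe domain, lesion embedding and sensor layout.

Coordinate convention
---------------------
The grid is a structured box.  ``x`` runs along the foot (heel at x=0,
toes at x=length), ``y`` across it, and ``z`` increases *downward*: z=0 at
the deep (proximal) muscle face, the plantar skin surface at the cumulative
tissue thickness, then the insole stack and shoe sole, ending at the floor
face.  Lesion depths are measured from the plantar skin surface to the
lesion center, i.e. depth d corresponds to z = skin_z - d.

The foot may cover only part of the insole footprint: with a
``contact_patch`` the tissue stack occupies a rectangular sub-region and
cells above the insole outside that patch are void (exposed to the
environment).  Without a patch the tissue spans the whole footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import LESION, LayerSpec, MaterialProps

__all__ = [
    "GridResolution",
    "DomainGrid",
    "LesionSpec",
    "SensorLayout",
    "build_domain",
    "embed_lesion",
    "default_sensor_layout",
    "AIR",
]

#: Layer id of void (no material; exposed to the environment).
AIR = -1


@dataclass(frozen=True)
class GridResolution:
    """Discretization parameters.

    dx, dy : lateral cell size, m (default 2 mm).
    dz_fine : vertical target spacing in the near-skin tissue band, m.
    fine_band : tissue depth range below the skin surface resolved at
        ``dz_fine`` (covers all published lesion depths).
    dz_coarse : vertical target elsewhere (deep muscle, thick insole layers).
    min_cells_per_layer : every physical layer spans at least this many cells.
    """

    dx: float = 2.0e-3
    dy: float = 2.0e-3
    dz_fine: float = 0.5e-3
    fine_band: float = 12.0e-3
    dz_coarse: float = 2.5e-3
    min_cells_per_layer: int = 3

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz_fine", "fine_band", "dz_coarse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"resolution parameter {name} must be > 0")
        if self.min_cells_per_layer < 1:
            raise ValueError("min_cells_per_layer must be >= 1")


@dataclass
class DomainGrid:
    """Structured grid with per-cell layer assignment.

    ``cell_layer`` holds an integer per cell indexing into ``layers``
    (AIR = -1 marks void cells excluded from the solve).  Layer interfaces
    coincide exactly with grid lines, so per-layer thicknesses are
    reproduced to machine precision.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    z_edges: np.ndarray
    cell_layer: np.ndarray  # (nx, ny, nz) int
    layers: list[LayerSpec]
    is_tissue_layer: list[bool]
    skin_z: float  # z of the tissue/insole interface (sock plane)
    footprint: tuple[float, float]
    contact_patch: tuple[float, float, float, float] | None = None
    layer_z_spans: list[tuple[float, float]] = field(default_factory=list)

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell_layer.shape

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def active(self) -> np.ndarray:
        return self.cell_layer >= 0

    def cell_volumes(self) -> np.ndarray:
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def material_of(self, layer_id: int) -> MaterialProps:
        return self.layers[layer_id].material

    def cell_property(self, getter) -> np.ndarray:
        """Per-cell array of ``getter(material)``; 0 for void cells."""
        table = np.array(
            [getter(spec.material) for spec in self.layers], dtype=float
        )
        out = np.zeros(self.shape, dtype=float)
        act = self.active
        out[act] = table[self.cell_layer[act]]
        return out

    def layer_mask(self, name: str) -> np.ndarray:
        ids = [i for i, sp in enumerate(self.layers) if sp.material.name == name]
        return np.isin(self.cell_layer, ids)

    def layer_names(self) -> list[str]:
        return [sp.material.name for sp in self.layers]

    @property
    def skin_face_index(self) -> int:
        """Index of the z grid line at the tissue/insole (sock) interface."""
        return int(np.argmin(np.abs(self.z_edges - self.skin_z)))

    @property
    def has_insole(self) -> bool:
        return any(not t for t in self.is_tissue_layer)

    @property
    def insole_top_cell_index(self) -> int:
        """z index of the first cell below the skin interface (insole top).

        For a tissue-only grid this falls back to the deepest cell layer,
        i.e. the plantar contact surface itself.
        """
        return min(self.skin_face_index, self.shape[2] - 1)

    def copy(self) -> "DomainGrid":
        return replace(
            self,
            cell_layer=self.cell_layer.copy(),
            layers=list(self.layers),
            is_tissue_layer=list(self.is_tissue_layer),
            layer_z_spans=list(self.layer_z_spans),
        )


def _segment_edges(z0: float, z1: float, target: float) -> np.ndarray:
    n = max(1, math.ceil((z1 - z0) / target - 1e-12))
    return np.linspace(z0, z1, n + 1)


def _layer_z_edges(
    z0: float, z1: float, res: GridResolution, fine_from: float | None
) -> np.ndarray:
    """Subdivide one layer [z0, z1], refining below ``fine_from`` (if given)."""
    if fine_from is None or fine_from >= z1:
        edges = _segment_edges(z0, z1, res.dz_coarse)
    elif fine_from <= z0:
        edges = _segment_edges(z0, z1, res.dz_fine)
    else:
        coarse = _segment_edges(z0, fine_from, res.dz_coarse)
        fine = _segment_edges(fine_from, z1, res.dz_fine)
        edges = np.concatenate([coarse, fine[1:]])
    while len(edges) - 1 < res.min_cells_per_layer:
        # split the widest cell until the minimum count is met
        i = int(np.argmax(np.diff(edges)))
        edges = np.insert(edges, i + 1, 0.5 * (edges[i] + edges[i + 1]))
    return edges


def build_domain(
    tissue_layers: list[LayerSpec],
    insole_layers: list[LayerSpec] | None = None,
    footprint: tuple[float, float] = (0.26, 0.09),
    resolution: GridResolution | None = None,
    contact_patch: tuple[float, float, float, float] | None = None,
) -> DomainGrid:
    """Build the layered slab domain.

    ``tissue_layers`` is ordered top (deep muscle) to bottom (epidermis);
    ``insole_layers`` continues top (foot side) to bottom (floor side).
    Grid lines are placed on every layer interface, so configured
    thicknesses are honored exactly.  With a ``contact_patch`` the tissue
    occupies only that (x0, x1, y0, y1) rectangle of the footprint.
    """
    if not tissue_layers:
        raise ValueError("at least one tissue layer is required")
    insole_layers = insole_layers or []
    res = resolution or GridResolution()
    length, width = footprint
    if length <= 0 or width <= 0:
        raise ValueError("footprint must be positive")
    if length < 2 * res.dx or width < 2 * res.dy:
        raise ValueError("footprint smaller than two lateral cells")

    nx = max(2, round(length / res.dx))
    ny = max(2, round(width / res.dy))
    x_edges = np.linspace(0.0, length, nx + 1)
    y_edges = np.linspace(0.0, width, ny + 1)

    layers = list(tissue_layers) + list(insole_layers)
    is_tissue = [True] * len(tissue_layers) + [False] * len(insole_layers)
    skin_z = sum(sp.thickness for sp in tissue_layers)
    fine_from = skin_z - res.fine_band

    z_edges = [np.array([0.0])]
    spans: list[tuple[float, float]] = []
    z0 = 0.0
    for i, sp in enumerate(layers):
        z1 = z0 + sp.thickness
        fine = fine_from if is_tissue[i] else None
        seg = _layer_z_edges(z0, z1, res, fine)
        seg[-1] = z1  # exact interface placement
        z_edges.append(seg[1:])
        spans.append((z0, z1))
        z0 = z1
    z_edges = np.concatenate(z_edges)

    cell_layer = np.empty((nx, ny, len(z_edges) - 1), dtype=np.int32)
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    for i, (a, b) in enumerate(spans):
        cell_layer[:, :, (zc > a) & (zc < b)] = i

    if contact_patch is not None:
        x0, x1, y0, y1 = contact_patch
        if not (0 <= x0 < x1 <= length and 0 <= y0 < y1 <= width):
            raise ValueError("contact_patch must lie inside the footprint")
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        outside = ~(
            ((xc >= x0) & (xc <= x1))[:, None]
            & ((yc >= y0) & (yc <= y1))[None, :]
        )
        # mark tissue cells outside the patch as void
        tissue_zone = zc < skin_z
        mask3 = outside[:, :, None] & tissue_zone[None, None, :]
        cell_layer[mask3] = AIR

    return DomainGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        z_edges=z_edges,
        cell_layer=cell_layer,
        layers=layers,
        is_tissue_layer=is_tissue,
        skin_z=skin_z,
        footprint=footprint,
        contact_patch=contact_patch,
        layer_z_spans=spans,
    )


@dataclass(frozen=True)
class LesionSpec:
    """Subcutaneous lesion inclusion.

    The published lesion is irregular with a stated height (0.25 cm) and
    volume (1.5 cm^3); it is modeled as an oblate ellipsoid matching those
    two constraints: vertical semi-axis c = height/2 and equal lateral
    semi-axes a = b solving volume = 4/3 pi a^2 c.  ``center_depth`` is the
    distance from the plantar skin surface to the lesion *center*.
    """

    lesion_type: str  # "inflammation" | "ischemia"
    center_depth: float  # m below the skin surface
    lateral_center: tuple[float, float]  # (x, y), m
    height: float = 2.5e-3
    volume: float = 1.5e-6
    material: MaterialProps | None = None

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION and self.material is None:
            raise ValueError(
                f"unknown lesion_type {self.lesion_type!r}; provide material"
            )
        if self.height <= 0:
            raise ValueError("lesion height must be > 0")
        if self.volume < 0:
            raise ValueError("lesion volume must be >= 0")
        if self.volume > 0 and self.lateral_semi_axis < self.height / 2:
            raise ValueError(
                "lesion volume inconsistent with height (lateral semi-axis "
                "smaller than vertical)"
            )

    @property
    def vertical_semi_axis(self) -> float:
        return self.height / 2.0

    @property
    def lateral_semi_axis(self) -> float:
        if self.volume == 0:
            return 0.0
        return math.sqrt(self.volume / (4.0 / 3.0 * math.pi * self.vertical_semi_axis))

    @property
    def props(self) -> MaterialProps:
        return self.material if self.material is not None else LESION[self.lesion_type]


def embed_lesion(grid: DomainGrid, lesion: LesionSpec) -> DomainGrid:
    """Reassign tissue cells inside the lesion ellipsoid to lesion material.

    Returns a new grid on the same mesh (cells are reassigned, never
    remeshed, so paired lesion/healthy fields share discretization error).
    The vertical extent is clipped to the tissue sub-domain; embedding is
    idempotent for a fixed grid and lesion.
    """
    out = grid.copy()
    if lesion.volume == 0:
        return out
    a = lesion.lateral_semi_axis
    c = lesion.vertical_semi_axis
    x0, y0 = lesion.lateral_center
    length, width = grid.footprint
    if not (0 <= x0 - a and x0 + a <= length and 0 <= y0 - a and y0 + a <= width):
        raise ValueError("lesion extends laterally outside the footprint")
    if grid.contact_patch is not None:
        px0, px1, py0, py1 = grid.contact_patch
        if not (px0 <= x0 - a and x0 + a <= px1 and py0 <= y0 - a and y0 + a <= py1):
            raise ValueError("lesion extends laterally outside the foot contact patch")

    zc_lesion = grid.skin_z - lesion.center_depth
    xc, yc, zc = grid.x_centers, grid.y_centers, grid.z_centers
    r2 = (
        ((xc[:, None, None] - x0) / a) ** 2
        + ((yc[None, :, None] - y0) / a) ** 2
        + ((zc[None, None, :] - zc_lesion) / c) ** 2
    )
    # eligible: tissue (or previously embedded lesion) cells only; this
    # clips the vertical extent to the tissue sub-domain and makes repeated
    # embedding idempotent.
    tissue_like = np.array(grid.is_tissue_layer + [True] * 0, dtype=bool)
    eligible = np.zeros(grid.shape, dtype=bool)
    act = grid.active
    eligible[act] = tissue_like[grid.cell_layer[act]]
    inside = (r2 <= 1.0) & eligible

    lesion_id = len(out.layers)
    out.layers.append(LayerSpec(lesion.props, lesion.height))
    out.is_tissue_layer.append(True)
    out.layer_z_spans.append((zc_lesion - c, zc_lesion + c))
    out.cell_layer[inside] = lesion_id
    return out


def voxelized_lesion_volume(grid: DomainGrid, lesion_name: str | None = None) -> float:
    """Total volume of cells assigned to the lesion material."""
    name = lesion_name or grid.layers[-1].material.name
    return float(grid.cell_volumes()[grid.layer_mask(name)].sum())


@dataclass(frozen=True)
class SensorLayout:
    """Eight planar sensor positions on the insole top surface."""

    positions: np.ndarray  # (8, 2) m
    labels: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 9))
    detection_threshold: float = 0.1  # degC

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError(
                f"expected {len(self.labels)} (x, y) positions, got {pos.shape}"
            )
        object.__setattr__(self, "positions", pos)
        if self.detection_threshold <= 0:
            raise ValueError("detection_threshold must be > 0")


#: Sensor positions as fractions of foot length (x along the foot from the
#: heel, y across it): hallux, three metatarsal-head points, lateral and
#: medial midfoot, and two heel points.  Schematic, user-overridable.
_SENSOR_FRACTIONS = np.array(
    [
        (0.85, 0.142),  # S1 hallux
        (0.72, 0.142),  # S2 medial metatarsal head
        (0.66, 0.173),  # S3 central metatarsal head
        (0.64, 0.204),  # S4 lateral metatarsal head
        (0.56, 0.196),  # S5 lateral midfoot
        (0.44, 0.150),  # S6 medial arch
        (0.17, 0.192),  # S7 lateral heel
        (0.10, 0.154),  # S8 heel center
    ]
)


def default_sensor_layout(
    foot_length: float,
    detection_threshold: float = 0.1,
    positions: np.ndarray | None = None,
) -> SensorLayout:
    """Eight-point plantar sensor layout scaled linearly with foot length.

    ``positions`` overrides the default pattern verbatim.
    """
    if not (0.20 <= foot_length <= 0.32):
        raise ValueError(
            f"foot_length {foot_length} m outside the supported 0.20-0.32 m range"
        )
    if positions is None:
        positions = _SENSOR_FRACTIONS * foot_length
    return SensorLayout(
        positions=np.asarray(positions, dtype=float),
        detection_threshold=detection_threshold,
    )
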