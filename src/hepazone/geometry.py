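"""Physical spot geometry on the Visium hexagonal lattice.

Array coordinates follow the Visium convention: ``array_row`` and
``array_col`` share parity, horizontally adjacent spots differ by 2 in
``array_col``, and the center-to-center pitch between first-ring neighbours
is 100 um on a standard slide.  Physical coordinates are derived from array
coordinates (x = col * pitch/2, y = row * pitch * sqrt(3)/2), never from
image pixels, because pixel scale varies per slide while array geometry is
exact.

Each interior spot has six first-ring neighbours at the pitch distance and
six second-ring neighbours at pitch * sqrt(3) (~173 um at 100 um pitch).
Boundary spots keep partial rings rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PositionsTable

#: (d_row, d_col) offsets of the six first-ring neighbours.
RING1_OFFSETS: frozenset[tuple[int, int]] = frozenset(
    {(0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1)}
)
#: (d_row, d_col) offsets of the six second-ring neighbours (distance pitch*sqrt(3)).
RING2_OFFSETS: frozenset[tuple[int, int]] = frozenset(
    {(2, 0), (-2, 0), (1, 3), (1, -3), (-1, 3), (-1, -3)}
)


@dataclass(frozen=True)
class SpotGeometry:
    """Spot identities with array and physical (um) coordinates."""

    spot_ids: tuple[str, ...]
    array_row: np.ndarray
    array_col: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        pairs = list(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (array_row, array_col) pairs in geometry")

    def __len__(self) -> int:
        return len(self.spot_ids)

    @property
    def _id_to_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.spot_ids)}

    @property
    def _array_to_id(self) -> dict[tuple[int, int], str]:
        return {
            (int(r), int(c)): s
            for s, r, c in zip(self.spot_ids, self.array_row, self.array_col)
        }

    def index_of(self, spot_id: str) -> int:
        try:
            return self._id_to_index[spot_id]
        except KeyError:
            raise KeyError(f"spot {spot_id!r} not in geometry") from None


@dataclass(frozen=True)
class RingNeighborhood:
    """First- and second-ring neighbours of one center spot."""

    center: str
    ring1: frozenset[str]
    ring2: frozenset[str]


def build_geometry(positions: PositionsTable, pitch_um: float = 100.0) -> SpotGeometry:
    """Derive physical geometry for the in-tissue spots of a positions table."""
    tissue = positions.tissue_only()
    if len(tissue) < 1:
        raise ValueError("no in-tissue spots in positions table")
    col = tissue.array_col.astype(float)
    row = tissue.array_row.astype(float)
    return SpotGeometry(
        spot_ids=tuple(tissue.barcode),
        array_row=tissue.array_row.copy(),
        array_col=tissue.array_col.copy(),
        x_um=col * (pitch_um / 2.0),
        y_um=row * (pitch_um * np.sqrt(3.0) / 2.0),
        pitch_um=float(pitch_um),
    )


def ring_neighbors(geometry: SpotGeometry, spot_id: str) -> RingNeighborhood:
    """Resolve rings by exact array-coordinate offsets.

    Interior spots yield six neighbours per ring; boundary spots yield fewer,
    never erroring.
    """
    i = geometry.index_of(spot_id)
    lookup = geometry._array_to_id
    r, c = int(geometry.array_row[i]), int(geometry.array_col[i])
    ring1 = frozenset(
        lookup[(r + dr, c + dc)] for dr, dc in RING1_OFFSETS if (r + dr, c + dc) in lookup
    )
    ring2 = frozenset(
        lookup[(r + dr, c + dc)] for dr, dc in RING2_OFFSETS if (r + dr, c + dc) in lookup
    )
    return RingNeighborhood(spot_id, ring1, ring2)


def ring_neighbors_by_distance(
    geometry: SpotGeometry, spot_id: str, tol_rel: float = 0.01
) -> RingNeighborhood:
    """Resolve rings by Euclidean distance bands, for irregular inputs.

    Ring 1 collects spots at distance within ``pitch * (1 +- tol_rel)``;
    ring 2 within ``pitch * sqrt(3) * (1 +- tol_rel)``.  On a perfect lattice
    this equals :func:`ring_neighbors` exactly; with ``tol_rel = 0`` on
    jittered coordinates rings may come back empty.
    """
    i = geometry.index_of(spot_id)
    dx = geometry.x_um - geometry.x_um[i]
    dy = geometry.y_um - geometry.y_um[i]
    dist = np.hypot(dx, dy)
    pitch = geometry.pitch_um
    ids = np.asarray(geometry.spot_ids, dtype=object)
    in_band1 = (dist >= pitch * (1 - tol_rel)) & (dist <= pitch * (1 + tol_rel))
    d2 = pitch * np.sqrt(3.0)
    in_band2 = (dist >= d2 * (1 - tol_rel)) & (dist <= d2 * (1 + tol_rel))
    in_band1[i] = in_band2[i] = False
    return RingNeighborhood(
        spot_id, frozenset(ids[in_band1]), frozenset(ids[in_band2])
    )


def hex_full_lattice(n_rows: int, n_cols: int, barcode_prefix: str = "S") -> PositionsTable:
    """Build a full rectangular patch of the Visium lattice as a PositionsTable.

    Row ``r`` holds ``n_cols`` spots at array columns ``2*c + (r % 2)``,
    honouring the row/column parity convention.  Barcodes are
    ``{prefix}{row:03d}x{col:03d}``.
    """
    barcodes, rows, cols = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            col = 2 * c + (r % 2)
            barcodes.append(f"{barcode_prefix}{r:03d}x{col:03d}")
            rows.append(r)
            cols.append(col)
    n = len(barcodes)
    return PositionsTable(
        tuple(barcodes),
        np.ones(n, dtype=bool),
        np.asarray(rows, dtype=np.int64),
        np.asarray(cols, dtype=np.int64),
        np.asarray(rows, dtype=float),
        np.asarray(cols, dtype=float),
    )
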