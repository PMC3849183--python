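"""Planar sensor layouts for simulated whole-head gradiometer arrays.

The analyses in this package (planar-gradient estimation, cluster-based
permutation tests, hemispheric regions of interest) only need three pieces
of geometry: 2-D sensor positions, a left/right/midline hemisphere tag per
sensor, and a neighbourhood graph.  Real MEG systems provide these through
their channel definitions; here they are constructed synthetically as a
mirror-symmetric grid, which is sufficient for planting and recovering
lateralized posterior effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorArray", "make_sensor_array"]

#: adjacency threshold as a multiple of the unit grid spacing; 1.5 connects
#: horizontal, vertical and diagonal neighbours but not next-nearest columns,
#: so the two hemispheres touch only through midline sensors.
_ADJACENCY_FACTOR = 1.5


@dataclass(frozen=True)
class SensorArray:
    """A 2-D sensor layout with hemisphere tags and a neighbour graph.

    Attributes
    ----------
    labels : tuple of str
        Sensor identifiers (e.g. ``"L03"``, ``"R03"``, ``"M00"``).
    positions : ndarray, shape (n, 2)
        Planar layout coordinates in arbitrary grid units.  x < 0 is the
        left hemisphere, x > 0 the right; smaller y is more posterior.
    hemisphere : ndarray of str, shape (n,)
        ``"L"``, ``"R"`` or ``"M"`` (midline) per sensor.
    adjacency : ndarray of bool, shape (n, n)
        Symmetric, irreflexive neighbour relation (distance threshold).
    posterior : ndarray of bool, shape (n,)
        Posterior band (lower third of rows) where the generator plants the
        lateralized alpha sources.
    """

    labels: tuple
    positions: np.ndarray
    hemisphere: np.ndarray
    adjacency: np.ndarray
    posterior: np.ndarray
    neighbor_lists: tuple = field(repr=False, default=())

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    def hemisphere_mask(self, side: str) -> np.ndarray:
        return self.hemisphere == side

    def to_frame(self) -> pd.DataFrame:
        """Layout as a table (label, x, y, hemisphere, posterior)."""
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "hemisphere": self.hemisphere,
                "posterior": self.posterior,
            }
        )


def _grid_half(n: int) -> tuple[np.ndarray, int]:
    """Row/column indices for one hemisphere's grid of ``n`` sensors."""
    n_rows = max(2, int(round(math.sqrt(n))))
    n_cols = math.ceil(n / n_rows)
    idx = np.arange(n)
    rows = idx // n_cols
    cols = idx % n_cols
    return np.column_stack([rows, cols]), rows.max() + 1


def make_sensor_array(n_sensors: int, layout_preset: str = "grid") -> SensorArray:
    """Build a mirror-symmetric planar sensor array.

    Parameters
    ----------
    n_sensors : int
        Total sensor count, at least 6.  An even count splits exactly in
        half between hemispheres; an odd count places the remainder on the
        midline (the 273-channel preset mimics a whole-head axial
        gradiometer system after sensor dropout).
    layout_preset : {"grid", "ctf-like"}
        Both presets use the same rectangular-grid construction; the name
        records intent ("ctf-like" is conventionally called with 273
        sensors).

    Returns
    -------
    SensorArray

    Raises
    ------
    ValueError
        If ``n_sensors`` is too small to form a posterior band per
        hemisphere, or the preset is unknown.
    """
    if layout_preset not in ("grid", "ctf-like"):
        raise ValueError(f"unknown layout preset {layout_preset!r}")
    if n_sensors < 6:
        raise ValueError(
            "need at least 6 sensors to form two hemispheres with posterior bands"
        )
    half = n_sensors // 2
    n_mid = n_sensors - 2 * half

    rc, n_rows = _grid_half(half)
    rows, cols = rc[:, 0], rc[:, 1]
    # y decreases with row index: the last rows are the posterior band
    ys = -rows.astype(float)
    xs_right = (cols + 1).astype(float)

    positions = []
    labels = []
    hemis = []
    for i in range(half):  # left hemisphere mirrors the right
        positions.append((-xs_right[i], ys[i]))
        labels.append(f"L{i:02d}")
        hemis.append("L")
    for i in range(half):
        positions.append((xs_right[i], ys[i]))
        labels.append(f"R{i:02d}")
        hemis.append("R")
    for i in range(n_mid):
        positions.append((0.0, -float(i)))
        labels.append(f"M{i:02d}")
        hemis.append("M")

    positions = np.asarray(positions, dtype=float)
    hemis = np.asarray(hemis, dtype=object)

    # posterior band: last ceil(n_rows / 3) rows of each hemisphere
    n_post_rows = math.ceil(n_rows / 3)
    post_rows = set(range(n_rows - n_post_rows, n_rows))
    post_half = np.array([r in post_rows for r in rows])
    posterior = np.concatenate([post_half, post_half, np.zeros(n_mid, dtype=bool)])
    if post_half.sum() < 1:
        raise ValueError("layout too small to form posterior bands")

    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adjacency = (d > 0) & (d <= _ADJACENCY_FACTOR)
    np.fill_diagonal(adjacency, False)

    neighbor_lists = tuple(
        tuple(np.flatnonzero(adjacency[i])) for i in range(n_sensors)
    )
    return SensorArray(
        labels=tuple(labels),
        positions=positions,
        hemisphere=hemis,
        adjacency=adjacency,
        posterior=posterior,
        neighbor_lists=neighbor_lists,
    )
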