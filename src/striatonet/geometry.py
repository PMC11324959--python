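"""Synthetic striatal geometry.

The model network lives on a 3-D point cloud standing in for atlas-derived
neuron coordinates: two disjoint ellipsoidal nuclei (a caudate-like and a
putamen-like volume, in mm, MNI-like frame) populated by uniform rejection
sampling, with ~95% medium spiny neurons (MSN) and ~5% fast-spiking (FS)
interneurons assigned uniformly at random.

The default shapes are sized so the two nuclei total roughly 18 cm^3 of
tissue (gross adult striatal scale) with an inter-nucleus gap of a few mm;
at 1,995 points this puts several dozen neighbours inside a 5 mm ball of a
typical cell, which the local-connectivity rule of
:mod:`striatonet.connectome` relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Ellipsoid",
    "NeuronTable",
    "default_shapes",
    "density_matched_shapes",
    "generate_synthetic_striatum",
    "read_coordinates",
    "write_coordinates",
]

NUCLEI = ("caudate", "putamen")
CELL_TYPES = ("MSN", "FS")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoidal nucleus volume (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive (zero volume)")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, pts: np.ndarray) -> np.ndarray:
        u = (np.asarray(pts, float) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (u**2).sum(axis=-1) <= 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the ellipsoid by rejection from the bounding box."""
        out = np.empty((0, 3))
        while len(out) < n:
            cand = rng.uniform(-1.0, 1.0, size=(max(2 * n, 64), 3))
            cand = cand[(cand**2).sum(axis=1) <= 1.0]
            out = np.vstack([out, cand])
        return out[:n] * np.asarray(self.semi_axes) + np.asarray(self.center)


def default_shapes() -> dict[str, Ellipsoid]:
    """Caudate-like (elongated, superior-medial) and putamen-like (larger,
    lateral) ellipsoids of one hemisphere; total volume ~10 cm^3 (gross
    single-side striatal scale), surface gap >= 2 mm.  At 1,995 points this
    density puts ~100 neighbours in an interior 5 mm ball, enough for both
    the MSN (k=20) and the five-fold denser FS (k=100) connection rules."""
    return {
        "caudate": Ellipsoid(center=(-11.0, 6.0, 8.0), semi_axes=(5.5, 18.0, 9.5)),
        "putamen": Ellipsoid(center=(8.0, -2.0, -4.0), semi_axes=(7.5, 16.0, 12.0)),
    }


def density_matched_shapes(n_total: int, n_ref: int = 1995) -> dict[str, Ellipsoid]:
    """Default shapes rescaled so a reduced point cloud keeps the reference
    point density (axes and centres scale with (n_total/n_ref)^(1/3)).

    Reduced networks built this way preserve the local-neighbourhood
    statistics the k-in-a-5-mm-ball construction rule depends on, which is
    what keeps per-neuron firing rates comparable across network sizes.
    """
    f = (n_total / n_ref) ** (1.0 / 3.0)
    return {
        name: Ellipsoid(
            center=tuple(c * f for c in e.center),
            semi_axes=tuple(s * f for s in e.semi_axes),
        )
        for name, e in default_shapes().items()
    }


@dataclass
class NeuronTable:
    """Neuron coordinates with nucleus and cell-type labels.

    ids are contiguous from 0; ``pos`` is (N, 3) in mm.
    """

    pos: np.ndarray
    nucleus: np.ndarray
    cell_type: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, float)
        self.nucleus = np.asarray(self.nucleus, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.ids is None:
            self.ids = np.arange(len(self.pos))
        self.ids = np.asarray(self.ids)
        self.validate()

    def validate(self) -> None:
        n = len(self.pos)
        if self.pos.shape != (n, 3):
            raise ValueError("pos must be (N, 3)")
        if not np.isfinite(self.pos).all():
            raise ValueError("positions must be finite")
        if len(self.ids) != n or len(self.nucleus) != n or len(self.cell_type) != n:
            raise ValueError("column lengths disagree")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate values in field 'id'")
        if not np.array_equal(np.sort(self.ids), np.arange(n)):
            raise ValueError("field 'id' must be contiguous from 0")
        bad = set(self.nucleus) - set(NUCLEI)
        if bad:
            raise ValueError(f"unknown nucleus labels {bad!r}")
        bad = set(self.cell_type) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell_type labels {bad!r}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def msn_mask(self) -> np.ndarray:
        return self.cell_type == "MSN"

    @property
    def fs_mask(self) -> np.ndarray:
        return self.cell_type == "FS"

    @property
    def n_fs(self) -> int:
        return int(self.fs_mask.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
                "nucleus": self.nucleus,
                "cell_type": self.cell_type,
            }
        )


def _check_disjoint(shapes: dict[str, Ellipsoid], gap: float = 2.0) -> None:
    """Reject overlapping nucleus volumes (surface separation < gap, mm).

    Checked numerically on a dense surface sampling of each ellipsoid against
    the other ellipsoid inflated by ``gap``.
    """
    (n1, e1), (n2, e2) = shapes.items()
    rng = np.random.default_rng(0)
    for a, b in ((e1, e2), (e2, e1)):
        u = rng.normal(size=(4096, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        surface = u * np.asarray(a.semi_axes) + np.asarray(a.center)
        inflated = Ellipsoid(b.center, tuple(s + gap for s in b.semi_axes))
        if inflated.contains(surface).any():
            raise ValueError(
                f"nucleus volumes {n1!r} and {n2!r} overlap or are closer than {gap} mm"
            )


def generate_synthetic_striatum(
    n_total: int = 1995,
    fs_fraction: float = 0.05,
    nucleus_shapes: dict[str, Ellipsoid] | None = None,
    seed: int = 0,
) -> NeuronTable:
    """Generate the synthetic striatal point cloud.

    Points are split between the two nuclei proportionally to volume and
    placed uniformly at random inside each ellipsoid; ``round(fs_fraction *
    n_total)`` cells are labelled FS, uniformly at random over all positions.

    When no shapes are given, the default ellipsoids are rescaled to keep
    the reference point density (1,995 points in ~18 cm^3), so reduced
    clouds remain usable with the 5 mm local-connectivity rule.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    if not 0.0 < fs_fraction < 1.0:
        raise ValueError("fs_fraction must lie in (0, 1)")
    if nucleus_shapes is not None:
        shapes, gap = nucleus_shapes, 2.0
    else:
        shapes = density_matched_shapes(n_total)
        gap = 2.0 * min(1.0, (n_total / 1995.0) ** (1.0 / 3.0))
    if len(shapes) != 2:
        raise ValueError("exactly two nucleus volumes required")
    _check_disjoint(shapes, gap=gap)

    rng = np.random.default_rng(seed)
    names = list(shapes)
    vols = np.array([shapes[n].volume for n in names])
    n_first = int(round(n_total * vols[0] / vols.sum()))
    n_first = min(max(n_first, 1), n_total - 1)
    counts = {names[0]: n_first, names[1]: n_total - n_first}

    pos = np.vstack([shapes[n].sample(counts[n], rng) for n in names])
    nucleus = np.concatenate([[n] * counts[n] for n in names])

    # floor rather than round: 5% of 1,995 labels 99 interneurons
    n_fs = int(np.floor(fs_fraction * n_total + 1e-9))
    cell_type = np.array(["MSN"] * n_total, dtype=object)
    fs_idx = rng.choice(n_total, size=n_fs, replace=False)
    cell_type[fs_idx] = "FS"

    return NeuronTable(pos=pos, nucleus=nucleus, cell_type=cell_type)


_COLUMNS = ["id", "x", "y", "z", "nucleus", "cell_type"]


def write_coordinates(table: NeuronTable, path) -> None:
    """Write the neuron table as CSV with header id,x,y,z,nucleus,cell_type."""
    table.to_dataframe().to_csv(path, index=False)


def read_coordinates(path) -> NeuronTable:
    """Read a neuron coordinate CSV; errors name the offending field."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing!r}")
    for c in ("x", "y", "z"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric value in field {c!r}")
        df[c] = vals
    if df["id"].duplicated().any():
        raise ValueError("duplicate values in field 'id'")
    order = np.argsort(df["id"].to_numpy())
    df = df.iloc[order]
    return NeuronTable(
        pos=df[["x", "y", "z"]].to_numpy(float),
        nucleus=df["nucleus"].to_numpy(object),
        cell_type=df["cell_type"].to_numpy(object),
        ids=df["id"].to_numpy(int),
    )
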