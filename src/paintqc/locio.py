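"""Localization-table IO, structure picking and per-structure extraction.

Coordinate conventions (the single conversion boundary of the package):

* Localization files store **camera pixels** in the convention of standard
  single-molecule localization software: origin at the top-left corner, x
  rightward, y downward, 0-based frame indices.  Precisions ``lpx``/``lpy``
  are in pixels.
* All downstream analysis works in **nm with the y axis pointing up**,
  relative to a pick center.  :func:`extract` performs the conversion using
  the table's pixel size.

Tables round-trip losslessly through HDF5 (compound dataset ``locs`` with
metadata attributes, field-compatible with Picasso) and through a CSV dialect
with ``# key: value`` metadata header lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

__all__ = [
    "LocalizationTable",
    "PickRegion",
    "StructureLocs",
    "read_table",
    "write_table",
    "pick_structures",
    "extract",
    "save_picks",
    "load_picks",
]

REQUIRED_COLUMNS = ("frame", "x", "y", "photons", "lpx", "lpy")
_META_KEYS = ("pixel_size", "n_frames", "width", "height")


@dataclass
class LocalizationTable:
    """Localization records plus camera metadata.

    ``locs`` holds one row per localization with columns ``frame`` (0-based),
    ``x``/``y`` (camera px), ``photons`` and ``lpx``/``lpy`` (precision, px).
    ``pixel_size`` is nm per camera pixel; ``width``/``height`` the camera
    image size in pixels.
    """

    locs: pd.DataFrame
    pixel_size: float
    n_frames: int
    width: int
    height: int

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.locs.columns]
        if missing:
            raise ValueError(f"localization table is missing columns: {missing}")
        self.locs = self.locs[list(REQUIRED_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.locs)

    def validate(self) -> None:
        df = self.locs
        if len(df) == 0:
            return
        if df["frame"].min() < 0 or df["frame"].max() >= self.n_frames:
            raise ValueError("frame indices outside [0, n_frames)")
        if (df["photons"] <= 0).any():
            raise ValueError("photon counts must be positive")
        if (
            df["x"].min() < 0
            or df["y"].min() < 0
            or df["x"].max() > self.width
            or df["y"].max() > self.height
        ):
            raise ValueError("coordinates outside image bounds")


@dataclass(frozen=True)
class PickRegion:
    """Circular pick isolating one structure (camera-pixel units)."""

    center: tuple
    radius: float
    structure_id: str

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("pick radius must be positive")


@dataclass
class StructureLocs:
    """Localizations of one picked structure, in nm relative to the pick center
    (y up)."""

    structure_id: str
    xy: np.ndarray  # (n, 2) nm
    frame: np.ndarray
    photons: np.ndarray
    precision_nm: np.ndarray

    def __len__(self) -> int:
        return len(self.xy)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

_H5_DTYPE = np.dtype(
    [
        ("frame", "u4"),
        ("x", "f8"),
        ("y", "f8"),
        ("photons", "f8"),
        ("lpx", "f8"),
        ("lpy", "f8"),
    ]
)


def write_table(table: LocalizationTable, path) -> None:
    """Write a table as ``.hdf5``/``.h5`` or ``.csv`` depending on extension."""
    path = str(path)
    if path.endswith((".hdf5", ".h5")):
        rec = np.empty(len(table), dtype=_H5_DTYPE)
        for name in REQUIRED_COLUMNS:
            rec[name] = table.locs[name].to_numpy()
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("locs", data=rec)
            ds.attrs["pixel_size"] = float(table.pixel_size)
            ds.attrs["n_frames"] = int(table.n_frames)
            ds.attrs["width"] = int(table.width)
            ds.attrs["height"] = int(table.height)
    elif path.endswith(".csv"):
        with open(path, "w") as fh:
            fh.write(f"# pixel_size: {table.pixel_size!r}\n")
            fh.write(f"# n_frames: {table.n_frames}\n")
            fh.write(f"# width: {table.width}\n")
            fh.write(f"# height: {table.height}\n")
            table.locs.to_csv(fh, index=False, float_format=None)
    else:
        raise ValueError(f"unknown localization-table dialect for {path!r}")


def read_table(path) -> LocalizationTable:
    path = str(path)
    if path.endswith((".hdf5", ".h5")):
        with h5py.File(path, "r") as fh:
            if "locs" not in fh:
                raise ValueError(f"{path!r} has no 'locs' dataset")
            ds = fh["locs"]
            missing = [c for c in REQUIRED_COLUMNS if c not in ds.dtype.names]
            if missing:
                raise ValueError(f"localization table is missing columns: {missing}")
            rec = ds[()]
            meta = {k: ds.attrs[k] for k in _META_KEYS if k in ds.attrs}
        if len(meta) != len(_META_KEYS):
            raise ValueError(f"{path!r} is missing metadata attributes")
        df = pd.DataFrame({c: rec[c] for c in REQUIRED_COLUMNS})
        df["frame"] = df["frame"].astype(np.int64)
        return LocalizationTable(
            df,
            pixel_size=float(meta["pixel_size"]),
            n_frames=int(meta["n_frames"]),
            width=int(meta["width"]),
            height=int(meta["height"]),
        )
    if path.endswith(".csv"):
        meta = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                else:
                    body.append(line)
        missing_meta = [k for k in _META_KEYS if k not in meta]
        if missing_meta:
            raise ValueError(f"CSV table is missing metadata: {missing_meta}")
        df = pd.read_csv(io.StringIO("".join(body)), float_precision="round_trip")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"localization table is missing columns: {missing}")
        df["frame"] = df["frame"].astype(np.int64)
        return LocalizationTable(
            df,
            pixel_size=float(meta["pixel_size"]),
            n_frames=int(meta["n_frames"]),
            width=int(meta["width"]),
            height=int(meta["height"]),
        )
    raise ValueError(f"unknown localization-table dialect for {path!r}")


# ---------------------------------------------------------------------------
# picking and extraction
# ---------------------------------------------------------------------------

def pick_structures(
    table: LocalizationTable,
    expected_radius_nm: float = 100.0,
    min_locs: int = 100,
) -> list:
    """Automated structure picking by density clustering.

    Localizations are binned on a grid of half the expected structure radius;
    8-connected occupied bins form candidate clusters.  Clusters with at
    least ``min_locs`` localizations whose maximal distance from the centroid
    does not exceed ``expected_radius_nm`` become picks (one region per
    structure).  Oversized clusters (e.g. two structures fused together) are
    rejected by the extent filter.  Deterministic; replaces interactive
    pick-similar selection.
    """
    if len(table) == 0:
        return []
    ps = table.pixel_size
    x_nm = table.locs["x"].to_numpy() * ps
    y_nm = table.locs["y"].to_numpy() * ps
    bin_nm = max(expected_radius_nm / 2.0, 1e-6)
    ix = np.floor(x_nm / bin_nm).astype(np.int64)
    iy = np.floor(y_nm / bin_nm).astype(np.int64)
    ix -= ix.min()
    iy -= iy.min()
    occ = np.zeros((iy.max() + 1, ix.max() + 1), dtype=bool)
    occ[iy, ix] = True
    labels, n_comp = ndimage.label(occ, structure=np.ones((3, 3), dtype=int))
    comp = labels[iy, ix]  # component id per localization, 1-based

    regions = []
    order = np.argsort(comp, kind="stable")
    boundaries = np.searchsorted(comp[order], np.arange(1, n_comp + 2))
    for k in range(n_comp):
        idx = order[boundaries[k]: boundaries[k + 1]]
        if len(idx) < min_locs:
            continue
        cx = x_nm[idx].mean()
        cy = y_nm[idx].mean()
        extent = np.hypot(x_nm[idx] - cx, y_nm[idx] - cy).max()
        if extent > expected_radius_nm:
            continue
        regions.append((cy, cx, len(idx)))
    regions.sort()
    out = []
    for i, (cy, cx, _n) in enumerate(regions):
        out.append(
            PickRegion(
                center=(cx / ps, cy / ps),
                radius=expected_radius_nm / ps,
                structure_id=f"s{i:04d}",
            )
        )
    return out


def save_picks(regions, path) -> None:
    """Write pick regions as YAML (center and radius in camera px)."""
    doc = {
        "picks": [
            {
                "structure_id": r.structure_id,
                "center": [float(r.center[0]), float(r.center[1])],
                "radius": float(r.radius),
            }
            for r in regions
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_picks(path) -> list:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        PickRegion(
            center=tuple(p["center"]), radius=p["radius"],
            structure_id=p["structure_id"],
        )
        for p in doc["picks"]
    ]


def extract(table: LocalizationTable, region: PickRegion) -> StructureLocs:
    """Extract the localizations inside a pick, converted to nm (y up)
    relative to the pick center."""
    ps = table.pixel_size
    cx, cy = region.center
    x = table.locs["x"].to_numpy()
    y = table.locs["y"].to_numpy()
    dx = (x - cx) * ps
    dy = (cy - y) * ps  # flip to y-up
    r_nm = region.radius * ps
    mask = np.hypot(dx, dy) <= r_nm
    prec = 0.5 * (table.locs["lpx"].to_numpy() + table.locs["lpy"].to_numpy()) * ps
    return StructureLocs(
        structure_id=region.structure_id,
        xy=np.column_stack([dx[mask], dy[mask]]),
        frame=table.locs["frame"].to_numpy()[mask],
        photons=table.locs["photons"].to_numpy()[mask],
        precision_nm=prec[mask],
    )
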