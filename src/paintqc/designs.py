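"""Origami docking-site geometries and template rendering.

A design is a :class:`SitePattern`: a set of site coordinates in nm, expressed
in a y-up frame whose origin is the centroid of the full site set.  Three
kinds of sites are distinguished:

* **probed** sites carry a docking strand in this variant and are scored for
  detection,
* **alignment** sites (the arrowhead + line pattern) are always present on the
  structure and are used only for registration/classification, never scored,
* **absent-by-design** sites exist in the layout but carry no docking strand
  in this variant; they are scored to measure false positives.

Templates for image cross-correlation are rendered by placing a unit-amplitude
isotropic Gaussian on every probed and alignment site.  The template encodes
the design geometry only — it is deliberately not weighted by binding
kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SitePattern",
    "TemplateSpec",
    "TemplateImage",
    "RectangleLayout",
    "build_grid_20nm",
    "build_bs_pair",
    "build_variant_library",
    "default_variant_config",
    "rectangle_layout",
    "render_template",
    "save_design",
    "load_design",
]

_CENTROID_TOL = 1e-6


@dataclass(frozen=True)
class SitePattern:
    """Designed docking-site coordinates of one origami variant.

    Parameters
    ----------
    name:
        Variant identifier, unique within a library.
    sites:
        ``(n, 2)`` array of site positions in nm, centroid at the origin.
    site_labels:
        One stable label per site.
    probe_mask:
        Boolean mask of sites carrying a docking strand in this variant.
    alignment_mask:
        Boolean mask of the always-present alignment (arrowhead + line) sites.
    """

    name: str
    sites: np.ndarray
    site_labels: tuple
    probe_mask: np.ndarray
    alignment_mask: np.ndarray

    def __post_init__(self):
        sites = np.asarray(self.sites, dtype=float)
        probe = np.asarray(self.probe_mask, dtype=bool)
        align = np.asarray(self.alignment_mask, dtype=bool)
        labels = tuple(str(x) for x in self.site_labels)
        if sites.ndim != 2 or sites.shape[1] != 2:
            raise ValueError("sites must be an (n, 2) array")
        n = len(sites)
        if not np.all(np.isfinite(sites)):
            raise ValueError("site positions must be finite")
        if len(labels) != n or len(set(labels)) != n:
            raise ValueError("site_labels must be unique and match sites")
        if probe.shape != (n,) or align.shape != (n,):
            raise ValueError("masks must have one entry per site")
        if np.any(probe & align):
            raise ValueError("alignment sites are never scored as detection sites")
        if n and np.abs(sites.mean(axis=0)).max() > _CENTROID_TOL:
            raise ValueError("centroid of the full site set must be (0, 0)")
        for arr in (sites, probe, align):
            arr.setflags(write=False)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "probe_mask", probe)
        object.__setattr__(self, "alignment_mask", align)
        object.__setattr__(self, "site_labels", labels)

    # -- derived views ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def absent_mask(self) -> np.ndarray:
        """Sites present in the layout but not probed in this variant."""
        return ~(self.probe_mask | self.alignment_mask)

    @property
    def probed_sites(self) -> np.ndarray:
        return self.sites[self.probe_mask]

    @property
    def alignment_sites(self) -> np.ndarray:
        return self.sites[self.alignment_mask]

    @property
    def absent_sites(self) -> np.ndarray:
        return self.sites[self.absent_mask]

    def min_site_spacing(self) -> float:
        """Smallest pairwise distance between any two sites (nm)."""
        if self.n_sites < 2:
            return np.inf
        d = self.sites[:, None, :] - self.sites[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        dist[np.diag_indices(self.n_sites)] = np.inf
        return float(dist.min())

    def radius(self) -> float:
        """Distance from the centroid to the outermost site (nm)."""
        if self.n_sites == 0:
            return 0.0
        return float(np.hypot(*self.sites.T).max())


def _recenter(sites: np.ndarray) -> np.ndarray:
    sites = np.asarray(sites, dtype=float)
    return sites - sites.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# concrete designs
# ---------------------------------------------------------------------------

def build_grid_20nm(rows: int = 4, cols: int = 3, pitch: float = 20.0) -> SitePattern:
    """The 20-nm grid: 12 docking sites on a 4x3 lattice, all probed.

    The grid has rotational (180 deg) and mirror symmetry; it carries no
    alignment pattern, so per-site identities are only defined up to that
    symmetry and analyses of this design average over sites.
    """
    xs = (np.arange(cols) - (cols - 1) / 2) * pitch
    ys = (np.arange(rows) - (rows - 1) / 2) * pitch
    sites = np.array([(x, y) for y in ys for x in xs])
    labels = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    n = len(sites)
    return SitePattern(
        name="grid20",
        sites=_recenter(sites),
        site_labels=labels,
        probe_mask=np.ones(n, bool),
        alignment_mask=np.zeros(n, bool),
    )


# Rectangle staple lattice used for the bs pair and the 18-variant library.
# 14 columns x 13 rows at 8 x 7 nm pitch; 9 cells form the asymmetric
# arrowhead + line alignment pattern; 5 cells adjacent to the biotin anchors
# are excluded from probing.  Exact coordinates are a synthetic fixture: the
# pipeline only requires the pattern to be asymmetric and fixed.
_N_COLS, _N_ROWS = 14, 13
_PITCH_X, _PITCH_Y = 8.0, 7.0
_ARROW_CELLS = ((2, 6), (3, 7), (4, 8), (3, 5), (4, 4))  # "<" chevron
_LINE_CELLS = ((6, 1), (8, 1), (10, 1), (12, 1))  # collinear row near one edge
_ALIGN_CELLS = _ARROW_CELLS + _LINE_CELLS
_BIOTIN_CELLS = ((0, 0), (13, 0), (0, 12), (13, 12), (7, 6))
_ALIGN_LABELS = tuple(f"arrow{i + 1}" for i in range(len(_ARROW_CELLS))) + tuple(
    f"line{i + 1}" for i in range(len(_LINE_CELLS))
)


@dataclass(frozen=True)
class RectangleLayout:
    """Staple-position layout of the 2D rectangle.

    Maps site labels to lattice cells ``(col, row)`` and to nm coordinates in
    the shared (recentred) pattern frame.  ``excluded_labels`` are the
    biotin-adjacent positions that carry no value in heatmaps.
    """

    cells: Mapping[str, tuple]
    positions: Mapping[str, tuple]
    detection_labels: tuple
    alignment_labels: tuple
    excluded_labels: tuple


def rectangle_layout() -> RectangleLayout:
    align_cells = dict(zip(_ALIGN_LABELS, _ALIGN_CELLS))
    biotin = set(_BIOTIN_CELLS)
    det_cells = {}
    for row in range(_N_ROWS):
        for col in range(_N_COLS):
            cell = (col, row)
            if cell in biotin or cell in _ALIGN_CELLS:
                continue
            det_cells[f"r{row:02d}c{col:02d}"] = cell
    cells = {**det_cells, **align_cells}
    raw = np.array([(c * _PITCH_X, r * _PITCH_Y) for (c, r) in cells.values()])
    centred = _recenter(raw)
    positions = {lab: tuple(p) for lab, p in zip(cells, centred)}
    biotin_labels = tuple(f"r{r:02d}c{c:02d}" for (c, r) in _BIOTIN_CELLS)
    return RectangleLayout(
        cells=cells,
        positions=positions,
        detection_labels=tuple(det_cells),
        alignment_labels=_ALIGN_LABELS,
        excluded_labels=biotin_labels,
    )


def build_bs_pair() -> tuple:
    """The 3 BS / 6 BS design pair sharing the arrowhead + line pattern.

    Returns ``(bs3, bs6)``.  Both variants contain the same six site
    positions; the 3 BS variant probes sites 1-3 and retains 4-6 as
    absent-by-design sites for false-positive scoring.
    """
    layout = rectangle_layout()
    bs_cells = [(6, 9), (9, 9), (12, 9), (6, 4), (9, 4), (12, 4)]
    align_xy = [
        (c * _PITCH_X, r * _PITCH_Y) for (c, r) in _ALIGN_CELLS
    ]
    bs_xy = [(c * _PITCH_X, r * _PITCH_Y) for (c, r) in bs_cells]
    sites = _recenter(np.array(bs_xy + align_xy))
    labels = [f"bs{i + 1}" for i in range(6)] + list(layout.alignment_labels)
    n = len(sites)
    align_mask = np.zeros(n, bool)
    align_mask[6:] = True
    probe6 = np.zeros(n, bool)
    probe6[:6] = True
    probe3 = np.zeros(n, bool)
    probe3[:3] = True
    bs6 = SitePattern("bs6", sites, labels, probe6, align_mask)
    bs3 = SitePattern("bs3", sites, labels, probe3, align_mask)
    return bs3, bs6


def default_variant_config() -> dict:
    """Default 18-variant assignment covering all 168 detection labels.

    Variants v01-v14 tile the 168 labels disjointly (168 = 14 x 12); v15-v18
    re-probe 48 evenly spaced labels so every probed set is distinct and the
    union is exactly the full label set.
    """
    labels = list(rectangle_layout().detection_labels)
    assert len(labels) == 168
    config = {}
    for i in range(14):
        config[f"v{i + 1:02d}"] = labels[12 * i: 12 * (i + 1)]
    reused = [labels[j] for j in range(0, 96, 2)]
    for i in range(4):
        config[f"v{i + 15:02d}"] = reused[12 * i: 12 * (i + 1)]
    return config


def build_variant_library(config: Mapping[str, Sequence[str]] | None = None) -> list:
    """Build the template library of rectangle variants.

    ``config`` maps variant names to the detection-site labels probed in that
    variant (default: :func:`default_variant_config`).  Every variant pattern
    contains the full rectangle layout (shared frame, identical alignment
    coordinates); non-probed detection sites are retained as absent-by-design
    sites.  Duplicate variant names or coinciding probed sets are rejected.
    """
    if config is None:
        config = default_variant_config()
    names = list(config)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variant names in config")
    layout = rectangle_layout()
    all_labels = list(layout.detection_labels) + list(layout.alignment_labels)
    sites = np.array([layout.positions[lab] for lab in all_labels])
    align_mask = np.array([lab in layout.alignment_labels for lab in all_labels])
    seen: dict[frozenset, str] = {}
    patterns = []
    for name, probed in config.items():
        probed_set = frozenset(probed)
        if len(probed_set) != len(list(probed)):
            raise ValueError(f"variant {name!r} lists duplicate labels")
        unknown = probed_set - set(layout.detection_labels)
        if unknown:
            raise ValueError(f"variant {name!r} probes unknown labels: {sorted(unknown)}")
        if probed_set in seen:
            raise ValueError(
                f"variants {seen[probed_set]!r} and {name!r} probe identical site sets"
            )
        seen[probed_set] = name
        probe_mask = np.array([lab in probed_set for lab in all_labels])
        patterns.append(SitePattern(name, sites, all_labels, probe_mask, align_mask))
    return patterns


# ---------------------------------------------------------------------------
# template rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSpec:
    """Rendering parameters for design templates.

    ``render_sigma`` is the Gaussian spot width in nm placed on each site
    (3 nm for grid analyses, 2 nm for the staple-excess series, 1 nm for
    single-site designs); ``bin_size`` is nm per rendered pixel.  When
    ``image_extent`` is None a square extent covering all sites plus a
    4-sigma + 10 nm margin is chosen.
    """

    render_sigma: float = 3.0
    bin_size: float = 1.0
    image_extent: float | None = None

    def __post_init__(self):
        if self.render_sigma <= 0:
            raise ValueError("render_sigma must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


@dataclass(frozen=True)
class TemplateImage:
    """Rendered design template on a regular nm grid.

    ``data[iy, ix]`` covers the square with lower-left corner
    ``origin + (ix, iy) * bin_size`` in the pattern's nm frame (y up).
    """

    data: np.ndarray
    bin_size: float
    origin: tuple
    render_sigma: float
    name: str = ""

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixel_centers(self) -> tuple:
        """Return ``(x_centers, y_centers)`` in nm."""
        h, w = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(w) + 0.5) * self.bin_size
        ys = y0 + (np.arange(h) + 0.5) * self.bin_size
        return xs, ys

    def argmax_nm(self) -> tuple:
        iy, ix = np.unravel_index(int(np.argmax(self.data)), self.data.shape)
        xs, ys = self.pixel_centers()
        return float(xs[ix]), float(ys[iy])

    def save_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(str(path), self.data, origin="lower", cmap="magma")


def _auto_extent(points: np.ndarray, sigma: float, pad: float = 10.0) -> float:
    reach = float(np.abs(points).max()) if len(points) else 0.0
    return 2.0 * (reach + 4.0 * sigma + pad)


def render_gaussians(
    points: np.ndarray,
    sigma: float,
    bin_size: float,
    extent: float,
    amplitudes: np.ndarray | None = None,
) -> tuple:
    """Sum of isotropic Gaussians sampled on a centred square grid.

    Returns ``(data, origin)``; shared by template rendering and tests.
    """
    n = max(int(np.ceil(extent / bin_size)), 1)
    origin = (-n * bin_size / 2.0, -n * bin_size / 2.0)
    xs = origin[0] + (np.arange(n) + 0.5) * bin_size
    ys = origin[1] + (np.arange(n) + 0.5) * bin_size
    data = np.zeros((n, n))
    if amplitudes is None:
        amplitudes = np.ones(len(points))
    for (x, y), a in zip(np.asarray(points, float), amplitudes):
        gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
        data += a * gy[:, None] * gx[None, :]
    return data, origin


def render_template(pattern: SitePattern, spec: TemplateSpec = TemplateSpec()) -> TemplateImage:
    """Render the ideal template image of a pattern.

    Unit-amplitude Gaussians of width ``spec.render_sigma`` are placed on
    every probed and alignment site (absent-by-design sites carry no docking
    strand and are not rendered).
    """
    if pattern.n_sites == 0:
        raise ValueError("pattern is empty")
    points = np.vstack([pattern.probed_sites, pattern.alignment_sites])
    if len(points) == 0:
        raise ValueError("pattern has no probed or alignment sites to render")
    extent = spec.image_extent
    min_extent = 2.0 * (np.abs(points).max() + 3.0 * spec.render_sigma)
    if extent is None:
        # auto extent covers the full site layout (incl. absent-by-design
        # sites) so all variants of a library render on one common grid
        extent = _auto_extent(pattern.sites, spec.render_sigma)
    elif extent < min_extent:
        raise ValueError(
            f"image_extent {extent} nm too small; need >= {min_extent:.1f} nm "
            "to cover all sites plus a 3-sigma margin"
        )
    data, origin = render_gaussians(points, spec.render_sigma, spec.bin_size, extent)
    return TemplateImage(
        data=data,
        bin_size=spec.bin_size,
        origin=origin,
        render_sigma=spec.render_sigma,
        name=pattern.name,
    )


# ---------------------------------------------------------------------------
# design file IO
# ---------------------------------------------------------------------------

def save_design(pattern: SitePattern, path) -> None:
    """Write a design specification as YAML (name, sites in nm, flags)."""
    doc = {
        "name": pattern.name,
        "sites": [
            {
                "label": lab,
                "x": float(x),
                "y": float(y),
                "probed": bool(p),
                "alignment": bool(a),
            }
            for lab, (x, y), p, a in zip(
                pattern.site_labels, pattern.sites, pattern.probe_mask, pattern.alignment_mask
            )
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_design(path) -> SitePattern:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sites = np.array([[s["x"], s["y"]] for s in doc["sites"]])
    return SitePattern(
        name=doc["name"],
        sites=sites,
        site_labels=[s["label"] for s in doc["sites"]],
        probe_mask=np.array([bool(s["probed"]) for s in doc["sites"]]),
        alignment_mask=np.array([bool(s["alignment"]) for s in doc["sites"]]),
    )
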