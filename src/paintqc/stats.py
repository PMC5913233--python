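"""Two-color coincidence statistics, incorporation estimates, saturation fit
and heatmap assembly.

The two-color analysis decouples the two reasons a docking site can go
undetected: the staple was never incorporated into the origami, or it is
incorporated but inaccessible.  Staples carry orthogonal docking sites on
their 3'- and 5'-ends and are imaged in two channels; every designed site
instance falls into one of four categories (both ends detected / only 3' /
only 5' / none).  Assuming the two ends are detected independently, the
probability that an *incorporated* staple escapes both channels is

    chance_none = miss3 * miss5,
    miss3 = f_only5 + f_none,   miss5 = f_only3 + f_none.

When ``chance_none`` is much smaller than ``f_none``, the no-signal category
is attributed to missing incorporation: ``incorporated = 1 - f_none``.  The
difference between incorporation and single-channel (3') detection,
``offset = incorporated - det3``, translates detection efficiencies into
absolute incorporation efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .designs import RectangleLayout
from .site_detect import SiteCallMatrix

__all__ = [
    "TwoColorTally",
    "IncorporationEstimate",
    "MMFit",
    "Heatmap",
    "coincidence_tally",
    "independence_estimate",
    "detection_to_incorporation",
    "fit_michaelis_menten",
    "build_heatmap",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TwoColorTally:
    """Fractions of docking-site instances per joint detection category."""

    f_both: float
    f_only3: float
    f_only5: float
    f_none: float
    n_sites: int

    def __post_init__(self):
        fracs = (self.f_both, self.f_only3, self.f_only5, self.f_none)
        if any(f < 0 for f in fracs):
            raise ValueError("category fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > _SUM_TOL:
            raise ValueError("category fractions must sum to 1")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass(frozen=True)
class IncorporationEstimate:
    """Derived incorporation/miss statistics under channel independence."""

    miss3: float
    miss5: float
    chance_none: float
    incorporated: float
    det3: float
    det5: float
    offset: float


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit of detection efficiency vs staple molar excess."""

    vmax: float
    km: float
    residuals: np.ndarray
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.vmax * x / (self.km + x)


@dataclass(frozen=True)
class Heatmap:
    """Per-staple-position efficiencies on the rectangle layout."""

    values: Mapping[str, float]
    n_structures: Mapping[str, int]
    layout: RectangleLayout

    def to_rows(self) -> list:
        """Rows of (label, row, col, value, n); excluded positions carry None."""
        rows = []
        for lab in self.layout.detection_labels:
            col, r = self.layout.cells[lab]
            rows.append((lab, r, col, self.values.get(lab), self.n_structures.get(lab, 0)))
        for lab in self.layout.excluded_labels:
            # biotin-adjacent positions: no docking strand, no value
            rows.append((lab, None, None, None, 0))
        return rows

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label,row,col,value,n_structures\n")
            for lab, r, c, v, n in self.to_rows():
                fh.write(
                    f"{lab},{'' if r is None else r},{'' if c is None else c},"
                    f"{'' if v is None else f'{v:.6f}'},{n}\n"
                )

    def save_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rows = [r for _, r, _, _, _ in self.to_rows() if r is not None]
        cols = [c for _, _, c, _, _ in self.to_rows() if c is not None]
        grid = np.full((max(rows) + 1, max(cols) + 1), np.nan)
        for lab, r, c, v, _n in self.to_rows():
            if r is not None and v is not None:
                grid[r, c] = v
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(grid, origin="lower", cmap="viridis", vmin=0, vmax=1)
        fig.colorbar(im, ax=ax, label="detection efficiency")
        ax.set_xlabel("column")
        ax.set_ylabel("row")
        fig.tight_layout()
        fig.savefig(str(path), dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# two-color coincidence
# ---------------------------------------------------------------------------

def _detected_matrix(calls) -> tuple:
    if isinstance(calls, SiteCallMatrix):
        det = calls.detected[:, calls.probe_mask]
        labels = tuple(
            lab for lab, p in zip(calls.site_labels, calls.probe_mask) if p
        )
        return det, labels, calls.structure_ids
    det = np.atleast_2d(np.asarray(calls, dtype=bool))
    return det, None, None


def coincidence_tally(calls_ch3, calls_ch5) -> TwoColorTally:
    """Tally joint 3'/5' detection categories over all probed site instances.

    Accepts two :class:`SiteCallMatrix` objects (probed sites are compared)
    or two boolean ``(structures, sites)`` arrays covering the same
    structures and sites.
    """
    det3, labels3, ids3 = _detected_matrix(calls_ch3)
    det5, labels5, ids5 = _detected_matrix(calls_ch5)
    if det3.shape != det5.shape:
        raise ValueError("channels cover different structure/site sets")
    if labels3 is not None and labels5 is not None and labels3 != labels5:
        raise ValueError("channels cover different site labels")
    if ids3 is not None and ids5 is not None and ids3 != ids5:
        raise ValueError("channels cover different structures")
    n = det3.size
    if n == 0:
        raise ValueError("no site instances to tally")
    both = float(np.mean(det3 & det5))
    only3 = float(np.mean(det3 & ~det5))
    only5 = float(np.mean(~det3 & det5))
    none = float(np.mean(~det3 & ~det5))
    return TwoColorTally(both, only3, only5, none, n_sites=n)


def independence_estimate(tally: TwoColorTally) -> IncorporationEstimate:
    """Derive incorporation and miss probabilities from a two-color tally.

    ``chance_none = miss3 * miss5`` is the expected no-signal fraction for
    incorporated staples under channel independence; when it is small
    compared to the observed ``f_none``, the no-signal category reflects
    missing incorporation and ``incorporated = 1 - f_none``.
    """
    miss3 = tally.f_only5 + tally.f_none
    miss5 = tally.f_only3 + tally.f_none
    det3 = tally.f_both + tally.f_only3
    det5 = tally.f_both + tally.f_only5
    incorporated = 1.0 - tally.f_none
    return IncorporationEstimate(
        miss3=miss3,
        miss5=miss5,
        chance_none=miss3 * miss5,
        incorporated=incorporated,
        det3=det3,
        det5=det5,
        offset=incorporated - det3,
    )


def detection_to_incorporation(efficiency: float, offset: float = 0.07) -> float:
    """Translate a detection efficiency into an incorporation efficiency.

    Adds the two-color-derived offset and clamps to [0, 1].  The default
    offset of 7% is used only when no two-color data are available.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    if not 0.0 <= offset <= 1.0:
        raise ValueError("offset must lie in [0, 1]")
    return min(efficiency + offset, 1.0)


# ---------------------------------------------------------------------------
# saturation fit
# ---------------------------------------------------------------------------

def fit_michaelis_menten(excess_values, efficiencies) -> MMFit:
    """Least-squares fit of ``E(x) = vmax * x / (km + x)``.

    ``excess_values`` are staple molar excesses over the scaffold;
    efficiencies keep whatever unit they are given in (fraction or percent).
    Raw unweighted residuals; a near-zero ``km`` (constant efficiencies) is
    flagged degenerate.
    """
    x = np.asarray(excess_values, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("excess_values and efficiencies must be 1D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit a Michaelis-Menten curve")
    if np.any(x <= 0):
        raise ValueError("molar excess values must be positive")

    def mm(xv, vmax, km):
        return vmax * xv / (km + xv)

    p0 = (float(y.max()) or 1.0, float(np.median(x)))
    popt, _ = optimize.curve_fit(
        mm, x, y, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
    )
    vmax, km = popt
    resid = y - mm(x, vmax, km)
    degenerate = bool(km < 1e-6 * np.median(x))
    return MMFit(vmax=float(vmax), km=float(km), residuals=resid, degenerate=degenerate)


# ---------------------------------------------------------------------------
# heatmap assembly
# ---------------------------------------------------------------------------

def build_heatmap(
    per_site_efficiencies: Mapping[str, Sequence[tuple]],
    layout: RectangleLayout,
    layouts: Mapping[str, RectangleLayout] | None = None,
) -> Heatmap:
    """Merge per-variant site efficiencies onto the rectangle layout.

    ``per_site_efficiencies`` maps variant name to an iterable of
    ``(label, efficiency, n_structures)``.  Labels probed in several variants
    are averaged weighted by structure counts.  Biotin-adjacent (excluded)
    labels may not carry values; with per-variant ``layouts``, a label placed
    at different positions in different variants is rejected.
    """
    acc: dict[str, float] = {}
    wts: dict[str, int] = {}
    placement: dict[str, tuple] = {}
    for variant, entries in per_site_efficiencies.items():
        var_layout = layouts.get(variant, layout) if layouts else layout
        for label, eff, n in entries:
            if label in layout.excluded_labels:
                raise ValueError(f"label {label!r} is excluded (biotin-adjacent)")
            if label not in var_layout.cells:
                raise ValueError(f"label {label!r} not in layout")
            cell = var_layout.cells[label]
            if label in placement and placement[label] != cell:
                raise ValueError(
                    f"label {label!r} placed at conflicting positions "
                    f"{placement[label]} and {cell}"
                )
            placement[label] = cell
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency for {label!r} outside [0, 1]")
            acc[label] = acc.get(label, 0.0) + eff * n
            wts[label] = wts.get(label, 0) + n
    values = {lab: acc[lab] / wts[lab] for lab in acc if wts[lab] > 0}
    return Heatmap(values=values, n_structures=wts, layout=layout)
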