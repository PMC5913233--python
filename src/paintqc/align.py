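"""Template alignment by stepwise rotational cross-correlation.

A picked structure is rendered as a 2D localization histogram on the
template's grid, blurred, rotated stepwise through a full circle, and at
every step cross-correlated with the template image in the frequency domain
(which yields the translation search for free).  The transform with the
globally highest normalized correlation wins; ties are broken towards the
smallest angle and the non-mirrored orientation.

Scores are normalized by the image norms (``corr = <T, S_shift> / (|T||S|)``)
so they are comparable across templates of a library, enabling template
classification; scores lie in [0, 1] for the non-negative images used here.

Sign convention: :class:`AlignmentResult` stores the *correction* transform —
the rotation/shift applied to the structure's localizations (mirror first,
then rotation about the pick center, then translation) that maps them onto
the template frame.  A structure that was physically rotated by +37 deg is
therefore reported with ``angle = 323 deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .designs import TemplateImage
from .locio import StructureLocs

__all__ = [
    "AlignmentResult",
    "render_structure",
    "align_to_template",
    "classify_template",
    "transform_locs",
]

DEFAULT_MIN_CORRELATION = 0.45  # uniform-noise picks score ~0.1-0.3 (see docs)


@dataclass(frozen=True)
class AlignmentResult:
    """Correction transform mapping a structure onto a template."""

    angle: float  # deg in [0, 360)
    shift: tuple  # (dx, dy) nm
    mirror: bool
    correlation: float
    template: str = ""
    assigned: bool = True

    def __post_init__(self):
        if not np.isfinite(self.correlation):
            raise ValueError("correlation must be finite")
        object.__setattr__(self, "angle", float(self.angle) % 360.0)


def _as_xy(structure_locs) -> np.ndarray:
    if isinstance(structure_locs, StructureLocs):
        return structure_locs.xy
    return np.asarray(structure_locs, dtype=float)


def render_structure(
    structure_locs,
    bin_size: float = 1.0,
    blur_sigma: float = 0.0,
    extent: float | None = None,
) -> TemplateImage:
    """Render a structure as a (optionally blurred) 2D localization histogram.

    The histogram is computed on a centred square grid; total counts are
    preserved before blurring.  ``blur_sigma`` is in nm.
    """
    xy = _as_xy(structure_locs)
    if len(xy) == 0:
        raise ValueError("cannot render an empty structure")
    if extent is None:
        extent = 2.0 * (np.abs(xy).max() + max(3.0 * blur_sigma, 2.0 * bin_size))
    n = max(int(np.ceil(extent / bin_size)), 1)
    origin = (-n * bin_size / 2.0, -n * bin_size / 2.0)
    data = _hist_stack(xy, np.array([0.0]), origin, (n, n), bin_size)[0]
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, blur_sigma / bin_size)
    return TemplateImage(
        data=data, bin_size=bin_size, origin=origin, render_sigma=blur_sigma,
        name="structure",
    )


def _hist_stack(
    xy: np.ndarray,
    angles_deg: np.ndarray,
    origin: tuple,
    shape: tuple,
    bin_size: float,
) -> np.ndarray:
    """2D histograms of ``xy`` rotated by each angle, as an (A, H, W) stack."""
    h, w = shape
    a = np.radians(angles_deg)[:, None]
    c, s = np.cos(a), np.sin(a)
    x, y = xy[:, 0][None, :], xy[:, 1][None, :]
    xr = c * x - s * y
    yr = s * x + c * y
    ix = np.floor((xr - origin[0]) / bin_size).astype(np.int64)
    iy = np.floor((yr - origin[1]) / bin_size).astype(np.int64)
    valid = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    aidx = np.broadcast_to(np.arange(len(angles_deg))[:, None], ix.shape)
    lin = (aidx * h + iy) * w + ix
    counts = np.bincount(lin[valid], minlength=len(angles_deg) * h * w)
    return counts.reshape(len(angles_deg), h, w).astype(np.float32)


def align_to_templates(
    structure_locs,
    templates,
    step_deg: float = 1.0,
    try_mirror: bool = False,
    blur_sigma: float | None = None,
    max_shift_nm: float | None = None,
    angle_chunk: int = 90,
) -> list:
    """Align one structure against several templates sharing one grid.

    The rotated, blurred histogram stack of the structure (the expensive
    part) is computed once and correlated with every template, which makes
    library classification tractable.  All templates must share shape,
    origin and bin size.  ``max_shift_nm`` bounds the translation search
    (None: unrestricted); picks are centred on the localization centroid, so
    a window of a few tens of nm is ample.  Returns one
    :class:`AlignmentResult` per template.
    """
    templates = list(templates)
    if not templates:
        raise ValueError("template library is empty")
    xy = _as_xy(structure_locs)
    if len(xy) == 0:
        raise ValueError("cannot align an empty structure")
    ref = templates[0]
    h, w = ref.data.shape
    bs = ref.bin_size
    for t in templates[1:]:
        if t.data.shape != (h, w) or t.bin_size != bs or t.origin != ref.origin:
            raise ValueError("templates must share shape, origin and bin size")
    Ts = [np.asarray(t.data, dtype=np.float32) for t in templates]
    if any(not np.any(T > 0) for T in Ts):
        raise ValueError("template image is degenerate (all zero)")
    if blur_sigma is None:
        blur_sigma = ref.render_sigma
    if max_shift_nm is None:
        win_h, win_w = h - 1, w - 1
    else:
        win_h = win_w = max(int(np.ceil(max_shift_nm / bs)), 1)
    fshape = (
        sp_fft.next_fast_len(h + win_h),
        sp_fft.next_fast_len(w + win_w),
    )
    dy_idx = np.concatenate([np.arange(0, win_h + 1), np.arange(-win_h, 0)]) % fshape[0]
    dx_idx = np.concatenate([np.arange(0, win_w + 1), np.arange(-win_w, 0)]) % fshape[1]
    Tfs = [sp_fft.rfft2(T, s=fshape) for T in Ts]
    norm_ts = [float(np.sqrt((T.astype(np.float64) ** 2).sum())) for T in Ts]
    angles = np.arange(0.0, 360.0, step_deg)
    sigma_bins = blur_sigma / bs

    best = [None] * len(templates)
    for mirror in ((False, True) if try_mirror else (False,)):
        pts = xy * np.array([-1.0, 1.0]) if mirror else xy
        for lo in range(0, len(angles), angle_chunk):
            chunk = angles[lo: lo + angle_chunk]
            stack = _hist_stack(pts, chunk, ref.origin, (h, w), bs)
            if sigma_bins > 0:
                ndimage.gaussian_filter(
                    stack, (0.0, sigma_bins, sigma_bins), output=stack
                )
            norms = np.sqrt((stack.astype(np.float64) ** 2).sum(axis=(1, 2)))
            Sf_conj = np.conj(sp_fft.rfft2(stack, s=fshape, axes=(-2, -1)))
            for ti, (Tf, norm_t) in enumerate(zip(Tfs, norm_ts)):
                C = sp_fft.irfft2(Tf[None] * Sf_conj, s=fshape, axes=(-2, -1))
                Cw = C[:, dy_idx[:, None], dx_idx[None, :]]
                flat = Cw.reshape(len(chunk), -1)
                peak_idx = np.argmax(flat, axis=1)
                peaks = flat[np.arange(len(chunk)), peak_idx]
                with np.errstate(divide="ignore", invalid="ignore"):
                    scores = np.where(norms > 0, peaks / (norm_t * norms), -np.inf)
                k = int(np.argmax(scores))
                if best[ti] is None or scores[k] > best[ti][0]:
                    iy, ix = np.unravel_index(int(peak_idx[k]), Cw.shape[1:])
                    dy = iy if iy <= win_h else iy - (2 * win_h + 1)
                    dx = ix if ix <= win_w else ix - (2 * win_w + 1)
                    best[ti] = (
                        float(scores[k]),
                        float(chunk[k]),
                        (dx * bs, dy * bs),
                        mirror,
                    )
    return [
        AlignmentResult(
            angle=angle, shift=shift, mirror=mirror, correlation=corr,
            template=t.name,
        )
        for t, (corr, angle, shift, mirror) in zip(templates, best)
    ]


def align_to_template(
    structure_locs,
    template: TemplateImage,
    step_deg: float = 1.0,
    try_mirror: bool = False,
    blur_sigma: float | None = None,
    max_shift_nm: float | None = None,
    angle_chunk: int = 90,
) -> AlignmentResult:
    """Align a structure to one template by stepwise rotation.

    The structure is rendered on the template's own grid; ``blur_sigma``
    defaults to the template's render sigma so structure and template spots
    have comparable widths.  Returns the best correction transform; ties are
    broken towards the smallest angle and the non-mirrored orientation.
    """
    return align_to_templates(
        structure_locs,
        [template],
        step_deg=step_deg,
        try_mirror=try_mirror,
        blur_sigma=blur_sigma,
        max_shift_nm=max_shift_nm,
        angle_chunk=angle_chunk,
    )[0]


def classify_template(
    structure_locs,
    template_library,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
    **kwargs,
) -> AlignmentResult:
    """Assign a structure to the best-matching template of a library.

    Aligns the structure against every template and returns the result with
    the highest correlation.  Structures whose best correlation falls below
    ``min_correlation`` are flagged unassigned (the automated analogue of
    discarding structures without a correct alignment pattern).
    """
    templates = list(template_library)
    if not templates:
        raise ValueError("template library is empty")
    ref = templates[0]
    shared = all(
        t.data.shape == ref.data.shape
        and t.bin_size == ref.bin_size
        and t.origin == ref.origin
        for t in templates[1:]
    )
    if shared:
        results = align_to_templates(structure_locs, templates, **kwargs)
    else:
        results = [align_to_template(structure_locs, t, **kwargs) for t in templates]
    best = max(results, key=lambda r: r.correlation)
    if best.correlation < min_correlation:
        best = replace(best, assigned=False)
    return best


def transform_locs(structure_locs, alignment: AlignmentResult, inverse: bool = False):
    """Apply (or undo) a correction transform to localization coordinates.

    Forward order: mirror (if set), rotation by ``alignment.angle`` about the
    pick center, translation by ``alignment.shift``.  Returns the same type
    as the input (``StructureLocs`` or a bare ``(n, 2)`` array).
    """
    if not (np.isfinite(alignment.angle) and np.all(np.isfinite(alignment.shift))):
        raise ValueError("alignment transform must be finite")
    xy = _as_xy(structure_locs)
    a = math.radians(alignment.angle)
    c, s = math.cos(a), math.sin(a)
    rot = np.array([[c, -s], [s, c]])
    shift = np.asarray(alignment.shift, dtype=float)
    flip = np.array([-1.0, 1.0])
    if inverse:
        out = (xy - shift) @ rot  # rot.T applied on the right == @ rot
        if alignment.mirror:
            out = out * flip
    else:
        out = xy * flip if alignment.mirror else xy
        out = out @ rot.T + shift
    if isinstance(structure_locs, StructureLocs):
        return StructureLocs(
            structure_id=structure_locs.structure_id,
            xy=out,
            frame=structure_locs.frame,
            photons=structure_locs.photons,
            precision_nm=structure_locs.precision_nm,
        )
    return out
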