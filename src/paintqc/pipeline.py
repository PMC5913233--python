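"""End-to-end analysis: pick -> align -> count -> threshold -> call -> report.

Presets bundle the per-analysis parameters (counting-disc diameter, template
render sigma, image binning, rotation step):

========== ============== ============ ========
preset     count diameter render sigma bin size
========== ============== ============ ========
grid20     20 nm          3 nm         2 nm
twocolor   20 nm          3 nm         2 nm
excess     18 nm          2 nm         2 nm
bs3bs6     5 nm           1 nm         1 nm
variants18 6 nm           1 nm         1 nm
========== ============== ============ ========
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import align as _align
from . import locio, site_detect
from .designs import SitePattern, TemplateImage, TemplateSpec, render_template

__all__ = ["AnalysisParams", "AnalysisResult", "PRESETS", "analyze_table"]


@dataclass(frozen=True)
class AnalysisParams:
    """Numeric parameters of one analysis run."""

    count_diameter: float = 20.0
    render_sigma: float = 3.0
    bin_size: float = 2.0
    step_deg: float = 1.0
    try_mirror: bool = False
    # None: 0 for designs without alignment sites (nothing to verify, e.g.
    # the symmetric grid), DEFAULT_MIN_CORRELATION for designs with an
    # arrowhead + line pattern (the automated malformed-structure discard).
    min_correlation: float | None = None
    max_shift_nm: float = 50.0
    threshold_mode: str = "half_peak"
    threshold_override: float | None = None
    pick_radius_nm: float | None = None  # default: pattern radius + 40 nm
    min_locs: int = 100
    bootstrap_subset: int = 250
    bootstrap_reps: int = 10


PRESETS = {
    "grid20": AnalysisParams(count_diameter=20.0, render_sigma=3.0, bin_size=2.0),
    "twocolor": AnalysisParams(count_diameter=20.0, render_sigma=3.0, bin_size=2.0),
    "excess": AnalysisParams(count_diameter=18.0, render_sigma=2.0, bin_size=2.0),
    "bs3bs6": AnalysisParams(count_diameter=5.0, render_sigma=1.0, bin_size=1.0),
    "variants18": AnalysisParams(count_diameter=6.0, render_sigma=1.0, bin_size=1.0),
}


@dataclass
class AnalysisResult:
    """Everything a run produces, for reporting and downstream statistics."""

    pattern: SitePattern
    template: TemplateImage
    alignments: list
    call_matrix: site_detect.SiteCallMatrix
    threshold_fit: site_detect.ThresholdFit | None
    report: site_detect.EfficiencyReport
    false_positive_rate: float | None
    n_picked: int
    n_discarded: int


def analyze_table(
    table: locio.LocalizationTable,
    pattern: SitePattern,
    params: AnalysisParams = PRESETS["grid20"],
    rng: np.random.Generator | int = 0,
    run_bootstrap: bool = False,
) -> AnalysisResult:
    """Run the full single-design detection pipeline on a localization table.

    Structures are picked automatically, aligned to the design template by
    rotational cross-correlation (picks below ``min_correlation`` are
    discarded, the automated analogue of removing structures without a
    correct alignment pattern), localizations are counted per site, a
    detection threshold is fitted to the pooled counts histogram (unless
    overridden) and sites are called.  Returns counts, calls, efficiencies
    and — when the design contains absent-by-design sites — the
    false-positive rate.
    """
    if len(table) == 0:
        raise ValueError("localization table is empty")
    template = render_template(
        pattern, TemplateSpec(render_sigma=params.render_sigma, bin_size=params.bin_size)
    )
    pick_radius = params.pick_radius_nm
    if pick_radius is None:
        pick_radius = pattern.radius() + 40.0
    regions = locio.pick_structures(
        table, expected_radius_nm=pick_radius, min_locs=params.min_locs
    )
    if not regions:
        raise ValueError("no structures picked; check pick radius / min_locs")

    min_corr = params.min_correlation
    if min_corr is None:
        min_corr = (
            _align.DEFAULT_MIN_CORRELATION if pattern.alignment_mask.any() else 0.0
        )

    config = site_detect.SiteCountConfig(count_diameter=params.count_diameter)
    alignments = []
    counts_rows = []
    ids = []
    n_discarded = 0
    for region in regions:
        locs = locio.extract(table, region)
        res = _align.align_to_template(
            locs,
            template,
            step_deg=params.step_deg,
            try_mirror=params.try_mirror,
            max_shift_nm=params.max_shift_nm,
        )
        if res.correlation < min_corr:
            n_discarded += 1
            continue
        aligned = _align.transform_locs(locs, res)
        counts_rows.append(site_detect.count_sites(aligned, pattern, config))
        alignments.append(res)
        ids.append(region.structure_id)
    if not counts_rows:
        raise ValueError("every picked structure fell below min_correlation")
    counts = np.vstack(counts_rows)

    fit = None
    if params.threshold_override is not None:
        threshold = params.threshold_override
    else:
        scored = counts[:, ~pattern.alignment_mask]
        fit = site_detect.fit_threshold(scored, mode=params.threshold_mode)
        threshold = fit.threshold
    calls = site_detect.call_sites(counts, threshold, pattern, structure_ids=ids)
    report = site_detect.efficiency(calls)
    if run_bootstrap and params.bootstrap_subset <= calls.n_structures:
        report = replace(
            report,
            bootstrap_std_per_site=site_detect.bootstrap_std(
                calls,
                subset_size=params.bootstrap_subset,
                reps=params.bootstrap_reps,
                rng=rng,
            ),
        )
    fp = (
        site_detect.false_positive_rate(calls)
        if calls.absent_mask.any()
        else None
    )
    return AnalysisResult(
        pattern=pattern,
        template=template,
        alignments=alignments,
        call_matrix=calls,
        threshold_fit=fit,
        report=report,
        false_positive_rate=fp,
        n_picked=len(regions),
        n_discarded=n_discarded,
    )
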