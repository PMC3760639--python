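"""Dual-channel miRNA array analysis.

Implements the spotted-array detection and enrichment workflow for paired
exosome (Hy3) / donor-cell (Hy5) hybridizations:

1. per-slide, per-channel background = median foreground of the whole slide;
2. per-probe detection status per slide from the replicate spots: *absent*
   when at least half the replicate foregrounds are at or below their spot
   background, otherwise *detectable* when the summarized (median replicate)
   signal exceeds ``detect_multiplier`` x the slide background, otherwise
   *below_limit*;
3. aggregation across slides: a probe is *detected* in a channel only when
   detectable on at least ``min_slides`` slides (default: all);
4. global Lowess normalization of the log ratio M = log2(Hy3/Hy5) against
   mean log intensity A per slide, subtracting the fitted trend;
5. mean +/- sample SD of the normalized log2 ratios over slides, three-way
   fold-change classification with inclusive boundaries, Venn set algebra of
   the detected sets, and ranking of the most exosome-enriched probes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ConfigurationError, InvariantError

__all__ = [
    "SlideBackground",
    "VennCounts",
    "MirnaParams",
    "MirnaResult",
    "estimate_slide_background",
    "call_slide_status",
    "aggregate_detection",
    "detection_profiles",
    "lowess_normalize_slide",
    "normalize_ratios",
    "summarize_ratios",
    "classify_fold_change",
    "build_venn",
    "rank_enriched",
    "run_mirna_pipeline",
]

log = logging.getLogger(__name__)

CHANNELS = ("Hy3", "Hy5")
_FG_COLUMN = {"Hy3": "hy3_fg", "Hy5": "hy5_fg"}
_BG_COLUMN = {"Hy3": "hy3_bg", "Hy5": "hy5_bg"}

ELEVATED_IN_EXOSOMES = "elevated_in_exosomes"
EQUAL = "equal"
ELEVATED_IN_CELLS = "elevated_in_cells"


@dataclass(frozen=True)
class SlideBackground:
    """Slide-wide channel background: the median of all foreground signals."""

    slide: int
    channel: str
    background: float


@dataclass(frozen=True)
class VennCounts:
    """Sizes of the exosome/cell detected sets and their overlap."""

    exo_total: int
    cell_total: int
    shared: int

    @property
    def exo_only(self) -> int:
        return self.exo_total - self.shared

    @property
    def cell_only(self) -> int:
        return self.cell_total - self.shared

    @property
    def union_size(self) -> int:
        return self.exo_only + self.cell_only + self.shared

    def as_dict(self) -> dict[str, int]:
        return {
            "exo_total": self.exo_total,
            "cell_total": self.cell_total,
            "shared": self.shared,
            "exo_only": self.exo_only,
            "cell_only": self.cell_only,
            "union_size": self.union_size,
        }


@dataclass(frozen=True)
class MirnaParams:
    """Tunable parameters of the dual-channel pipeline.

    ``detect_multiplier``: detectability limit as a multiple of the slide
    background (default 3).  ``min_slides``: slides on which a probe must be
    detectable to count as detected; ``None`` means all available slides.
    ``threshold_log2fc``: half-width of the "equal" band on the log2 scale
    (default 2.0, i.e. 4-fold).  ``lowess_span``/``lowess_iterations``:
    fraction of points per local fit and robustness passes of the Lowess
    normalization.
    """

    detect_multiplier: float = 3.0
    min_slides: int | None = None
    threshold_log2fc: float = 2.0
    lowess_span: float = 0.3
    lowess_iterations: int = 1

    def __post_init__(self) -> None:
        if self.detect_multiplier <= 0:
            raise ConfigurationError(
                f"detect_multiplier must be > 0, got {self.detect_multiplier}"
            )
        if self.threshold_log2fc <= 0:
            raise ConfigurationError(
                f"threshold_log2fc must be > 0, got {self.threshold_log2fc}"
            )
        if not 0 < self.lowess_span <= 1:
            raise ConfigurationError(f"lowess_span must be in (0, 1], got {self.lowess_span}")
        if self.lowess_iterations < 0:
            raise ConfigurationError(
                f"lowess_iterations must be >= 0, got {self.lowess_iterations}"
            )
        if self.min_slides is not None and self.min_slides < 1:
            raise ConfigurationError(f"min_slides must be >= 1, got {self.min_slides}")


@dataclass
class MirnaResult:
    """Everything the dual-channel pipeline produces for one slide set."""

    backgrounds: list[SlideBackground]
    detection: pd.DataFrame  # probe x (channel status per slide + aggregate)
    ratio_table: pd.DataFrame  # probe_id, per-slide ratios, mean, sd, n, fc_class
    detected_exosome: set[str]
    detected_cell: set[str]
    venn: VennCounts
    excluded: dict[int, list[str]]  # slide -> probes excluded from the Lowess fit


def estimate_slide_background(slides: pd.DataFrame) -> list[SlideBackground]:
    """Median foreground per (slide, channel) over all replicate spots of all probes."""
    if slides.empty:
        raise ConfigurationError("slide set is empty")
    out: list[SlideBackground] = []
    for slide, group in slides.groupby("slide", sort=True):
        for channel in CHANNELS:
            values = group[_FG_COLUMN[channel]].to_numpy(float)
            if values.size == 0:
                raise ConfigurationError(f"slide {slide} has no {channel} spots")
            out.append(SlideBackground(int(slide), channel, float(np.median(values))))
    return out


def call_slide_status(
    replicate_foregrounds,
    replicate_spot_backgrounds,
    slide_background: float,
    detect_multiplier: float = 3.0,
) -> str:
    """Detection status of one probe in one channel on one slide.

    *absent* when foreground is at or below the spot background in at least
    ``ceil(k/2)`` of the ``k`` replicate spots (2 of 4 in the standard
    design); otherwise *detectable* when the median replicate foreground
    exceeds ``detect_multiplier`` x the slide-wide channel background;
    otherwise *below_limit*.
    """
    fg = np.asarray(replicate_foregrounds, dtype=float)
    bg = np.asarray(replicate_spot_backgrounds, dtype=float)
    if fg.shape != bg.shape or fg.ndim != 1 or fg.size == 0:
        raise ConfigurationError(
            f"replicate vectors must be equal-length 1-D and non-empty, "
            f"got shapes {fg.shape} and {bg.shape}"
        )
    n_at_or_below = int(np.sum(fg <= bg))
    if n_at_or_below >= math.ceil(fg.size / 2):
        return "absent"
    if float(np.median(fg)) > detect_multiplier * slide_background:
        return "detectable"
    return "below_limit"


def aggregate_detection(statuses, min_slides: int | None = None) -> str:
    """Cross-slide verdict: *detected* iff detectable on >= ``min_slides`` slides.

    ``min_slides=None`` requires detectability on every available slide; with
    the standard triplicate design this implements "fewer than 3 of 3 slides
    means unreliable, excluded from the detected set".
    """
    statuses = list(statuses)
    if not statuses:
        raise ConfigurationError("at least one slide status is required")
    if min_slides is None:
        min_slides = len(statuses)
    if min_slides > len(statuses):
        raise ConfigurationError(
            f"min_slides={min_slides} exceeds the {len(statuses)} available slides"
        )
    n_detectable = sum(s == "detectable" for s in statuses)
    return "detected" if n_detectable >= min_slides else "undetected"


def _replicate_pivot(slides: pd.DataFrame, column: str) -> pd.DataFrame:
    """probe x (slide, replicate) wide table of one signal column."""
    return slides.pivot_table(
        index="probe_id", columns=["slide", "replicate"], values=column, sort=True
    )


def detection_profiles(
    slides: pd.DataFrame, params: MirnaParams = MirnaParams()
) -> pd.DataFrame:
    """Per-probe detection statuses per slide/channel plus aggregated verdicts.

    Returns a DataFrame indexed by probe_id with one ``status_{channel}_s{slide}``
    column per slide and channel and one ``detected_{channel}`` aggregate
    column per channel ("detected"/"undetected").
    """
    backgrounds = {(b.slide, b.channel): b.background for b in estimate_slide_background(slides)}
    slide_ids = sorted(slides["slide"].unique())

    result: dict[str, pd.Series] = {}
    for channel in CHANNELS:
        fg = _replicate_pivot(slides, _FG_COLUMN[channel])
        bg = _replicate_pivot(slides, _BG_COLUMN[channel])
        per_slide = {}
        for slide in slide_ids:
            fg_s = fg[slide].to_numpy(float)
            bg_s = bg[slide].to_numpy(float)
            k = fg_s.shape[1]
            n_at_or_below = (fg_s <= bg_s).sum(axis=1)
            med = np.median(fg_s, axis=1)
            limit = params.detect_multiplier * backgrounds[(slide, channel)]
            status = np.where(
                n_at_or_below >= math.ceil(k / 2),
                "absent",
                np.where(med > limit, "detectable", "below_limit"),
            )
            per_slide[slide] = pd.Series(status, index=fg.index)
            result[f"status_{channel}_s{slide}"] = per_slide[slide]
        status_frame = pd.DataFrame(per_slide)
        min_slides = params.min_slides if params.min_slides is not None else len(slide_ids)
        if min_slides > len(slide_ids):
            raise ConfigurationError(
                f"min_slides={min_slides} exceeds the {len(slide_ids)} available slides"
            )
        detected = (status_frame == "detectable").sum(axis=1) >= min_slides
        result[f"detected_{channel}"] = detected.map({True: "detected", False: "undetected"})

    out = pd.DataFrame(result)
    out.index.name = "probe_id"
    return out


def lowess_normalize_slide(
    hy3: pd.Series,
    hy5: pd.Series,
    span: float = 0.3,
    iterations: int = 1,
) -> tuple[pd.Series, list[str]]:
    """Global Lowess normalization of one slide's summarized channel signals.

    Computes M = log2(Hy3/Hy5) and A = (log2 Hy3 + log2 Hy5)/2 per probe,
    fits a Lowess curve of M on A over all probes with strictly positive
    signals in both channels, and returns M minus the fit.  Probes with a
    non-positive signal in either channel are excluded from the fit, returned
    as NaN and listed in the second return value.
    """
    if not hy3.index.equals(hy5.index):
        raise ConfigurationError("channel series must share the same probe index")
    values3 = hy3.to_numpy(float)
    values5 = hy5.to_numpy(float)
    ok = (values3 > 0) & (values5 > 0)
    excluded = list(hy3.index[~ok])
    if excluded:
        log.warning("lowess: excluded %d probe(s) with non-positive signal", len(excluded))
    n_fit = int(ok.sum())
    if n_fit < 8:
        raise ConfigurationError(
            f"lowess normalization needs >= 8 probes with positive signals, got {n_fit}"
        )
    m = np.log2(values3[ok]) - np.log2(values5[ok])
    a = 0.5 * (np.log2(values3[ok]) + np.log2(values5[ok]))
    # Ties in A (replicate-identical probes) make some zero-width local
    # windows; statsmodels emits a harmless divide warning and returns finite
    # fits, so silence it here.
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = _sm_lowess(
            m, a, frac=span, it=iterations, delta=0.0, return_sorted=False
        )
    normalized = np.full(values3.shape, np.nan)
    normalized[ok] = m - fit
    return pd.Series(normalized, index=hy3.index, name="normalized_log2_ratio"), excluded


def normalize_ratios(
    slides: pd.DataFrame, params: MirnaParams = MirnaParams()
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Per-slide Lowess-normalized log2 ratios for every probe.

    Replicate spots are summarized by the median foreground per (probe,
    slide, channel) before the ratio is formed.  Returns a probe x slide
    DataFrame of normalized M values (NaN where excluded) and the per-slide
    exclusion lists.
    """
    hy3 = _replicate_pivot(slides, "hy3_fg")
    hy5 = _replicate_pivot(slides, "hy5_fg")
    columns: dict[int, pd.Series] = {}
    excluded: dict[int, list[str]] = {}
    for slide in sorted(slides["slide"].unique()):
        med3 = hy3[slide].median(axis=1)
        med5 = hy5[slide].median(axis=1)
        normalized, dropped = lowess_normalize_slide(
            med3, med5, span=params.lowess_span, iterations=params.lowess_iterations
        )
        columns[slide] = normalized
        excluded[int(slide)] = [str(p) for p in dropped]
    ratios = pd.DataFrame(columns)
    ratios.index.name = "probe_id"
    ratios.columns.name = "slide"
    return ratios, excluded


def summarize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of per-slide ratios per probe.

    Slides on which a probe was excluded (NaN) are skipped; a probe excluded
    on every slide has a missing mean, never zero.  ``sd_log2_ratio`` is NaN
    when fewer than two slides contribute.
    """
    n_used = ratios.notna().sum(axis=1)
    mean = ratios.mean(axis=1, skipna=True)
    sd = ratios.std(axis=1, ddof=1, skipna=True)
    out = pd.DataFrame(
        {
            "mean_log2_ratio": mean,
            "sd_log2_ratio": sd,
            "n_slides": n_used,
        }
    )
    out.index.name = "probe_id"
    return out


def classify_fold_change(mean_log2_ratio: float, threshold: float = 2.0) -> str | None:
    """Three-way fold-change class with boundaries inclusive to the elevated classes.

    ``elevated_in_exosomes`` when mean >= threshold, ``elevated_in_cells``
    when mean <= -threshold, ``equal`` strictly in between; ``None``
    (unclassified) for a missing mean.
    """
    if threshold <= 0:
        raise ConfigurationError(f"threshold must be > 0, got {threshold}")
    if mean_log2_ratio is None or (isinstance(mean_log2_ratio, float) and math.isnan(mean_log2_ratio)):
        return None
    if mean_log2_ratio >= threshold:
        return ELEVATED_IN_EXOSOMES
    if mean_log2_ratio <= -threshold:
        return ELEVATED_IN_CELLS
    return EQUAL


def build_venn(exo_detected: set, cell_detected: set) -> VennCounts:
    """Exact set algebra over the two detected probe-id sets."""
    exo = set(exo_detected)
    cell = set(cell_detected)
    counts = VennCounts(
        exo_total=len(exo), cell_total=len(cell), shared=len(exo & cell)
    )
    if counts.union_size != len(exo | cell):  # pragma: no cover - arithmetic identity
        raise InvariantError("Venn counts are inconsistent with the union size")
    return counts


def rank_enriched(
    ratio_table: pd.DataFrame,
    n: int,
    direction: str = "exosome",
    within: set[str] | None = None,
) -> list[str]:
    """Top-``n`` probes by mean normalized log2 ratio.

    ``direction="exosome"`` sorts descending (most exosome-enriched first),
    ``"cell"`` ascending; ties are broken lexicographically by probe_id.
    Probes with a missing mean are never ranked; ``within`` optionally
    restricts the candidates.
    """
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    if direction not in ("exosome", "cell"):
        raise ConfigurationError(f"direction must be 'exosome' or 'cell', got {direction!r}")
    means = ratio_table["mean_log2_ratio"].dropna()
    if within is not None:
        means = means[means.index.isin(within)]
    frame = means.rename("mean").reset_index()
    frame = frame.sort_values(
        ["mean", "probe_id"], ascending=[direction == "cell", True], kind="mergesort"
    )
    return frame["probe_id"].head(n).tolist()


def run_mirna_pipeline(
    slides: pd.DataFrame, params: MirnaParams = MirnaParams()
) -> MirnaResult:
    """Run the full dual-channel analysis on a quantified slide set."""
    backgrounds = estimate_slide_background(slides)
    detection = detection_profiles(slides, params)
    ratios, excluded = normalize_ratios(slides, params)
    summary = summarize_ratios(ratios)
    summary["fc_class"] = [
        classify_fold_change(m, params.threshold_log2fc) for m in summary["mean_log2_ratio"]
    ]
    per_slide = ratios.rename(columns=lambda s: f"log2_ratio_s{s}")
    ratio_table = per_slide.join(summary)

    detected_exo = set(detection.index[detection["detected_Hy3"] == "detected"].astype(str))
    detected_cell = set(detection.index[detection["detected_Hy5"] == "detected"].astype(str))
    venn = build_venn(detected_exo, detected_cell)
    return MirnaResult(
        backgrounds=backgrounds,
        detection=detection,
        ratio_table=ratio_table,
        detected_exosome=detected_exo,
        detected_cell=detected_cell,
        venn=venn,
        excluded=excluded,
    )
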