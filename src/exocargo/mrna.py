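"""Single-channel mRNA expression analysis.

Workflow for two groups of arrays (exosome vs. donor cell), consuming
background-corrected expression values plus Present/Marginal/Absent calls:

* scale each array so its median intensity equals a common target (100);
* intensity filter — a probe passes for a group when its value on *every*
  array of that group lies in that array's top 25% (boundary inclusive);
* presence filter — P calls on every array of the group;
* detected(group) = intensity filter AND presence filter;
* unique-to-group — P on every own-group array and A on every other-group
  array (a Marginal call anywhere disqualifies on both sides);
* detected-fraction summary: |exosome detected| / |cell detected|, with the
  percentage reported round-half-up to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .simulate import ExpressionStudy

__all__ = [
    "MrnaParams",
    "PresenceSummary",
    "MrnaResult",
    "scale_to_median",
    "intensity_filter",
    "presence_filter",
    "unique_set",
    "detected_summary",
    "run_mrna_pipeline",
]

GROUPS = ("exosome", "cell")


@dataclass(frozen=True)
class MrnaParams:
    """Tunable parameters of the single-channel pipeline."""

    scale_target: float = 100.0
    top_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.scale_target <= 0:
            raise ConfigurationError(f"scale_target must be > 0, got {self.scale_target}")
        if not 0 < self.top_fraction < 1:
            raise ConfigurationError(
                f"top_fraction must be in (0, 1), got {self.top_fraction}"
            )


@dataclass(frozen=True)
class PresenceSummary:
    """Detected counts per compartment and their ratio.

    ``fraction`` is |exosome detected| / |cell detected| and ``percent`` its
    round-half-up integer percentage; both are None when no probe is detected
    in the cell group.
    """

    exosome_detected: int
    cell_detected: int
    exosome_unique: int
    cell_unique: int

    @property
    def fraction(self) -> float | None:
        if self.cell_detected == 0:
            return None
        return self.exosome_detected / self.cell_detected

    @property
    def percent(self) -> int | None:
        if self.fraction is None:
            return None
        return int(math.floor(100.0 * self.fraction + 0.5))

    def as_dict(self) -> dict:
        return {
            "exosome_detected": self.exosome_detected,
            "cell_detected": self.cell_detected,
            "exosome_unique": self.exosome_unique,
            "cell_unique": self.cell_unique,
            "detected_fraction": self.fraction,
            "detected_percent": self.percent,
        }


@dataclass
class MrnaResult:
    """Outputs of the single-channel pipeline."""

    scaled_signals: pd.DataFrame
    detected: dict[str, set[str]]  # group -> detected probe ids
    unique: dict[str, set[str]]  # group -> unique-to-group probe ids
    summary: PresenceSummary


def scale_to_median(signals: pd.DataFrame, target: float = 100.0) -> pd.DataFrame:
    """Scale each array (column) so its median intensity equals ``target``."""
    if target <= 0:
        raise ConfigurationError(f"target must be > 0, got {target}")
    medians = signals.median(axis=0)
    bad = medians[~(medians > 0)]
    if not bad.empty:
        raise ConfigurationError(
            f"array {bad.index[0]!r} has non-positive median intensity {bad.iloc[0]}"
        )
    return signals * (target / medians)


def intensity_filter(group_signals: pd.DataFrame, top_fraction: float = 0.25) -> set[str]:
    """Probes whose signal lies in the top ``top_fraction`` on every array of the group.

    The cutoff is the per-array (1 - top_fraction) quantile with the linear
    interpolation convention; a value exactly at the cutoff passes.
    """
    if not 0 < top_fraction < 1:
        raise ConfigurationError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if group_signals.shape[1] == 0:
        raise ConfigurationError("intensity_filter: the group has no arrays")
    cutoffs = group_signals.quantile(1.0 - top_fraction, axis=0, interpolation="linear")
    passes = (group_signals >= cutoffs).all(axis=1)
    return set(group_signals.index[passes].astype(str))


def presence_filter(group_calls: pd.DataFrame) -> set[str]:
    """Probes called Present on every array of the group."""
    passes = (group_calls == "P").all(axis=1)
    return set(group_calls.index[passes].astype(str))


def unique_set(
    calls: pd.DataFrame, own_samples: list[str], other_samples: list[str]
) -> set[str]:
    """Probes Present on every own-group array and Absent on every other-group array."""
    own = set(own_samples)
    other = set(other_samples)
    if not own or not other:
        raise ConfigurationError("unique_set: both groups must be non-empty")
    if own & other:
        raise ConfigurationError(
            f"unique_set: groups overlap in samples {sorted(own & other)}"
        )
    present = (calls[own_samples] == "P").all(axis=1)
    absent = (calls[other_samples] == "A").all(axis=1)
    return set(calls.index[present & absent].astype(str))


def detected_summary(
    exosome_detected: set[str],
    cell_detected: set[str],
    exosome_unique: set[str] | None = None,
    cell_unique: set[str] | None = None,
) -> PresenceSummary:
    """Counts and the exosome/cell detected-fraction (percentage round-half-up)."""
    return PresenceSummary(
        exosome_detected=len(exosome_detected),
        cell_detected=len(cell_detected),
        exosome_unique=len(exosome_unique or set()),
        cell_unique=len(cell_unique or set()),
    )


def run_mrna_pipeline(study: ExpressionStudy, params: MrnaParams = MrnaParams()) -> MrnaResult:
    """Run the full single-channel analysis on an expression study."""
    unknown = set(study.groups.unique()) - set(GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown group label(s) {sorted(unknown)}; expected {GROUPS}")
    samples = {g: study.group_samples(g) for g in GROUPS}
    for g in GROUPS:
        if not samples[g]:
            raise ConfigurationError(f"group {g!r} has no arrays")

    scaled = scale_to_median(study.signals, params.scale_target)
    detected: dict[str, set[str]] = {}
    for g in GROUPS:
        by_intensity = intensity_filter(scaled[samples[g]], params.top_fraction)
        by_presence = presence_filter(study.calls[samples[g]])
        detected[g] = by_intensity & by_presence

    unique = {
        "exosome": unique_set(study.calls, samples["exosome"], samples["cell"]),
        "cell": unique_set(study.calls, samples["cell"], samples["exosome"]),
    }
    summary = detected_summary(
        detected["exosome"], detected["cell"], unique["exosome"], unique["cell"]
    )
    return MrnaResult(scaled_signals=scaled, detected=detected, unique=unique, summary=summary)
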