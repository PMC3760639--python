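"""Synthetic microarray data with known compartment structure.

Simulates the two study designs the analysis pipelines consume:

* a dual-channel spotted miRNA array experiment — ``n_slides`` slides,
  ``replicates_per_slide`` replicate spots per probe, exosome RNA in the Hy3
  channel and donor-cell RNA in the Hy5 channel, with intensity-dependent dye
  bias, spot-level additive background and multiplicative lognormal noise;
* a single-channel expression study — two groups of arrays (exosome vs. cell)
  with per-sample Present/Marginal/Absent detection calls.

Every probe carries a ground-truth compartment class so downstream detection
calling, normalization, fold-change classification and set algebra can be
tested against known answers.  Probes fall into four classes:

``shared``
    expressed in both compartments, with a log2 enrichment effect drawn from
    a truncated normal (0 for balanced probes);
``exosome_only`` / ``cell_only``
    expressed in one compartment; in the other the true abundance sits below
    the background regime, so detection rules — not the simulator — decide
    set membership;
``absent``
    unexpressed in both compartments.  Most probes on a real array are in
    this class, which is what makes slide-median-based detection limits and
    top-quantile intensity filters meaningful.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "ExpressionStudy",
    "generate_truth",
    "simulate_two_channel_slides",
    "simulate_expression_study",
    "true_fold_change_class",
    "true_presence",
]

#: Compartment classes a probe can belong to.
COMPARTMENT_CLASSES = ("exosome_only", "cell_only", "shared", "absent")

#: Columns of a truth table.
TRUTH_COLUMNS = (
    "probe_id",
    "compartment_class",
    "true_log2fc",
    "base_intensity",
    "exo_abundance",
    "cell_abundance",
)

#: Columns of a quantified two-channel slide set (long format).
SLIDE_COLUMNS = (
    "probe_id",
    "slide",
    "replicate",
    "hy3_fg",
    "hy3_bg",
    "hy5_fg",
    "hy5_bg",
)

# Enrichment effects are truncated at 16-fold so expressed probes stay within
# the dynamic range of the simulated assays (a probe 2^4-fold depleted in one
# compartment would otherwise fall through the detection floor there).
_MAX_ABS_LOG2FC = 4.0

# True abundance of an unexpressed probe, as a fraction of the background
# level: low enough to be statistically indistinguishable from background.
_RESIDUAL_FRACTION = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated paired exosome/cell profiling experiment.

    Defaults mirror the experimental design being emulated: triplicate
    dual-channel slides with 4 replicate spots per probe, and 4 single-channel
    arrays per group; ~850 probes of which a minority are expressed, in
    proportions resembling the detected/shared set sizes of an HMC-1
    exosome-versus-cell comparison.
    """

    n_probes: int = 850
    n_slides: int = 3
    replicates_per_slide: int = 4
    n_arrays_per_group: int = 4
    fraction_exosome_only: float = 0.032
    fraction_cell_only: float = 0.053
    fraction_shared: float = 0.105
    #: SD (log2 scale) of shared-probe enrichment effects; 0 = all balanced.
    enrichment_sd: float = 1.5
    #: Peak-to-trough amplitude (log2 scale) of the smooth intensity-dependent
    #: dye bias added to the two-channel ratios.
    dye_bias_amplitude: float = 0.5
    #: Mean additive background fluorescence per spot.
    background_level: float = 100.0
    #: Coefficient of variation of the multiplicative lognormal noise.
    noise_cv: float = 0.1
    #: Range of expressed-probe base intensities (log-uniform draw).
    intensity_range: tuple[float, float] = (2048.0, 32768.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_slides", "replicates_per_slide", "n_arrays_per_group"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("fraction_exosome_only", "fraction_cell_only", "fraction_shared"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        total = self.fraction_exosome_only + self.fraction_cell_only + self.fraction_shared
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                "fraction_exosome_only + fraction_cell_only + fraction_shared "
                f"must be <= 1, got {total}"
            )
        if self.enrichment_sd < 0:
            raise ConfigurationError(f"enrichment_sd must be >= 0, got {self.enrichment_sd}")
        if self.background_level < 0:
            raise ConfigurationError(
                f"background_level must be >= 0, got {self.background_level}"
            )
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        lo, hi = self.intensity_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"intensity_range must satisfy 0 < lo <= hi, got {self.intensity_range}")

    def with_(self, **overrides) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass
class ExpressionStudy:
    """A single-channel expression study: signals, P/M/A calls, group labels.

    ``signals`` and ``calls`` are probes x samples DataFrames with identical
    labels; ``groups`` maps each sample to ``"exosome"`` or ``"cell"``.
    ``true_present`` (set by the simulator, absent for data read from disk)
    maps each group to the set of probes truly expressed there.
    """

    signals: pd.DataFrame
    calls: pd.DataFrame
    groups: pd.Series
    true_present: dict[str, set[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.signals.index.equals(self.calls.index) or not self.signals.columns.equals(
            self.calls.columns
        ):
            from .errors import AlignmentError

            raise AlignmentError("signal and call matrices must share identical labels")

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.signals.columns if self.groups[s] == group]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named child generator so each simulated artifact is independently reproducible."""
    root = np.random.SeedSequence(config.seed)
    streams = {"truth": 0, "slides": 1, "expression": 2}
    return np.random.default_rng(root.spawn(max(streams.values()) + 1)[streams[stream]])


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Generate the per-probe ground-truth table for a simulation.

    Class counts are ``floor(fraction * n_probes)`` for the exosome-only,
    cell-only and absent classes; the remainder goes to ``shared``.  Class
    labels are assigned to shuffled probe positions so class is independent
    of probe order.  Deterministic for a fixed seed.
    """
    rng = _rng(config, "truth")
    n = config.n_probes
    if n == 0:
        return pd.DataFrame(columns=list(TRUTH_COLUMNS)).astype({"probe_id": str})

    n_exo = math.floor(config.fraction_exosome_only * n)
    n_cell = math.floor(config.fraction_cell_only * n)
    frac_absent = max(
        0.0,
        1.0 - config.fraction_exosome_only - config.fraction_cell_only - config.fraction_shared,
    )
    n_absent = math.floor(frac_absent * n)
    n_shared = n - n_exo - n_cell - n_absent

    classes = np.array(
        ["exosome_only"] * n_exo
        + ["cell_only"] * n_cell
        + ["absent"] * n_absent
        + ["shared"] * n_shared
    )
    rng.shuffle(classes)

    width = max(4, len(str(n)))
    probe_ids = np.array([f"probe_{i:0{width}d}" for i in range(1, n + 1)])

    lo, hi = config.intensity_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    residual = _RESIDUAL_FRACTION * config.background_level

    fc = np.zeros(n)
    shared_mask = classes == "shared"
    if config.enrichment_sd > 0:
        draws = rng.normal(0.0, config.enrichment_sd, size=int(shared_mask.sum()))
        fc[shared_mask] = np.clip(draws, -_MAX_ABS_LOG2FC, _MAX_ABS_LOG2FC)

    exo_ab = np.empty(n)
    cell_ab = np.empty(n)
    exo_ab[shared_mask] = base[shared_mask] * 2.0 ** (fc[shared_mask] / 2.0)
    cell_ab[shared_mask] = base[shared_mask] * 2.0 ** (-fc[shared_mask] / 2.0)

    exo_mask = classes == "exosome_only"
    exo_ab[exo_mask] = base[exo_mask]
    cell_ab[exo_mask] = residual
    cell_mask = classes == "cell_only"
    exo_ab[cell_mask] = residual
    cell_ab[cell_mask] = base[cell_mask]
    absent_mask = classes == "absent"
    exo_ab[absent_mask] = residual
    cell_ab[absent_mask] = residual
    base = np.where(absent_mask, residual, base)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cell_ab > 0, exo_ab / np.where(cell_ab > 0, cell_ab, 1.0), np.inf)
        fc_all = np.where(
            (exo_ab > 0) & (cell_ab > 0),
            np.log2(np.where(ratio > 0, ratio, 1.0)),
            np.where(exo_ab > 0, np.inf, np.where(cell_ab > 0, -np.inf, 0.0)),
        )
    fc_all[absent_mask] = 0.0

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "compartment_class": classes,
            "true_log2fc": fc_all,
            "base_intensity": base,
            "exo_abundance": exo_ab,
            "cell_abundance": cell_ab,
        }
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _dye_bias_log2(a_values: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth intensity-dependent bias (log2 units) as a quadratic in standardized A.

    Applied symmetrically (+delta/2 to Hy3, -delta/2 to Hy5) so the mean log
    intensity A is unchanged and a Lowess fit of M on A is the exact remedy.
    """
    if amplitude == 0 or a_values.size == 0:
        return np.zeros_like(a_values)
    mu = a_values.mean()
    sd = a_values.std()
    if sd == 0:
        return np.zeros_like(a_values)
    z = (a_values - mu) / sd
    return amplitude * (z * z - 1.0) / 2.0


def simulate_two_channel_slides(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate quantified dual-channel slide signals from a truth table.

    For every (probe, slide, replicate spot), each channel's foreground is

        abundance * dye_bias(A) * lognormal_noise + background_draw

    with the exosome compartment in Hy3 and the cell compartment in Hy5, and
    the reported spot background an independent draw around the background
    level.  Returns a long-format DataFrame with one row per spot
    (columns :data:`SLIDE_COLUMNS`).
    """
    if truth.empty:
        raise ConfigurationError("truth table must be non-empty")
    rng = _rng(config, "slides")

    n = len(truth)
    n_s, n_r = config.n_slides, config.replicates_per_slide
    exo_ab = truth["exo_abundance"].to_numpy(float)
    cell_ab = truth["cell_abundance"].to_numpy(float)

    with np.errstate(divide="ignore"):
        a_true = 0.5 * (np.log2(np.maximum(exo_ab, 1e-300)) + np.log2(np.maximum(cell_ab, 1e-300)))
    expressed = (exo_ab > 0) & (cell_ab > 0)
    delta = np.zeros(n)
    if expressed.any():
        delta[expressed] = _dye_bias_log2(a_true[expressed], config.dye_bias_amplitude)
    gain3 = 2.0 ** (delta / 2.0)
    gain5 = 2.0 ** (-delta / 2.0)

    shape = (n, n_s, n_r)
    cv = config.noise_cv
    bgl = config.background_level
    hy3_fg = (
        exo_ab[:, None, None] * gain3[:, None, None] * _lognormal_factor(rng, cv, shape)
        + bgl * _lognormal_factor(rng, cv, shape)
    )
    hy5_fg = (
        cell_ab[:, None, None] * gain5[:, None, None] * _lognormal_factor(rng, cv, shape)
        + bgl * _lognormal_factor(rng, cv, shape)
    )
    hy3_bg = bgl * _lognormal_factor(rng, cv, shape)
    hy5_bg = bgl * _lognormal_factor(rng, cv, shape)

    probe_ids = truth["probe_id"].to_numpy()
    return pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, n_s * n_r),
            "slide": np.tile(np.repeat(np.arange(1, n_s + 1), n_r), n),
            "replicate": np.tile(np.arange(1, n_r + 1), n * n_s),
            "hy3_fg": hy3_fg.ravel(),
            "hy3_bg": hy3_bg.ravel(),
            "hy5_fg": hy5_fg.ravel(),
            "hy5_bg": hy5_bg.ravel(),
        }
    )


def simulate_expression_study(truth: pd.DataFrame, config: SimulationConfig) -> ExpressionStudy:
    """Simulate a single-channel expression study from a truth table.

    Signals emulate background-corrected per-probe summaries: compartment
    abundance times multiplicative lognormal noise.  Detection calls follow a
    fixed rule against the known background level ``b``: ``P`` if signal >
    3 b, ``A`` if signal <= b, ``M`` otherwise.  The returned study carries
    the ground-truth present set per group in ``true_present``.
    """
    if truth.empty:
        raise ConfigurationError("truth table must be non-empty")
    rng = _rng(config, "expression")

    n = len(truth)
    k = config.n_arrays_per_group
    exo_ab = truth["exo_abundance"].to_numpy(float)
    cell_ab = truth["cell_abundance"].to_numpy(float)

    exo_sig = exo_ab[:, None] * _lognormal_factor(rng, config.noise_cv, (n, k))
    cell_sig = cell_ab[:, None] * _lognormal_factor(rng, config.noise_cv, (n, k))

    samples = [f"exo_{i}" for i in range(1, k + 1)] + [f"cell_{i}" for i in range(1, k + 1)]
    signals = pd.DataFrame(
        np.hstack([exo_sig, cell_sig]), index=truth["probe_id"].to_numpy(), columns=samples
    )
    signals.index.name = "probe_id"

    b = config.background_level
    values = signals.to_numpy()
    call_codes = np.where(values > 3.0 * b, "P", np.where(values <= b, "A", "M"))
    calls = pd.DataFrame(call_codes, index=signals.index, columns=signals.columns)

    groups = pd.Series(
        ["exosome"] * k + ["cell"] * k, index=samples, name="group", dtype=object
    )
    return ExpressionStudy(
        signals=signals, calls=calls, groups=groups, true_present=true_presence(truth)
    )


def true_presence(truth: pd.DataFrame) -> dict[str, set[str]]:
    """Ground-truth expressed probe sets per compartment."""
    cls = truth["compartment_class"]
    ids = truth["probe_id"]
    return {
        "exosome": set(ids[cls.isin(["shared", "exosome_only"])]),
        "cell": set(ids[cls.isin(["shared", "cell_only"])]),
    }


def true_fold_change_class(truth: pd.DataFrame, threshold: float = 2.0) -> pd.Series:
    """Fold-change class implied by the true log2 enrichment of each probe.

    Uses the same inclusive-boundary rule as the pipeline classifier; indexed
    by probe_id.
    """
    from .mirna import classify_fold_change

    return pd.Series(
        [classify_fold_change(fc, threshold) for fc in truth["true_log2fc"]],
        index=truth["probe_id"].to_numpy(),
        name="true_fc_class",
    )
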