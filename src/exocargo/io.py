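"""Readers and writers for the tabular formats the pipelines exchange.

One on-disk dialect throughout: tab-delimited text with a header row for
inputs (quantified slide signals, expression/call matrices, group maps,
truth tables), CSV for result tables, and a JSON summary file for counts.
Readers validate and refuse malformed data explicitly — no row is ever
silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError
from .mirna import VennCounts
from .mrna import PresenceSummary
from .simulate import SLIDE_COLUMNS, TRUTH_COLUMNS, ExpressionStudy

__all__ = [
    "read_slide_set",
    "write_slide_set",
    "read_truth",
    "write_truth",
    "read_expression_study",
    "write_expression_study",
    "write_results",
    "read_summary",
]

_SIGNAL_COLUMNS = ("hy3_fg", "hy3_bg", "hy5_fg", "hy5_bg")
_VALID_CALLS = {"P", "M", "A"}


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    except Exception as exc:  # malformed delimiter/quoting
        raise ParseError(f"{path}: {exc}") from exc


def read_slide_set(path) -> pd.DataFrame:
    """Read a quantified two-channel slide set from tab-delimited text.

    Validates the required columns, uniqueness of every
    (probe_id, slide, replicate) triple and that all signal and background
    values are finite and non-negative.
    """
    frame = _read_tsv(path)
    missing = [c for c in SLIDE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for column in ("slide", "replicate"):
        try:
            frame[column] = frame[column].astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: column {column!r} is not integer-valued") from exc
    for column in _SIGNAL_COLUMNS:
        values = pd.to_numeric(frame[column], errors="coerce")
        bad = values.isna() | ~np.isfinite(values) | (values < 0)
        if bad.any():
            row = int(frame.index[bad][0])
            raise ParseError(
                f"{path}: row {row + 2}, column {column!r}: "
                f"value {frame.loc[frame.index[bad][0], column]!r} is not a finite non-negative number"
            )
        frame[column] = values.astype(float)
    duplicated = frame.duplicated(subset=["probe_id", "slide", "replicate"])
    if duplicated.any():
        key = frame.loc[frame.index[duplicated][0], ["probe_id", "slide", "replicate"]]
        raise ParseError(
            f"{path}: duplicated (probe, slide, replicate) triple "
            f"({key['probe_id']}, {key['slide']}, {key['replicate']})"
        )
    return frame[list(SLIDE_COLUMNS)]


def write_slide_set(slides: pd.DataFrame, path) -> Path:
    path = Path(path)
    slides[list(SLIDE_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_truth(path) -> pd.DataFrame:
    """Read a ground-truth table written by :func:`write_truth`."""
    frame = _read_tsv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return frame[list(TRUTH_COLUMNS)]


def write_truth(truth: pd.DataFrame, path) -> Path:
    path = Path(path)
    truth[list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def _read_matrix(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    if frame.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id', got {frame.columns[0]!r}")
    if frame["probe_id"].duplicated().any():
        dup = frame.loc[frame["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicated probe_id {dup!r}")
    return frame.set_index("probe_id")


def read_expression_study(signals_path, calls_path, groups_path) -> ExpressionStudy:
    """Read a signals/calls/groups TSV trio into an aligned expression study.

    The two matrices must share identical row and column labels; every call
    must be one of P/M/A; every sample in the group map must appear in the
    matrices (and vice versa).
    """
    signals = _read_matrix(signals_path)
    for column in signals.columns:
        values = pd.to_numeric(signals[column], errors="coerce")
        if values.isna().any():
            row = signals.index[values.isna()][0]
            raise ParseError(
                f"{signals_path}: probe {row!r}, sample {column!r}: non-numeric signal"
            )
        signals[column] = values.astype(float)
    calls = _read_matrix(calls_path)

    if list(signals.index) != list(calls.index) or list(signals.columns) != list(calls.columns):
        rows = set(signals.index) ^ set(calls.index)
        cols = set(signals.columns) ^ set(calls.columns)
        raise AlignmentError(
            "signal and call matrices disagree on labels; "
            f"row difference {sorted(rows)}, column difference {sorted(cols)}"
        )
    invalid = ~calls.isin(_VALID_CALLS)
    if invalid.to_numpy().any():
        probe = calls.index[invalid.any(axis=1)][0]
        sample = calls.columns[invalid.loc[probe]][0]
        raise ParseError(
            f"{calls_path}: probe {probe!r}, sample {sample!r}: "
            f"call {calls.loc[probe, sample]!r} not in {sorted(_VALID_CALLS)}"
        )

    groups_frame = _read_tsv(groups_path)
    if list(groups_frame.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{groups_path}: expected columns 'sample' and 'group'")
    groups = pd.Series(
        groups_frame["group"].to_numpy(), index=groups_frame["sample"].to_numpy(), name="group"
    )
    diff = set(groups.index) ^ set(signals.columns)
    if diff:
        raise AlignmentError(
            f"group map and matrices disagree on samples: {sorted(diff)}"
        )
    groups = groups.reindex(signals.columns)
    return ExpressionStudy(signals=signals, calls=calls, groups=groups)


def write_expression_study(study: ExpressionStudy, out_dir) -> dict[str, Path]:
    """Write the signals/calls/groups trio as tab-delimited text; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out_dir / "signals.tsv",
        "calls": out_dir / "calls.tsv",
        "groups": out_dir / "groups.tsv",
    }
    study.signals.rename_axis("probe_id").to_csv(paths["signals"], sep="\t")
    study.calls.rename_axis("probe_id").to_csv(paths["calls"], sep="\t")
    pd.DataFrame({"sample": study.groups.index, "group": study.groups.to_numpy()}).to_csv(
        paths["groups"], sep="\t", index=False
    )
    return paths


def _sorted_ratio_table(ratios: pd.DataFrame) -> pd.DataFrame:
    table = ratios.reset_index()
    # Deterministic order: descending mean, NaN means last, ties by probe_id.
    table["_nan"] = table["mean_log2_ratio"].isna()
    table = table.sort_values(
        ["_nan", "mean_log2_ratio", "probe_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_nan")
    return table


def write_results(
    venn: VennCounts | None,
    ratios: pd.DataFrame | None,
    sets: dict[str, set[str]],
    out_dir,
    presence: PresenceSummary | None = None,
) -> dict[str, Path]:
    """Write the structured summary, the classified ratio table and the set lists.

    Returns a manifest mapping logical names to written paths.  The ratio
    table is ordered by descending mean log2 ratio with ties broken by
    probe_id, so repeated runs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    summary: dict = {}
    if venn is not None:
        summary["venn"] = venn.as_dict()
    if presence is not None:
        summary["presence"] = presence.as_dict()
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["summary"] = summary_path

    if ratios is not None:
        table = _sorted_ratio_table(ratios)
        ratio_path = out_dir / "ratio_table.csv"
        table.to_csv(ratio_path, index=False)
        manifest["ratio_table"] = ratio_path

    for name, members in sets.items():
        path = out_dir / f"set_{name}.txt"
        path.write_text("".join(f"{probe}\n" for probe in sorted(members)))
        manifest[f"set_{name}"] = path
    return manifest


def read_summary(path) -> dict:
    """Read back a summary file written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
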