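"""Published summary constants of the HMC-1 exosome cargo study, and a check
that the package's set algebra reproduces the derived numbers.

The constants are the printed totals of the original profiling experiment:
how many miRNAs were detected in exosomes and in the donor mast cells and
how many in both, the detected mRNA counts per compartment, and the ten most
exosome-enriched miRNAs in order.  ``verify_reported_summaries`` rebuilds
membership sets of exactly those sizes, runs the pipeline's Venn and
detected-fraction operations on them, and reports whether each derived
quantity (exosome-only, cell-only, union, detected percentage) comes out at
its published value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mirna import build_venn
from .mrna import detected_summary

__all__ = ["SummaryConstant", "ReportedSummaries", "REPORTED", "verify_reported_summaries"]


@dataclass(frozen=True)
class SummaryConstant:
    """One published count with a label saying what it counts."""

    value: int
    label: str


@dataclass(frozen=True)
class ReportedSummaries:
    """Immutable bundle of the published summary counts."""

    mirna_exosome_total: SummaryConstant = SummaryConstant(
        116, "miRNAs detected in exosomes (dual-channel LNA array, triplicate slides)"
    )
    mirna_cell_total: SummaryConstant = SummaryConstant(
        134, "miRNAs detected in donor HMC-1 cells (dual-channel LNA array)"
    )
    mirna_shared: SummaryConstant = SummaryConstant(
        89, "miRNAs detected in both exosomes and cells"
    )
    mirna_exosome_only: SummaryConstant = SummaryConstant(
        27, "miRNAs detected only in exosomes"
    )
    mirna_cell_only: SummaryConstant = SummaryConstant(
        45, "miRNAs detected only in cells"
    )
    mrna_exosome: SummaryConstant = SummaryConstant(
        1849, "mRNAs detected in exosomes (single-channel arrays, n=4)"
    )
    mrna_cell: SummaryConstant = SummaryConstant(
        12346, "mRNAs detected in donor HMC-1 cells (single-channel arrays, n=4)"
    )
    mrna_detected_percent: SummaryConstant = SummaryConstant(
        15, "exosomal mRNA count as a percentage of the cellular count"
    )
    mrna_exosome_unique: SummaryConstant = SummaryConstant(
        54, "mRNAs present in all exosome arrays and absent in all cell arrays"
    )
    top_enriched_mirnas: tuple[str, ...] = (
        "hsa-miR-451",
        "hsa-miR-503",
        "miRPlus_27560",
        "miRPlus_2843",
        "miRPlus_27564",
        "hsa-miR-583",
        "miRPlus_1795",
        "miRPlus_17890",
        "hsa-miR-663",
        "hsa-miR-30b",
    )


REPORTED = ReportedSummaries()


def _membership_sets(exo_total: int, cell_total: int, shared: int) -> tuple[set, set]:
    """Synthetic probe-id sets with exactly the given sizes and overlap."""
    shared_ids = {f"shared_{i}" for i in range(shared)}
    exo = shared_ids | {f"exo_{i}" for i in range(exo_total - shared)}
    cell = shared_ids | {f"cell_{i}" for i in range(cell_total - shared)}
    return exo, cell


def verify_reported_summaries() -> dict[str, dict]:
    """Recompute the derived published numbers with the package's own operations.

    Builds miRNA membership sets of the published sizes (116 exosome, 134
    cell, 89 shared), runs :func:`~exocargo.mirna.build_venn` on them, and
    computes the mRNA detected percentage from the published counts with
    :func:`~exocargo.mrna.detected_summary`.  Returns, per derived quantity,
    the recomputed value, the expected value and a pass flag.
    """
    exo, cell = _membership_sets(
        REPORTED.mirna_exosome_total.value,
        REPORTED.mirna_cell_total.value,
        REPORTED.mirna_shared.value,
    )
    venn = build_venn(exo, cell)
    mrna_exo = {f"m_exo_{i}" for i in range(REPORTED.mrna_exosome.value)}
    mrna_cell = {f"m_cell_{i}" for i in range(REPORTED.mrna_cell.value)}
    presence = detected_summary(mrna_exo, mrna_cell)

    checks = {
        "mirna_exosome_only": (venn.exo_only, REPORTED.mirna_exosome_only.value),
        "mirna_cell_only": (venn.cell_only, REPORTED.mirna_cell_only.value),
        "mirna_union": (
            venn.union_size,
            REPORTED.mirna_exosome_only.value
            + REPORTED.mirna_cell_only.value
            + REPORTED.mirna_shared.value,
        ),
        "mrna_detected_percent": (presence.percent, REPORTED.mrna_detected_percent.value),
    }
    return {
        name: {"computed": computed, "expected": expected, "pass": computed == expected}
        for name, (computed, expected) in checks.items()
    }
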