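"""Cross-tool assignment comparison summaries.

Given total read counts and the number of reads each annotation tool
assigned, produce the headline figures used when benchmarking one
annotation engine against another (e.g. a desktop binning tool against a
web annotation service): per-tool assignment rates and each tool's
assignments as a percentage of a reference tool's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["percent_of", "ToolComparison", "compare_assignment_counts"]


def percent_of(part: float, whole: float) -> float:
    """``part`` as a percentage of ``whole`` (exact, unrounded)."""
    if whole == 0:
        raise ZeroDivisionError("reference count is zero")
    return 100.0 * part / whole


@dataclass
class ToolComparison:
    """Assignment-count comparison across tools on one dataset."""

    total_reads: int
    assigned: dict[str, int]
    reference: str

    @property
    def assignment_rate(self) -> dict[str, float]:
        """Percent of all reads each tool assigned."""
        return {t: percent_of(n, self.total_reads) for t, n in self.assigned.items()}

    @property
    def relative_to_reference(self) -> dict[str, float]:
        """Each tool's assignments as a percent of the reference tool's."""
        ref = self.assigned[self.reference]
        return {t: percent_of(n, ref) for t, n in self.assigned.items()}

    def summary(self) -> str:
        lines = [f"total reads: {self.total_reads}"]
        rel = self.relative_to_reference
        rate = self.assignment_rate
        for tool in sorted(self.assigned):
            lines.append(
                f"{tool}: {self.assigned[tool]} assigned "
                f"({rate[tool]:.1f}% of reads, {rel[tool]:.1f}% of {self.reference})"
            )
        return "\n".join(lines)


def compare_assignment_counts(
    total_reads: int, assigned: Mapping[str, int], reference: str
) -> ToolComparison:
    """Build a :class:`ToolComparison`; the reference must be one of the tools."""
    if reference not in assigned:
        raise ValueError(f"reference tool {reference!r} not among {sorted(assigned)}")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    for tool, n in assigned.items():
        if n < 0 or n > total_reads:
            raise ValueError(f"{tool}: assigned count {n} outside [0, {total_reads}]")
    return ToolComparison(total_reads, dict(assigned), reference)
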