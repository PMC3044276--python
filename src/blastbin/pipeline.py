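"""End-to-end convenience layer: BLAST file in, assignments/profiles out.

Thin glue over the per-module operations; the CLI, the test suite's
recovery checks and downstream scripts all drive the pipeline through
these functions so they agree on the order of operations
(parse -> filter -> assign -> profile -> min-support).
"""

from __future__ import annotations

from pathlib import Path

from .assign import Assignment, assign_ko, assign_seed
from .blast import AssignmentParams, ParseStats, parse_blast_tab
from .profiles import CountProfile, build_profile
from .reference import ReferenceData
from .taxonomy import apply_min_support, assign_taxon

__all__ = ["SampleResult", "run_sample", "recovery_by_kind"]


class SampleResult:
    """All per-read assignments and profiles for one sample."""

    def __init__(
        self,
        sample_id: str,
        ref: ReferenceData,
        params: AssignmentParams,
        seed_assignments: list[Assignment],
        taxon_assignments: list[Assignment],
        ko_assignments: list[Assignment],
        stats: ParseStats,
    ) -> None:
        self.sample_id = sample_id
        self.params = params
        self.stats = stats
        self.seed_assignments = seed_assignments
        self.taxon_assignments = taxon_assignments
        self.ko_assignments = ko_assignments
        self.seed_profile: CountProfile = build_profile(
            seed_assignments, ref.seed, sample_id
        )
        raw = build_profile(taxon_assignments, ref.taxonomy, sample_id)
        self.taxon_profile_raw = raw
        self.taxon_profile = apply_min_support(raw, ref.taxonomy, params.min_support)

    @property
    def total_reads(self) -> int:
        return len(self.seed_assignments)

    def summary(self) -> dict[str, int]:
        prof = self.seed_profile
        return {
            "total_reads": self.total_reads,
            "assigned": prof.unique_assigned,
            "NoHits": prof.bins["NoHits"],
            "NotAssigned": prof.bins["NotAssigned"],
        }


def run_sample(
    blast_path: str | Path,
    ref: ReferenceData,
    params: AssignmentParams | None = None,
    sample_id: str | None = None,
) -> SampleResult:
    """Parse one BLAST tabular file and compute all three assignment kinds."""
    params = params or AssignmentParams()
    blast_path = Path(blast_path)
    if sample_id is None:
        sample_id = blast_path.name.split(".")[0]
    stats = ParseStats()
    reads = list(parse_blast_tab(blast_path, stats))
    seed_a = [assign_seed(rh, ref.functions, params) for rh in reads]
    taxon_a = [assign_taxon(rh, ref.taxa, ref.taxonomy, params) for rh in reads]
    ko_a = [assign_ko(rh, ref.kos, params) for rh in reads]
    return SampleResult(sample_id, ref, params, seed_a, taxon_a, ko_a, stats)


def recovery_by_kind(result: SampleResult, truth_path: str | Path) -> dict[str, float]:
    """Fraction of truth-table rows recovered exactly, per assignment kind.

    The truth table (written by the fixture generator) lists each read's
    intended role, taxon and KO; NoHits rows must be recovered as NoHits.
    Reads from other samples are ignored.
    """
    truth: dict[str, tuple[str, str, str]] = {}
    with open(truth_path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            read_id, sample, role, taxon, ko = line.rstrip("\n").split("\t")
            if sample == result.sample_id:
                truth[read_id] = (role, taxon, ko)
    by_kind = {
        "role": {a.read_id: a.target for a in result.seed_assignments},
        "taxon": {a.read_id: a.target for a in result.taxon_assignments},
        "ko": {a.read_id: a.target for a in result.ko_assignments},
    }
    out = {}
    for pos, kind in enumerate(("role", "taxon", "ko")):
        got = by_kind[kind]
        # hitless reads never reach the parser's output; they count as
        # correctly binned NoHits when absent from the assignment map
        hits = sum(
            1
            for read_id, expected in truth.items()
            if got.get(read_id, "NoHits") == expected[pos]
        )
        out[kind] = hits / len(truth) if truth else 1.0
    return out
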