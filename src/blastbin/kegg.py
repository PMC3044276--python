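"""KEGG pathway aggregation of per-read KO assignments.

Every read assigned to a KO contributes one hit to *each* pathway that
contains the KO (a KO in k pathways yields k pathway hits; no fractional
splitting), so pathway totals are comparable to the "hits per pathway"
numbers functional viewers print.  A KO with no known pathway is collected
under the synthetic ``unmapped-KO`` pathway.  Abundance scaling maps
counts into [0, 1] for downstream map coloring: the most abundant KO
scales to 1, absent KOs to 0, and any KO with at least one read scales
strictly above 0 so that rare-but-present enzymes stay distinguishable
from absent ones (the point of the yellow-to-red gradient).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import Assignment
from .errors import UnknownNodeError
from .reference import Hierarchy, KoMap
from .taxonomy import reads_under_taxa

__all__ = [
    "UNMAPPED_PATHWAY",
    "PathwayProfile",
    "AbundanceScale",
    "pathway_counts",
    "scale_abundance",
    "compare_pathway",
    "restricted_pathway_counts",
]

UNMAPPED_PATHWAY = "unmapped-KO"


@dataclass
class PathwayProfile:
    """Hit counts for one pathway, broken down by KO and by sample."""

    pathway_id: str
    name: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # ko -> sample -> n

    @property
    def ko_totals(self) -> dict[str, int]:
        return {ko: sum(per.values()) for ko, per in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.ko_totals.values())

    def samples(self) -> list[str]:
        return sorted({s for per in self.counts.values() for s in per})


@dataclass
class AbundanceScale:
    """Per-KO display intensities in [0, 1] (the color channel)."""

    values: dict[str, float]
    mode: str  # {"linear", "log"}


def pathway_counts(
    ko_assignments: Mapping[str, Iterable[Assignment]], km: KoMap
) -> list[PathwayProfile]:
    """Tally per-pathway hits from per-sample KO assignments.

    ``ko_assignments`` maps sample id -> that sample's KO assignments;
    binned reads are ignored.  Returns profiles sorted by total hits
    descending (ties by pathway id) — the synthetic unmapped-KO pathway
    sorts with the rest.
    """
    profiles: dict[str, PathwayProfile] = {}
    for sample, assignments in ko_assignments.items():
        for a in assignments:
            if a.kind != "ko" or a.is_binned:
                continue
            targets = km.pathways_of(a.target) or {UNMAPPED_PATHWAY}
            for pw in targets:
                prof = profiles.get(pw)
                if prof is None:
                    label = (
                        "KOs without pathway annotation"
                        if pw == UNMAPPED_PATHWAY
                        else km.pathway_label.get(pw, pw)
                    )
                    prof = profiles[pw] = PathwayProfile(pw, label)
                per = prof.counts.setdefault(a.target, {})
                per[sample] = per.get(sample, 0) + 1
    return sorted(profiles.values(), key=lambda p: (-p.total, p.pathway_id))


def scale_abundance(profile: PathwayProfile, mode: str = "linear") -> AbundanceScale:
    """Scale a pathway's KO counts into [0, 1].

    linear: count / max count; log: ln(1 + count) / ln(1 + max count).
    An all-zero profile scales to all zeros.
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    totals = profile.ko_totals
    peak = max(totals.values(), default=0)
    if peak == 0:
        return AbundanceScale({ko: 0.0 for ko in totals}, mode)
    if mode == "linear":
        values = {ko: c / peak for ko, c in totals.items()}
    else:
        denom = math.log1p(peak)
        values = {ko: math.log1p(c) / denom for ko, c in totals.items()}
    return AbundanceScale(values, mode)


def compare_pathway(
    profiles: Sequence[PathwayProfile], pathway_id: str
) -> pd.DataFrame:
    """KO x sample count table for one pathway, plus its presence pattern.

    The ``presence`` column names the subset of samples hitting each KO
    (``+``-joined, sorted) — the categorical version of coloring a map
    region by which datasets contain it.
    """
    for prof in profiles:
        if prof.pathway_id == pathway_id:
            break
    else:
        raise UnknownNodeError(f"unknown pathway {pathway_id!r}")
    samples = prof.samples()
    rows = []
    for ko in sorted(prof.counts):
        per = prof.counts[ko]
        row = {"ko": ko}
        row.update({s: per.get(s, 0) for s in samples})
        row["presence"] = "+".join(s for s in samples if per.get(s, 0) > 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["ko", *samples, "presence"]).set_index("ko")


def restricted_pathway_counts(
    ko_assignments: Mapping[str, Iterable[Assignment]],
    taxon_assignments: Mapping[str, Iterable[Assignment]],
    tax: Hierarchy,
    selected: Iterable[str],
    km: KoMap,
) -> list[PathwayProfile]:
    """Pathway tally restricted to reads binned inside the selected taxa.

    Genes found in different members of a consortium rarely operate in one
    pathway together; restricting to a clade gives per-organism pathway
    views.  Equivalent to :func:`pathway_counts` on the reads returned by
    :func:`blastbin.taxonomy.reads_under_taxa`.
    """
    selected = list(selected)
    restricted: dict[str, list[Assignment]] = {}
    for sample, assignments in ko_assignments.items():
        keep = reads_under_taxa(taxon_assignments.get(sample, ()), tax, selected)
        restricted[sample] = [a for a in assignments if a.read_id in keep]
    return pathway_counts(restricted, km)


def write_pathway_summary(profiles: Sequence[PathwayProfile], path: str | Path) -> None:
    """Pathway summary TSV: id, name, distinct KOs, total hits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#pathway\tname\tkos\ttotal_hits\n")
        for p in profiles:
            fh.write(f"{p.pathway_id}\t{p.name}\t{len(p.counts)}\t{p.total}\n")


def write_pathway_bundle(
    profiles: Sequence[PathwayProfile], path: str | Path, mode: str = "linear"
) -> None:
    """JSON bundle: pathway -> KO -> per-sample counts and display scale."""
    bundle = {}
    for p in profiles:
        scale = scale_abundance(p, mode).values
        bundle[p.pathway_id] = {
            "name": p.name,
            "total": p.total,
            "kos": {
                ko: {"samples": dict(sorted(per.items())), "scale": round(scale[ko], 6)}
                for ko, per in sorted(p.counts.items())
            },
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
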