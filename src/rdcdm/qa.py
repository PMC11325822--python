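"""QA reporting: cohort summaries, symptom-overlap tables, mapping success."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .catalogs import CatalogBundle, shared_symptoms
from .etl_genopheno import MappingReport
from .model import RDCDMBundle

__all__ = ["cohort_summary", "symptom_overlap_report", "OverlapReport",
           "mapping_success_summary"]

#: overlap sets as narrated alongside the overlap figure; the computed table
#: is checked against these and differences are surfaced, never corrected
NARRATIVE_ALL_GROUP_CODES = frozenset({
    "HP:0001945",  # fever
    "HP:0002014",  # diarrhea
    "HP:0012378",  # fatigue
    "HP:0003326",  # myalgia
})


def cohort_summary(source: Mapping[str, int] | Iterable[RDCDMBundle]
                   ) -> dict[str, int]:
    """Distinct-person count per domain plus their arithmetic total.

    Accepts either bundles (persons are counted) or an already-aggregated
    ``domain -> count`` mapping, e.g. externally reported cohort sizes.
    """
    if isinstance(source, Mapping):
        counts = dict(source)
    else:
        counts = {}
        for bundle in source:
            label = bundle.domain or "unlabeled"
            counts[label] = counts.get(label, 0) + len(
                {p.person_id for p in bundle.persons})
    counts["total"] = sum(counts.values())
    return counts


@dataclass
class OverlapReport:
    pairwise: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    full_intersection: set[str] = field(default_factory=set)
    code_names: dict[str, str] = field(default_factory=dict)
    discrepancies: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for (a, b), codes in sorted(self.pairwise.items()):
            names = ", ".join(f"{c} ({self.code_names.get(c, '?')})"
                              for c in sorted(codes)) or "(none)"
            lines.append(f"{a} ∩ {b}: {names}")
        full = ", ".join(f"{c} ({self.code_names.get(c, '?')})"
                         for c in sorted(self.full_intersection)) or "(none)"
        lines.append(f"all groups: {full}")
        for d in self.discrepancies:
            lines.append(f"DISCREPANCY: {d}")
        return "\n".join(lines)


def symptom_overlap_report(catalog: CatalogBundle,
                           groups: Iterable[str] | None = None) -> OverlapReport:
    """Pairwise and k-way HPO intersections over the bundled symptom table.

    Where the computed all-group intersection differs from the narrated
    shared-symptom list, the difference is flagged in ``discrepancies``.
    """
    groups = list(groups) if groups is not None else list(catalog.symptom_groups())
    if not groups:
        raise ValueError("at least one group is required")

    report = OverlapReport()
    report.code_names = {s.hpo_code: s.symptom_name for s in catalog.symptoms}
    for a, b in itertools.combinations(groups, 2):
        report.pairwise[(a, b)] = shared_symptoms(catalog, [a, b])
    report.full_intersection = shared_symptoms(catalog, groups)

    missing = NARRATIVE_ALL_GROUP_CODES - report.full_intersection
    extra = report.full_intersection - NARRATIVE_ALL_GROUP_CODES
    if len(groups) > 2 and (missing or extra):
        report.discrepancies.append(
            "computed all-group intersection differs from the narrated "
            f"shared-symptom list: missing {sorted(missing)}, extra {sorted(extra)}")
    return report


def mapping_success_summary(report: MappingReport,
                            threshold: float | None = None
                            ) -> tuple[str, dict[str, object], int]:
    """Human text + JSON-able dict + exit code for a mapping report.

    The exit code is non-zero iff a threshold is given and the success rate
    falls below it.
    """
    rate = report.success_rate
    summary = {
        "records_in": report.records_in,
        "mapped": report.mapped,
        "unmapped": report.unmapped,
        "rejected": report.rejected,
        "success_rate": round(rate, 1),
    }
    text = (f"records_in: {report.records_in}\n"
            f"mapped: {report.mapped}\n"
            f"unmapped: {report.unmapped}\n"
            f"rejected: {report.rejected}\n"
            f"success_rate: {rate:.1f}%")
    exit_code = 1 if threshold is not None and rate < threshold else 0
    return text, summary, exit_code
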