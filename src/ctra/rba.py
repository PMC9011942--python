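"""The per-sentence, per-organ rule engine.

For every sentence the engine counts unnegated disease mentions — multi-organ
descriptors first (these require an organ co-mention in the same sentence),
then single-organ descriptors (these do not) — and only when no disease was
counted anywhere does it consider the normal logic.  A report is labeled

* ``positive`` for every disease with at least one unnegated mention,
* else ``normal`` if some sentence asserts normality (organ mention + normal
  term, no qualifier, no unnegated other abnormality, short enough) and no
  sentence anywhere carries an unnegated other abnormality for the organ,
* else ``uncertain`` (e.g. the organ system is never mentioned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus import RadiologyReport, Sentence, split_sentences
from .lexicon import DISEASES, Lexicon, TermHit, match_terms

DEFAULT_LENGTH_THRESHOLD = 20

POSITIVE = "positive"
NORMAL = "normal"
UNCERTAIN = "uncertain"


@dataclass
class SentenceVerdict:
    """What one sentence contributes to an organ's report label."""

    counts: dict[str, int]
    normal_candidate: bool
    blockers: list[str] = field(default_factory=list)
    has_unnegated_other_abnormality: bool = False

    def __post_init__(self) -> None:
        if self.normal_candidate and any(self.counts.values()):
            raise ValueError("a sentence with disease counts cannot be a normal candidate")


@dataclass(frozen=True)
class OrganLabel:
    organ_system: str
    status: str
    diseases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in (POSITIVE, NORMAL, UNCERTAIN):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == POSITIVE) != bool(self.diseases):
            raise ValueError("diseases must be non-empty iff status is positive")
        unknown = self.diseases - set(DISEASES[self.organ_system])
        if unknown:
            raise ValueError(f"diseases {sorted(unknown)} not defined for {self.organ_system}")

    def as_binary(self) -> dict[str, int]:
        """Binary vector over the organ's four diseases plus ``normal``."""
        row = {d: int(d in self.diseases) for d in DISEASES[self.organ_system]}
        row["normal"] = int(self.status == NORMAL)
        return row


def _negation_starts(hits: Sequence[TermHit]) -> list[int]:
    return [h.start for h in hits if h.entry.descriptor_class == "negation"]


def _is_negated(hit: TermHit, negation_starts: Sequence[int]) -> bool:
    # Negation scope: any negation earlier in the sentence negates the hit.
    return any(s < hit.start for s in negation_starts)


def judge_sentence(
    sentence: Sentence,
    organ_system: str,
    lexicon: Lexicon,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
) -> SentenceVerdict:
    organ_lex = lexicon.for_organ(organ_system)
    hits = match_terms(sentence, organ_lex)
    neg_starts = _negation_starts(hits)

    organ_mentioned = any(h.entry.descriptor_class == "organ" for h in hits)
    counts: dict[str, int] = {d: 0 for d in DISEASES[organ_system]}
    counted_spans: set[tuple[int, int, str]] = set()
    blockers: list[str] = []

    # (a) multi-organ then (b) single-organ descriptor logic.
    for cls, needs_organ in (("multi_organ", True), ("single_organ", False)):
        for hit in hits:
            if hit.entry.descriptor_class != cls:
                continue
            disease = hit.entry.disease_label
            if disease not in counts:
                continue
            if needs_organ and not organ_mentioned:
                continue
            if _is_negated(hit, neg_starts):
                if "negated" not in blockers:
                    blockers.append("negated")
                continue
            key = (hit.start, hit.end, disease)
            if key not in counted_spans:  # exact + wildcard entry on one span count once
                counted_spans.add(key)
                counts[disease] += 1

    other_unnegated = any(
        h.entry.descriptor_class == "other_abnormality" and not _is_negated(h, neg_starts)
        for h in hits
    )

    # (c) normal logic, only when no disease was counted in this sentence.
    normal_candidate = False
    if not any(counts.values()):
        has_normal = any(h.entry.descriptor_class == "normal" for h in hits)
        has_qualifier = any(h.entry.descriptor_class == "qualifier" for h in hits)
        if organ_mentioned and has_normal:
            normal_candidate = True
            if has_qualifier:
                normal_candidate = False
                blockers.append("qualifier_present")
            if other_unnegated:
                normal_candidate = False
                blockers.append("other_abnormality")
            if sentence.length > length_threshold:
                normal_candidate = False
                blockers.append("too_long")
    return SentenceVerdict(
        counts=counts,
        normal_candidate=normal_candidate,
        blockers=blockers,
        has_unnegated_other_abnormality=other_unnegated,
    )


def label_report(
    report: RadiologyReport,
    organ_system: str,
    lexicon: Lexicon,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
) -> OrganLabel:
    findings = report.findings
    if not findings:
        return OrganLabel(organ_system=organ_system, status=UNCERTAIN)
    totals: dict[str, int] = {d: 0 for d in DISEASES[organ_system]}
    any_normal_candidate = False
    any_other_abnormality = False
    for sentence in split_sentences(findings, report_id=report.report_id):
        verdict = judge_sentence(sentence, organ_system, lexicon, length_threshold)
        for d, c in verdict.counts.items():
            totals[d] += c
        any_normal_candidate = any_normal_candidate or verdict.normal_candidate
        any_other_abnormality = any_other_abnormality or verdict.has_unnegated_other_abnormality
    positives = frozenset(d for d, c in totals.items() if c >= 1)
    if positives:
        return OrganLabel(organ_system=organ_system, status=POSITIVE, diseases=positives)
    if any_normal_candidate and not any_other_abnormality:
        return OrganLabel(organ_system=organ_system, status=NORMAL)
    return OrganLabel(organ_system=organ_system, status=UNCERTAIN)


def label_corpus(
    reports: Sequence[RadiologyReport],
    organ_system: str,
    lexicon: Lexicon,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
) -> tuple[dict[str, OrganLabel], dict[str, int]]:
    """Label every report; returns (labels by report_id, summary counts)."""
    labels: dict[str, OrganLabel] = {}
    summary: dict[str, int] = {d: 0 for d in DISEASES[organ_system]}
    summary.update({NORMAL: 0, UNCERTAIN: 0, POSITIVE: 0})
    for report in reports:
        label = label_report(report, organ_system, lexicon, length_threshold)
        labels[report.report_id] = label
        summary[label.status] += 1
        for d in label.diseases:
            summary[d] += 1
    return labels, summary


def labels_to_rows(
    labels: Mapping[str, OrganLabel], organ_system: str
) -> list[dict[str, object]]:
    """Flatten labels to CSV-ready rows: report_id, organ, status, 0/1 columns."""
    rows = []
    for report_id in labels:
        label = labels[report_id]
        row: dict[str, object] = {
            "report_id": report_id,
            "organ": organ_system,
            "status": label.status,
        }
        row.update(label.as_binary())
        rows.append(row)
    return rows
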