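"""Report data model, section parsing, tokenization, and subject-wise splitting.

A report is semi-structured free text with named sections (protocol,
indication, technique, findings, impression).  All downstream labeling is
restricted to the findings section; the impression is deliberately never
consulted so that labels reflect image observations only.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Valid CT protocol codes: combinations of chest (C), abdomen (A), pelvis (P).
PROTOCOLS = ("CAP", "C", "AP", "A", "P", "CA", "CP")

ORGAN_SYSTEMS = ("lungs_pleura", "liver_gallbladder", "kidneys_ureters")

#: Which protocols cover each organ system.  Lungs/pleura require the chest;
#: liver/gallbladder and kidneys/ureters require the abdomen.
DEFAULT_PROTOCOL_MAP: dict[str, frozenset[str]] = {
    "lungs_pleura": frozenset({"CAP", "C", "CA", "CP"}),
    "liver_gallbladder": frozenset({"CAP", "AP", "A", "CA"}),
    "kidneys_ureters": frozenset({"CAP", "AP", "A", "CA"}),
}

SECTION_NAMES = ("protocol", "indication", "technique", "findings", "impression")

#: Padding id and out-of-vocabulary id for RNN token sequences.
PAD_ID = 0
OOV_ID = 1
PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"

_TOKEN_RE = re.compile(r"[a-z]+(?:-[a-z]+)*")
# Sentence-final punctuation followed by whitespace/end.  A decimal point in
# "3.2 cm" is followed by a digit, so it can never match.
_SENT_SPLIT_RE = re.compile(r"[.!?](?=\s|$)")
_NUM_PUNCT_RE = re.compile(r"[0-9]|[^\w\s]|_")


@dataclass
class RadiologyReport:
    """One body-CT radiology report; the unit of labeling."""

    report_id: str
    subject_id: str
    protocol: str
    sections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(
                f"report {self.report_id!r}: unknown protocol {self.protocol!r}; "
                f"expected one of {PROTOCOLS}"
            )

    @property
    def findings(self) -> str | None:
        """The findings section text, or None when the report has none."""
        return self.sections.get("findings")


@dataclass(frozen=True)
class Sentence:
    report_id: str
    index: int
    text: str
    tokens: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length integer encoding of a findings section."""

    token_ids: tuple[int, ...]
    vocab_size: int

    def __post_init__(self) -> None:
        if any(t < 0 or t >= self.vocab_size for t in self.token_ids):
            raise ValueError("token id out of vocabulary range")


@dataclass
class SubjectSplit:
    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def partition_of(self, subject_id: str) -> str:
        return self.assignment[subject_id]

    def subjects(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "partition"])
            for subject, part in sorted(self.assignment.items()):
                writer.writerow([subject, part])


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase word tokens: maximal alphabetic runs with internal hyphens."""
    return tuple(_TOKEN_RE.findall(text.lower()))


def parse_report(
    raw_text: str,
    report_id: str = "",
    subject_id: str = "",
    protocol: str = "CAP",
    section_aliases: Mapping[str, Sequence[str]] | None = None,
) -> RadiologyReport:
    """Split raw report text into named sections on case-insensitive headers.

    Headers are section names followed by a colon (``FINDINGS:``,
    ``Findings:``...).  Text before the first recognized header — or the whole
    text if no header is found — lands in an ``unsectioned`` slot, so parsing
    is total: every character belongs to exactly one section.
    """
    if not raw_text:
        raise ValueError("raw_text must be non-empty")
    aliases: dict[str, str] = {}
    for canonical in SECTION_NAMES:
        aliases[canonical] = canonical
    if section_aliases:
        for canonical, alts in section_aliases.items():
            for alt in alts:
                aliases[alt.lower()] = canonical
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(a) for a in aliases) + r")[ \t]*:",
        re.IGNORECASE,
    )
    sections: dict[str, str] = {}
    matches = list(pattern.finditer(raw_text))
    if not matches:
        sections["unsectioned"] = raw_text.strip()
    else:
        head = raw_text[: matches[0].start()].strip()
        if head:
            sections["unsectioned"] = head
        for i, m in enumerate(matches):
            name = aliases[m.group(1).lower()]
            end = matches[i + 1].start() if i + 1 < len(matches) else len(raw_text)
            sections[name] = raw_text[m.end(): end].strip()
    return RadiologyReport(
        report_id=report_id, subject_id=subject_id, protocol=protocol, sections=sections
    )


def filter_by_protocol(
    reports: Sequence[RadiologyReport],
    organ_system: str,
    mapping: Mapping[str, frozenset[str] | set[str]] | None = None,
) -> list[RadiologyReport]:
    """Keep only reports whose protocol covers the organ system (order kept)."""
    mapping = mapping if mapping is not None else DEFAULT_PROTOCOL_MAP
    if organ_system not in mapping:
        raise KeyError(f"no protocol mapping for organ system {organ_system!r}")
    allowed = mapping[organ_system]
    return [r for r in reports if r.protocol in allowed]


def split_sentences(findings: str, report_id: str = "") -> list[Sentence]:
    """Segment a findings section into lowercased, tokenized sentences.

    Splits on sentence-final ``.``/``!``/``?``; a period between two digits
    (decimal measurement) never splits.  Run-on text with no terminal
    punctuation comes back as a single long sentence — the rule engine's
    length criterion is what guards against mislabeling those.
    """
    if not findings:
        return []
    pieces = [p.strip() for p in _SENT_SPLIT_RE.split(findings)]
    sentences = []
    for piece in pieces:
        if not piece:
            continue
        text = piece.lower()
        sentences.append(
            Sentence(report_id=report_id, index=len(sentences), text=text, tokens=tokenize(text))
        )
    return sentences


def clean_for_rnn(text: str) -> list[str]:
    """Strip numbers and punctuation, lowercase, and whitespace-tokenize."""
    return _NUM_PUNCT_RE.sub(" ", text.lower()).split()


def build_vocab(texts: Iterable[str], min_count: int = 1) -> dict[str, int]:
    """Frequency-ordered vocabulary with reserved padding (0) and OOV (1) ids."""
    counts: dict[str, int] = {}
    for text in texts:
        for tok in clean_for_rnn(text):
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {PAD_TOKEN: PAD_ID, OOV_TOKEN: OOV_ID}
    for tok in sorted(counts, key=lambda t: (-counts[t], t)):
        if counts[tok] >= min_count:
            vocab[tok] = len(vocab)
    return vocab


def preprocess_for_rnn(
    findings: str, vocab: Mapping[str, int], max_len: int = 650
) -> TokenSequence:
    """Encode findings text as a fixed-length id sequence.

    Numbers and punctuation are removed, text lowercased and tokenized, tokens
    mapped through ``vocab`` (missing tokens to the OOV id), then the sequence
    is truncated to the first ``max_len`` ids or zero-padded up to ``max_len``.
    """
    ids = [vocab.get(tok, OOV_ID) for tok in clean_for_rnn(findings or "")]
    ids = ids[:max_len]
    ids += [PAD_ID] * (max_len - len(ids))
    return TokenSequence(token_ids=tuple(ids), vocab_size=max(vocab.values()) + 1)


def split_by_subject(
    reports: Sequence[RadiologyReport],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SubjectSplit:
    """Randomly partition subjects into train/val/test at the given fractions.

    Every report of a subject lands in the same partition; the assignment is
    deterministic for a given seed.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    subjects = sorted({r.subject_id for r in reports})
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n = len(subjects)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    assignment: dict[str, str] = {}
    for i, subject in enumerate(subjects):
        if i < n_train:
            assignment[subject] = "train"
        elif i < n_train + n_val:
            assignment[subject] = "val"
        else:
            assignment[subject] = "test"
    return SubjectSplit(assignment=assignment, fractions=tuple(fractions), seed=seed)


def partition_reports(
    reports: Sequence[RadiologyReport], split: SubjectSplit
) -> dict[str, list[RadiologyReport]]:
    out: dict[str, list[RadiologyReport]] = {"train": [], "val": [], "test": []}
    for r in reports:
        out[split.assignment[r.subject_id]].append(r)
    return out


# ---------------------------------------------------------------------------
# I/O

def load_reports_jsonl(path: str | Path) -> list[RadiologyReport]:
    """Read reports from JSONL: one object per line with report_id,
    subject_id, protocol, and either ``sections`` or raw ``text``."""
    reports = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            reports.append(_report_from_record(obj))
    return reports


def load_reports_csv(path: str | Path) -> list[RadiologyReport]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [_report_from_record(row) for row in csv.DictReader(fh)]


def _report_from_record(obj: Mapping[str, object]) -> RadiologyReport:
    if obj.get("sections") is not None:
        sections = dict(obj["sections"])  # type: ignore[arg-type]
        return RadiologyReport(
            report_id=str(obj["report_id"]),
            subject_id=str(obj["subject_id"]),
            protocol=str(obj["protocol"]),
            sections={k: str(v) for k, v in sections.items()},
        )
    return parse_report(
        str(obj.get("text", "")),
        report_id=str(obj["report_id"]),
        subject_id=str(obj["subject_id"]),
        protocol=str(obj["protocol"]),
    )


def save_reports_jsonl(reports: Sequence[RadiologyReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "subject_id": r.subject_id,
                        "protocol": r.protocol,
                        "sections": r.sections,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
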