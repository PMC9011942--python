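"""Dictionary data model and wildcard term matching for the rule engine.

Entries fall into seven descriptor classes:

* ``organ`` — names an organ system ("lungs", "hepatic").
* ``single_organ`` — a disease term that uniquely implies its organ system
  ("emphysema"); countable without an organ co-mention.
* ``multi_organ`` — a disease term applicable to several organs ("stone",
  "lesion"); countable only when the organ is mentioned in the same sentence.
* ``negation`` — signals absence ("no", "without"); organ-agnostic.
* ``qualifier`` — signals confounded context ("however"); organ-agnostic.
* ``normal`` — asserts normal anatomy ("unremarkable").
* ``other_abnormality`` — abnormalities outside the four target diseases that
  must block a normal verdict ("pneumothorax").
"""

from __future__ import annotations

import fnmatch
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus import ORGAN_SYSTEMS, Sentence

logger = logging.getLogger(__name__)

DESCRIPTOR_CLASSES = (
    "organ",
    "single_organ",
    "multi_organ",
    "negation",
    "qualifier",
    "normal",
    "other_abnormality",
)

#: The four target diseases per organ system.
DISEASES: dict[str, tuple[str, ...]] = {
    "lungs_pleura": ("atelectasis", "nodule", "emphysema", "effusion"),
    "liver_gallbladder": ("stone", "lesion", "dilation", "fatty"),
    "kidneys_ureters": ("stone", "lesion", "atrophy", "cyst"),
}

_PATTERN_TOKEN_RE = re.compile(r"^[a-z*]+(?:-[a-z*]+)*$")


class LexiconError(ValueError):
    """Raised when a lexicon file violates the entry invariants."""


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    descriptor_class: str
    organ_system: str | None = None
    disease_label: str | None = None

    @property
    def pattern_tokens(self) -> tuple[str, ...]:
        return tuple(self.pattern.split())

    @property
    def has_wildcard(self) -> bool:
        return "*" in self.pattern

    def validate(self) -> list[str]:
        problems = []
        cls = self.descriptor_class
        if cls not in DESCRIPTOR_CLASSES:
            problems.append(f"unknown descriptor class {cls!r}")
            return problems
        for tok in self.pattern_tokens:
            if not _PATTERN_TOKEN_RE.match(tok):
                problems.append(f"malformed pattern token {tok!r}")
        if cls in ("single_organ", "multi_organ"):
            if self.disease_label is None:
                problems.append(f"{cls} entry {self.pattern!r} needs a disease label")
        elif self.disease_label is not None:
            problems.append(f"{cls} entry {self.pattern!r} must not carry a disease label")
        if cls in ("organ", "single_organ", "normal", "other_abnormality"):
            if self.organ_system is None:
                problems.append(f"{cls} entry {self.pattern!r} needs an organ system")
        elif self.organ_system is not None:
            problems.append(f"{cls} entry {self.pattern!r} must be organ-agnostic")
        if self.organ_system is not None and self.organ_system not in ORGAN_SYSTEMS:
            problems.append(f"unknown organ system {self.organ_system!r}")
        if cls == "single_organ" and self.organ_system in DISEASES:
            if self.disease_label not in DISEASES[self.organ_system]:
                problems.append(
                    f"disease {self.disease_label!r} not among the "
                    f"{self.organ_system} diseases {DISEASES[self.organ_system]}"
                )
        if cls == "multi_organ" and self.disease_label is not None:
            if not any(self.disease_label in ds for ds in DISEASES.values()):
                problems.append(f"disease {self.disease_label!r} unknown to every organ system")
        return problems


@dataclass(frozen=True)
class TermHit:
    """A lexicon entry matched on a token span of one sentence."""

    entry: LexiconEntry
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("span must be non-empty")


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        problems = []
        seen = set()
        for i, entry in enumerate(self.entries, start=1):
            for problem in entry.validate():
                problems.append(f"entry {i}: {problem}")
            key = (entry.pattern, entry.descriptor_class, entry.organ_system, entry.disease_label)
            if key in seen:
                problems.append(f"entry {i}: duplicate of {key}")
            seen.add(key)
        if problems:
            raise LexiconError("invalid lexicon:\n  " + "\n  ".join(problems))

    def for_organ(self, organ_system: str) -> "Lexicon":
        """Entries relevant to one organ system: its own entries, all
        organ-agnostic entries, and multi-organ entries whose disease belongs
        to its four-disease set."""
        diseases = set(DISEASES[organ_system])
        kept = []
        for e in self.entries:
            if e.organ_system is not None:
                if e.organ_system == organ_system:
                    kept.append(e)
            elif e.descriptor_class == "multi_organ":
                if e.disease_label in diseases:
                    kept.append(e)
            else:
                kept.append(e)
        return Lexicon(entries=kept)

    def without_wildcards(self) -> "Lexicon":
        """Literal-pattern entries only (for measuring what wildcards buy)."""
        return Lexicon([e for e in self.entries if not e.has_wildcard])

    def subset(self, classes: Iterable[str]) -> "Lexicon":
        wanted = set(classes)
        return Lexicon([e for e in self.entries if e.descriptor_class in wanted])


def _token_matches(pattern_tok: str, token: str) -> bool:
    if "*" in pattern_tok:
        return fnmatch.fnmatchcase(token, pattern_tok)
    return pattern_tok == token


def match_terms(sentence: Sentence, lexicon: Lexicon) -> list[TermHit]:
    """All non-overlapping term hits, left to right.

    At each token position the longest matching pattern wins; every entry
    matching at that maximal length is reported (distinct descriptor classes
    may legitimately share a span), then matching resumes past the span.
    The result is independent of lexicon entry order.
    """
    tokens = sentence.tokens
    hits: list[TermHit] = []
    i = 0
    n = len(tokens)
    while i < n:
        best_len = 0
        best_entries: list[LexiconEntry] = []
        for entry in lexicon.entries:
            ptoks = entry.pattern_tokens
            k = len(ptoks)
            if k == 0 or i + k > n:
                continue
            if all(_token_matches(p, tokens[i + j]) for j, p in enumerate(ptoks)):
                if k > best_len:
                    best_len, best_entries = k, [entry]
                elif k == best_len:
                    best_entries.append(entry)
        if best_len == 0:
            i += 1
            continue
        surface = " ".join(tokens[i: i + best_len])
        for entry in sorted(
            best_entries,
            key=lambda e: (e.descriptor_class, e.organ_system or "", e.disease_label or "", e.pattern),
        ):
            hits.append(TermHit(entry=entry, start=i, end=i + best_len, surface=surface))
        i += best_len
    return hits


# ---------------------------------------------------------------------------
# File formats: YAML (list of {pattern, class, organ, label}) and TSV.

def _entry_from_record(rec: dict, where: str) -> LexiconEntry:
    try:
        return LexiconEntry(
            pattern=str(rec["pattern"]).lower(),
            descriptor_class=str(rec["class"]),
            organ_system=rec.get("organ") or None,
            disease_label=rec.get("label") or None,
        )
    except KeyError as exc:
        raise LexiconError(f"{where}: missing field {exc}") from exc


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from YAML or TSV (by extension)."""
    path = Path(path)
    records: list[dict]
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            logger.warning("lexicon file %s is empty", path)
            return Lexicon([])
        if not isinstance(data, list):
            raise LexiconError(f"{path}: expected a YAML list of entries")
        records = data
    else:
        records = []
        with open(path, encoding="utf-8") as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    continue
                records.append({k: (v or None) for k, v in zip(header, parts)})
        if not records:
            logger.warning("lexicon file %s is empty", path)
            return Lexicon([])
    entries = [
        _entry_from_record(rec, f"{path} entry {i}") for i, rec in enumerate(records, start=1)
    ]
    lex = Lexicon(entries=entries)
    lex.validate()
    return lex


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    path = Path(path)
    records = [
        {
            "pattern": e.pattern,
            "class": e.descriptor_class,
            "organ": e.organ_system,
            "label": e.disease_label,
        }
        for e in lexicon.entries
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(records, fh, sort_keys=False, allow_unicode=True)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pattern\tclass\torgan\tlabel\n")
            for r in records:
                fh.write(
                    "\t".join([r["pattern"], r["class"], r["organ"] or "", r["label"] or ""]) + "\n"
                )


def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package (illustrative, not exhaustive)."""
    return load_lexicon(Path(__file__).parent / "data" / "lexicon.yaml")
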