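"""TF-IDF ranking of findings-section terms to seed lexicon construction.

Variant (fixed for reproducibility): raw term counts for tf, natural-log
idf = ln(N / df), and a configurable per-document aggregate (max or mean
over the documents containing the term).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import tokenize


@dataclass(frozen=True)
class TermScore:
    term: str
    document_frequency: int
    score: float


def compute_tfidf(
    findings_texts: Sequence[str], aggregate: str = "max"
) -> list[TermScore]:
    """Score every term; returns scores sorted descending (ties lexicographic)."""
    if not findings_texts:
        raise ValueError("need at least one findings section")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    n_docs = len(findings_texts)
    doc_counts = [Counter(tokenize(t)) for t in findings_texts]
    df: Counter[str] = Counter()
    for counts in doc_counts:
        df.update(counts.keys())
    scores = []
    for term, term_df in df.items():
        idf = math.log(n_docs / term_df)
        per_doc = [c[term] * idf for c in doc_counts if term in c]
        score = max(per_doc) if aggregate == "max" else sum(per_doc) / len(per_doc)
        scores.append(TermScore(term=term, document_frequency=term_df, score=score))
    scores.sort(key=lambda s: (-s.score, s.term))
    return scores


def top_terms(scores: Sequence[TermScore], k: int, stopwords: Iterable[str] = ()) -> list[str]:
    if k < 0:
        raise ValueError("k must be >= 0")
    banned = set(stopwords)
    return [s.term for s in scores if s.term not in banned][:k]


def sample_findings(
    findings_texts: Sequence[str], sample: int, seed: int
) -> list[str]:
    """Seeded random batch of findings sections (without replacement)."""
    if sample >= len(findings_texts):
        return list(findings_texts)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(findings_texts), size=sample, replace=False)
    return [findings_texts[i] for i in sorted(idx)]


def save_scores_tsv(scores: Sequence[TermScore], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tdf\tscore\n")
        for s in scores:
            fh.write(f"{s.term}\t{s.document_frequency}\t{s.score:.6f}\n")
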