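"""Glue between the rule engine and the classifier: building label matrices,
assembling train/val/test tensors, and the end-to-end weak-supervision run."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import attention_rnn as arnn
from .corpus import (
    RadiologyReport,
    build_vocab,
    filter_by_protocol,
    partition_reports,
    split_by_subject,
)
from .lexicon import DISEASES, Lexicon
from .rba import DEFAULT_LENGTH_THRESHOLD, UNCERTAIN, OrganLabel, label_corpus
from .synthetic import GroundTruth


def label_names(organ_system: str) -> list[str]:
    """The five outputs per organ: its four diseases plus ``normal``."""
    return list(DISEASES[organ_system]) + ["normal"]


def label_matrix(
    labels: Mapping[str, OrganLabel], report_ids: Sequence[str], organ_system: str
) -> np.ndarray:
    names = label_names(organ_system)
    rows = []
    for rid in report_ids:
        binary = labels[rid].as_binary()
        rows.append([binary[name] for name in names])
    return np.asarray(rows, dtype=np.float64)


def truth_matrix(
    truth: GroundTruth, report_ids: Sequence[str], organ_system: str
) -> np.ndarray:
    names = label_names(organ_system)
    rows = []
    for rid in report_ids:
        binary = truth.labels[(rid, organ_system)].as_binary()
        rows.append([binary[name] for name in names])
    return np.asarray(rows, dtype=np.float64)


@dataclass
class Dataset:
    """Preprocessed tensors for one partition."""

    reports: list[RadiologyReport]
    X: np.ndarray
    y: np.ndarray
    subjects: list[str]
    report_ids: list[str]


@dataclass
class WeakSupervisionRun:
    organ_system: str
    vocab: dict[str, int]
    train: Dataset
    val: Dataset
    test: Dataset
    rba_labels: dict[str, OrganLabel]
    rba_summary: dict[str, int]


def prepare_weak_supervision(
    reports: Sequence[RadiologyReport],
    organ_system: str,
    lexicon: Lexicon,
    max_len: int,
    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    protocol_map: Mapping[str, frozenset[str]] | None = None,
) -> WeakSupervisionRun:
    """Protocol-filter, RBA-label, drop uncertain reports, split by subject,
    and encode findings for the classifier.

    The vocabulary is built from the training partition only, so validation
    and test text exercise the out-of-vocabulary path as it would in
    deployment.
    """
    eligible = filter_by_protocol(reports, organ_system, protocol_map)
    labels, summary = label_corpus(eligible, organ_system, lexicon, length_threshold)
    labeled = [r for r in eligible if labels[r.report_id].status != UNCERTAIN]
    split = split_by_subject(labeled, fractions=fractions, seed=seed)
    parts = partition_reports(labeled, split)
    vocab = build_vocab(r.findings or "" for r in parts["train"])
    out: dict[str, Dataset] = {}
    for name in ("train", "val", "test"):
        subset = parts[name]
        texts = [r.findings or "" for r in subset]
        out[name] = Dataset(
            reports=subset,
            X=arnn.encode_texts(texts, vocab, max_len),
            y=label_matrix(labels, [r.report_id for r in subset], organ_system),
            subjects=[r.subject_id for r in subset],
            report_ids=[r.report_id for r in subset],
        )
    return WeakSupervisionRun(
        organ_system=organ_system,
        vocab=vocab,
        train=out["train"],
        val=out["val"],
        test=out["test"],
        rba_labels=labels,
        rba_summary=summary,
    )


def train_weak_supervision(
    run: WeakSupervisionRun,
    config: arnn.ModelConfig | None = None,
    embeddings: arnn.EmbeddingMatrix | None = None,
    seed: int = 0,
) -> arnn.TrainedModel:
    if config is None:
        config = arnn.ModelConfig.scaled(
            vocab_size=max(run.vocab.values()) + 1, seed=seed
        )
    model = arnn.build_model(config, embeddings=embeddings, vocab=run.vocab)
    arnn.train(model, run.train.X, run.train.y, run.val.X, run.val.y)
    return model
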