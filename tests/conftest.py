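"""Shared fixtures.  The expensive artifacts (2,000-report corpus, trained
classifier) are session-scoped so every test that needs them shares one run."""

from __future__ import annotations

import numpy as np
import pytest

from ctra import attention_rnn as arnn, pipeline
from ctra.lexicon import Lexicon, LexiconEntry, default_lexicon
from ctra.synthetic import GeneratorConfig, generate_corpus

LUNG_DISEASES = ("atelectasis", "nodule", "emphysema", "effusion")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def toy_lexicon():
    """Small literal-only lexicon for oracle comparisons."""
    return Lexicon([
        LexiconEntry("lungs", "organ", "lungs_pleura"),
        LexiconEntry("lung", "organ", "lungs_pleura"),
        LexiconEntry("pleural", "organ", "lungs_pleura"),
        LexiconEntry("atelectasis", "single_organ", "lungs_pleura", "atelectasis"),
        LexiconEntry("pleural effusion", "single_organ", "lungs_pleura", "effusion"),
        LexiconEntry("effusion", "single_organ", "lungs_pleura", "effusion"),
        LexiconEntry("nodule", "multi_organ", None, "nodule"),
        LexiconEntry("no", "negation"),
        LexiconEntry("without", "negation"),
        LexiconEntry("however", "qualifier"),
        LexiconEntry("clear", "normal", "lungs_pleura"),
        LexiconEntry("pneumothorax", "other_abnormality", "lungs_pleura"),
    ])


@pytest.fixture(scope="session")
def default_corpus():
    """2,000 reports with default adversarial rates (training corpus)."""
    return generate_corpus(GeneratorConfig(n_reports=2000, seed=7))


@pytest.fixture(scope="session")
def lungs_run(default_corpus, lexicon):
    reports, _ = default_corpus
    return pipeline.prepare_weak_supervision(
        reports, "lungs_pleura", lexicon, max_len=128, seed=7
    )


@pytest.fixture(scope="session")
def lungs_model(lungs_run):
    config = arnn.ModelConfig.scaled(
        vocab_size=max(lungs_run.vocab.values()) + 1, seed=7
    )
    return pipeline.train_weak_supervision(lungs_run, config=config)


@pytest.fixture(scope="session")
def single_finding_corpus():
    """Reports covering only lungs/pleura, each positive for diseases drawn at
    moderate prevalence, no adversarial features — for attention checks."""
    config = GeneratorConfig(
        n_reports=300,
        seed=55,
        protocol_mix={"C": 1.0},
        disease_prevalence={
            "lungs_pleura": {d: 0.25 for d in LUNG_DISEASES},
            "liver_gallbladder": {d: 0.0 for d in ("stone", "lesion", "dilation", "fatty")},
            "kidneys_ureters": {d: 0.0 for d in ("stone", "lesion", "atrophy", "cyst")},
        },
        normal_prevalence={o: 0.0 for o in
                           ("lungs_pleura", "liver_gallbladder", "kidneys_ureters")},
        negated_mention_rate=0.0,
        qualifier_rate=0.0,
        fused_sentence_rate=0.0,
        misspelling_rate=0.0,
        out_of_lexicon_rate=0.0,
        other_abnormality_rate=0.0,
    )
    return generate_corpus(config)
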