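import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ctra.corpus import RadiologyReport, Sentence, split_sentences
from ctra.lexicon import DISEASES, Lexicon, LexiconEntry
from ctra.rba import (
    NORMAL,
    POSITIVE,
    UNCERTAIN,
    OrganLabel,
    judge_sentence,
    label_corpus,
    label_report,
    labels_to_rows,
)


def _sentence(text):
    (s,) = split_sentences(text + ".")
    return s


def _report(findings, rid="r1", protocol="CAP"):
    return RadiologyReport(rid, "s1", protocol, {"findings": findings})


class TestJudgeSentence:
    def test_short_normal_sentence(self, lexicon):
        v = judge_sentence(
            _sentence("limited view of the lung bases appear clear"),
            "lungs_pleura", lexicon,
        )
        assert v.normal_candidate
        assert not any(v.counts.values())

    def test_negation_blocks_single_organ(self, lexicon):
        v = judge_sentence(_sentence("no pleural effusion"), "lungs_pleura", lexicon)
        assert v.counts["effusion"] == 0
        assert not v.normal_candidate
        assert "negated" in v.blockers

    def test_multi_organ_needs_co_mention(self, lexicon):
        v = judge_sentence(
            _sentence("there is a nodule in the liver"), "lungs_pleura", lexicon
        )
        assert not any(v.counts.values())

    def test_multi_organ_with_co_mention(self, lexicon):
        v = judge_sentence(
            _sentence("there is a nodule in the right lung"), "lungs_pleura", lexicon
        )
        assert v.counts["nodule"] == 1

    def test_length_criterion_blocks_normal(self, lexicon):
        text = "lungs are unremarkable " + " ".join(["and"] * 36)
        v = judge_sentence(_sentence(text), "lungs_pleura", lexicon, length_threshold=20)
        assert not v.normal_candidate
        assert "too_long" in v.blockers

    def test_qualifier_blocks_normal(self, lexicon):
        v = judge_sentence(
            _sentence("however the lungs are clear"), "lungs_pleura", lexicon
        )
        assert not v.normal_candidate
        assert "qualifier_present" in v.blockers

    def test_other_abnormality_blocks_normal(self, lexicon):
        v = judge_sentence(
            _sentence("lungs otherwise clear with a small pneumothorax"),
            "lungs_pleura", lexicon,
        )
        assert not v.normal_candidate
        assert v.has_unnegated_other_abnormality

    def test_negated_other_abnormality_does_not_block(self, lexicon):
        v = judge_sentence(
            _sentence("lungs are clear without pneumothorax"), "lungs_pleura", lexicon
        )
        assert v.normal_candidate
        assert not v.has_unnegated_other_abnormality


class TestLabelReport:
    def test_normal_report(self, lexicon):
        label = label_report(
            _report("lungs are unremarkable. no pleural effusion."),
            "lungs_pleura", lexicon,
        )
        assert label.status == NORMAL

    def test_positive_two_diseases(self, lexicon):
        label = label_report(
            _report("bibasilar atelectasis. small right pleural effusion."),
            "lungs_pleura", lexicon,
        )
        assert label.status == POSITIVE
        assert label.diseases == {"atelectasis", "effusion"}

    def test_no_organ_mention_is_uncertain(self, lexicon):
        label = label_report(
            _report("the gallbladder is unremarkable."), "lungs_pleura", lexicon
        )
        assert label.status == UNCERTAIN

    def test_absent_findings_is_uncertain(self, lexicon):
        report = RadiologyReport("r", "s", "CAP", {"impression": "normal"})
        assert label_report(report, "lungs_pleura", lexicon).status == UNCERTAIN

    def test_other_abnormality_elsewhere_blocks_normal(self, lexicon):
        label = label_report(
            _report("lungs are clear. patchy consolidation at the left base."),
            "lungs_pleura", lexicon,
        )
        assert label.status == UNCERTAIN

    def test_positive_overrides_normal_sentence(self, lexicon):
        label = label_report(
            _report("lungs are clear. moderate centrilobular emphysema."),
            "lungs_pleura", lexicon,
        )
        assert label.status == POSITIVE
        assert label.diseases == {"emphysema"}

    def test_monotone_in_added_disease_sentence(self, lexicon):
        base = "lungs are clear. bibasilar atelectasis."
        extended = base + " moderate centrilobular emphysema."
        a = label_report(_report(base), "lungs_pleura", lexicon)
        b = label_report(_report(extended), "lungs_pleura", lexicon)
        assert b.status == POSITIVE
        assert a.diseases <= b.diseases


class TestOrganLabelInvariants:
    def test_positive_needs_diseases(self):
        with pytest.raises(ValueError):
            OrganLabel("lungs_pleura", POSITIVE, frozenset())

    def test_normal_must_have_no_diseases(self):
        with pytest.raises(ValueError):
            OrganLabel("lungs_pleura", NORMAL, frozenset({"nodule"}))

    def test_unknown_disease_rejected(self):
        with pytest.raises(ValueError):
            OrganLabel("lungs_pleura", POSITIVE, frozenset({"steatosis"}))

    def test_as_binary(self):
        label = OrganLabel("lungs_pleura", POSITIVE, frozenset({"nodule"}))
        row = label.as_binary()
        assert row == {"atelectasis": 0, "nodule": 1, "emphysema": 0,
                       "effusion": 0, "normal": 0}


class TestLabelCorpus:
    def test_two_report_composition(self, lexicon):
        reports = [
            _report("lungs are unremarkable. no pleural effusion.", rid="a"),
            _report("bibasilar atelectasis. small right pleural effusion.", rid="b"),
        ]
        labels, summary = label_corpus(reports, "lungs_pleura", lexicon)
        assert labels["a"].status == NORMAL
        assert labels["b"].diseases == {"atelectasis", "effusion"}
        assert summary[POSITIVE] == 1 and summary[NORMAL] == 1
        assert summary["atelectasis"] == 1 and summary["effusion"] == 1

    def test_empty_corpus(self, lexicon):
        labels, summary = label_corpus([], "lungs_pleura", lexicon)
        assert labels == {}
        assert summary[POSITIVE] == summary[NORMAL] == summary[UNCERTAIN] == 0

    def test_deterministic(self, lexicon):
        reports = [_report("bibasilar atelectasis.", rid=f"r{i}") for i in range(20)]
        assert label_corpus(reports, "lungs_pleura", lexicon) == \
            label_corpus(reports, "lungs_pleura", lexicon)

    def test_rows_shape(self, lexicon):
        reports = [_report("bibasilar atelectasis.", rid="x")]
        labels, _ = label_corpus(reports, "lungs_pleura", lexicon)
        (row,) = labels_to_rows(labels, "lungs_pleura")
        assert row["report_id"] == "x" and row["atelectasis"] == 1


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive case analysis of the three rules over a toy
# lexicon, for short sentences

def _oracle_label(sentences, organ, lex, threshold=20):
    """Independent re-statement of the rule logic via per-hit case analysis
    on literal token scans (no span machinery)."""
    diseases = set()
    any_normal = False
    any_other = False
    for tokens in sentences:
        neg_positions = [i for i, t in enumerate(tokens)
                         if t in ("no", "without")]
        organ_here = any(t in ("lungs", "lung", "pleural") for t in tokens)

        def unnegated(i):
            return not any(p < i for p in neg_positions)

        counts = set()
        for i, t in enumerate(tokens):
            if t == "atelectasis" and unnegated(i):
                counts.add("atelectasis")
            if t == "effusion" and unnegated(i):
                counts.add("effusion")
            if t == "nodule" and organ_here and unnegated(i):
                counts.add("nodule")
        other_here = any(
            t == "pneumothorax" and unnegated(i) for i, t in enumerate(tokens)
        )
        any_other = any_other or other_here
        if not counts:
            if (organ_here and "clear" in tokens and "however" not in tokens
                    and not other_here and len(tokens) <= threshold):
                any_normal = True
        diseases |= counts
    if diseases:
        return POSITIVE, frozenset(diseases)
    if any_normal and not any_other:
        return NORMAL, frozenset()
    return UNCERTAIN, frozenset()


VOCAB = ["no", "lungs", "clear", "effusion", "nodule", "atelectasis",
         "however", "pneumothorax", "the"]


@given(st.lists(st.lists(st.sampled_from(VOCAB), min_size=1, max_size=8),
                min_size=1, max_size=3))
@settings(max_examples=300, deadline=None)
def test_label_report_matches_bruteforce_oracle(toy_sentences):
    from ctra.lexicon import Lexicon, LexiconEntry
    lex = Lexicon([
        LexiconEntry("lungs", "organ", "lungs_pleura"),
        LexiconEntry("lung", "organ", "lungs_pleura"),
        LexiconEntry("pleural", "organ", "lungs_pleura"),
        LexiconEntry("atelectasis", "single_organ", "lungs_pleura", "atelectasis"),
        LexiconEntry("effusion", "single_organ", "lungs_pleura", "effusion"),
        LexiconEntry("nodule", "multi_organ", None, "nodule"),
        LexiconEntry("no", "negation"),
        LexiconEntry("without", "negation"),
        LexiconEntry("however", "qualifier"),
        LexiconEntry("clear", "normal", "lungs_pleura"),
        LexiconEntry("pneumothorax", "other_abnormality", "lungs_pleura"),
    ])
    findings = " ".join(" ".join(s) + "." for s in toy_sentences)
    label = label_report(_report(findings), "lungs_pleura", lex)
    status, diseases = _oracle_label(toy_sentences, "lungs_pleura", lex)
    assert label.status == status
    assert label.diseases == diseases
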