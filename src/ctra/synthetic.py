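"""Synthetic body-CT report generator with known per-organ ground truth.

Reports follow the five-section template (protocol, indication, technique,
findings, impression).  Findings are assembled from sentence templates whose
realization is controlled by adversarial knobs: negated mentions (which never
make truth positive), qualifier clauses, fused run-on sentences, single
character misspellings of disease terms, and out-of-lexicon paraphrases that
no dictionary rule can match but that share context tokens with the
in-lexicon phrasings — the hook that lets a trained classifier generalize
beyond the rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import ORGAN_SYSTEMS, PROTOCOLS, DEFAULT_PROTOCOL_MAP, RadiologyReport
from .lexicon import DISEASES
from .rba import NORMAL, POSITIVE, UNCERTAIN, OrganLabel

# ---------------------------------------------------------------------------
# Sentence templates.  Each disease has in-lexicon phrasings (matchable by the
# default dictionary) and paraphrases (not matchable); the two families share
# signature tokens (e.g. "layering fluid" for effusion) on purpose.

_LAT = ("left", "right")
_SIZES = ("3", "5", "8", "12", "15", "21")

DISEASE_TEMPLATES: dict[tuple[str, str], dict[str, list[str]]] = {
    ("lungs_pleura", "atelectasis"): {
        "in_lex": [
            "bibasilar atelectasis with bandlike volume loss",
            "subsegmental atelectasis at the lung bases",
        ],
        "paraphrase": [
            "bibasilar bandlike volume loss at the lung bases",
            "subsegmental bandlike volume loss in the {lat} lower lobe",
        ],
    },
    ("lungs_pleura", "nodule"): {
        "in_lex": [
            "a {size} mm spiculated pulmonary nodule in the {lat} upper lobe",
            "scattered solid rounded pulmonary nodules",
        ],
        "paraphrase": [
            "a {size} mm spiculated density in the {lat} upper lobe",
            "scattered solid rounded densities in both lungs",
        ],
    },
    ("lungs_pleura", "emphysema"): {
        "in_lex": [
            "moderate centrilobular emphysema in the upper lobes",
            "severe paraseptal emphysema with lucency",
        ],
        "paraphrase": [
            "moderate centrilobular lucency in the upper lobes",
            "severe paraseptal lucency apically",
        ],
    },
    ("lungs_pleura", "effusion"): {
        "in_lex": [
            "a small {lat} pleural effusion with layering fluid",
            "moderate layering pleural effusion on the {lat}",
        ],
        "paraphrase": [
            "layering fluid in the {lat} pleural space",
            "dependent layering fluid within the {lat} hemithorax",
        ],
    },
    ("liver_gallbladder", "stone"): {
        "in_lex": [
            "multiple dependent stones within the gallbladder",
            "cholelithiasis with dependent stones",
        ],
        "paraphrase": [
            "multiple dependent calculi within the gallbladder",
            "layering dependent calculi in the gallbladder lumen",
        ],
    },
    ("liver_gallbladder", "lesion"): {
        "in_lex": [
            "a hypodense lesion in the hepatic parenchyma",
            "indeterminate hypodense hepatic lesions",
        ],
        "paraphrase": [
            "a hypodense focus in the hepatic parenchyma",
            "indeterminate hypodense foci within the liver",
        ],
    },
    ("liver_gallbladder", "dilation"): {
        "in_lex": [
            "dilated intrahepatic ducts with prominent caliber",
            "intrahepatic biliary ductal dilatation with prominent ducts",
        ],
        "paraphrase": [
            "prominent caliber of the intrahepatic ducts",
            "prominent intrahepatic ducts centrally",
        ],
    },
    ("liver_gallbladder", "fatty"): {
        "in_lex": [
            "diffuse hepatic steatosis with decreased attenuation",
            "fatty infiltration with diffusely decreased attenuation of the liver",
        ],
        "paraphrase": [
            "diffusely decreased attenuation of the hepatic parenchyma",
            "geographic decreased attenuation throughout the liver",
        ],
    },
    ("kidneys_ureters", "stone"): {
        "in_lex": [
            "a {size} mm punctate nonobstructing stone in the {lat} kidney",
            "punctate stones in the renal collecting system",
        ],
        "paraphrase": [
            "a {size} mm punctate nonobstructing calculus in the {lat} kidney",
            "punctate calculi within the renal collecting system",
        ],
    },
    ("kidneys_ureters", "lesion"): {
        "in_lex": [
            "an enhancing lesion in the {lat} kidney",
            "indeterminate enhancing renal lesions",
        ],
        "paraphrase": [
            "an enhancing focus in the {lat} kidney",
            "indeterminate enhancing renal foci",
        ],
    },
    ("kidneys_ureters", "atrophy"): {
        "in_lex": [
            "the {lat} kidney is atrophic with cortical thinning",
            "diminutive atrophic {lat} kidney",
        ],
        "paraphrase": [
            "the {lat} kidney is diminutive with cortical thinning",
            "diminutive {lat} kidney with thinned cortex",
        ],
    },
    ("kidneys_ureters", "cyst"): {
        "in_lex": [
            "a simple cyst in the {lat} kidney",
            "scattered simple fluid attenuation renal cysts",
        ],
        "paraphrase": [
            "a simple fluid attenuation structure in the {lat} kidney",
            "scattered simple fluid attenuation structures in both kidneys",
        ],
    },
}

NORMAL_TEMPLATES: dict[str, dict[str, list[str]]] = {
    "lungs_pleura": {
        "in_lex": [
            "the lungs are clear and well aerated",
            "lungs and pleural spaces are unremarkable",
            "normal well aerated lung parenchyma",
        ],
        "paraphrase": [
            "well aerated lung parenchyma throughout",
            "fully aerated lung parenchyma bilaterally",
        ],
    },
    "liver_gallbladder": {
        "in_lex": [
            "the liver and gallbladder are unremarkable",
            "normal homogeneous hepatic parenchyma",
            "the liver is unremarkable with homogeneous parenchyma",
        ],
        "paraphrase": [
            "homogeneous hepatic parenchyma with smooth contour",
            "smooth homogeneous appearance of the hepatic parenchyma",
        ],
    },
    "kidneys_ureters": {
        "in_lex": [
            "the kidneys are unremarkable",
            "both kidneys are normal and enhance symmetrically",
            "the kidneys and ureters are unremarkable",
        ],
        "paraphrase": [
            "both kidneys enhance symmetrically with prompt excretion",
            "the kidneys enhance symmetrically and excrete promptly",
        ],
    },
}

NEGATED_TEMPLATES: dict[tuple[str, str], list[str]] = {
    ("lungs_pleura", "atelectasis"): ["no significant atelectasis"],
    ("lungs_pleura", "nodule"): ["no suspicious pulmonary nodules"],
    ("lungs_pleura", "emphysema"): ["no emphysema"],
    ("lungs_pleura", "effusion"): ["no pleural effusion"],
    ("liver_gallbladder", "stone"): ["no gallbladder stones"],
    ("liver_gallbladder", "lesion"): ["no focal hepatic lesions"],
    ("liver_gallbladder", "dilation"): ["no biliary ductal dilatation"],
    ("liver_gallbladder", "fatty"): ["no hepatic steatosis"],
    ("kidneys_ureters", "stone"): ["no renal stones"],
    ("kidneys_ureters", "lesion"): ["no suspicious renal lesions"],
    ("kidneys_ureters", "atrophy"): ["no renal atrophy"],
    ("kidneys_ureters", "cyst"): ["no renal cysts"],
}

OTHER_ABNORMALITY_TEMPLATES: dict[str, list[str]] = {
    "lungs_pleura": [
        "patchy consolidation in the {lat} lower lobe",
        "small {lat} pneumothorax",
    ],
    "liver_gallbladder": [
        "cirrhotic morphology of the liver",
        "gallbladder wall thickening with cholecystitis",
    ],
    "kidneys_ureters": [
        "mild {lat} hydronephrosis",
        "perinephric stranding around the {lat} kidney",
    ],
}

#: Organ-agnostic noise sentences; none contains a lexicon term.
FILLER_SENTENCES = (
    "visualized osseous structures are intact",
    "degenerative changes of the thoracolumbar spine",
    "surgical clips in the anterior abdominal wall",
    "the urinary bladder is moderately distended",
    "moderate stool burden throughout the colon",
    "a small hiatal hernia is present",
    "mild degenerative disc disease at multiple levels",
    "vascular calcifications of the abdominal aorta",
    "the bowel gas pattern is nonspecific",
    "postsurgical changes in the subcutaneous tissues",
)

#: Disease-term surface tokens eligible for misspelling (length >= 5;
#: wildcard lexicon entries absorb a perturbed final character).
MISSPELLABLE_TOKENS = frozenset(
    {
        "atelectasis", "nodule", "nodules", "emphysema", "effusion", "effusions",
        "stone", "stones", "lesion", "lesions", "cysts", "atrophy", "atrophic",
        "dilated", "dilatation", "dilation", "fatty", "steatosis",
        "cholelithiasis", "masses",
    }
)

_PROTOCOL_PHRASE = {
    "CAP": "ct chest abdomen and pelvis with contrast",
    "C": "ct chest with contrast",
    "AP": "ct abdomen and pelvis with contrast",
    "A": "ct abdomen with contrast",
    "P": "ct pelvis with contrast",
    "CA": "ct chest and abdomen with contrast",
    "CP": "ct chest and pelvis with contrast",
}

_INDICATIONS = (
    "abdominal pain",
    "follow up of known malignancy",
    "shortness of breath",
    "trauma evaluation",
    "weight loss",
)

DEFAULT_PROTOCOL_MIX = {
    "CAP": 0.40, "C": 0.15, "AP": 0.20, "A": 0.10, "P": 0.05, "CA": 0.05, "CP": 0.05,
}


@dataclass
class GeneratorConfig:
    n_reports: int = 1000
    seed: int = 0
    protocol_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROTOCOL_MIX))
    disease_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            organ: {d: 0.18 for d in diseases} for organ, diseases in DISEASES.items()
        }
    )
    normal_prevalence: dict[str, float] = field(
        default_factory=lambda: {organ: 0.35 for organ in ORGAN_SYSTEMS}
    )
    negated_mention_rate: float = 0.25
    qualifier_rate: float = 0.04
    fused_sentence_rate: float = 0.04
    misspelling_rate: float = 0.06
    out_of_lexicon_rate: float = 0.05
    other_abnormality_rate: float = 0.30
    max_reports_per_subject: int = 3

    def validate(self) -> None:
        rates = {
            "negated_mention_rate": self.negated_mention_rate,
            "qualifier_rate": self.qualifier_rate,
            "fused_sentence_rate": self.fused_sentence_rate,
            "misspelling_rate": self.misspelling_rate,
            "out_of_lexicon_rate": self.out_of_lexicon_rate,
            "other_abnormality_rate": self.other_abnormality_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for organ, prevs in self.disease_prevalence.items():
            for disease, p in prevs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence {organ}/{disease} out of [0, 1]")
        for organ, p in self.normal_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"normal_prevalence {organ} out of [0, 1]")
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.max_reports_per_subject < 1:
            raise ValueError("max_reports_per_subject must be >= 1")
        unknown = set(self.protocol_mix) - set(PROTOCOLS)
        if unknown:
            raise ValueError(f"unknown protocols in mix: {sorted(unknown)}")
        if abs(sum(self.protocol_mix.values()) - 1.0) > 1e-9:
            raise ValueError("protocol_mix must sum to 1")

    def adversarial_free(self) -> "GeneratorConfig":
        """Copy with every adversarial knob switched off."""
        cfg = GeneratorConfig(
            n_reports=self.n_reports,
            seed=self.seed,
            protocol_mix=dict(self.protocol_mix),
            disease_prevalence={o: dict(p) for o, p in self.disease_prevalence.items()},
            normal_prevalence=dict(self.normal_prevalence),
            negated_mention_rate=self.negated_mention_rate,
            qualifier_rate=0.0,
            fused_sentence_rate=0.0,
            misspelling_rate=0.0,
            out_of_lexicon_rate=0.0,
            other_abnormality_rate=self.other_abnormality_rate,
            max_reports_per_subject=self.max_reports_per_subject,
        )
        return cfg


@dataclass
class GroundTruth:
    labels: dict[tuple[str, str], OrganLabel] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> OrganLabel:
        return self.labels[key]

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for (report_id, organ), label in self.labels.items():
            row: dict[str, object] = {
                "report_id": report_id,
                "organ": organ,
                "status": label.status,
            }
            row.update(label.as_binary())
            rows.append(row)
        return rows


def _fill(template: str, rng: np.random.Generator) -> str:
    if "{lat}" in template:
        template = template.replace("{lat}", str(rng.choice(_LAT)))
    if "{size}" in template:
        template = template.replace("{size}", str(rng.choice(_SIZES)))
    return template


def _misspell(sentence: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return sentence
    words = sentence.split()
    for i, word in enumerate(words):
        if word in MISSPELLABLE_TOKENS and rng.random() < rate:
            # Perturb the final character; wildcard entries keep the prefix.
            alphabet = "abcdefghijklmnopqrstuvwxyz".replace(word[-1], "")
            words[i] = word[:-1] + str(rng.choice(list(alphabet)))
    return " ".join(words)


def _organ_sentences(
    organ: str,
    truth_status: str,
    diseases: frozenset[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    sentences: list[str] = []
    if truth_status == POSITIVE:
        for disease in sorted(diseases):
            bank = DISEASE_TEMPLATES[(organ, disease)]
            family = "paraphrase" if rng.random() < config.out_of_lexicon_rate else "in_lex"
            sent = _fill(str(rng.choice(bank[family])), rng)
            if family == "in_lex":
                sent = _misspell(sent, config.misspelling_rate, rng)
            sentences.append(sent)
        for disease in sorted(set(DISEASES[organ]) - diseases):
            if rng.random() < config.negated_mention_rate:
                sentences.append(_fill(str(rng.choice(NEGATED_TEMPLATES[(organ, disease)])), rng))
    elif truth_status == NORMAL:
        bank = NORMAL_TEMPLATES[organ]
        family = "paraphrase" if rng.random() < config.out_of_lexicon_rate else "in_lex"
        sent = str(rng.choice(bank[family]))
        if rng.random() < config.qualifier_rate:
            sent = "however " + sent
        sentences.append(sent)
        for disease in DISEASES[organ]:
            if rng.random() < config.negated_mention_rate / 2:
                sentences.append(_fill(str(rng.choice(NEGATED_TEMPLATES[(organ, disease)])), rng))
    else:  # uncertain: ambiguous or no mention of the organ
        u = rng.random()
        if u < config.other_abnormality_rate:
            sentences.append(_fill(str(rng.choice(OTHER_ABNORMALITY_TEMPLATES[organ])), rng))
        elif u < config.other_abnormality_rate + 0.35:
            for disease in DISEASES[organ]:
                if rng.random() < config.negated_mention_rate:
                    sentences.append(
                        _fill(str(rng.choice(NEGATED_TEMPLATES[(organ, disease)])), rng)
                    )
        # else: organ simply not mentioned
    return sentences


def _sample_truth(
    organ: str, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, frozenset[str]]:
    if rng.random() < config.normal_prevalence[organ]:
        return NORMAL, frozenset()
    positives = frozenset(
        d for d in DISEASES[organ] if rng.random() < config.disease_prevalence[organ][d]
    )
    if positives:
        return POSITIVE, positives
    return UNCERTAIN, frozenset()


def generate_corpus(
    config: GeneratorConfig,
    protocol_map: Mapping[str, frozenset[str]] | None = None,
) -> tuple[list[RadiologyReport], GroundTruth]:
    """Generate reports plus per-(report, organ) ground-truth labels.

    Organs not covered by the sampled protocol are never mentioned and carry
    an ``uncertain`` truth label.  Deterministic given ``config.seed``.
    """
    config.validate()
    protocol_map = protocol_map or DEFAULT_PROTOCOL_MAP
    rng = np.random.default_rng(config.seed)
    protocols = sorted(config.protocol_mix)
    probs = np.array([config.protocol_mix[p] for p in protocols])
    reports: list[RadiologyReport] = []
    truth = GroundTruth()

    subject_idx = 0
    reports_left_for_subject = 0
    subject_id = ""
    for i in range(config.n_reports):
        if reports_left_for_subject == 0:
            subject_idx += 1
            subject_id = f"S{subject_idx:06d}"
            reports_left_for_subject = int(rng.integers(1, config.max_reports_per_subject + 1))
        reports_left_for_subject -= 1
        report_id = f"R{i + 1:06d}"
        protocol = protocols[int(rng.choice(len(protocols), p=probs))]

        findings_sentences: list[str] = []
        for organ in ORGAN_SYSTEMS:
            covered = protocol in protocol_map[organ]
            if covered:
                status, diseases = _sample_truth(organ, config, rng)
            else:
                status, diseases = UNCERTAIN, frozenset()
            truth.labels[(report_id, organ)] = OrganLabel(
                organ_system=organ, status=status, diseases=diseases
            )
            if covered:
                findings_sentences.extend(
                    _organ_sentences(organ, status, diseases, config, rng)
                )
        # interleave organ-agnostic filler at random positions so findings
        # have realistic length and the informative content moves around
        n_filler = int(rng.integers(2, 6))
        fillers = rng.choice(len(FILLER_SENTENCES), size=n_filler, replace=False)
        for f in fillers:
            at = int(rng.integers(0, len(findings_sentences) + 1))
            findings_sentences.insert(at, FILLER_SENTENCES[f])

        findings = _render_findings(findings_sentences, config.fused_sentence_rate, rng)
        sections = {
            "protocol": _PROTOCOL_PHRASE[protocol],
            "indication": str(rng.choice(_INDICATIONS)),
            "technique": "axial images were obtained with multiplanar reformats",
            "findings": findings,
            "impression": "as described above",
        }
        reports.append(
            RadiologyReport(
                report_id=report_id,
                subject_id=subject_id,
                protocol=protocol,
                sections=sections,
            )
        )
    return reports, truth


def _render_findings(
    sentences: list[str], fused_rate: float, rng: np.random.Generator
) -> str:
    """Join sentences with periods; with the fused rate, drop the period
    between adjacent sentences (run-on grammar error)."""
    if not sentences:
        return "limited examination."
    out = []
    for i, sent in enumerate(sentences):
        last = i == len(sentences) - 1
        if not last and rng.random() < fused_rate:
            out.append(sent + " ")
        else:
            out.append(sent + ". ")
    return "".join(out).strip()


def corpus_stats(
    reports: Sequence[RadiologyReport], truth: GroundTruth
) -> dict[str, dict[str, int]]:
    """Per-organ disease/status counts plus per-protocol report counts."""
    stats: dict[str, dict[str, int]] = {}
    for organ in ORGAN_SYSTEMS:
        counts = {d: 0 for d in DISEASES[organ]}
        counts.update({POSITIVE: 0, NORMAL: 0, UNCERTAIN: 0})
        stats[organ] = counts
    protocol_counts: dict[str, int] = {p: 0 for p in PROTOCOLS}
    for report in reports:
        protocol_counts[report.protocol] += 1
        for organ in ORGAN_SYSTEMS:
            label = truth.labels[(report.report_id, organ)]
            stats[organ][label.status] += 1
            for d in label.diseases:
                stats[organ][d] += 1
    stats["protocols"] = protocol_counts
    return stats
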