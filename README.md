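# ctra — CT report annotation

Weakly supervised multi-label disease annotation of body-CT radiology
reports.  The pipeline has two stages:

1. **Rule-based algorithm (RBA)** — a configurable dictionary labeler that
   reads only the *findings* section of a report and, per organ system
   (lungs/pleura, liver/gallbladder, kidneys/ureters), marks it positive for
   one or more of four diseases, normal, or uncertain.  The rules distinguish
   single-organ descriptors ("emphysema"), multi-organ descriptors that need
   an organ co-mention ("nodule", "stone"), negations ("no", "without"),
   qualifiers ("however"), normal terms ("unremarkable") and other
   abnormalities that block a normal verdict.  Wildcard entries absorb
   misspellings; a sentence-length criterion guards against run-on sentences.
2. **Attention-guided BiLSTM** — a multi-label classifier trained on the
   RBA's labels (weak supervision) that generalizes beyond the dictionary.
   Implemented in pure NumPy (embedding → BiLSTM → dropout → per-timestep
   attention softmax → context vector → dense → sigmoid heads, weighted
   binary cross-entropy, Adam), with per-token attention traces for
   interpretability.

Around these sit TF-IDF term discovery for building lexicons, a synthetic
report generator with known ground truth (negated mentions, fused run-on
sentences, misspellings, out-of-lexicon paraphrases), and an evaluation
stack: accuracy/precision/recall/F1, ROC AUC with DeLong confidence
intervals, and a training-size ablation harness.

## Command-line usage

All functionality is exposed through the `ctra` entry point:

```sh
ctra gen-synthetic --n 2000 --seed 7 --out out/            # corpus + truth
ctra discover-terms --reports out/reports.jsonl --sample 3500 --top 50 \
    --out terms.tsv                                        # TF-IDF ranking
ctra annotate --reports out/reports.jsonl --organ lungs_pleura --out out/
ctra split --reports out/reports.jsonl --fractions 0.7,0.15,0.15 --seed 7
ctra train --reports out/reports.jsonl --organ lungs_pleura --seed 7 --out out/
ctra evaluate --truth out/truth.csv --pred out/labels-lungs_pleura.csv
ctra attend --model out/model-lungs_pleura --reports out/reports.jsonl \
    --report-id R000001 --out attention.html               # heat-map overlay
ctra ablate --reports out/reports.jsonl --organ lungs_pleura \
    --fractions 0.2,0.4,0.6,0.8,1.0 --out out/
```

`ctra train` defaults to a desk-scale model configuration (64 embedding
dimensions, 64 recurrent units per direction, 10 epochs, batch 64); pass
`--paper-config` for the full-size configuration (200/200, 650-token
padding, 50 epochs, batch 512, learning rate 1e-4).  Pre-trained word
vectors in word2vec text format can be supplied with `--embeddings`.

## Layout

| Module | Contents |
| --- | --- |
| `ctra.corpus` | report model, section parsing, sentence segmentation, RNN preprocessing, subject-wise splits |
| `ctra.lexicon` | descriptor-class data model, YAML/TSV formats, wildcard term matching |
| `ctra.rba` | the per-sentence rule engine and report/corpus labeling |
| `ctra.tfidf` | TF-IDF term ranking |
| `ctra.synthetic` | synthetic report generator with ground truth |
| `ctra.attention_rnn` | the NumPy attention BiLSTM: model, training, traces, embedding loader |
| `ctra.evaluation` | metrics, DeLong AUC CIs, ablation harness |
| `ctra.pipeline` | weak-supervision glue (filter → label → split → encode → train) |
| `ctra.cli` | the `ctra` command |

The shipped lexicon (`src/ctra/data/lexicon.yaml`) is illustrative: it
covers the descriptor taxonomy and the documented example terms, not an
exhaustive clinical dictionary, and is meant to be extended per deployment.
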