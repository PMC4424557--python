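# bilex

Bilingual term-lexicon induction from comparable corpora: given two
monolingual, term-annotated corpora (e.g. clinical discharge summaries in
two languages) and a small seed lexicon of known translation pairs, the
package ranks target-language translation candidates for source-language
test terms.

Three extraction routes are implemented:

* **Context-similarity baseline** (`bilex.context`) — every term gets a
  sparse context vector over seed-pair dimensions, built from a narrow
  window (the nearest seed occurrence on each side of every term
  occurrence, frequency-weighted); candidates are ranked by cosine.
* **Label propagation for single-word terms** (`bilex.lp`) — a
  per-language sentence co-occurrence graph with context-cosine edge
  weights; seed vertices carry clamped one-hot labels, all other labels
  are iteratively replaced by the weight-normalised average of their
  neighbours' labels (10 synchronous cycles by default).  Converged
  labels of the two languages live in the same seed-pair space and are
  compared by cosine.  A clamped-harmonic linear-solve oracle
  (`fixed_point_oracle`) is provided for verification.
* **Multi-word-term alignment** (`bilex.mwt`) — for a source term of m
  words: rank candidates per component word via label propagation, keep
  the top 100 per component, flatten to candidate words, intersect
  across components, match word subsets of size 1..m against terms that
  actually occur in the target corpus, and rank matched terms by the
  average component-to-word similarity.

`bilex.evaluation` computes Top-N accuracy against a gold lexicon
(exact-match only).  `bilex.synthetic` generates paired comparable
corpora with a planted seed lexicon, planted single-word translation
pairs, and planted m-to-n multi-word pairs, so the entire pipeline is
testable without any private clinical data.

## Command line

```sh
# generate a synthetic corpus pair with planted lexicons
bilex simulate --config synth.yaml --seed 17 --out data/

# individual stages
bilex extract   --corpus data/source.jsonl --seeds data/seeds.tsv --out vectors.tsv
bilex propagate --corpus data/source.jsonl --seeds data/seeds.tsv \
                --iterations 10 --edge-weight cosine --out labels.tsv
bilex rank      --source-corpus data/source.jsonl --target-corpus data/target.jsonl \
                --seeds data/seeds.tsv --method lp --out rankings.tsv
bilex align-mwt --source-corpus data/source.jsonl --target-corpus data/target.jsonl \
                --seeds data/seeds.tsv --top-k 100 --score pairs-mean --out mwt.tsv
bilex evaluate  --rankings rankings.tsv --gold data/gold_swt.tsv --topn 1,10,100

# everything at once (writes all intermediate artifacts)
bilex run --config pipeline.yaml
```

`pipeline.yaml` mirrors `bilex.cli.PipelineConfig`:

```yaml
source_corpus: data/source.jsonl
target_corpus: data/target.jsonl
seed_lexicon: data/seeds.tsv
gold_swt: data/gold_swt.tsv
gold_mwt: data/gold_mwt.tsv
out_dir: out/
iterations: 10
K: 100
```

## File formats

* **Corpus** — JSON lines, one document per line, UTF-8:
  `{"doc_id": str, "lang": str, "sentences": [[token, ...], ...],
  "terms": [{"sent": int, "start": int, "end": int, "cat": str}, ...]}`.
  Term spans are 0-based half-open token offsets within one sentence;
  `cat` is one of `problem|treatment|test|other`.
* **Seed / gold lexicon** — two-column TSV (`source_term`,
  `target_term`), words space-separated inside a column, `#` for
  comments.  Line order defines the seed-pair dimension order.

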