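# dyadalign

Turn-level psycholinguistic time series and alignment indices for dyadic
(two-person) conversation transcripts.

`dyadalign` ingests a folder of raw transcripts (one `.csv` or `.txt` file
per conversation), cleans and tokenizes the text, attaches per-word
psycholinguistic norms (e.g., valence, concreteness, frequency) from a
pluggable lexicon, aggregates them into per-turn time series paired by
exchange, and computes two complementary whole-conversation alignment
indices:

- **dAUC** (proximity): trapezoidal area under the absolute per-turn
  difference curve, reported raw, standardized to a 50-turn length, and
  under a lag-1 re-pairing of turns within exchanges;
- **lead/lag correlations** (synchrony): Spearman or Pearson coefficients
  with the first speaker's series shifted across a range of offsets.

It also generates **sham controls** (each speaker's turn order permuted
within a conversation, seeded and reproducible), a descriptive **corpus
analytics** table (word counts, cleaning retention rate, type-token
ratios, words per turn, lexicon-backed word measures), and **synthetic
coupled dyads** (AR(1) leader + delayed linear follower) that can be
realized as word-level transcripts so the whole pipeline is testable
without any external data.

## Quick start (Python)

```python
import dyadalign as da

table = da.mark_turns(da.read_dyads("transcripts/"))
lexicon = da.load_lexicon("my_norms.csv")      # or da.fixture_lexicon()
config = da.CleaningConfig(dimensions=("valence",), stopword_list="default",
                           lemmatize=True, remove_backchanneling=False)
tokens = da.prep_dyads(table, lexicon, config)
series = da.aggregate_turns(tokens, ["valence"])
summary = da.summarize_dyads(series, offsets=range(-3, 4),
                             corr_type="spearman")
analytics = da.describe_corpus(table, tokens, lexicon)
```

Transcript files need a speaker-identifier column and an utterance-text
column (CSV with a header, or `Speaker: utterance` lines in TXT); the
filename stem becomes the conversation id. Extra columns pass through as
metadata. Conversations with fewer than 50 turns trigger a warning —
alignment indices are unstable on short samples.

Offset semantics: positive offsets *lag* the first speaker (pair their
later turns with the partner's earlier turns, emphasizing the first
speaker's responses); negative offsets are *leads*. Non-overlapping ends
are trimmed.

## CLI

```bash
dyadalign read      --input transcripts/ --out utterances.csv
dyadalign prep      --input transcripts/ --dims valence --out tokens.csv
dyadalign summarize --input tokens.csv --dims valence \
                    --corr-type spearman --lags -3:3 --out summary.csv
dyadalign shams     --input tokens.csv --seed 17 --n 200 --out shams.csv
dyadalign describe  --input transcripts/ --dims valence --out analytics.csv
dyadalign simulate  --spec sim.json --out synthetic_corpus/
dyadalign run       --config config.json     # full pipeline, all outputs
```

`dyadalign run` reads a JSON/YAML config (see `RunConfig` in
`dyadalign.cli`) and writes utterances, tokens, the long-format turn
series, the alignment summary (real + sham rows), the analytics table, a
JSON-lines log, and the resolved config for provenance. Reruns with the
same config and seeds are byte-identical.

## Word lists and lexicons

Stopword tiers (`none` ⊆ `minimal` ⊆ `default` ⊆ `strict`), the
contraction map, and the static lemma dictionary ship as plain-text
package data under `dyadalign/data/` and can be overridden
(`--stopwords FILE`). The packaged *fixture lexicon*
(`da.fixture_lexicon()`) contains ~300 common words with **synthetic**
values — it exists for tests, docs, and simulations only; supply real
published norms via `--lexicon FILE` for substantive analyses.

## Tests and acceptance report

```bash
python -m pytest tests/            # full suite, ~10 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-verifies the eight property-based acceptance
criteria (dAUC vs. a brute-force trapezoid oracle, the 50-turn
normalization identity, interpolation vs. a closed-form fill oracle,
correlations vs. textbook formulas on explicitly shifted vectors,
leader–follower recovery on coupled AR(1) dyads, sham-null separation,
pipeline determinism, and backchannel merging) and writes the target
report to `--out`. No numeric published targets are reproducible offline
(they require an externally hosted interview corpus and a large norm
database), so the target object is empty by design; the criterion
metrics are printed to stdout.
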