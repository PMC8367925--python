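# predlex

Simulation tools for asking whether "less signal for expected input" is a
reliable signature of predictive coding in spoken word recognition.

The package implements two models side by side, together with the
novel-word-learning experiment design used to probe them:

- **Cohort prediction model** (`predlex.prediction_model`): by-position,
  frequency-weighted probabilities of the next phoneme given the input so
  far, and the summed-absolute prediction error against the presented
  phoneme (bounded in [0, 2]).
- **Interactive-activation simulator** (`predlex.iam_simulator`): a
  TRACE-family network with time-reduplicated phoneme and word units,
  bottom-up excitation, excitatory lexical feedback and within-layer
  lateral inhibition, instrumented to record per-cycle unit activations,
  total word→phoneme feedback flow, and raw word-/phoneme-layer activation
  totals.
- **Experiment harness** (`predlex.experiment`): item triples (source word,
  novel nonword, baseline nonword) sharing a prefix up to a deviation point
  (DP); "training" adds the novel form to the lexicon at its source word's
  frequency; runs are counterbalanced over which nonword is trained,
  aligned on the DP, and scored against three findings predicates
  (post-DP orderings pre/post training, and the pre-DP training effect).
- **Synthetic data** (`predlex.synthetic_data`): seeded generators for
  cohort-structured lexicons (Zipf frequencies, controllable onset sharing)
  and valid item triples, so the full pipeline runs with no external data.

## Command line

```sh
# generate a synthetic lexicon + triples
predlex generate --seed 1 --out-lexicon lex.tsv --out-triples triples.tsv

# cohort model: per item x position CSV (both phases, both counterbalances)
predlex predict --lexicon lex.tsv --triples triples.tsv --out results/

# interactive-activation simulator: per item x cycle CSV
predlex simulate --lexicon lex.tsv --triples triples.tsv --out results/

# DP-aligned cell means, findings checks, plots
predlex analyze --results results/ --out report/

# everything above in one seeded, deterministic run
predlex reproduce --seed 1 --out out/
```

Lexicons are TSV (`orthography <TAB> space-separated phonemes <TAB>
frequency`); the lexicon format of the public C/Java TRACE distributions is
readable via `read_lexicon(path, dialect="trace")`. Simulator parameters
can be overridden from a YAML file passed to `simulate --params`.

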