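# wamr

Weighted associative memory registers (AMRs) with entropy-based
disambiguation, plus the surrounding machinery to exercise them on a
phonetic-recognition-style task: quantization of real feature vectors,
a multi-register memory system, phone-string evaluation metrics over the
Mexbet-22 alphabet, an incremental self-training loop, and a synthetic
data generator so everything runs offline.

An AMR is an `n x m` table of non-negative integer weights; columns are
discrete features, rows are quantized values. It supports three operations:

- **register** — increment the cells addressed by a cue (additive storage);
- **recognize** — a relaxed material-implication test controlled by the
  parameters `(iota, kappa, xi)`: per-cell sensitivity, overall cue
  strength, and the number of features allowed to fail;
- **retrieve** — sample each output feature from the column distribution
  modulated by a normal kernel of width `sigma` centred on the cue
  (`sigma = 0` returns the cue photographically).

A `MemorySystem` holds one labelled register per class; when several
registers accept a cue it picks the one minimising `entropy / rho`
(register indeterminacy over cue weight). Six named parameter scenarios
(`I`-`VI`) are built in.

## CLI

```sh
wamr synth --n-utterances 100 --n-classes 8 --out corpus/   # synthetic corpus
wamr build --units corpus/rem.csv --m 64 --scenario V --out sys/
wamr recognize --system sys/ --units corpus/test.csv
wamr retrieve  --system sys/ --units corpus/test.csv --seed 0 --out rec.csv
wamr sweep --rem corpus/rem.csv --test corpus/test.csv --scenario V --out sweep.csv
wamr learn --n-stages 5 --seed 0 --out stages.csv           # self-training loop
wamr eval --table5                                          # worked example report
```

Registers persist as a JSON header plus an integer CSV matrix (bit-exact
round-trip); a system is a directory with a manifest, a quantizer file and
one register per class.

## Layout

- `src/wamr/core.py` — `WeightedAMR`, the three operations, entropy and
  function counting
- `src/wamr/quantization.py` — min-max quantizer between real vectors and
  discrete feature functions
- `src/wamr/system.py` — labelled register ensemble, decision rule,
  size/fill sweep
- `src/wamr/evaluation.py` — Mexbet-22 tokenizer, token Levenshtein,
  error rate, precision/recall conventions, bigram simplification
- `src/wamr/learning.py` — window sampling, active-phase collection,
  corpus balancing, staged loop
- `src/wamr/synthetic.py` — class-conditional generators, frame streams,
  partitioned corpora
- `src/wamr/io.py`, `src/wamr/cli.py` — persistence and command line
- `src/wamr/examples.py` — the packaged worked-example phone strings
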