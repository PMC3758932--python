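# pcrnet

Analysis pipeline for **Perceived Causal Relations (PCR) scaling**: a survey
methodology in which respondents first rate how frequently they experienced
each of 40 psychological symptoms in the past month (ordinal 0–7) and are
then asked, for every ordered pair of symptoms they endorsed, "How much do
you think your problems with X cause your problems with Y?" (0–10).  The
result is a per-person *directed, weighted* causal network over symptoms of
depression, posttraumatic stress, anxiety, dissociation and related problems.

The package is written for researchers in psychopathology network analysis
and psychometrics.  It covers the full analysis chain:

- **Typed data model** — frequency and PCR ratings with explicit
  missing-*by-design* (question never asked because a symptom was not
  endorsed) vs missing-*by-intention* (question skipped) semantics, and
  long-format CSV readers/writers that enforce the eligibility invariants.
- **Cause/effect scoring** — per symptom *i*, the mean causal association
  C_i (average PCR_i→j over rated partners) and mean effect association E_i
  (average PCR_j→i); across participants, the paired contrast
  t = mean(C−E) / (SD(C−E)/√n) with effect size d = |t|/√(df+1) and
  Holm–Bonferroni control over the 40-contrast family.
- **Bootstrap regression designs** — moderation (y ~ x + w + x·w on
  mean-centered predictors, ΔR² F-test, simple slopes at w̄ ± 1 SD),
  incremental prediction, mediation (indirect effect a·b with case-resampling
  percentile CIs), and moderated mediation with conditional indirect effects
  (a₁+a₃w₀)(b₁+b₃v₀) on a moderator probe grid.
- **Symptom networks** — group-level mean-PCR directed networks; weighted
  outdegree/indegree and betweenness with inverse-weight path costs
  (cost = w⁻ᵅ); permutation nulls that re-scatter the observed edge weights
  and flag symptoms outside the central 95% interval.
- **Feedback loops** — bounded-length simple directed cycle enumeration
  (≤ 4 symptoms) in each participant's supra-threshold (PCR > 4.5) network,
  per-symptom loop involvement, and Spearman / partial-Spearman association
  between loop counts and the 40-item symptom-frequency sum score.
- **Synthetic populations** — a seeded generator driven by a ground-truth
  causal weight matrix with planted feedback loops, so every stage has a
  recovery test with a known answer.

## Worked example

The `analysis/` drivers run the whole study on a simulated population
(n = 300, seed 42) and narrate what they find:

```bash
python analysis/01_simulate.py
python analysis/02_score.py
python analysis/03_models.py
python analysis/04_network.py
python analysis/05_loops.py
```

`05_loops.py` prints, for that population:

```
295 feedback loops across 300 participants (5 distinct loop types); per-participant range 0-4
planted loops recovered: 5/5 (spurious types: 0)
most loop-involved symptoms (per endorsing participant): DPRM (0.93), WRRY (0.92), MEMT (0.62), EMOT (0.58), SHME (0.54)
loop count vs frequency sum: rho = 0.54 (p = 2.1e-24); partialling n symptoms: rho = 0.19 (p = 0.00095); + n PCR entries: rho = 0.19 (p = 0.00082)
```

Reading this: thresholding each participant's PCR ratings at 4.5 and
enumerating directed cycles recovers exactly the five feedback loops planted
in the generator's weight matrix; the symptoms inside those loops (depressed
mood, worrying, guilt/shame, reexperiencing) dominate loop involvement; and
participants whose networks contain more loops report reliably higher total
symptom frequency, even after controlling for how many symptoms and PCR
ratings they have — the coherence property the loop analysis is designed to
detect.  `04_network.py` likewise flags the same planted-loop symptoms as
having extreme outdegree/indegree/betweenness relative to 1,000
weight-permuted networks.

The same stages are scriptable via the CLI (`pcrnet simulate|score|models|
network|loops|run`) or the `run_pipeline` function with a YAML config.

## Layout

```
src/pcrnet/        library: catalog, records, io, simulate, scoring,
                   regression, network, loops, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, conventions, generator design, limitations
```
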