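# dynppi

Stage-specific dynamic protein–protein interaction (PPI) network inference
from temporal expression profiles, interaction-difference networks between
differentiation stages, and relevance scoring of proteins and functional
modules.

## The problem

Directed differentiation protocols steer pluripotent stem cells toward a
target fate by adding inducers at fixed times (e.g. LSB, then SHH/FGF8, then
CHIR for dopaminergic neurons). Each induction condition yields a composite
time course, and the question is *which protein interactions rewire* as the
protocol advances — those interactions are candidates for controlling the
direction of differentiation. `dynppi` answers this with three steps:

1. **Dynamic network identification.** For every target protein *p* with
   candidate interactors *q* = 1..*Q* (from a pooled PPI database edge list),
   a discrete bilinear model is fitted to the stage's time course:

   ```
   z_p[t+1] = z_p[t] + Σ_q b_pq z_p[t] z_q[t] + α_p x_p[t] − β_p z_p[t] + ω_p[t+1]
   ```

   where `z_p` is the protein level (mRNA used as a proxy), `b_pq` the
   interaction activity, `α_p` the translation effect of the mRNA input
   `x_p`, `β_p` the degradation rate and `ω_p` noise. The profile is
   cubic-spline interpolated to `L ≈ 4(Q+2)` pseudo-time points, the
   coefficients solved by ordinary least squares, and false-positive
   interactions removed by minimising AIC = `L·ln(rss/L) + 2k` over
   interaction subsets (exhaustively for small neighbourhoods, greedy
   backward elimination otherwise).

2. **Interaction difference networks (IDNs).** For two stages the identified
   matrices are differenced, `d_pq = b̂_pq^(s2) − b̂_pq^(s1)`, and each changed
   edge is classified as enhancing/attenuating and emerged/diminished/
   coexisting.

3. **Relevance scores.** A protein's score is the mean absolute activity
   change over its changed interactions, `RS_p = Σ_q |d_pq| / degree(p)`;
   a functional module (gene set) scores `RS_f = Σ_{p∈f} RS_p`, with a
   hypergeometric enrichment p-value of the module among the rewired genes.

A fully-instrumented synthetic generator simulates the three-condition,
seven-day, three-replicate design from known ground-truth stage networks, so
every inference step can be benchmarked against the truth.

## Worked example

Simulate a 20-gene dataset with 25 true edges plus decoys, then run the full
pipeline (normalisation → per-stage ANOVA/FDR filtering → three stage
networks → two IDNs → rankings):

```bash
dynppi simulate --genes 20 --true-edges 25 --decoy-ratio 0.5 --seed 0 --out data
dynppi run --expr data/expression.tsv --annot data/annotations.tsv \
           --candidates data/candidates.sif --out results
```

which prints

```
stage I: 17 DE genes, 17 nodes, 30 edges
stage II: 15 DE genes, 14 nodes, 20 edges
stage III: 15 DE genes, 15 nodes, 26 edges
manifest: results/manifest.json
```

i.e. per stage: how many genes pass the differential-expression filter and
the size of the identified network. Ranking the stage I → II IDN:

```bash
dynppi score --idn results/idn_I_to_II.tsv --top 3 --out scores.tsv
```

```
 rank gene       rs  degree
    1 G013 1.189082       5
    2 G006 0.758053       3
    3 G000 0.413565       5
```

`G013` changed 5 of its fitted interactions with a mean absolute activity
change of 1.19 — the strongest rewiring between the two simulated stages.
`dynppi subnet --idn results/idn_I_to_II.tsv --seeds G013 --radius 1` extracts
its first-neighbour subnetwork; `dynppi score-modules` ranks GMT gene sets
the same way. Every run writes a `manifest.json` with content hashes:
identical inputs and seed reproduce every table byte for byte.

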