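# srnakit

Bacterial small non-coding RNAs (sRNAs) are 50–600 nt regulators that show
up in strand-specific RNA-seq as expression antisense to genes
(*cis*-encoded, extensively complementary to the opposite-strand transcript)
or in intergenic space (*trans*-encoded, acting through short seed
duplexes). `srnakit` is a Python library for the computational side of an
sRNA survey in a bacterium grown under contrasting nutrient limitations
(carbon- vs nitrogen-limited continuous culture):

* **Detection** — call expressed intervals from per-base stranded coverage
  (depth ≥ a threshold, short gaps merged, a size band applied), drop
  5′-UTR-like signal upstream of same-strand gene starts, and classify the
  rest as *cis* (antisense overlap ≥ 50% of the call) or *trans*
  (overlapping no gene on either strand).
* **Differential expression** — TMM normalization of genes and sRNAs
  together, per-feature negative-binomial dispersions
  (method of moments, shrunk toward a mean–dispersion trend), and the
  conditional **exact NB test**: replicates are collapsed to per-condition
  pseudo-sums on a common effective library size, and conditional on the
  total *t* = *s*₁ + *s*₂ the two-sided p-value is
  Σ {P(*k*, *t* − *k*) : P ≤ P(*s*₁, *s*₂)} under NB(μ, φ) variation, with
  Benjamini–Hochberg FDR control.
* **Target assignment** — each *cis* sRNA's presumed target is the gene on
  the antisense strand; *trans* sRNAs are screened against start-codon
  windows with a seed-complementarity score (Watson–Crick 1.0, G:U wobble
  0.5) and an empirical p-value from dinucleotide-preserving shuffles.
* **Mode-of-action statistics** — OLS regression of target log₂ fold-change
  on sRNA log₂ fold-change, with a null built by **randomly re-pairing**
  targets and sRNAs 10,000 times and recomputing the regression F; for
  independent pairs this null follows F(1, *n* − 2), whose median at
  *n* ≈ 69 is ≈ 0.45.
* **Network connectedness** — a dyadic-independent exponential random graph
  model over a directed metabolic network: each ordered dyad (i, j) is a tie
  with log-odds θ_edges + θ_target·(x_i + x_j), where x flags sRNA-target
  genes. The MLE is exact (Newton on the aggregated dyad likelihood), and
  θ_target = log(0.8) corresponds to targets being ~20% less connected.
  Membership fractions are compared with a pooled two-proportion Z-test.
* **Size calibration** — a gamma GLM with inverse link,
  E[size] = 1/(b₀ + b₁·distance), fitted to electrophoresis ladder
  standards by IRLS, converting blot migration distances to RNA sizes with
  95% intervals.

A seeded synthetic-data generator (`srnakit.synthetic`) produces every input
the pipeline consumes — annotation, stranded coverage, counts, network,
ladder — with planted ground truth, so each stage is testable for parameter
recovery without external data.

## Worked example

```bash
python examples/03_fold_change_regression.py
```

simulates a default dataset, detects sRNAs, runs the exact NB test, pairs
each *cis* sRNA with its antisense target and prints:

```
pairs (cis sRNA, target) : 19
slope                    : +0.191
R^2                      : 0.019
observed F(1, 17)        : 0.32
median null F            : 0.479
empirical p              : 0.5779
```

The simulation plants no sRNA–target coupling, so the observed F is
unremarkable against its own re-pairing null (empirical p ≈ 0.58), while the
null median sits near the F(1, n−2) median as theory predicts. With real
coupled fold-changes the observed F lands far in the null's upper tail.
The other scripts in `examples/` walk through detection
(`01_simulate_and_detect.py`), differential expression (`02`), network
connectedness (`04`), size calibration (`05`) and trans-target prediction
(`06`), each printing the quantities it computes and what they mean.

A thin CLI mirrors the stages for shell use:

```bash
srnakit run-all --seed 7 --outdir run/   # simulate + every analysis stage
srnakit detect --gff ann.gff3 --plus p.bedgraph --minus m.bedgraph --outdir out/
```

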