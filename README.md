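# dotprint

Dot-plot fingerprints for repeat proteins.

Tandem-repeat proteins frustrate ordinary sequence analysis: their
repetitive, degenerate sequences make it hard to tell convergent from
divergent evolution, and repeat-detection tools disagree wildly. But a
repeat is, tautologically, similar to its sibling repeats — so a protein's
self-comparison **dot plot** carries a characteristic 2-D pattern of
diagonal lines that survives far more sequence change than the sequence
itself does. `dotprint` turns that observation into a quantitative
toolkit for structural bioinformaticians and protein-evolution people:

- **Fingerprints** — windowed BLOSUM62 self-similarity matrices
  (window W = 25, scores clamped to 0–255), binarized at a black point of
  31 into sparse upper-triangle pixel sets.
- **Sliding Jaccard comparison** — two fingerprints are slid along the
  self-identity diagonal and scored at each offset by
  J_X = |A ∩ B| / |A ∪ B| over black pixels; the maximum over offsets
  measures pattern similarity and J_D = 1 − J_X is a distance.
- **Repeat detection & deconvolution** — a chain is repeat-containing if
  it has ≥ 121 residues and ≥ 0.42 pixels/residue; per-residue pixel
  profiles yield repeat segments, and the off-diagonal pixel histogram
  yields repeat periods.
- **Evolution experiments** — BLOSUM-driven substitution decay
  (J_X = e^(−b·z) in the identity loss z, half-life z50 = ln 2 / b),
  insertion decay, and a Monte-Carlo alphabet shuffle that erases sequence
  identity while preserving the fingerprint.
- **Consensus fingerprints** — trim gappy MSA columns (≥ 20% gaps), pad
  termini with 25 gaps, average member grey matrices, re-binarize.
- **Clustering** — hierarchical (McQuitty/WPGMA and friends) on dense J_D
  matrices, top-k sparsification plus Markov clustering (MCL) for larger
  sets, with medoids and purity reports.
- **Synthetic benchmarks** — tandem-repeat, control, and homolog-family
  generators with machine-readable ground truth, so everything above is
  testable offline.

## Worked example

Generate a tandem-repeat protein (25-residue unit, 6 copies, 20%
divergence per copy), fingerprint it, and scan it:

```sh
dotprint synth --count 1 --seed 5 --out-dir demo
dotprint scan demo/synthetic.fasta --out-dir demo
cat demo/scan.tsv
```

```text
id	length	pixels	density	is_repeat	periods
tandem000	170	382	2.24706	True	25:128;50:101;75:77
```

The chain is 170 residues with 382 upper-triangle pixels (2.25
pixels/residue, far above the 0.42 census cutoff, hence
`is_repeat=True`), and the pixel histogram peaks at off-diagonal
distances 25, 50 and 75 — the repeat period and its multiples, read
straight off the fingerprint. Library use is symmetric:

```python
import numpy as np
import dotprint as dp

m = dp.load_substitution_matrix("BLOSUM62")
rng = np.random.default_rng(5)
seq, truth = dp.make_tandem_protein(dp.RepeatSpec(), m, rng)
plot = dp.fingerprint(seq, m)                  # sparse DotPlot
dp.pixel_density(plot)                         # 2.247...
dp.estimate_periods(plot)                      # [(25.0, 128), (50.0, 101), (75.0, 77)]

# decay kinetics on a natural-like chain from the synthetic standard set
chain = dp.make_standard_set(1, m, rng)[0][0]
curve = dp.decay_experiment(chain, m, replicates=24, rng=rng, measure_every=4)
fit = dp.fit_exponential(curve)
round(fit.z50, 2), round(fit.r_squared, 3)     # (9.37, 0.99)
```

The half-life says the fingerprint loses half its Jaccard similarity
after roughly 8% loss of sequence identity: the pattern decays quickly
once selection stops maintaining it.

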