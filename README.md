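# fractalseq

Fractal-dimension and entropy profiling of nucleotide sequences, built for
comparative studies of the coding (CDS) and noncoding portions of mRNA
transcripts — the kind of analysis that asks whether the untranslated
remainder of a transcript ("long noncoding" content, the 5' and 3'
untranslated regions concatenated) carries systematically different
sequence complexity than the coding region it flanks.

The package is aimed at bioinformaticians who want these estimators as a
tested library (or a small CLI) rather than spreadsheet scripts: each
primitive is unit-tested against independent oracles, and a seedable
synthetic-data module generates sequences, mRNA/CDS panels and expression
tables with *known* planted structure so every pipeline stage can be
validated offline, without downloading anything.

## The model

A DNA sequence over {A, C, G, T} is encoded as a numeric series Int(i) by
mapping each base to the sum of the atomic numbers of its nucleobase's
atoms (adenine C5H5N5 → 70, cytosine C4H5N3O → 58, guanine C5H5N5O → 78,
thymine C5H6N2O2 → 66; uracil is folded to T on input because its atom sum
collides with cytosine's). The map is configurable; the fractal dimension
below is invariant to affine re-mappings of the four values.

**Higuchi fractal dimension.** For lags k = 1..maxK (default maxK = 7) the
normalized curve length is

    L(k) = [ Σ_{i=k+1..N} |Int(i) − Int(i−k)| ] · (1/k²) · (N−1)/(N−k)

and the fractal dimension FD is the OLS slope of log L(k) against
log(1/k). A straight ramp gives exactly FD = 1; an i.i.d. random sequence
gives FD ≈ 2; fractional Brownian motion with Hurst exponent H gives
FD ≈ 2 − H. Values near 2 signal high positional complexity, values near
1 a smooth, low-information series.

**Shannon entropies.** Mononucleotide entropy H₁ = −Σ p_b log₂ p_b over
the 4 base states (max 2 bits) and dinucleotide entropy H₂ over the 16
overlapping adjacent-pair states (max 4 bits), plain plug-in estimates.

**Pipeline statistics.** Panels of mRNA/CDS pairs are summarized by the
regression of CDS FD on mRNA FD (slope, intercept, R², adjusted
R² = 1 − (1−R²)(n−1)/(n−2)), per-gene FD deltas and CDS/mRNA length
ratios, inclusion/exclusion R² comparisons over named gene subsets,
FD-versus-entropy maps with explicitly designated fit subsets, and
per-gene skewness (adjusted Fisher–Pearson) of expression z-score
distributions across brain regions.

## Worked example

```python
from fractalseq import (gen_iid_sequence, encode_atomic, higuchi_fd,
                        mono_entropy, di_entropy, gen_pair_panel,
                        compare_fd, inclusion_study)

# an i.i.d. uniform sequence sits at the rough end of the scale
seq = gen_iid_sequence(10_000, seed=1)
res = higuchi_fd(encode_atomic(seq))
print(f"fd={res.fd:.4f}  mono={mono_entropy(seq):.4f} bits  di={di_entropy(seq):.4f} bits")

# a 15-pair panel with a planted CDS-vs-mRNA relation: 13 collinear pairs
# on fd_cds = 1.2 * fd_mrna - 0.4, plus 2 pairs displaced below the line
panel = gen_pair_panel(seed=0)
rows = compare_fd(panel.pairs)
core = list(panel.planted.gene[panel.planted.core])
study = inclusion_study(rows, {"core": core, "all": list(panel.planted.gene)})
print(study[["subset", "n", "r2", "adjusted_r2", "slope", "intercept"]].round(4).to_string(index=False))
print("negative-delta pairs:", [r.gene for r in rows if r.delta < 0])
```

prints

```
fd=2.0009  mono=1.9999 bits  di=3.9992 bits
subset  n     r2  adjusted_r2  slope  intercept
  core 13 0.9890       0.9880 1.2108    -0.4219
   all 15 0.8992       0.8914 1.3474    -0.7045
negative-delta pairs: ['gene14', 'gene15']
```

The i.i.d. sequence shows the expected dimension ≈ 2 and near-maximal
entropies. The panel regression over the 13 core pairs recovers the
planted slope 1.2 and negative intercept; including the two pairs whose
CDS dimension falls below their mRNA's (negative delta) degrades R² from
0.989 to 0.899 — the deletion/inclusion logic the pipeline is built to
quantify.

The same analyses run from the shell:

```sh
fractalseq simulate --out-dir sim --seed 0          # FASTA + manifest + expression table
fractalseq compare --manifest sim/manifest.tsv --fasta-dir sim --out-dir reports
fractalseq fd --fasta sim/sequences.fasta --out fd.tsv
fractalseq skew --table sim/expression.tsv --out skew.tsv
```

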