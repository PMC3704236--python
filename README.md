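# codonscape

Genome-wide analysis of synonymous codon usage bias, built for the question
that AT-rich animal genomes pose: when every preferred codon ends in G or C
but the surrounding introns and flanks are strongly AT-biased, how much of
codon bias is mutation, and how much is selection on translation or on mRNA
structure?

The package provides a tested, reusable implementation of the full analysis
chain for a genome with gene models, a developmental expression time
course, tRNA gene counts, pairwise ortholog alignments and RNA
secondary-structure predictions:

- **Bias metrics** — Wright's effective number of codons
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` (61 = uniform usage, 20 = one
  codon per amino acid), its background-corrected variant **Nc′** (family
  homozygosity replaced by a χ² deviation from composition-derived expected
  codon frequencies, so mutational composition alone does not register as
  bias), GC partitions (GC3, GC_cds, GC_i, GC_f), per-amino-acid **sENC-X**
  rescaled to [0, 1], and degeneracy-centered usage
  `v = (p − 1/d)/(1 − 1/d)`.
- **Preferred codons** — per family, the codon whose within-family
  frequency has the most significant negative Spearman correlation with
  Nc′ (threshold 0.05/d), or the pooled-majority codon within a gene group.
- **Codon usage groups (CUGs)** — a multinomial mixture over synonymous
  codon choice conditioned on amino-acid sequence, fit by EM; the number of
  groups S is chosen by maximizing Δ(S) = B(S) − B_random(S), a
  self-consistency score against a structure-free null (see
  `docs/methods.md`).
- **Akashi's conservation test** — per-gene 2×2 strata of codon preference
  × amino-acid conservation against an ortholog, combined with the
  Mantel–Haenszel common odds ratio and Cochran–Mantel–Haenszel χ²,
  Woolf homogeneity test, and a reference distribution over randomly drawn
  synonymous codon sets ("P(better codon set)").
- **mRNA structure preference** — one-sided CMH test of whether third
  positions (N3) of preferred codons pair in stems rather than loops,
  stratified by gene and by third-position base (A3/C3/G3/U3/N3).
- **tRNA correspondence** — wobble-rule decoding of anticodons and Spearman
  correlation of tRNA gene-copy frequencies with synonymous codon and
  amino-acid usage.
- **Synthetic studies** — a generator that plants all of the above
  (clusters, bias gradients, conservation and stem-pairing odds ratios,
  tRNA proportionality) so every stage is testable without downloads.

## Worked example

Generate a three-cluster synthetic study and run the whole pipeline:

```sh
codonscape simulate --out demo --seed 17 --n-genes 150 --clusters 3 \
    --separation 0.45 --mean-len 200
cat > demo/run.yaml <<EOF
genome: demo/genome.fa
gff: demo/models.gff3
expression: demo/expression.tsv
alignments_dir: demo/alignments
folds_dir: demo/folds
trna: demo/trna.tsv
outdir: demo/out
s_min: 1
s_max: 5
n_null_reps: 3
n_restarts: 5
n_random_sets: 200
seed: 17
EOF
codonscape run --config demo/run.yaml
```

The run prints a stage summary ending in

```json
"cluster":  { "chosen_S": 3, "B": 0.9999999999768189 },
"akashi":   { "n_groups": 4 },
"structure":{ "n_rows": 20 }
```

`demo/out/model_selection.tsv` shows why S = 3 was retained — the
self-consistency excess over the null peaks there and collapses once extra
clusters only fit sampling noise:

```
S  B       B_random  Delta
1  1.0000  1.0000     0.000
2  1.0000  0.4475     0.553
3  1.0000  0.0929     0.907   <- retained
4  0.3056  0.0715     0.234
5  0.0492  0.0671    -0.018
```

`demo/out/akashi.tsv` recovers the planted conservation odds ratio of 1.3
within each codon usage group, and shows the diagnostic signature of
group-specific preferred codons: each group's own preferred set associates
more strongly with conservation than the single combined set does.

```
group  n_genes  MH_chi2  OR     p         p_better_codon_set
All    150       5.17    1.067  2.3e-02   0.045
CUG0    43      37.86    1.369  7.6e-10   0.000
CUG1    65      33.57    1.278  6.9e-09   0.000
CUG2    42      32.29    1.350  1.3e-08   0.000
```

Here `OR` is the Mantel–Haenszel common odds ratio for preferred codons
being conserved (amino acid unchanged in the ortholog), and
`p_better_codon_set` is the fraction of 200 random synonymous codon sets
with a stronger association — near zero when the identified preferred set
is genuinely special. `demo/out/structure.tsv` and
`demo/out/trna_correlations.tsv` likewise report the stem/loop CMH tests
per third-position base and the tRNA–usage correlations (ρ ≈ 0.95 at the
codon level for this study, against a planted proportionality with Poisson
noise).

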