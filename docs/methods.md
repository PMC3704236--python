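# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where the methodology was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Codon bias metrics

**Families and classes.** The 61 sense codons of the standard nuclear code
are grouped into synonymous families. The three sixfold amino acids (Leu,
Ser, Arg) are kept as single 6-codon families rather than split 2+4, so
the degeneracy classes carry weights 9 (twofold), 1 (threefold, Ile),
5 (fourfold) and 3 (sixfold) and Wright's Nc spans exactly [20, 61].

**Nc.** Per family with n ≥ 2 observed codons, the codon homozygosity is
estimated as F̂ = (n·Σp̂ᵢ² − 1)/(n − 1). Class means F̄ₖ average the usable
families of each degeneracy class; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
clamped to [20, 61]. Families with n < 2 or F̂ ≤ 0 are excluded from their
class average (small families otherwise produce division blow-ups). A
class with no usable family is imputed: the threefold class (Ile alone)
takes the mean of the two- and fourfold means; any other missing class
takes the mean of the available class means. This mirrors the behavior of
the classic Nc implementations.

**Nc′.** Expected within-family codon frequencies are derived from a
background mononucleotide composition: e(c) ∝ f(b₁)f(b₂)f(b₃),
renormalized within each family. Per family,
F̂′ = (χ² + n − m)/(m(n − 1)) with χ² = n·Σ(p̂ᵢ − eᵢ)²/eᵢ and m the family
size; assembly and clamping are identical to Nc. Under a uniform
background this reduces algebraically to Wright's F̂, so Nc′ = Nc exactly —
property-tested to 1e-9. The background is the pooled composition of all
1000-nt up/downstream flanks (a single genome-wide composition, not
position-specific), floored at 1e-9 per base to survive degenerate
synthetic inputs.

**sENC-X.** Per amino acid, ENC-X = 1/Σp̂ᵢ² uses plain frequency
homozygosity — not the small-sample estimator — so the rescaled
sENC-X = (d − ENC-X)/(d − 1) hits its printed endpoints (0 = no bias,
1 = maximum bias) exactly at any sample size. It is invariant to scaling
all family counts by a positive integer.

**GC partitions.** GC3 is computed over third positions of sense codons
with the terminal stop excluded (stops carry no synonymous-choice
information and are excluded from all codon counts); GC_i over
concatenated introns (absent for intronless genes); GC_f over both flanks.
Ambiguous bases are skipped in all GC denominators.

## Gene models and filters

GFF3 is consumed as 1-based closed intervals (via gffutils); internal
coordinates are 0-based half-open. The spliced CDS of a minus-strand gene
is the reverse complement of the ascending-coordinate exon concatenation;
introns and flanks are strand-corrected the same way. Validation flags —
non-ATG start (`bad_start`; alternate starts configurable), length not a
multiple of three (`partial_last_codon`), ambiguous codons
(`untranslatable_codon`), stops before the final codon (`internal_stop`) —
are collected rather than raised; a missing contig is a hard error, an
exon running off its contig flags the gene and leaves it unextracted.

Study filters drop flagged genes, genes absent from the expression table,
and genes whose maximum expression across stages is below 200 AU
(arbitrary units); among genes with exactly identical expression vectors
across all stages (treated as unhandled duplicates) only the one with the
smallest Nc is kept. High expression is a maximum above 25,000 AU. The
filter is idempotent and order-preserving.

## Preferred codons

Genome scope: for every family, each codon's within-family frequency
(missing for genes lacking the family; pairwise-complete deletion) is
Spearman-correlated with Nc′ across genes. The preferred codon is the one
with the smallest two-sided p among codons with ρ < 0, accepted iff
p < 0.05/d — the per-family Bonferroni correction for comparing more
codons in more degenerate families. "Most significant" (smallest p) rather
than "most negative ρ" is the operative rule. Group scope: the codon with
the greatest pooled usage across the group's genes (pooled counts, not
per-gene majority votes); exact ties break to the lexicographically first
codon with a logged warning.

## Codon usage groups

**Model.** A gene's synonymous choices are modeled as draws from
cluster-specific within-family codon distributions θ_s(c | family), so the
gene log-likelihood under cluster s is Σ_c n_g(c)·log θ_s(c|fam(c)) —
conditioning on the amino-acid sequence, which differs between genes but
carries no information about synonymous preference. The S-component
mixture is fit by EM with R = 10 restarts (k-means++-style seeding on
within-family frequency vectors), a Dirichlet-MAP pseudocount of 0.5 per
codon in the θ updates (prevents log 0 for codons absent from a cluster;
the EM ascent guarantee is asserted every iteration on the penalized
objective), convergence at relative objective change < 1e-8 or 500
iterations, empty-cluster reseeding from the worst-fit gene, and hard
maximum-posterior assignment at the end. bg(s), the posterior probability
of a gene's assigned cluster, is the per-gene assignment-quality score.

**Choosing S.** B(S) is a subsampling-stability self-consistency: the
model is refit on random 70% subsamples of the genes, subsample clusters
are matched to the full-data clusters by assignment overlap (Hungarian
matching), and B(S) is the geometric mean over genes of the subsample
model's posterior for each gene's full-data cluster. B_random(S) applies
the same score to artificial data in which each gene keeps its amino-acid
composition and lengths but draws codons from the pooled genome-wide
family frequencies (no structure); null replicates share random numbers
across S to reduce the variance of comparisons. The retained S maximizes
Δ(S) = B(S) − B_random(S) among values of S whose Δ exceeds twice its
Monte-Carlo standard error; if no S qualifies the smallest scanned S is
returned.

Two simpler variants were evaluated and rejected during design. Scoring B
on the training data itself (geometric mean of bg(s)) is not identifiable
when clusters are well separated: posteriors saturate near 1 even for
S above the truth, because spurious sub-clusters fitted to sampling noise
still assign confidently, and Δ(S) then grows with S. Scoring by
regeneration — simulating data from the fitted model and re-clustering —
fails for the same reason one step later: data regenerated from an overfit
model contain the noise-fitted sub-clusters as real structure. Subsampling
breaks both failure modes because noise clusters do not reproduce across
gene subsets. On planted data the stability criterion recovers
S ∈ {2, 3, 5} at 500 genes × 300 codons with cluster separation 0.4.

**Heatmap export.** θ is centered per codon by Eq.-style
v = (p − 1/d)/(1 − 1/d) over the 59 degenerate sense codons; rows and
columns can be ordered by complete-linkage hierarchical clustering on
Euclidean distance for display.

## Conservation of preferred codons

Each aligned gene yields a 2×2 stratum: a = preferred & conserved,
b = preferred & nonconserved, c = unpreferred & conserved,
d = unpreferred & nonconserved, where "preferred" is judged on the focal
species' codon against the group's preferred set and "conserved" means the
aligned ortholog codon encodes the same amino acid (synonymous state).
Codons aligned to gaps, stops or ambiguity, nondegenerate codons, and
codons of families without an assigned preferred codon are skipped. A
stratum is usable iff all four marginals are positive — the minimal
condition under which it informs an odds ratio; unusable strata are
dropped with a logged count.

Combination uses OR_MH = Σ(aₖdₖ/nₖ)/Σ(bₖcₖ/nₖ) and the CMH statistic
χ² = (|Σ(aₖ − Eₖ)| − ½)²/ΣVₖ with the hypergeometric mean and variance per
stratum. The continuity-corrected numerator is not clamped at zero when
the absolute deviation is below ½, matching the classical R
`mantelhaen.test` and statsmodels conventions. One-sided p-values halve
the two-sided p when the deviation sign matches the alternative.
Conservation tests default to two-sided; structure tests are fixed
one-sided (stem > loop for preferred codons) with the correction on.
Woolf's homogeneity test applies the Haldane +0.5 correction per cell,
inverse-variance weights wₖ, and Σwₖ(ln ORₖ − pooled)² on K − 1 df.

The randomized reference draws one codon uniformly per degenerate family
(families the observed set leaves unassigned stay unassigned, keeping the
comparison like for like), rebuilds all strata, and reports the fraction
of sets with a strictly greater OR_MH than the observed set — ties count
as not better. Table rebuilding is vectorized over an encoded alignment
representation so 1000 random sets complete in about a second on typical
study sizes.

## mRNA structure preference

Structures arrive as dot-bracket strings (any paired position is "stem",
any unpaired position "loop"; bulges count as loop). The folded sequence
is the CDS itself, keeping structure coordinates aligned to codons. Per
gene, third positions of degenerate codons with an assigned preferred
codon are cross-classified preferred × stem, optionally restricted to one
third-position base; the four base-restricted tables partition the N3
table exactly. Strata feed the one-sided CMH test above. A
base-pair-maximization folder (Watson–Crick + GU, hairpin loops ≥ 3,
deterministic leftmost-pairing traceback) is included so the machinery can
be exercised without an external thermodynamic predictor; it is a testing
device, not an energy model.

## tRNA correspondence

Anticodons decode codons by Watson–Crick pairing at codon positions 1–2
and wobble at position 3 (anticodon position 34): G34 → {C, U},
U34 → {A, G}, C34 → {G}, A34 treated as inosine-like → {U, C, A}; the rule
table is configurable. Decoded stops are discarded; if a decoded set spans
two amino acids, only codons of the full Watson–Crick codon's amino acid
are kept, with a warning. A species' usage frequency is the summed genome
frequency of its recognized codons; amino acids represented by a single
tRNA gene copy are excluded; gene-count and usage vectors are each
normalized to a maximum of 1 (which leaves Spearman correlations
unchanged but matches the conventional presentation). Amino-acid-level
correlations sum counts and usage within amino acids first.

## Synthetic studies

The generator emulates the statistical shape of a codon-bias study in an
AT-rich genome. Defaults: 500 genes, S = 5 clusters, mean length 500
codons, intron/flank GC 0.36 against elevated GC3 in biased clusters,
lognormal expression with one high-expression cluster (median ≈ 12,400 AU
vs ≈ 3,100 AU, σ = 0.8, five stages with per-stage jitter σ = 0.3),
conservation odds ratio 1.3 over a baseline synonymous-state probability
of 0.7, stem-pairing odds ratio 1.5 over a baseline stem probability of
0.5, and tRNA counts Poisson around 2000 × recognized-codon usage. Cluster
s prefers the (s mod d)-th codon of each family with excess frequency
`separation`·(1 − 1/d); an optional per-gene bias-gradient multiplier
produces the genome-wide bias continuum needed for preferred-codon
identification. Genes alternate strands, are split into exons at arbitrary
nucleotide positions, and are written in the same FASTA/GFF3/TSV/aligned
FASTA/dot-bracket formats the pipeline reads, with truth labels for
recovery tests. All randomness flows from a mandatory seed; identical
seeds give byte-identical output.

What the generator does **not** emulate: phylogenetic codon substitution
processes (ortholog codons are drawn i.i.d. per site at a planted odds
ratio, with no rate heterogeneity or dS structure), thermodynamically
consistent secondary structures (stem/loop states are planted per site and
then matched into a nested bracket layout), isochores or regional GC
structure, alternative transcripts, and annotation errors beyond the QC
classes the validator detects. Passing recovery tests therefore
demonstrates correctness of the estimators and tests under the stated
generative model, not robustness to the full messiness of real genomes.

## Problem sizes used in the automated checks

Recovery checks run at desk scale chosen to mirror the study's shape:
cluster-count recovery at 500 genes × 300 codons (separation 0.4, scan
S = 1..7, 3 stability/null replicates, 5 EM restarts), membership
recovery at separation 0.3 averaged over 5 seeds, conservation-OR
recovery at 500 genes (planted OR 1.3), stem-preference power at 300
genes (planted OR 1.5), preferred-codon recovery at 500 genes with a
bias gradient, and CMH type-I calibration over 1000 simulated stratified
datasets of 40 strata each.

## Known limitations

- Nc/Nc′ class imputation follows one (common) convention; published
  implementations differ in corner-case handling of rare families, so
  third-decimal differences against other tools are expected.
- The mixture conditions on amino-acid composition but assumes codon
  choices are independent across sites given the cluster; intragenic
  spatial structure is out of scope.
- The stability-based Δ(S) is a model-selection heuristic: its two-SE
  qualification rule trades a little power for protection against
  selecting noise, and very weakly separated clusters (below roughly the
  detection limit implied by gene length) will resolve to smaller S.
- The Woolf test uses the Haldane correction unconditionally, which is
  slightly conservative for large balanced strata.
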