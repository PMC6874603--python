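# Methods

This note documents the models, estimators, numerical choices and
limitations behind `pelletpop`, and what the synthetic-data generator
does and does not emulate.

## Study design being modelled

The target setting is a museum-style sample: small-mammal skulls
(water-shrew mandibles) recovered from barn-owl pellets over roughly
fifty years, photographed with a scale, and genotyped at six short intron
loci (153–229 bp) chosen to amplify from degraded DNA. Each individual
contributes a 16-landmark 2D configuration and, per locus, two phased
allele sequences. Groups (taxa, subspecies, geographic populations) are an
analytical input supplied in the sample table — never inferred from the
data.

## Morphometrics

**Coronoid height and classification.** The coronoid height is the
Euclidean distance between landmarks 1 and 7 times the image scale
(mm per coordinate unit). Classification uses fixed bands:
≤ 4.70 mm → `anomalus`, 4.80–5.35 mm → `fodiens`, > 5.35 mm →
`niethammeri`. The open interval (4.70, 4.80) has no published
assignment rule, so it is reported as `ambiguous` rather than silently
attached to a neighbouring class. Landmark numbering is 1-based
throughout. Partial configurations retaining only landmarks 1 and 7
(broken mandibles) are classified but excluded from shape analysis.

**Generalized Procrustes analysis.** Full superimposition: each complete
configuration is centred, scaled to unit centroid size, and iteratively
rotated onto the running mean with the closed-form 2D orthogonal solution
(SVD with the determinant sign forced positive, so reflections are never
introduced). The mean is re-estimated, re-centred and re-normalized each
sweep; iteration stops when the mean changes by less than 1e-10
(Frobenius norm; `converged` is set then), with a few further sweeps down
to machine precision so the fixed point is independent of input order.
The reported `mean_shape` is the coordinate-wise mean of the aligned
configurations. Centroid sizes are reported in mm (raw coordinates ×
scale). Degenerate configurations (centroid size 0) are rejected by
sample id.

**Shape PCA.** Eigendecomposition of the sample covariance matrix of the
flattened (n × 32) Procrustes coordinates. At most `min(n−1, 2k−4)`
components are retained: the 2D similarity fit absorbs four degrees of
freedom (two translation, one rotation, one scale). No explicit tangent
projection is applied; for the small shape variation this analysis
targets, the difference from tangent-space PCA is far below the noise
level. Group separation on scores or centroid sizes is assessed with a
two-group permutation test on |mean difference| (999 permutations,
p = (1 + #{perm ≥ obs})/(n_perm + 1)).

## Sequence handling

Alignments arrive phased, one FASTA per locus, headers
`<sample>_a1`/`<sample>_a2` (the dialect regex is configurable).
Cleaning removes every column that contains a gap or any non-ACGT symbol
in any sequence — column removal is the only edit, so cleaning is
idempotent; removing all columns is an error. IUPAC ambiguity codes are
treated as unknown, since retained sequences are assumed to be resolved
haplotypes. Positions are 0-based internally and 1-based in reports.

Multi-allelic encoding assigns code 1..k to distinct sequences at a
locus by first occurrence in sorted-individual order, so the coding is
stable under input-order permutation. The per-locus allele counts summed
over loci are the single source of truth for the "total alleles" figure
reported by the pipeline, computed over exactly the individuals entering
the genetic analysis.

Individual heterozygosity pools counts: (heterozygous positions summed
over the individual's available loci) / (summed cleaned lengths). The
per-locus-mean alternative is exposed (`per_locus_mean=True`) but is not
the default, because the pooled form weights loci by the sequence
actually observed.

## F-statistics

`wc84_fst` implements the Weir & Cockerham (1984) variance-components
estimator for diploid multi-allelic data, with the heterozygote
correction. Per locus and allele u, with r = 2 populations, nᵢ typed
individuals, p̂ᵢᵤ allele frequencies and ĥᵢᵤ observed heterozygote
frequencies:

    n̄  = mean nᵢ,   n_c = (Σnᵢ − Σnᵢ²/Σnᵢ)/(r−1)
    p̄ᵤ = Σ nᵢp̂ᵢᵤ/(r n̄),  s²ᵤ = Σ nᵢ(p̂ᵢᵤ−p̄ᵤ)²/((r−1) n̄),  h̄ᵤ = Σ nᵢĥᵢᵤ/(r n̄)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

and θ̂ = Σa / Σ(a+b+c), the ratio of sums over all alleles and loci —
not the mean of per-locus ratios (the per-locus mean is computed as a
diagnostic only). Individuals missing a locus are excluded locus-wise;
loci leaving fewer than two typed individuals in a population are
skipped with a warning. Data monomorphic at every locus make the ratio
0/0 and raise an explicit error instead of propagating NaN. Estimates
below −0.5 are flagged as pathological.

**Bootstrap CI.** Loci are resampled with replacement and θ̂ recomputed
per replicate from the cached per-locus (a, b, c) sums, which makes the
resampling a vectorized array operation; the 95% interval is the
percentile interval (not BCa), matching common F_ST bootstrap practice.
Replicates whose resample has zero denominator are dropped and counted.
Significance = the interval excludes zero. With a single usable locus the
CI degenerates to the point estimate and is flagged. The default
replicate count is 100,000; analyses in the test suite use 500–10,000,
which is ample for a 95% percentile interval.

## Diversity

Per locus over a chosen set of individuals (both alleles each):
Watterson's θ_W = S/(a_n·L) with a_n = Σ_{i=1}^{n−1} 1/i, and π = mean
pairwise proportion of differing sites over all C(n,2) allele pairs.
Across-locus means are unweighted by default ("average over loci");
length-weighted means are an option.

## Distances and trees

The diploid distance between two individuals takes, per shared locus,
the mean of the four allele-pair Jukes–Cantor distances
d = −(3/4)ln(1 − 4p/3) (p ≥ 0.75 is a saturation error), then combines
loci by a cleaned-length-weighted mean; a pooled-site mode (mismatches
and sites summed across loci before correction) is available. Note that
averaging corrected distances is not the same as correcting the average
mismatch: for one mismatch in 200 sites shared across one heterozygous
pair the mean-of-four value is JC(1/200)/2 ≈ 0.0025084. Missing pairs
(no shared locus) fail loudly; there is no imputation.

Trees are built by Saitou–Nei neighbor joining (Studier–Keppler Q), with
ties in Q broken deterministically by the lexicographic order of each
cluster's smallest member label, followed by unweighted least-squares
re-estimation of all branch lengths on the fixed topology
(`numpy.linalg.lstsq` on the leaf-pair path incidence matrix; negative
estimates clamped to 0). On additive matrices this reproduces the
generating tree's path distances exactly, which is the property the test
oracle checks; it is a deterministic stand-in for a Fitch–Margoliash
global search and agrees with it on near-additive data. Midpoint rooting
places the root halfway along the longest leaf-to-leaf path, ties broken
by the sorted leaf-label pair; an all-zero-length tree is rooted at the
first internal node with a warning.

Haplotype genealogies collapse identical alleles at a locus into nodes
(frequency = allele copies, with per-group composition) connected by a
Kruskal minimum spanning tree over Hamming distances; equal-weight ties
are resolved by node-index (first-occurrence) order, so output is
deterministic.

## Synthetic data

The generator provides the structure the analysis assumes, not a fitted
demographic model of any real population.

**Coalescent mode.** Per locus, a Kingman coalescent on the 2n sampled
lineages: k lineages in a deme coalesce at rate k(k−1)/2, and with more
than one deme each lineage migrates at rate `migration_rate`/2 to a
uniformly chosen other deme, all in the same time units. Mutations occur
at θ_locus/2 per lineage per unit time (θ_locus = `theta_per_site` × L),
so E[S] = θ·a_n exactly — the identity the recovery tests use. Mutations
follow the infinite-sites model on a finite sequence: each hits a fresh
site (uniform, resampled on collision) and substitutes a different base;
recurrent hits are disallowed, which is accurate for short, low-θ
introns. With `migration_rate = 0` and several demes, demes coalesce
independently and share the ancestral sequence at their roots.

**Frequency (Balding–Nichols) mode.** An ancestral pool of K alleles
(default 2) gets frequencies p ~ Dirichlet(2,…); each population draws
frequencies ~ Dirichlet(p(1−F)/F) with F = `fst_target` (F = 0 uses p
exactly), and genotypes are drawn multinomially under within-population
Hardy–Weinberg. The closed-form true F_ST makes this the
parameter-recovery and null-coverage workhorse.

**Landmarks.** Every group shares one stylized 16-landmark mandible mean
shape (coronoid height 5.0 mm) unless per-group shapes are supplied;
configurations are the group mean × the group's isotropic size factor
(defaults 1.0 and 1.15, putting the two groups in the `fodiens` and
`niethammeri` bands) plus i.i.d. Gaussian landmark noise (default
0.03 mm), then randomly rotated and translated, and written with a TPS
scale (default 0.02 mm/unit) so physical sizes are recoverable. Size
factors only rescale, so by construction the groups differ in size but
not shape — the contrast the Procrustes/PCA tests verify.

**Degradation.** Sample ages are uniform on [0, 50] years. Each
(individual, locus) drops independently with probability
1 − (1 − rate)^(age/10) (default rate 0.1 per decade); a fraction of
landmark configurations (default 0.09) is reduced to landmarks 1 and 7;
individuals retaining fewer than 4 loci are flagged for exclusion.

All stochastic operations draw from a single generator seeded by
`SimConfig.seed`.

**What the generator does not emulate:** recombination within loci,
selection, indel variation (alignments are generated gap-free; cleaning
is exercised by separate fixtures), sequencing/phasing error, spatial
population structure beyond discrete demes, and allometry (size-correlated
shape change). Passing tests therefore demonstrate correctness of the
estimators and the pipeline plumbing under the stated models, not
robustness to those real-data complications.

## Problem sizes and test design

The acceptance checks use: a 149-point mismatch grid for the
Jukes–Cantor closed form; 2×10 diploids for the exact Weir–Cockerham
cases; 2 populations × 50 diploids × 100 biallelic loci for F = 0.10
recovery (tolerance ±0.02); 200 null datasets (2×20 diploids × 100 loci,
2,000 bootstrap replicates each) for CI coverage, with acceptance at the
binomial 3σ interval around 0.95 — 100 loci per dataset because the
percentile bootstrap over loci is asymptotic in the locus count and
measurably under-covers at much smaller panels; 1,000 coalescent
replicates (n = 10, θ = 5) for the E[S] identity (tolerance 5%); random
5–8 taxon additive matrices for tree reconstruction (1e-9); and a full
degraded three-group, six-intron pipeline run. The end-to-end
demonstrations use 12–15 diploids per group, comparable to the per-group
sample sizes such studies actually achieve.

## Known limitations

- The least-squares branch refit distributes the two root-adjacent edges
  of the internal representation arbitrarily along their sum; all
  leaf-to-leaf path lengths, which are what distance methods estimate,
  are unaffected.
- The haplotype network is a single MST, not a full median-joining
  network; reticulations that equal-weight alternatives would add are
  dropped deterministically.
- F_ST is implemented for pairwise comparisons (r = 2) as the analysis
  requires; hierarchical F-statistics and AMOVA are out of scope.
- Percentile bootstrap CIs over a small number of loci (e.g. 6) are
  honest about sampling variance across loci but should not be read as
  exact 95% intervals; the coverage study above quantifies this.
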