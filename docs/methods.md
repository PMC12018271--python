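# Methods

This note records the statistical model, conventions and defaults behind
`pairscreen`, the choices made where the design was genuinely open, and what
the simulation-based tests do and do not establish about real screens.

## Library design

Genes are tiered by prior evidence — tier 1: essential for growth in K562
cells; tier 2: significant in at least four prior CRISPRi screens; tier 3: the
rest — and the tier selects the guide-ranking statistic (growth phenotype,
mean hit phenotype, or the CRISPRi-v2.1 regression score). Per transcription
start site, genes with strong knockout phenotypes receive their top guide plus
a mismatched variant engineered for partial knockdown; the variant is chosen
with measured relative activity in 0.47 ± 0.15 (nearest 0.47), falling back to
predicted activity nearest 0.5, always requiring on-target specificity ≥ 0.15.
All other genes receive their top two guides. If a strong-phenotype gene has
no admissible variant, the package falls back to its top two perfect guides
and warns — the alternative (dropping the gene) would silently shrink the
queried pair universe.

Pairing: each unordered gene pair is realized in exactly one orientation,
drawn from a seeded RNG over lexicographically sorted gene pairs so designs
are byte-reproducible; within the chosen orientation all guide cross-products
are emitted. Same-gene guide pairs are realized once, in guide_id-sorted
orientation (the orientation of same-gene pairs carries no information in the
model, so a canonical choice maximizes determinism). Every targeting guide is
paired with all 15 NT guides in both orientations (30 elements), and all
15 × 15 ordered NT combinations (225, self-pairs included) serve as the
negative-control and normalization anchor set. Synthesis oligos are
`upstream + protospacer_a + linker + protospacer_b + downstream` (148 nt), and
splitting an oligo on the three constant regions recovers both protospacers
exactly.

## Counting

A read pair reports one construct: read 1 carries the position-a protospacer,
read 2 the position-b protospacer. Matching is exact (Hamming distance 0) for
20-mers starting at offsets 0–2, i.e. anywhere within the first 22 bp
(half-open window [0, 22)). A read matching two different guides at different
offsets is discarded as ambiguous — the conservative choice; the simulator's
rejection-sampled fillers make this a real-data-only event. Read 2 is matched
against the stored position-b protospacer by default (the simulator writes
both mates protospacer-forward); `rc_read2` reverse-complements read 2 first
for chemistries that sequence the cassette's bottom strand. Per sample the
assignment log preserves `assigned + unassigned = total`.

## Normalization and LFC

Size factors use the median-of-ratios scheme over the NT×NT reference set
(the purest null constructs; a switch widens the reference to any NT-containing
element): per reference element, the geometric mean across samples forms a
pseudo-reference, and a sample's factor is the median ratio to it, computed
over elements with strictly positive counts everywhere. Factors are
accordingly *relative* (≈1), keeping normalized counts on the raw count scale
— that is what gives the fixed pseudo-count of 10 its meaning. The
consequence, stated openly: LFCs of low-count elements are not invariant to a
global rescaling of all samples, because the pseudo-count deliberately shrinks
them depth-dependently. No factor convention can be simultaneously ≈1 on the
count scale and proportional to absolute depth; we chose the count-scale
convention because the pseudo-count's stabilizing role depends on it.

Elements need ≥ 50 raw T0 reads in *every* replicate (filter is idempotent);
per replicate, `LFC = log2((n_T14 + 10) / (n_T0 + 10))` with `n = count /
factor`, normalization applied exactly once. T14 zeros are retained — the
pseudo-count bounds their LFC; no T14 filter is applied since depletion is the
signal. A guide is called essential when its mean LFC over all NT-partner
elements and replicates is strictly below −3 (a mean of exactly −3.0 is not
essential). For every essential *perfect* guide with a mismatched variant in
the library, all of its elements are dropped and the variant carries the gene
from then on; essential guides without variants are kept with a warning, since
dropping them would remove the gene entirely.

## Interaction model

Parameters: per-guide efficacy `x ∈ [0, 1]` (NT guides fixed at 0), per-gene
effect `y` (log2 depletion at full knockdown over the screen), per-gene-pair
interaction `s`. Predictions per construct class are given in the README. Pair
efficacy is the product `x_a x_b`; same-gene guides combine as a probabilistic
union — both reduce correctly at `x ∈ {0, 1}` and stay bounded. Identifiability
is fixed by rescaling each gene after every sweep so its strongest guide has
`x = 1` (with `y` and `s` rescaled inversely); replicates enter as independent
observations of the same construct mean.

The objective is `Σ (LFC − mu)² + ridge(‖y‖² + ‖s‖²)` with ridge 1e-3 —
enough to pin empty levels at 0 without visible shrinkage (relative bias
< 1e-3 at two guides per gene and two replicates). Optimization alternates an
exact ridge solve for `y` (genes couple through inter-gene elements; the
normal equations are assembled sparsely), independent exact updates for each
`s`, clamped Gauss–Seidel coordinate updates for `x` (the prediction is linear
in each single `x`), then the anchor rescaling; convergence is declared when
the largest parameter change falls below `tol` (1e-4). Every step is
deterministic; `seed` is recorded for provenance and only matters if
stochastic restarts are ever enabled. On instances small enough to
cross-check, the alternating fit matches a generic bound-constrained
minimizer of the identical objective (trying every per-gene anchor
assignment) to 1e-2.

Scoring: with `T = y_g + y_h + s`, the sensitive deviation is
`T − λ(y_g + y_h)` (λ = 1 by default, where it reduces to `s`) and the strong
deviation is `T − min(y_g, y_h)` — how much worse the double knockdown is
than its *stronger* single. Non-negative deviations (pairs no worse than
expected) are clipped to 0 and scores are reported ≤ 0; more negative means
stronger synthetic lethality, flagged at sensitive ≤ −1.

## Downstream

Synthetic-lethal calls are pairs at or below the cutoff, sorted strongest
first. Networks carry |sensitive score| as edge weight and user-supplied
cancer-gene / drug-target sets as node flags (external catalogues are inputs,
never bundled); an edge is "actionable" when one endpoint is a cancer gene
and the other a drug target. For profile clustering, genes are retained when
some pair deviates from the mean of all non-zero sensitive scores by ≥ 2 s.d.
— implemented two-sided on |score − m| with a one-sided switch; with all
scores ≤ 0 the low tail carries the signal, so the two agree in practice.
Unqueried pairs enter the symmetric matrix as 0, indistinguishable from
measured non-interactors by the clipping convention. Ward linkage on the
retained rows is cut at a user-set k (default 20; the data do not determine k
and the dendrogram is returned for other cuts). The 2-D embedding runs on the
symmetric strong-score matrix without prior dimension reduction; the backend
is pluggable and defaults to UMAP with a fixed random state (hyperparameters
are configuration, not contract). Cross-line comparisons threshold each line
at its own cutoff (screens differ in dynamic range — e.g. −1 for K562-like,
−0.5 for HeLa-like data), over the intersection of pair universes, reporting
the full Venn partition and fractions of the reference line's calls. The
additive expectation for validation assays is the sum of the two single log2
fold changes.

## Simulation

The generator emulates the screen the analysis assumes: a library built by the
design module over synthetic genes; 18% essential genes (y ~ U[−5, −3]) each
carrying a full-efficacy guide plus a mismatched variant with activity drawn
from the U[0.3, 0.7] selection window, other genes with two perfect guides
(x ~ U[0.7, 1], anchored per gene); neutral effects y ~ N(0, 0.3); 10% of gene
pairs interacting with s ~ U[−3, −1]; lognormal T0 abundances (s.d. 0.5 in log
space) around 500 reads per element; exponential growth over 10 population
doublings with T14 renormalized to the T0 sequencing depth; Poisson counts
(a negative-binomial dispersion knob exists, off by default — depth-dominated
counting is the regime of interest and no overdispersion model is specified
for these data); and FASTQ read pairs whose first 22 bp contain the
protospacers, with substitution errors at 1e-3 per base. Truth phenotypes are
parameterized directly on the endpoint LFC scale (per-doubling rate φ/10), so
fitted and true parameters compare without unit conversion. Everything is
deterministic given the config seed, down to FASTQ bytes.

What the simulations do *not* emulate: lentiviral infection statistics and
MOI, guide-level off-target effects, chromatin-dependent CRISPRi efficacy,
copy-number artefacts, replicate batch effects, and PCR jackpotting. Passing
recovery tests therefore demonstrates correctness of the computation under
the stated statistical assumptions, not performance on any particular real
dataset.

## Known limitations

* After mismatch-variant substitution, an essential gene is represented by a
  single guide, so its efficacy is unidentifiable and the anchor sets it to 1:
  fitted `y` and `s` for such genes absorb the variant's true activity
  (`s_fit ≈ x_mm · s_true`). This mirrors the real pipeline's behaviour and
  systematically attenuates interaction estimates for essential genes — on
  default simulations, interacting pairs without essential genes recover at
  r ≈ 0.99 while pairs with one essential gene recover at r ≈ 0.7 with slope
  ≈ 0.5. Calibrating scores by the design-time variant activity would remove
  the attenuation but is deliberately out of scope of the point-estimate fit.
* The count-scale size-factor convention trades global depth invariance of
  low-count LFCs for a meaningful pseudo-count (see Normalization).
* The fit is a penalized least-squares point estimate; no posterior
  uncertainty is produced, and multi-condition (drug-modifier) designs are out
  of scope.
* Problem sizes in tests and the acceptance script (60-gene screens, 20-gene
  FASTQ round-trips, a single full-size 548-gene design) were chosen to
  exercise every code path at meaningful scale while keeping the default runs
  reproducible on a laptop; all operations scale linearly in elements except
  the `y` solve (cubic in genes, trivial up to a few thousand).
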