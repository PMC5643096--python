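# Methods

## Model

The unit of analysis is a genetic element (protein-coding gene, conserved
non-coding element, or enhancer) with a branch-length tree estimated
externally on a fixed rooted binary species topology of S taxa (the
*master tree*; estimation of branch lengths from alignments is outside
this package's scope). Branches are identified by the taxon set of their
child clade, giving 2S−2 non-root branches whose identity is stable under
pruning; an element missing taxa contributes, for each branch of its
pruned tree, the *path* of master branches that branch spans, and the
observed path total is attributed to the deepest member branch of the
path. Elements whose induced topology contradicts the master are rejected
rather than reconciled, because the topology is fixed a priori.

### Expected divergence (average tree)

The expectation for branch *b* is estimated in two passes over the rate
matrix: pass 1 averages raw lengths over elements that observe *b* as an
un-merged single branch; pass 2 rescales every element by its projection
coefficient s_g = (g·A⁰)/(A⁰·A⁰) onto the pass-1 averages before
re-averaging, repeating to a fixed point (relative change < 10⁻⁶, at most
10 iterations). The rescaling keeps fast- or slow-evolving elements from
dominating the expectation; on data generated exactly as s_g·A the
procedure recovers A up to a global scalar.

### Relative evolutionary rates

With g the element's observed vector and A its expectation vector over
present branch-paths, β = (g·A)/(A·A) and RER = g − βA. The residual is
orthogonal to A by construction, so RER = 0 on a branch means the element
diverged there exactly as much as its overall rate predicts. Optional
standardizations are exposed: `scale="element"` divides each element's
residuals by their within-element SD; `scale="branch"` z-scores each
branch across elements. The default is unscaled (which is what the
orthogonality invariant refers to). Note an unscaled residual's spread
grows with the branch's expected divergence — pooled cross-branch
comparisons of raw RERs mix scales, which is why the per-branch
standardization exists (see Limitations).

### Scan statistic

Foreground membership defaults to the terminal branches of the foreground
species; when the foreground lineages are phylogenetically independent no
internal branch is exclusively foreground, and a
`terminal+internal` policy covers the other case. Per element, the
Mann-Whitney U statistic (ties counted ½) compares foreground to
background RERs; auc = U/(n_fg·n_bg) ∈ [0,1] is the common-language
effect size, the direction rule of the published analysis ("correlation
≥ 0.5" reads as auc ≥ 0.5). For tie-free splits with n_fg·n_bg ≤ 400 the
p-value is exact, from the full combinatorial null of U computed by the
classic count recurrence; otherwise a normal approximation with tie and
continuity corrections is used. Both the two-sided p and the one-sided
acceleration p are reported; ranking and precision–recall use the
one-sided p, matching the directional use of "acceleration p-value" in
this kind of analysis.

### Permutation q-values

Each of n_perm null datasets (default 10,000; analyses here use 500 where
noted) draws one pseudo-foreground species set, uniformly without
replacement from the taxa observed in the matrix, applied to all elements
— preserving cross-element dependence. Set-level collisions across
datasets are tolerated (with C(39,4) ≈ 8×10⁴ they are negligible). For
direction d, q(p) = [mean null discoveries with direction d at p] /
[observed discoveries with direction d at p], monotonized by a running
minimum from the largest p downward and capped at 1. A per-element
permutation mode (independent pseudo-foreground per element) is available
behind `permute="element"`. Calls: accelerated if auc ≥ 0.5 and
q_accel ≤ FDR (default 0.15); decelerated if auc < 0.5 and q_decel ≤ FDR.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| min_species | 10 | minimum taxa per element tree |
| min_foreground | 2 | minimum foreground taxa per element |
| zero_fraction | 0.80 | reject when ≥ 80% of terminal branches are zero |
| n_perm | 10,000 | null datasets for the empirical FDR |
| fdr | 0.15 | q-value call threshold |
| direction_threshold | 0.5 | minimum auc for an accelerated call |
| alpha (tissue sets) | 0.05 | Welch t-test level |
| k (panels) | 200 | elements per gene panel |

Filter defaults and thresholds mirror the published analysis settings.

## Synthetic data

The generator emulates the statistical structure of externally estimated
tree batches: a random rooted binary topology (default 39 taxa) with
exponential branch lengths (mean 0.05 substitutions/site, or
user-supplied), four pairwise non-sister foreground taxa (independent
lineages), per-element rate scalars s_g ~ lognormal(0, 0.5), unit-mean
multiplicative lognormal branch noise (sdlog 0.3), a planted foreground
rate multiplier λ (default 3) on a fraction π (default 0.10) of elements,
per-element taxon dropout (10%, never below min_species) and 1%
zero-length branches. Everything is reproducible from a single seed.

What it does *not* emulate: phylogenetic correlation of rates along the
tree, alignment- and estimation-induced error structure (PAML branch
lengths are not independent across branches), gene-tree/species-tree
discordance, and selection heterogeneity within elements. Passing
recovery tests on this generator therefore shows the statistical
machinery is correct and calibrated under the stated noise model, not
that real alignments would yield the published gene lists.

### Expression generator

Genes have standard-normal baselines; planted tissue-specific genes add
an effect of 8 noise-SD in their tissue's replicates (3 per tissue).
Tissue sets take genes significantly elevated (Welch t-test, two-sided
p < α with higher mean — the directional filter makes "differential"
mean *expressed in* the tissue) in exactly one tissue of interest; sets
are disjoint by construction. The exclusivity rule is enforced over the
supplied tissues of interest, not all tissues, and is configurable.

## Numerical choices

- Exact Mann-Whitney null distributions are cached per (n_fg, n_bg); the
  two-sided p is 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
- Completely tied elements get p = 1, auc = 0.5, label "neither".
- Rank-histogram and precision–recall ties are broken by element id.
- Panel distance ties are broken by the smaller start coordinate; an
  element within k-nearest of several genes is assigned to the closest
  gene only, keeping hypergeometric margins disjoint.
- Genomic intervals are 0-based half-open; gene center is
  floor((start+end)/2); strand is ignored for distances.
- Hypergeometric tails come from scipy's log-space implementation and are
  tested against exhaustive enumeration.
- Output TSV/JSON writers use fixed float formats and sorted keys so
  identical configs and seeds reproduce outputs byte-for-byte.

## Design choices where the design was open

- Cross-element comparability for unequal taxon sets uses child-clade
  branch identity and path sums; the residual of a merged path is carried
  by its deepest member branch so per-species columns stay meaningful for
  species profiles.
- The zero-length filter counts terminal branches ("species present in
  the tree").
- Null permutations are per-dataset (one pseudo-foreground for all
  elements); the per-element variant is exposed but breaks cross-element
  dependence.
- Two-sided p with the direction split applied afterwards, since a single
  analysis reports both accelerated and decelerated calls.

## Known limitations

- Raw RER spread scales with a branch's expected divergence, so the
  foreground/background RER distributions coincide under the null only
  after accounting for branch scale (pooled-KS checks in the tests use
  equal master branch lengths to isolate exchangeability). Per-dataset
  calibration of the scan consequently varies with the particular
  foreground branch lengths drawn; the permutation null absorbs this on
  average, and multi-seed summaries are the stable quantities.
- The empirical q-value needs enough permutations to resolve small
  q's; n_perm < 100 triggers a warning.
- No heteroskedasticity-weighted RER variant is implemented, and branch
  lengths are consumed as given (no re-estimation).
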