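# Methods

This note records the models implemented in `integromod`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical and design decisions made where the
problem left room.

## Node weights

**GWAS arm.** Gene-level association p-values are converted to
z-scores by the inverse normal transform `z = Φ⁻¹(1 − p)`, with `p`
clamped below at 1e−300 so extreme associations stay finite. When only
SNP-level summary statistics are available, genes receive the
Šidák-corrected minimum SNP p-value over a strand-aware window of
35 kb on the 5′ side and 10 kb on the 3′ side of the gene body
(1-based inclusive): with `k` SNPs in the window,
`p_gene = 1 − (1 − min p)^k`. This windowed aggregator is a simple,
LD-free stand-in for a dedicated gene-based test; since the pipeline
accepts externally computed gene p-values directly, it is fully
bypassable. Genes overlapping the MHC region (chr6:25,000,000–
33,500,000, any overlap of the gene interval) have their GWAS scores
removed *before* any cross-omics scaling is estimated, so the region's
extreme LD never influences the variance matching.

**Methylation arm.** Beta values are clamped to [1e−6, 1−1e−6] and
logit-transformed to M-values, `M = log2(β/(1−β))`, whose
homoscedasticity makes them the standard scale for differential
testing. Each probe gets a Welch two-sample t-test (case vs control);
a pooled-variance flag is available. We use the plain t rather than an
empirical-Bayes moderated t: at the sample sizes the pipeline targets
(≥10 per group) the two are very close, and the plain test is exactly
calibrated in the package's own null simulations (rejection rate
5.1 % at α = 0.05 over 2100 null probes). Probe p-values become signed
z-scores `z = sign(Δ M) · Φ⁻¹(1 − p/2)` — positive for
hypermethylation in cases — and probes in the TSS1500 promoter window
(from 1500 bp upstream of the transcription start site to the TSS,
strand-aware: the TSS is the annotation start on `+` genes and the end
on `−` genes) are aggregated per gene by Stouffer's method,
`z_gene = Σ zᵢ / √n`.

**Fusion.** The two arms are put on a common scale by
`s = sd(z_gwas) / sd(|z_meth|)` over the genes carrying both sources,
then combined per gene by a two-source Stouffer step,
`w = (z_gwas + s·|z_meth|)/√2`, so fused weights remain approximately
z-scaled. The *magnitude* of the methylation z enters the weight —
both hypo- and hypermethylation count as disease evidence, and a
signed sum would let them cancel — while the sign is retained in the
output table for direction-of-effect reporting. A
`signed_methylation` option restores the signed combination.
Single-source genes carry their (scaled) single score. Because the
folded methylation term has positive mean, fused weights have a known
positive location offset `s·√(2/π)/√2` under a global null; this is
asserted in the tests rather than removed, since module normalisation
is permutation-based and location-invariant.

## Edge weights

For every PPI edge whose endpoints are both measured, Pearson
correlations are computed separately in cases and controls and
compared by the classical Fisher test for two correlations:

    z_edge = |atanh(r₁) − atanh(r₂)| / sqrt(1/(n₁−3) + 1/(n₂−3)).

The absolute value makes the weight a magnitude, as the search only
cares how strongly co-expression *changes*. Edges exceeding 1.96 are
flagged nominally significant; by default all weights enter the
search (a significant-only filter is available), since thresholding
before the search discards graded evidence. A gene constant within a
group gets r = 0 for that group (logged) instead of dropping the edge,
keeping the searchable network aligned with the node-weighted one.

## Dense module search

Every weighted gene seeds one module. At each step the candidate set
is all non-member weighted genes within shortest-path distance
`d` (default 2) of *any* current member; the candidate maximising the
recomputed score is accepted iff the new score exceeds
`current × (1 + r)` (default r = 0.1). Ties between equal-scoring
candidates break lexicographically on gene id, making the search fully
deterministic. Scores are

    node mode:          Z_m = Σ zᵢ / √k
    edge-weighted mode: Z_m = (Σ zᵢ + λ Σ w_e) / sqrt(k + λ² m)

over the k member genes and the m induced edges, with
`λ = Var(node weights)/Var(edge weights)` computed from the full
tables unless supplied. These composites are the standard DMS-lineage
score forms, reconstructed here from that convention. In
edge-weighted mode the search graph is restricted to edges that carry
a weight (both endpoints measured), so induced edge sums are always
defined. A distance-2 recruitment can make the induced subgraph
transiently disconnected; final reporting always uses the
PPI-induced edges of the member set.

The greedy trajectory is verified against an independently coded naive
implementation (full BFS and from-scratch re-scoring at every step) on
hundreds of small random graphs in both modes; agreement is exact.

**A consequence of the r-rule worth knowing.** Each accepted step must
improve the score by more than 10 %. With member evidence around
z ≈ 3 the threshold gene at size k = 5 already needs z ≳ 3.1, so
modules stop near 5–6 genes regardless of how large the true module
is. Planted modules bigger than that are recovered across the merged
top modules rather than inside any single module (the worked example
in the README shows an 8-gene plant fully recovered by the top-10 %
selection while the single top module holds 3 of 8).

## Permutation normalisation

Two permutation schemes are provided.

*Fixed-set re-scoring* (default): node weights (and edge weights) are
shuffled uniformly and each module's fixed gene set — and fixed
induced edge set — is re-scored; `z_n = (z_m − mean_perm)/sd_perm`
over `n_perm` (default 1000) shuffles. This conditions on the module's
topology and is cheap, but because the observed `z_m` was *maximised*
by the greedy search while the permuted scores are not, `z_n` is not
calibrated against 1.96 under a global null; it is a ranking
statistic, which is how the selection stage uses it. Modules whose
permuted scores have (numerically) zero spread are flagged degenerate.

*Permuted re-search* (`permutation_normalize_research`): each
permutation re-runs the greedy search from a random subset of seeds
under the shuffled weights, and all modules are standardised against
the pooled null of re-searched scores. Both observed and null scores
are then greedy-maximised, so the scheme is calibrated: pooled over
five independent null datasets the fraction of modules with
z_n > 1.96 is ≈ 4 %. Within a single dataset the rate is volatile
(0.7–12 % measured) because all modules share one weight assignment —
module scores are strongly correlated — so calibration statements
should always pool datasets.

Permutation results are invariant to gene relabeling, and the RNG is
seeded, so runs are exactly reproducible.

## Module selection

Modules are deduplicated (identical gene sets collapse, best `z_n`
kept), ranked by `z_n`, and the top `ceil(fraction × n)` (default
10 %) are merged: node set = union of member genes, edge set =
PPI-induced. Scale-freeness of merged subnetworks is measured by
ordinary least squares of `log p_k` on `log k` over degrees with
nonzero count (no logarithmic binning; degree-0 nodes excluded since
log p is undefined); R² is the index and `γ̂ = −slope`. At least three
distinct degrees are required — any two-point fit is trivially R² = 1
— otherwise the value is recorded absent. The fraction is the
selection rule; the achieved R² (≈ 0.8 on realistic inputs) is
reported as a diagnostic, not enforced. On 2000-node
preferential-attachment graphs the fit gives R² ≈ 0.81–0.89 and
cleanly separates them from density-matched Erdős–Rényi graphs; at a
few hundred nodes the unbinned tail makes R² noisy, which is why the
diagnostics use the larger size.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ overlap) with Benjamini–Hochberg adjustment across all tested
sets (step-up with monotonicity repair, delegated to statsmodels and
cross-checked against a hand-coded textbook implementation in the
tests). The default universe is the *tested* gene space — the genes
carrying node weights — not the whole genome, the standard background
correction for ORA; gene sets are intersected with the universe before
testing. GO-style collections filter at q < 0.1, disease- and
drug-target-style at raw p < 0.05; both mode and threshold are
configurable.

## Mendelian randomization

Instruments are assumed independent (pre-clumped) and pre-harmonized.

* **IVW** (primary): `θ̂ = Σ(βX βY/seY²)/Σ(βX²/seY²)`,
  `se = 1/√(Σ βX²/seY²)`. The fixed-effect form is the default for its
  clean closed form; a multiplicative random-effects option inflates
  the se by `√(max(1, Q/(n−1)))`.
* **MR-Egger**: weighted least squares of βY on βX with a free
  intercept (weights 1/seY², exposures oriented positive); the slope
  is the causal estimate and the intercept a directional-pleiotropy
  test.
* **Weighted median**: per-SNP ratio estimates ordered, weights
  ∝ βX²/seY², estimate interpolated at cumulative weight 0.5;
  standard error from a seeded parametric bootstrap (default 1000
  draws). Consistent while valid instruments carry more than half the
  weight.

Null simulations confirm ≈ 5 % type-I error for IVW at α = 0.05, and
all three estimators are unbiased within ±0.02 at 50 instruments
without pleiotropy.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised:

* **PPI**: Barabási–Albert preferential attachment (default m = 3),
  giving the approximately power-law degree structure of real
  interactomes; nodes `G0001…`.
* **Planted module**: seeded random BFS from a random start node, so
  the plant is always connected (default size 8).
* **GWAS**: planted genes z ~ N(3, 1), background z ~ N(0, 1),
  p = 1 − Φ(z) — background p-values are exactly uniform.
* **Methylation**: default 13 cases / 15 controls (a realistic small
  tissue study), 3 probes per gene at 200/700/1200 bp upstream of the
  TSS, control M ~ N(0, 0.5²), planted case probes shifted by the
  logit offset matching Δβ = 0.2 at β = 0.5.
* **Expression**: default 50/50 samples; per group a target
  correlation matrix with ρ on planted edges (0.8 cases, 0.0 controls)
  is repaired to positive semi-definite by eigenvalue clipping (the
  simplest auditable repair) and rescaled to unit diagonal. With many
  planted edges the repair can attenuate planted correlations
  noticeably (a warning is logged beyond 0.1), so realised edge
  correlations should be read from the data, not the nominal ρ.
* **MR**: βX ~ N(0.15, 0.05²) clamped positive, seX = 0.01,
  seY = 0.02, βY = θ·βX + α + ε with pleiotropy α ~ N(0, σ²).

One global seed drives everything; each generator derives its own
stream from a CRC32 hash of its stage name, so stages are
independently reproducible. What the generators do *not* emulate:
linkage disequilibrium, genome-scale SNP panels, batch effects,
cell-type composition of methylation, probe cross-reactivity, or
library-size structure of counts — passing tests therefore demonstrate
algorithmic correctness and statistical calibration under clean
conditions, not robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

Correlations are clamped to ±0.999999 before atanh; probabilities to
[1e−300, 1−1e−16]; betas to [1e−6, 1−1e−6]. Zero-variance probes give
p = 1, z = 0; constant expression gives r = 0 with a warning;
zero-variance weight collections make λ and the fusion factor errors
rather than silent defaults. Matrix rows with more than 20 % missing
values are dropped, the rest imputed by row median. All outputs are
sorted on canonical keys so byte-identical reruns are guaranteed under
a fixed seed.

## Known limitations

* The windowed min-p gene aggregator ignores LD; with dense SNP panels
  it is conservative for large genes. Supply gene-level p-values from
  a dedicated method when available.
* The fixed-set permutation z_n is a ranking score, not a calibrated
  significance test (see above); use the re-search scheme when
  calibrated nulls are needed, and expect dataset-level volatility.
* Greedy growth under the r-rule caps module size; large true modules
  surface through the merged selection, not single modules.
* Identifier handling is exact-string uppercase symbols; no alias
  resolution or liftover.
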