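# Methods

## Model and assumptions

The unit of analysis is a fixed-width genomic bin. For cell `i`, bin `j`,
the observed read count is assumed proportional to the total copy number
`c'_ij + c''_ij`, and the B-allele frequency (BAF) estimates the allelic
fraction `c'/(c'+c'')`. Two derived features are used everywhere:

* `RDR_ij = X_ij / mean_j(X_ij)`, the bias-normalized count scaled to a
  per-cell mean of 1, so a state with total `T` in a cell of ploidy `p`
  (ploidy = genome-wide mean total copy number) has expected RDR `T / p`;
* `mBAF_ij = min(Y_ij, 1 - Y_ij) ∈ [0, 0.5]`, which removes the arbitrary
  labelling of homologous chromosomes; a state `{c_minor, c_major}` has
  expected mBAF `c_minor / T` (defined as 0.5 for `T = 0`, so nullisomic
  bins carry no imbalance signal).

All bins of all cells that share a latent allele-specific state are assumed
to follow one 2D Gaussian in `(RDR, mBAF)`; cells are assumed to be
sequenced under comparable conditions so the component covariances are
shared across cells. Masked bins (GC outside `(0.2, 0.8)`, mappability
below 0.9, strict inequalities) are excluded — never imputed — from every
mean, fit and likelihood. Coordinates are 0-based half-open; a breakpoint
is the 0-based index of the *left* bin of an adjacent pair whose state
differs, and this single convention is used by the mixture candidates, CBS,
the ensemble, the simulator truth and the evaluation metrics alike.

## Pipeline parameters

| parameter | default | role |
|---|---|---|
| `gc_low/gc_high/map_min` | 0.2 / 0.8 / 0.9 | bin masking thresholds (fractions) |
| `gini_threshold` | 0.02 (pipeline), 0.12 (function) | cells at or below are treated as normal |
| `k_min/k_max` | 8 / 25 | BIC search range for the mixture size |
| `n_restarts` | 5 | EM restarts per K (seeded) |
| `merge_delta` | 0.1 | weighted mean-distance below which components merge |
| `baf_weight` | 0.5 | mBAF down-weighting inside the merge distance |
| `cbs_alpha` | 0.05 | permutation p-value threshold per split |
| `cbs_n_perm` | 1000 | permutations per split test |
| `cbs_min_width` | 2 bins | smallest arc/complement considered |
| `min_cells` (`t`) | 5 | cross-cell frequency needed by a candidate breakpoint |
| `max_total` | 10 | state space bound (36 states) |
| `max_wgd` | 2 | WGD counts enumerated for candidate ploidies |
| `balanced_tol` | 0.05 | `|mBAF - 0.5|` tolerance for the balanced anchor |
| `tolerance_l` | 1 bin | breakpoint matching tolerance in evaluation |

The Gini convention of 0.12 separates flat from aneuploid profiles in
read-derived counts, whose technical noise inflates every cell's Gini; the
direct simulator produces much cleaner counts (normal cells sit at Gini ~0
noiseless and ~0.06 at 10% bin noise, tetraploid tumors at ~0.05–0.12
because a genome that is flat-relative-to-four is relatively even), so the
pipeline default is 0.02. When no cell passes, normalization falls back to
a LOWESS fit of the median count ratio on GC with a mappability divisor —
with the simulator's bias-free counts this returns factors ≈ 1, which is
the correct answer there.

## Ploidy selection details

Candidate ploidies are anchored per cell: components are weighted by the
share of the cell's bins they carry, the densest component with mean mBAF
within `balanced_tol` of 0.5 is the anchor, and its RDR is measured as the
median of the cell's own bins pooled over all balanced components within
0.1 RDR of the anchor (overlapping components each hold a slice of the
same cluster; pooling de-biases the median, and the cell's own bins rather
than the pooled component mean keep the scale from being dragged by other
clones). Candidates are `{T_0 · 2^w / r}` where the base total `T_0` is 2
for a balanced anchor; if the cell has no balanced component (a pure
triploid genome, say), `T_0` becomes the smallest total whose allelic
ratio matches the anchor's mBAF, so the anchor still pins a known total.

Each candidate is scored with `phi(p)·ln(m)·|Ω| − 2 L(p)`. `phi` is the
rounding sum-of-squares of `p · RDR`, computed on *segment means* weighted
by segment size (segments of fewer than 3 bins are left out): per-bin
rounding errors saturate at realistic noise levels and degrade `phi` into
a noise meter, while segment means keep the integer-grid signal. `L`
re-optimizes the per-component states for every candidate. Ties go to the
smaller ploidy. After selection, the scale is refined once within the
winning WGD basin by weighted least squares of called segment totals on
segment RDRs, and states are re-optimized at the refined scale; at zero
noise this reproduces the candidate exactly.

Two bias corrections matter at realistic noise:

* **mBAF folding.** Mirrored BAF is a folded quantity: Gaussian BAF noise
  of scale σ reflects at 0 and 0.5, so truly balanced bins average
  `0.5 − σ√(2/π)` and LOH bins `σ√(2/π)`. State likelihoods therefore use
  the *expected folded* mBAF (folded-normal mean excess at each boundary),
  with σ estimated per cell from the median deficit of its balanced bins
  below 0.5. Without this, high-total states with ratios just under 0.5
  (e.g. `{4,5}`) systematically outscore the balanced state and push cells
  toward spurious WGD calls.
* **Known ploidy.** When ploidies are supplied (e.g. FACS), candidate
  generation, selection and refinement are bypassed and states are called
  at the given scale.

## Numerical choices

* EM: restart 0 uses deterministic maximin (k-center) seeding — on
  (near-)noiseless data this covers every well-separated cluster, including
  tiny single-bin states, before spending capacity on near-duplicates —
  the other restarts use seeded k-means++; all are refined by a few Lloyd
  iterations with farthest-point re-seeding of empty clusters, and weights
  and covariances are initialized from the hard partition (an M-step from
  hard labels). Covariances carry a ridge of 1e-6 on the diagonal; empty
  components keep a vanishing weight rather than being re-seeded, which
  preserves the monotone likelihood trace. Convergence: relative
  log-likelihood change below 1e-6, at most 150 iterations. BIC counts
  `6K − 1` free parameters.
* CBS: with pooled-variance t and a fixed multiset of values,
  `t² = (n−2)·g·w² / (SStot − g·w²)` with `w` the mean-centred arc sum and
  `g = 1/n₁ + 1/n₂`; `SStot` is permutation-invariant, so permutations are
  compared on `g·w²` directly. The permutation loop rejects a split early
  once its p-value can no longer fall below α (decisions identical to the
  full test), and exceedance is strict: permutations that merely tie the
  observed maximum — measure zero for continuous data, routine in small
  integer examples — do not count against the split. Each subsegment's
  permutation stream derives from `(seed, lo, hi)`, so results are
  independent of the recursion path and monotone in α.
* Ties: equidistant segment-to-component assignment resolves to the
  higher-weight then lower-index component; exact state-likelihood ties
  resolve to the smaller (total, minor) state via enumeration order.
* Merging iterates the closest pair to a fixed point; the merged component
  takes the weight sum, weight-proportional mean and moment-matched
  covariance; bins are re-assigned by posterior under the merged model.
* The single global seed fans out per stage (simulation, mixture restarts,
  CBS permutations) through a seed sequence, so every stage is
  independently reproducible.

## The simulator

`synthetic_data` emulates direct-simulation datasets: a random clone tree
whose founder carries the ploidy mode (WGD for tetraploid, a genome-wide
extra copy for triploid, large hemizygous deletions totalling ~20–50% per
chromosome for hypodiploid), per-branch CNA events (default 4 per clone,
4–20 bins long, gains/losses of 1–2 copies on one haplotype, floored at 0
and capped at 4 copies per allele so states stay inside the default state
space), an exact `round(n · normal_fraction)` normal diploid cells, and
round-robin assignment of tumor cells to clones. Defaults keep clone
ploidies near their nominal mode, as ploidy-labelled dataset classes
imply. Read counts are Poisson around `coverage_scale · total / 2`
(default 1000 reads for a copy-neutral bin) with multiplicative Gaussian
jitter of sd `rdr_noise_sd`; BAFs are the true allelic fraction with
reflected Gaussian noise (`baf_noise_sd`) and random allele mirroring. At
`rdr_noise_sd = 0` counts are the rounded expectation, so the zero-noise
limit is fully deterministic and end-to-end recovery can be tested for
exactness.

What the simulator does **not** model: GC/mappability count bias (the
fallback normalization is therefore exercised only for correctness, not
realism), overdispersed counts, BAF errors from sparse heterozygous SNP
coverage or phasing mistakes, sub-bin CNA boundaries, and doublets. Tests
passing on these simulations show the algorithmic machinery is correct and
the noiseless limit exact; they do not certify accuracy on real
read-derived data.

## Known limitations

* **WGD aliasing.** Doubling every state preserves all expected RDRs and
  allelic ratios exactly, and halving does so for even-total states.
  Ploidy identification therefore rests on odd-total/imbalanced states,
  the integer-grid score and parsimony. At ~10% per-bin RDR noise these
  signals are marginal: clones dominated by even totals can be halved, and
  cells whose components straddle states can be doubled, whole clones at a
  time. The acceptance script computes the attained rates per condition;
  the noiseless and low-noise limits recover ploidy exactly.
* **Mixture identifiability.** At 10% bin noise, adjacent tetraploid
  states are ~2σ apart in RDR and the normal cells' balanced cluster sits
  between tumor clusters; BIC then prefers few broad components, and
  per-component state calls miscall the minority bins of a straddling
  component. Segment-mean information recovers much of this but not all.
* **Per-bin candidate breakpoints chatter.** With per-bin misassignment
  probabilities of ~0.2 at high noise, the cross-cell frequency filter
  passes spurious breakpoints at any usable `t`; CBS-based rescue keeps
  recall high but precision degrades, which is visible in the noisy
  breakpoint F1.
* Haplotype-specific (phased) copy numbers and lineage-aware breakpoint
  filtering are out of scope.
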