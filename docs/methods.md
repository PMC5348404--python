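# Methods

This note documents the statistical procedures, the synthetic-data
generators, and the numerical/design choices behind them. Everything stated
here is computed by the test suite or the analysis drivers; nothing is an
external empirical claim.

## Stage-stratified expression statistics

**Model.** Expression values are RPKM-like non-negative reals, analyzed on
the log₂(x + 1) scale (the pseudocount of 1 handles zeros; it is
configurable, as is skipping the transform). For one gene within one group,
a one-way layout across stage levels (normal, I–IV by default) gives the
classical F = (SSB/df_b)/(SSW/df_w). Degenerate input — every value
identical, so F is 0/0 — raises an explicit error; zero within-group
variance with real between-group spread returns F = ∞, p = 0.

**Planned contrast.** A single-df contrast Σwᵢx̄ᵢ with Σwᵢ = 0 (default
w = −1 on normal, +1 on Stage I) is tested with SE = √(MSE·Σwᵢ²/nᵢ) using
the pooled within-stage mean square from *all* levels and its df. A
two-level contrast therefore reproduces the pooled-variance two-sample
t test exactly (asserted in tests). The pooled-error choice, rather than a
two-sample subset test, is what "a contrast within a one-way ANOVA" means;
with 5 levels it borrows df from the other stages.

**Permutation empirical p.** Stage labels are permuted jointly over the
analyzed samples (never across groups — each group is analyzed as its own
cohort), F is recomputed per shuffle, and

p_emp = #{F_perm > f_obs} / n_perm

with *strict* inequality. This estimator can legitimately return exactly 0
when the observed F dominates every shuffle; an add-one smoothed variant
(1 + #{F ≥ f_obs})/(1 + n_perm) sits behind a flag, default off, for users
who need a positive lower bound. Ties are resolved with a relative
tolerance of 1e-9 on F so that round-off in the vectorized recomputation
cannot convert an exact tie into an exceedance (this matters when data
admit only a few distinct F values). Per-(gene, group) seeds are derived
from the master seed through `numpy` SeedSequence so any subset of the
batch is independently reproducible.

Calibration: with 2000 independent null genes (5 stages × 10 samples,
n_perm = 1000), the empirical p-values are uniform (KS test) and the
rejection rate at α = 0.05 sits within sampling error of 0.05 — the
analysis driver `04_calibration_and_recovery.py` computes both. Note the
uniformity check itself is a hypothesis test: on a perfectly calibrated
null, KS p < 0.01 still occurs for ~1% of seeds by construction.

**2×2 proportion tests.** Odds ratio ad/bc with explicit zero-cell
semantics (0, ∞, or NaN for 0/0) and the exact two-sided Fisher p summing
hypergeometric point probabilities ≤ the observed table's (the
point-probability convention; cross-checked against a brute-force
enumeration oracle in tests).

## The screening cascade

**Fingerprints and similarity.** Linear atom-bond paths of 0–7 bonds hashed
into 1024 bits (both configurable); length-0 paths (per-element bits) keep
single-atom molecules representable. Tanimoto similarity |a∧b|/|a∨b| with
an inclusive survival threshold of 0.6. The 0.6 cut and the path family
mirror common toolchain defaults for "similar backbone" searches; both are
exposed as configuration because reasonable alternatives (ECFP-style
circular fingerprints, > vs ≥) exist.

**Dockability.** A compound is dockable when at least one pose has energy
≤ −5.0 kcal/mol. The ceiling is a pipeline parameter; −5 kcal/mol
(≈ 200 µM-scale affinity by rule of thumb) is a conventional weak-binder
cut.

**Pose COM and clustering.** COM is the mass-weighted mean of atom
coordinates with standard atomic weights (a geometric-center variant is a
one-line change; mass weighting matches what molecular-mechanics packages
report). Binding regions come from energy-ordered leader clustering:
process poses from deepest energy (ties broken by compound then pose id),
join the first cluster whose *founding* pose lies within 4.0 Å, else found
a new cluster. Because processing order is by energy, each founder is its
cluster's representative (minimum-energy member), founding order equals
ascending representative energy, and the result is invariant to input row
order. Cluster 1 is always the deepest region. When sites are separated by
more than 2×cutoff + 6×scatter_sd the partition provably matches
single-linkage connected components, which the tests assert over 20 seeds.
Leader clustering was chosen over hierarchical/RMSD schemes because it is
deterministic, O(nK), and standard practice for docking-pose site binning;
a two-level (pocket/sub-pocket) scheme would be a faithful alternative but
adds a second cutoff with no way to validate it.

**Specificity statistic.** Per compound, representative energies are
per-region minima sorted ascending (ties by cluster id); E₁, E₂ are the two
lowest and ΔE_r = E₂ − E₁ ≥ 0. Compounds confined to a single region carry
no gap; they are flagged and reported separately rather than assigned an
artificial E₂ = 0, which would silently dominate any ranking.

**Significance of the gap.** The test conditions the difference statistic
M = ΔE_r on the signal axis A = (E₁+E₂)/2, in the spirit of MA-style
conditional-null testing for count data — but energies are not counts, so
the null is estimated empirically from the screened batch itself. For each
compound, the window is the `max(50, 10% of batch)` records nearest in A.
The reported effect size is the robust z-score (M − med)/(1.4826·MAD). The
p-value, however, is *not* the normal upper tail of that z: the null of a
between-region gap is a spacing-type distribution (difference of the two
lowest of several per-region minima), strongly right-skewed, and a normal
tail on it is anti-conservative by an order of magnitude — in a planted
simulation (100 compounds, 5 specific, gap 3 kcal/mol over N(−7, 0.2)
background) the normal tail produced an empirical FDR ≈ 0.43 at q < 0.05.
Instead the survival function is a median-calibrated exponential,

p = 2^(−M / med_window),

which is exact for an exponential null (whose median is med = mean·ln 2),
honest in the body, and conservative in the far tail because true spacing
tails here are sub-exponential (a large gap requires a Gaussian-suppressed
outlier minimum). With this calibration the same planted simulation gives
sensitivity 1.0 and empirical FDR 0.0 over 20 seeds. Degenerate cases: an
all-identical batch gives z = 0 and p = 0.5 (M equals the window median); a
window with median gap 0 raises an error rather than fabricating spread.
Benjamini–Hochberg q-values are computed across the batch (raw p is also
reported); candidates are ranked by (q, then ΔE_r descending, then id) and
survive at q ≤ α (default 0.05) or as a top-k list.

**Rule of five.** MW, Crippen atom-contribution logP, HBD as N–H/O–H
hydrogen count, HBA as N+O count (the original rule's conventions). The
default allowance is ≤ 1 violation of {MW > 500, logP > 5, HBD > 5,
HBA > 10}; strict mode (0) is available.

**Cascade order.** similarity → dockability → specificity → Lipinski,
configurable; specificity before Lipinski keeps the statistical batch as
large as possible (the null window is estimated from it). With α ≥ 1 the
specificity stage becomes a pass-through (single-region compounds
included), so a fully permissive configuration returns the input library
unchanged — a useful end-to-end identity check.

## Synthetic data: what it emulates, what it does not

`synthgen` exists so the pipeline can be exercised and validated without
cohort downloads or a docking engine.

* **Expression** (`gen_expression`): cell values are
  2^(baseline_g + shift + noise) — log-normal baselines
  (N(5, 1.5) on log₂ scale), i.i.d. cell noise (σ = 1 log₂ unit), additive
  per-(group, stage) shifts for planted genes, and anti-correlated pairs
  coupled by a shared per-sample latent factor carrying √|ρ| of the noise
  sd (sign applied to the second gene), giving pair correlation ρ with
  unchanged marginals. Defaults: 5 stages × 10 samples per group, two
  groups. This reproduces the *statistical* structure of a staged two-race
  cohort (exchangeable labels under the null; group-specific stage
  effects), not real RNA-seq marginals: no gene–gene correlation beyond
  the planted pairs, no library-size or GC artifacts, no heavy-tailed
  dispersion. Passing tests therefore certify the inference machinery, not
  robustness to real-cohort messiness.
* **Poses** (`gen_poses`): K = 9 sites (auto-placed 20 Å apart, or
  user-set centers validated against a 5×scatter separation floor),
  isotropic Gaussian scatter (0.5 Å), 9 poses per compound with the first
  forced to the compound's designated site, energies N(−7, 0.2) kcal/mol,
  and a planted extra depth of 3 kcal/mol at the designated site for a
  5% specific fraction — the standard recovery conditions used across the
  tests. Real docking funnels (correlated poses, pocket-shape anisotropy,
  energy–position correlation) are not modeled.
* **Library** (`gen_library`): the reference is an N-acylhydrazone with a
  piperonyl head (the scaffold family of Rhosin-like inhibitors); analogs
  are the scaffold plus 1–3 enumerated single-substituent decorations
  (graded similarity ladder reaching down to ≈ 0.6), decoys come from
  disjoint non-aromatic scaffold families and score near 0. All emitted
  SMILES are guaranteed to re-parse; generation is retry-bounded and
  seed-deterministic.

Every generator is a pure function of (config, seed) and emits truth
tables (planted shifts, designated sites and specificity flags, library
kinds) that tests and drivers compare against recovered structure.

## Problem sizes and numerics

The calibration study uses 2000 genes × 1000 permutations × 50 samples
(vectorized per gene over permutations; a few seconds), and recovery
studies use 20 seeds of 100-compound screens — sizes chosen so the whole
suite and the acceptance script each run in well under a minute while
keeping Monte-Carlo error far from the asserted margins. Other numerics:
permutation tie tolerance 1e-9 relative on F; MAD spread floored at 1e-9;
contrast weights validated to sum to 0 within 1e-9; cluster tie-breaks and
representative-energy ties resolved lexicographically for bit-for-bit
reproducibility.

## Known limitations

* The exponential-tail significance model is a calibration choice, not a
  derived null; screens whose background gap distribution is heavier than
  exponential (e.g. multimodal pockets) would need a refit.
* Single-region compounds are untested rather than scored; a screen where
  most compounds bind one region yields a small statistical batch (the
  minimum batch of 20 is enforced).
* Leader clustering guarantees exact site recovery only for well-separated
  sites; overlapping pockets merge.
* The expression arm tests one gene at a time; no cross-gene multiplicity
  correction is applied there (the screening arm's BH is per screening
  batch).
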