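# Methods

## Pipeline model

The analysis treats each (subject, task-state) run as a stationary
multivariate signal over `N` nodes and reduces it to a binary graph:

1. **Conditioning.** The first `k = 5` volumes are dropped (magnetization
   equilibration). Slow drifts are removed with a zero-phase Butterworth
   high-pass (order 2, cutoff 0.01 Hz at TR = 3 s, applied forward-backward
   with `sosfiltfilt`). The filter family is a design choice — only the
   cutoff is dictated by the study design — so order and family are
   configurable; zero-phase filtering was chosen because correlation
   estimates are phase-sensitive. Filtering is applied to ROI-averaged
   series rather than voxel data: both operations are linear, so the order
   is immaterial (property-tested), and the ROI-first order avoids 4-D
   passes.
2. **ROI extraction** (when starting from volumes). Node series are
   unweighted means over voxels whose centers lie strictly within 5 mm of
   the node coordinate (10 mm-diameter spheres). Partial-voxel weighting is
   deliberately not attempted; neighboring spheres may share voxels. An ROI
   capturing no voxel is an error naming the node, not a silent drop.
3. **Graph construction.** Pearson correlations over all node pairs; a
   proportional threshold keeps the top `p = 0.25` of the `N(N−1)/2`
   upper-triangle values as links, giving every run exactly
   `L = ⌊p·N(N−1)/2⌋` links. Ranking is by *signed* value by default (the
   most positive correlations become links); absolute-value ranking is
   available behind a switch because the verbal definition of "top
   correlations" is genuinely ambiguous. Ties at the cutoff are broken
   lexicographically by node pair so runs are bit-reproducible; on
   continuous data ties occur only at machine precision.
4. **Statistics.** Within-network connectivity is the mean full degree over
   a subnetwork's members (links to the outside count); between-network
   connectivity is the cross-link count between two disjoint subnetworks.
   Both are integers or simple means of integers; no weighted-graph,
   modularity or efficiency measures are computed.

## Statistical design

All group inference is rank-based: Wilcoxon signed-rank (normal
approximation, Pratt handling of zero differences; the reported statistic
is the signed rank sum T⁺ − T⁻), Friedman's chi-square with tie correction
for each three-state family, and pairwise Wilcoxon post-hocs with Bonferroni
correction (×3, capped at 1). The post-hoc procedure is a design choice —
the underlying study reports post-hoc values on a software-specific scale
that cannot be reconstructed — so this package reports its own statistics
and p-values and the relation table ("A > B" iff corrected p < .05 with the
matching mean ordering) is the comparable output. Degenerate inputs are
flagged rather than computed through: all-zero difference vectors give
p = 1, constant inputs give an undefined (NaN) Spearman rho.

The asymptotic approximations are accurate to ~0.07 (Wilcoxon, n = 8) and
~0.15 (Friedman, 5 × 3) against exhaustive permutation oracles at the
smallest sizes used in testing; at the cohort size (n = 43) they are
standard practice.

## Synthetic cohorts

The generator produces zero-mean multivariate normal time series whose
correlation matrix is block-structured over DMN (58 nodes), FPN (25) and
remaining (181) nodes:

| parameter | default | meaning |
|---|---|---|
| `rho0` | 0.08 | baseline correlation, all pairs |
| `dmn_boost` | 0.06 in T&E learning, else 0 | within-DMN block |
| `fpn_boost` | 0.12 learning, 0.10 test, 0 rest | within-FPN block |
| `between_boost` | 0.04 in both learning states, else 0 | DMN × FPN block |
| `tau` | 0.03 | SD of the per-subject DMN × FPN effect |
| `state_noise_sd` | 0.03 | SD of per-run perturbations of each block |
| `slope_a`, `sigma_b` | 670, 30 | behavioral coupling and noise |
| `phi` | 0 | optional AR(1) temporal coefficient |
| `volumes`, `tr_seconds` | 200, 3.0 | run length (10 min at TR 3 s) |

Construction notes:

* The covariance is repaired to positive definiteness by flooring
  eigenvalues at 1e−6 and re-normalizing to unit diagonal; with the default
  parameters the repair is a no-op or near-no-op.
* The per-subject effect is drawn once per subject and enters the
  DMN × FPN block with sign +½ in T&E learning and −½ in EL learning (zero
  elsewhere). A sign-symmetric split is required for the effect to survive
  in the T&E − EL difference that the brain-behavior analysis consumes; a
  same-sign effect would cancel exactly.
* Per-run state noise on the three block boosts models spontaneous
  engagement/arousal fluctuations. It is what gives the graph statistics
  realistic between-subject spread; without it, finite-run sampling noise
  is so small at n = 43 that even few-link systematic offsets (e.g. the
  link competition induced in non-boosted blocks by the fixed link budget)
  become significant and the designed null cells fail.
* Behavioral scores are `ability ± latent/2` rounded to multiples of 10 and
  clipped to [0, 400] (the 40-trial, 10-points-per-hit scoring rule), with
  `latent = slope_a·effect + N(0, sigma_b)` and ability ~ N(190, 65).

**Calibration.** The boosts, noise SDs and behavioral coupling are
calibration constants, not measured quantities: the raw study data are
unavailable, so they were chosen (once, via the sweep shipped as
`analysis/05_calibrate_effects.py`) such that (a) at n = 43 the learning
family reproduces the qualitative relation pattern — DMN elevated only in
T&E learning, FPN elevated in both learning states and both test states,
between-network connectivity elevated in both learning states — with high
per-cell success rates, and (b) the measured Spearman correlation between
connectivity differences and score differences lands in the weak-coupling
regime around 0.32. The planted latent coupling is deliberately stronger
(~0.55) because graph-metric measurement noise attenuates the observable
correlation; the calibration targets the *observed* value.

**What the simulator does not model:** hemodynamic convolution and its
frequency structure, head motion, physiological noise, spatial
autocorrelation within ROIs, non-Gaussian amplitude distributions, and any
true learning dynamics within a run. Passing recovery tests therefore
demonstrates that the pipeline correctly extracts planted block-correlation
structure at realistic sample sizes — not that the original neural effects
are real or that the pipeline is robust to fMRI artifacts.

## Stimulus algorithm

Targets are HSL colors (each channel an integer 0–255) with lightness
restricted to 100–200. For a target saturation `S`, the candidate grid is
every `S ± 35k` within [0, 255] (always 7 or 8 values — verified
exhaustively); the five-candidate set is a uniformly chosen window of five
consecutive grid values containing `S`. For a fixed target the window
position of `S` is uniform over its admissible positions. Averaged over
uniformly distributed target saturations the position marginal is symmetric
(≈ [.261, .167, .144, .167, .261]) but not flat; the property test checks
the empirical distribution against brute-force enumeration over all 256
saturations rather than against a flat law. Hue coverage ("the palette
represented evenly") is implemented as stratified one-per-bin sampling over
equal hue bins — the simplest scheme with the stated property; lightness is
uniform on [100, 200]. Session plans randomize association order per block
and candidate-to-slot assignment per trial; exposure timings are carried as
metadata only (no presentation engine).

## Problem sizes in tests and acceptance

Recovery studies run at reduced scale, chosen to keep the full suite in the
few-minute range while preserving the effect-to-noise geometry: pattern
recovery on 100 half-scale cohorts (131 nodes, 43 subjects), correlation
recovery on 200 half-scale two-condition cohorts, null calibration on 1,000
small cohorts (50 nodes, 15 subjects, exchangeable conditions, all boosts
zero and `tau = 0`). The acceptance script runs one full-scale cohort (264
nodes, 43 subjects, 5 conditions) plus 40/50/200-cohort reduced-scale
replications. Degree-scale quantities shrink roughly with node count, so
half-scale connectivity values are not comparable to full-scale ones;
relation patterns and correlations are.

## Known limitations

* The high-pass filter family used in the original processing chain is not
  recoverable from its description; results insensitive to this choice for
  the simulated data, but real-data reanalysis should check both.
* Signed vs. absolute correlation ranking changes which graphs are produced
  when strong negative correlations exist; the simulator produces
  predominantly positive couplings, so the tests do not discriminate the
  two modes.
* The between-network statistic is an unnormalized count; comparisons
  across parcellations of different size require rescaling.
* Wilcoxon p-values use the normal approximation even at small n; exact
  enumeration is available in the test oracles but not exposed as an
  analysis option.
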