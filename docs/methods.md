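# Methods

## The linear-system core

The central object is the constrained linear system `D a = f`. `D` is the
`n × b` matrix of connection weights from `b` inhibitory output neurons to
`n` target neurons; its entries are stored nonpositive (the output nuclei
are GABAergic), activities `a` are nonnegative rates, and the inhibition
function `f` is therefore elementwise nonpositive. A basis matrix can be
built three ways:

- **Shifted prototype** (`build_shifted_basis`): `b` copies of a
  nonnegative prototype placed at uniform spacing `n/b`, wrapping on a
  ring or truncating on a line. Prototypes are stored as magnitudes and
  negated once at construction, so all downstream algebra uses the
  inhibitory sign convention. The default overlapping prototype is
  `[0.6, 0.8, 1.0, 0.8, 0.6]` — a peak of 1 stepping down by 0.2 per
  side; two steps per side keeps supports overlapping at `b = 5`,
  `n = 20`, the configuration of the cortical demonstration. The shifted
  construction is usually full column rank, but not always: a prototype
  whose discrete Fourier transform vanishes on a used frequency (e.g. an
  all-equal prototype with `b = n`) is rank deficient. The constructor
  computes the rank and warns rather than trusting the generic claim.
- **Spanning code** (`build_spanning_basis`): entries in `{−1, 0}`, each
  output neuron covering one full row or column of an `N × N` grid. Its
  rank is `2N − 1` (row and column indicator spaces share the all-ones
  direction), so the spanning code is deliberately not full rank — two
  different output patterns can produce the same inhibition field.
- **Explicit** matrices, for anything else.

`solve_weights` returns the minimum-norm least-squares solution of
`D a = f` with the residual, a feasibility flag (all entries nonnegative
within tolerance), and a uniqueness certificate: full column rank plus a
vanishing residual implies at most one solution. Numerical rank counts
singular values above `max(n, b) · ε · σ_max`, the standard rule.

Capacity arithmetic is exact: `count_output_states(b, s) = s**b` in
arbitrary-precision integers. `spanning_code_capacity(b, ratio)` splits
`b` neurons between the two axes in proportion to the grid aspect ratio
(minor/major, in (0, 1]) and returns the product of the group sizes; at
extreme ratios at least one neuron stays on the minority axis, since a
zero-neuron axis controls nothing. At ratio 1 this equals the true
maximum over all partitions, `⌊b/2⌋·⌈b/2⌉`.

## Tracer-based expansion estimation

Inputs are three delimited tables: experiments (id, injected volume in
mm³, proportion of the injection inside the source nucleus), per-region
tracer densities `d_t ∈ [0, 1)` (fraction of region volume occupied by
fluorescent pixels), and a catalogue of non-overlapping regions with
neuron counts `n_t`. A single per-region density serves both as the noise
filter statistic and as the arborization weight. Defaults describe the
mouse SNr: volume 0.69 mm³, ~12,000 neurons.

Per experiment and threshold θ the pipeline retains regions with
`d_t ≥ θ` (inclusive comparison), sums `n_t` over retained regions (upper
bound on contacted neurons) and `n_t · d_t` (lower bound), fits each
total against injected volume by ordinary — optionally
proportion-weighted — least squares (statsmodels), and extrapolates to
the full nucleus volume. Both mean-response and prediction intervals are
exposed; the mean-response interval is what a fit line's 95% band shows.
The threshold sweep runs θ = 0 to 0.05 in steps of 0.005, and the
asymptote detector returns the last element of the first window of three
consecutive estimates whose successive absolute changes are each
strictly below 1, or nothing if no window qualifies.

An alternative per-experiment route for injections confined to the
nucleus (proportion > 0.9) divides the aggregated target count by
`Ŝ = S · V_eff / V_src`, the source neurons covered by the injection.
`V_eff` defaults to volume × proportion-in-source; a flag restores the
raw volume. The proportion-corrected form is the one consistent with the
printed coverage column of the reference injection table
(volume × proportion / 0.69): rows 100141993 (0.32) and 175263063 (0.24)
reproduce exactly at two-decimal half-up rounding, as does 158914182
(0.23). The three remaining rows print 0.30, 0.21 and 0.51 where the
arithmetic gives 0.29, 0.20 and 0.49 — discrepancies of one to two
hundredths presumably inherited from rounding of the published volumes;
they are noted here and not reconciled.

The compression side of the bottleneck is plain arithmetic:
`striatal_compression_ratio` defaults to 0.5 × 400,000 striatal
projection neurons per 12,000 SNr neurons ≈ 16.7:1.

## The synthetic tracer generator

The generator emulates exactly the features the pipeline consumes, with
known ground truth. Conditions (defaults): 295 regions with log-normal
neuron counts (median 50,000, σ_log = 1.5 — a heavy tail like real
region-size distributions); 40 true target regions chosen at random with
per-region strengths log-uniform on [0.5, 1]; six injections with the
volumes and confinement pattern of the reference experiments; true-target
density = gain × volume × strength with gain 0.17 per mm³; and uniform
noise on (0, 0.003] added to **every** region, so that at θ = 0 the whole
catalogue appears to receive projections and thresholding is
consequential, while one grid step (0.005) cleanly removes all noise.
Densities are clipped at 0.999, honouring `d_t < 1`.

Two tuning knobs pin the ground truth: `target_ratio` rescales
true-target counts so their sum is exactly ratio × source neurons (the
quantity the upper-bound route must recover), and
`target_weighted_ratio` rescales the gain against the realized strengths
so the expected density-weighted ratio at the full nucleus volume is
exact. The default gain already places the weighted mean density near
0.085 at the nucleus volume, i.e. a lower:upper ratio near 13:154.

The signal component is deterministic in the study seed (two injections
at volumes V and 2V have exactly doubled true-target signal); only the
noise uses the per-experiment seed. All streams derive from
`numpy.random.SeedSequence`, so studies are bit-reproducible across
platforms.

What the generator does *not* model bounds what recovery tests show: no
spatial geometry, no hemispheric asymmetry, no saturation of densities at
large volumes, and — importantly — the true-target *set* does not shrink
when an injection covers only part of the nucleus; only densities scale.
Under that structure the extrapolation route recovers the ground truth,
and the density-weighted per-experiment route with the raw-volume `Ŝ`
recovers the weighted truth exactly (the volume cancels), but the
*count-based* per-experiment route recovers truth/coverage rather than
truth: partial injections still label every true region. Real data, where
partial injections reach partial target sets, sits between these
idealizations. Recovery tests therefore exercise the sweep route (154
within 10%, 13 within 15% at θ one step above the noise floor) and the
weighted per-experiment identity, not count-based per-experiment
recovery.

## Cortical network model

A 200-unit rate network `τ ẋ = −x + W r(x) + I(t)` with τ = 20 ms and
the supralinear transfer `r(x) = k⌊x⌋^η`, k = 0.1, η = 2, integrated by
forward Euler at 0.1 ms. Connectivity: Bernoulli(p = 0.1) adjacency;
each column wholly excitatory (`+w0/√N`) or inhibitory (`−γ w0/√N`),
γ = 3. The scale `w0 = R / √(p(1−p)(f + (1−f)γ²))`, with `f` the
excitatory fraction, sets the expected bulk spectral radius to R = 10 by
the circular law; at `f = 0.5` it reduces to the familiar
`R/√(p(1−p)(1+γ²)/2)`. At the 80:20 split the realized radius over 50
seeds averages 11.2, within 15% of target.

Two regimes matter dynamically. At 80:20 with γ = 3 the mean column
weight is net excitatory (`f > γ(1−f)`), and under the input step the
supralinear network diverges — a rectified-square nonlinearity has no
saturation, so net-excitatory drift is fatal at radius 10. At 50:50 the
network is inhibition-dominant and the dynamics are stabilized in the
proper SSN sense; all dynamical demonstrations and tests therefore use
`excitatory_fraction = 0.5`. (Inhibition dominance also adds a large
*negative* real outlier eigenvalue, so the naive `max |λ|` at 50:50
exceeds R even though the bulk radius is R; the radius property is
checked on the 80:20 construction.) An eigenvalue-minimizing stability
optimization of W is left as an explicit `NotImplementedError` hook.

Input protocol: background 0.1 to all units outside the 1,000–2,000 ms
window; inside it, a fixed random 10% of units (20) receive the thalamic
drive `T = T_b − |D| a` with `T_b = 1` and `D` the 5 × 20 ring basis
(magnitude form; identical to `T_b + D a` under the core module's
nonpositive convention), and the remaining 180 units receive step values
drawn once from [0, 1] and then frozen. Across simulations only `a` is
resampled, uniformly from [0, 0.4]. Any |x| above 1e6 raises an
instability error naming the seed; unstable seeds are reported, never
silently dropped.

Analysis: rates are recorded every 1 ms; trajectories are projected onto
principal components (scikit-learn), with the baseline point the mean
projection over the last 200 ms before the step. Trajectory
dissimilarity is the mean pointwise Euclidean distance in the top-3
common principal components over the step window (components fit on the
pooled rates of all trajectories); the association between output
vectors and trajectories is the Spearman rank correlation between the
two pairwise-distance sets. With 20 resampled outputs the correlation is
positive (≈ 0.3–0.5 depending on seed); the choice of 3 components and
of the distance metric is a convention, so only the sign is treated as
meaningful.

## Collicular grid model

The build-up layer is an `N × N = 20 × 20` grid of uncoupled leaky units
`τ ṡ = −s + u + D a`, τ = 10 ms, with rectified output `r = max(0, s)`
and the spanning basis above (40 output neurons). The fixed point is
`s* = u + D a`; 200 ms of Euler integration (20 τ) lands within 1% of
it, and all scenario contracts are also derivable from `s*` by hand.

Scenario magnitudes are not printed anywhere, so they are chosen as the
minimal parameterization making all four behaviours realizable: target
drive U = 1.5 and tonic output a₀ = 1 satisfy `a₀ < U < 2a₀`, so two
tonic inputs suppress a target (1.5 − 2 < 0) while pausing both releases
it (1.5 > 0), and a competitor sharing one paused axis sits at
`U − a₀ = 0.5 > 0`. The corrective boost default (2.0) exceeds the
`U − a_col = 1.5` needed to re-suppress the competitor.

Hills are 4-connected components of cells with `r* > 0.05` (drive
units), located at their maxima (scipy.ndimage). An *absolute* threshold
is used deliberately: a relative cut at half the global maximum would
erase the half-height competitor hill that the competing scenario is
about. Selectability is checked exhaustively: for each of the 400
coordinates, pausing its row and column neurons yields activity at
exactly that cell, matching the spanning-code capacity `20 × 20` from
the core module.

## Problem sizes and determinism

Default problem sizes are those of the demonstrations themselves: a
295-region catalogue with six injections; a 200-unit network simulated
for 3 s (30,000 Euler steps), with 20 resampled output vectors for the
coupling analysis and 50 connectivity seeds for spectral statistics; a
400-unit grid for 200 ms. Every random stream is seeded explicitly;
generator studies and CLI runs are byte-reproducible for a fixed config
and seed.

## Known limitations

- The estimation pipeline consumes pre-exported tables; no image
  processing, registration, or atlas access.
- The generator's density-scaling idealization (above) limits what
  count-based per-experiment recovery can demonstrate.
- The cortical model makes no claim about which E/I ratio cortex uses;
  the 50:50 regime is a stability requirement of the supralinear
  transfer at this spectral radius, not an anatomical statement.
- The grid model has no intra-grid coupling, saccade kinematics, or
  topographic magnification; "build-up" is leaky integration toward the
  fixed point.
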