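# Methods

`wbsleep` models the descent from wakefulness (W) into NREM sleep
(N1-N3) as a change in two neuromodulatory axes of a whole-brain neural
mass model: cholinergic tone, expressed through the long-range coupling
`G`, and noradrenergic tone, expressed through the slope `sigma` of each
region's input-output function.  This note documents the model, the
numerical choices, the synthetic study conditions, and what the tests do
and do not establish.

## Neural network model

Each region of an N-region parcellation carries a Wilson-Cowan
excitatory/inhibitory pair with a homeostatic inhibitory-to-excitatory
weight `a_IE`:

    tau_E dE_i/dt = -E_i + (1 - r_E E_i) * S_E(a_EE E_i - a_i_IE I_i
                                               + G_i * sum_j C_ji E_j + P + D eps_i)
    tau_I dI_i/dt = -I_i + (1 - r_I I_i) * S_I(a_EI E_i)
    tau_ip da_i_IE/dt = I_i (E_i - rho_E)

with `S(x) = 1 / (1 + exp(-(x - mu) / sigma))`.  Constants (time in
seconds): `r_E = r_I = 0.5`, `tau_E = 0.01`, `tau_I = 0.02`,
`a_EE = 3.5`, `a_EI = 3.75`, `P = 0.4`, `D = 0.002`, `rho_E = 0.18`,
`mu = 1`, `sigma_I = 4`.  The plasticity rule drives each node's
time-averaged excitatory activity to the set point `rho_E`, making the
operating point robust across the whole (G, sigma) range swept —
verified as an acceptance-level property.

Integration is explicit Euler at `dt = 1e-4` (full protocol): 400 s of
transient with fast plasticity (`tau_ip = 0.05`) discarded, then 600 s
of analysis window with slow plasticity (`tau_ip = 2`).  Noise is an
i.i.d. standard-normal draw per region per step entering the sigmoid
argument scaled by `D` — an input fluctuation, not a Wiener increment; a
`1/sqrt(dt)` Euler-Maruyama convention is available via
`SimulationConfig(euler_maruyama=True)` for users who want
dt-invariant noise power.

Choices the model description leaves open, fixed here:

- **Coupling placement.** The regional coupling `G_i` multiplies the
  connectome input `sum_j C_ji E_j`; this is the only placement under
  which sweeping `G` acts on the dynamics.
- **Initial conditions.** `E = I = 0.1`, `a_IE = 1`.  The fast-plasticity
  transient erases them (tested: trajectories from different
  initializations agree to 1e-3 after 30 s).
- **`a_IE` floor.** The plasticity rule does not forbid negative
  inhibitory weights; they are clipped at zero, since a negative
  inhibitory synapse is meaningless.
- **Settling stretch.** Switching `tau_ip` from 0.05 to 2 shifts the
  plasticity quasi-equilibrium slightly, so the analysis window opens
  with a slow, node-identical relaxation drift.  `t_settle` inserts a
  discarded stretch at the slow constant before recording (0 in the full
  protocol, 10 s in the desk profile); residual drift is further handled
  in BOLD post-processing (below).
- **State recording.** The excitatory path is recorded every 1 ms
  (`record_dt`), inhibitory and plastic weights every 10 ms, to bound
  memory at full scale.

## Hemodynamics and BOLD

Excitatory activity drives the Balloon-Windkessel model per region
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q;
`tau_s = 0.65`, `tau_f = 0.41`, `tau_v = tau_q = 0.98`, stiffness
exponent `kappa = 0.32`, `E_0 = 0.4`, `V_0 = 0.04`,
`k1, k2, k3 = 2.77, 0.2, 0.5`; Euler at 1 ms), with readout
`B = V_0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]`.  The `v` and `q`
equations use the standard Friston form with exponent `1/kappa`; its
steady states match an independent algebraic fixed-point solution to
1e-6 (tested at five drive levels).

Post-processing: per-region linear detrend, zero-phase 2nd-order Bessel
band-pass 0.01-0.1 Hz at the native rate, then decimation to TR = 2 s.
Two deliberate additions to the minimal chain:

- **Start-up discard.** The hemodynamic state starts at rest; its step
  response to the network's operating level is a large transient common
  to all regions.  The composed forward chain drops the first 20 s of
  BOLD before filtering.
- **Detrending.** The plasticity drift noted above is slower than the
  0.01 Hz band edge but leaks through it; because it is node-identical
  it would otherwise inflate all correlations.  A linear detrend before
  filtering suppresses it (flag `detrend=False` restores the bare
  filter).
- **Drive pooling.** The forward chain mean-pools the neural drive to
  10 ms before hemodynamic integration.  The hemodynamic time constants
  are all >= 0.4 s and the analysis band ends at 0.1 Hz, so this
  anti-aliased decimation leaves filtered BOLD essentially unchanged
  (FC correlation 0.999 against the 1 ms path on a 30-node run) at a
  fraction of the cost.  `pool_dt=None` restores the 1 ms path.

Filter direction (zero-phase by default, forward-only via
`zero_phase=False`) and the filter-before-decimate order are exposed as
switches; FC is phase-sensitive, so the zero-phase default avoids a
systematic lag.

## Neuromodulation

Maps are positive per-region weight vectors normalized to mean 1; a raw
map whose subcortical entries dwarf the rest (the noradrenergic
projection density in thalamus) can optionally be de-escalated: thalamic
entries are clipped to the maximum non-thalamic value before
normalization.  Regional parameter fields follow

    G_i     = G     + deltaG      * ACh_i
    sigma_i = sigma + delta_sigma * NA_i

Lower cholinergic tone is modelled as higher coupling, so deeper sleep
corresponds to `deltaG > 0`; lower noradrenergic tone as
`delta_sigma < 0`.  A nonpositive resulting slope or negative coupling
is an error, never a clamp — sweeps record such grid points as
infeasible (+inf fit) so optima cannot silently sit on clamped
parameters.

Surrogate maps permute homotopic value pairs with a single permutation
applied identically in both hemispheres.  This preserves the value
multiset, both per-hemisphere means, and — because the connectome is
homotopically symmetric — the map's correlation structure with it.
Independent per-hemisphere permutation is available (`joint=False`) but
breaks homotopic correspondence.

## Fit metric and sweeps

Model fit to an FC matrix is the euccorrelation between strict lower
triangles: Euclidean distance divided by |Pearson correlation|, small
only when magnitudes and pattern both match; a vanishing correlation
maps to +inf so argmin selection never picks it.

The wake state is fitted first with an absolute homogeneous (G, sigma)
sweep; stage fits are then (deltaG, delta-sigma) offsets from that wake
anchor on endpoint-inclusive equidistant grids (full protocol: 50 x 50
over [-0.5, 0.5] x [-1, 1], 50 seeds per point).  The optimum is the
argmin of the seed-mean fit (median by flag); exact ties break toward
the smallest |deltaG|, then smallest |delta-sigma|, then the earlier
grid index — fully deterministic.  Three modalities are compared at
their own optima: homogeneous (maps = 1), map, and shuffled-map, using
Cohen's D between per-seed fit distributions and correlations between
simulated and empirical nodal integration/segregation profiles.

## Hierarchical modular analysis

The FC matrix is eigendecomposed; level 1 is the whole-network module,
and each further level splits the previous level's modules by the sign
of the next eigenvector's entries.  A module with uniform sign carries
forward unsplit, so the module count at level i is at most
min(2^(i-1), N) rather than forced to 2^(i-1).  Zero entries join the
nonnegative submodule.  With M_i modules of sizes m_j and
`p_i = sum_j |m_j - N/M_i| / N`, each level contributes
`H_i = Lambda_i^2 M_i (1 - p_i) / N`; integration is `H_in = H_1 / N`,
segregation `H_se = sum_{i>=2} H_i / N` (summation runs to N), and
nodal components weight levels by squared eigenvector entries.
Eigenvectors in numerically degenerate blocks are ordered by the index
of their largest-magnitude entry and sign-fixed (largest entry
positive); within such a block the split is basis-dependent and results
should be read accordingly.

## Homotopic connectome enhancement

Tractography underestimates interhemispheric connections; homotopic SC
entries are iteratively nudged by `eta * (FC_emp - FC_sim)` per epoch
(defaults: 60 epochs, simulated FC averaged over 20 seeds per epoch),
floored at zero, symmetric, with all other entries untouched.  The
forward engine is pluggable and defaults to this package's own
simulation chain; the learning rate is not prescribed anywhere, so the
default `eta = 0.05` ships with a divergence guard that halves `eta`
when the homotopic error grows two epochs running.

## Statistics

Cohen's D uses the classical pooled-SD form (not Hedges' g), with bins
very small / small / medium / large / very large / huge at
0.2 / 0.5 / 0.8 / 1.2 / 2 (boundary values go to the higher bin).
Stage comparisons are two-sided paired t-tests with Benjamini-Hochberg
correction; for region-profile panels the pairing unit is the brain
area (per-area values averaged across subjects).  Repeated-measures
correlation uses the shared-slope, subject-intercept ANCOVA closed form
(dof = N_obs - N_subjects - 1), dropping subjects without
within-subject variation; it is cross-checked against pingouin in the
test suite.

## Synthetic study conditions

The generator stands in for a night-sleep fMRI study and fixes these
conditions:

- **Connectome**: modular within-hemisphere blocks (3 modules),
  mirrored across hemispheres, homotopic entries pinned, density 0.6,
  rescaled to a mean row sum of 40 so the recurrent input
  `G * sum_j C_ji E_j` is of order one at the reference coupling.
- **Reference operating point**: `G = 0.44`, `sigma = 3.5` at desk
  scale.  This sits in the fluctuation-rich regime where the simulated
  wake FC is structured (mean ~0.33 with visible modular contrast)
  rather than globally saturated, while homeostasis still holds.
- **Stage ground truth**: W (0, 0), N1 (0.1, -0.2), N2 (0.2, -0.4),
  N3 (0.3, -0.6) — deeper sleep raises coupling and lowers slope, on
  grid nodes of the 11-point desk grids.
- **Maps**: lognormal (sigma_log 0.45), hemisphere-symmetric, mean 1,
  ACh/NA spatial correlation 0.3 by default.
- **Cohort**: 8 subjects, per-subject (deltaG, delta-sigma) jitter of
  SD 0.02, 180 s windows at TR 2 s; BF/LC analogue signals are
  map-weighted mixtures of regional BOLD.

What the generator does *not* emulate: measurement noise and scanner
drift, hemodynamic variability across regions and subjects, the heavy
tails and distance dependence of real tractography weights, head motion,
and physiological confounds.  Passing tests therefore demonstrate that
the pipeline recovers what the forward model encodes — not that the
model fits any particular empirical dataset.

## Problem sizes and profiles

Two profiles ship with the package. The full protocol (90 regions,
dt = 1e-4, 400 s + 600 s, 50 x 50 grid, 50 seeds) reproduces the
method's reference conditions; single simulations run in ~1-2 minutes,
full sweeps are cluster-scale.  The desk profile
(`wbsleep.neural.desk_config()`: dt = 2 ms, 20 s transient + 10 s
settling + 180 s window; 30 regions; 11 x 11 grids) runs a simulation
in ~0.3 s and a sweep in about a minute, and is what the test suite
uses.  Within the desk profile the simulation-heavy end-to-end tests
further reduce ensemble sizes (2 sweep seeds per grid point, 5
generator seeds for parameter recovery, 20 evaluation seeds per
modality) — the properties asserted (recovery rate >= 80%, |D| >= 0.8
orderings) are unchanged.  At desk dt the per-step noise convention
makes effective noise power dt-dependent; desk-profile analyses are
self-consistent (generator and sweeps share the profile) but desk and
full-protocol trajectories are not interchangeable.

## Known limitations

- Explicit Euler throughout; halving `dt` changes trajectories (and,
  with the default noise convention, effective noise power).  The
  homeostatic set point and BW steady states are dt-robust; fine
  temporal structure is not.
- The euccorrelation landscape has a G-sigma trade-off valley (both
  parameters shift network gain); seed averaging and map heterogeneity
  resolve it in the tested conditions, but single-seed sweeps can land
  elsewhere along the valley.
- HMA nodal components within degenerate eigenvalue blocks are
  basis-dependent.
- The empirical-data path expects already-parcellated region x time
  matrices; no imaging preprocessing is provided.
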