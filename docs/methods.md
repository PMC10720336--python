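# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `verletdiag`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external sources.

## The missed-interaction mechanism

Verlet-list MD engines evaluate short-range pair forces from a neighbor
list built with an outer cutoff `r_l >= r_c` and reused for `nstlist`
integration steps. A pair whose separation exceeds `r_l` at build time but
drops below the interaction cutoff `r_c` before the next rebuild is
*missed*: it exerts no force until it is re-listed. For an attractive
potential, missed pairs remove negative virial contributions, so the
apparent pressure is biased upward in proportion to how stale the list is.
A barostat acting on such pressures — especially out of phase with the
rebuild schedule, or anisotropically — converts a small systematic bias
into box deformation.

## The miss-count model (`missmodel`)

**Assumptions.** Partners form an ideal gas: uniform density `rho`,
Maxwell–Boltzmann velocities at temperature `T`, ballistic ("free flight")
motion over one list lifetime `t = nstlist * dt`. Under these assumptions
the relative displacement of a pair with masses `m1, m2` after time `t` is
an isotropic Gaussian with per-component standard deviation
`sigma_t = t * sqrt(kB T (1/m1 + 1/m2))` (the reduced-mass relative
particle; equal masses give `sqrt(2 kB T/m)`).

**Reference estimator (`path-MC`).** Initial pair separations are sampled
uniformly (with the correct `r^2` radial weight) in the shell
`[r_l, r_l + 8 sigma_t]` — the Gaussian tail beyond 8 sigma contributes
less than 1e-15 — and relative velocities from the Gaussian. A pair is a
*unique miss* if its separation is below `r_c` at any force-evaluation time
`k*dt`, `k = 1..nstlist-1` (at `k = nstlist` the list is fresh again);
`per_step` counts every offending `(pair, step)`. The expected unique
missed pairs per particle per lifetime is `rho * V_shell * P(miss)`, with a
binomial Monte-Carlo standard error. Fixed seeds make the estimate
bit-reproducible.

**Fast approximation (`endpoint`).** Only the end-of-lifetime separation
is tested. `P(|r_vec + d| < r_c)` has a closed form for Gaussian `d`
(radial integration of the Gaussian over the cutoff sphere), verified
against a 10^6-sample displacement oracle at 4 standard errors; it is
integrated over the initial shell by adaptive quadrature. The two
estimators agree within ~20% for coarse-grained-water-like conditions
(density 7.08 nm^-3, 72 amu, 310 K, dt = 0.02 ps, nstlist = 25,
r_c = 1.1 nm, r_l = 1.28 nm); the endpoint form is slightly high because
it uses the full lifetime `nstlist*dt` while the last stale force
evaluation happens at `(nstlist-1)*dt`. The path-MC estimator is
authoritative wherever the two disagree.

**Rigid molecules.** For small rigid molecules (e.g. three-site water) the
model samples a uniformly oriented molecule at the origin and a partner
centered uniformly in a shell wide enough to contain every configuration
from which a given site-type pair can start beyond `r_l` and reach `r_c`;
both receive Gaussian center-of-mass velocities (total mass `M`) and
Gaussian angular velocities about their principal axes (variance
`kB T / I_axis`). Free rigid-body rotation is approximated by holding the
angular-velocity vector fixed (Euler precession neglected — adequate for
the sub-picosecond lifetimes of interest, where rotations are small
fractions of a radian). The estimator reproduces the point model when all
site offsets vanish, and for a water-like geometry orders the per-site-pair
miss counts H–H > O–H > O–O: light peripheral sites sweep the widest arcs.
A zero principal moment combined with off-axis site mass is rejected
(equipartition would imply unbounded angular speed).

**Recommendation engine.** `recommend_rl` inverts the endpoint model by
bisection (to 1e-3 nm) for the smallest `r_l` whose expected unique miss
count does not exceed a user tolerance. The default tolerance used in the
acceptance script, 1e-4 misses per particle per lifetime, is a strict
"effectively none" criterion: in a 10^6-particle system it still allows
~100 missed pairs per rebuild interval. `drift_rate` converts the per-step
miss rate into an order-of-magnitude energy-drift-per-particle analog of an
engine buffer tolerance by weighting misses with the mean truncated-shifted
pair-energy magnitude over the sampled missed-pair distances; it is a scan
and comparison tool, not an engine reimplementation.

## The simulator (`ljsim`)

A velocity-Verlet simulator for truncated-and-shifted Lennard-Jones
particles in periodic orthorhombic boxes, with the neighbor list rebuilt
every `nstlist` steps and *deliberately* reused in between, so that missed
interactions occur exactly as in production engines. Design choices:

* **Truncated-and-shifted LJ, no tail corrections** — tail corrections
  would partially mask the missed-interaction signal. The energy is zero
  at `r_c`; the force retains the usual discontinuity of magnitude
  `|u'(r_c)|` there. An optional force-shifted variant (continuous force at
  `r_c`) exists for strict conservation studies.
* **Exact 1x1 pair list.** Pair search uses a grid/tree periodic
  fixed-radius query whose pair set equals the O(N^2) minimum-image search
  exactly (tested). There is no particle clustering, so the search is
  isotropic by construction; cluster-induced anisotropy of production
  engines is out of scope. Minimum-image validity requires every box
  length > 2 `r_l`, which is enforced.
* **Dual pair list.** An inner list (cutoff `r_inner`) is pruned from the
  outer list every `nstlist_inner` steps and used for forces. With
  `r_inner = r_l` no pruning is applied, making dual mode bit-identical to
  the single list (tested).
* **Thermostat/barostat.** Velocity rescaling to the target temperature
  and a Berendsen-type first-order box relaxation
  (`mu = (1 - dt_couple * kappa_T * (P_target - P)/tau_p)^(1/3)`, per
  coupled axis group: isotropic, semi-isotropic xy/z, or fully
  anisotropic). Neither is ensemble-rigorous; the artifacts under study
  are barostat-independent, so the simplest couplers suffice.
* **Instrumentation.** Per-step diagonal pressure-tensor samples
  (`P = (sum m v v^T + sum d f^T)/V`, converted with 16.6054 bar per
  (kJ/mol)/nm^3 or factor 1 in reduced units), energies, box lengths, and
  an optional exact miss log (pairs currently within `r_c` absent from the
  active force list; unique misses deduplicated per list lifetime).

**Energy-drift sign.** With a zero buffer and infrequent rebuilds the NVE
total energy drifts measurably *downward* for attractive LJ: a pair missed
while approaching is re-listed at the next rebuild with `u(r) < 0`, an
uncompensated potential-energy drop. (The apparent *pressure* is
simultaneously biased upward — the two signs are consistent, since the
pressure error reflects the missing attractive virial while the lists are
stale.) With complete lists (`nstlist = 1`) the integrator conserves
energy to better than 1e-4 epsilon per particle over 10^4 steps at
dt = 0.002 tau (measured as the fitted secular slope).

**Problem sizes.** The desk-scale study conditions are: dense fluid
N = 1000, rho = 0.8, T = 1.0 (reduced), r_c = 2.5 sigma, dt = 0.005 tau,
equilibrated 2000 steps under a thermostat; the artifact condition is
`r_l = r_c` with `nstlist = 40` for 300 lifetimes (12,000 steps), the
control `nstlist = 1` for 6,000 steps. Free-flight validation uses
N = 2000 coarse-grained-water-like particles over 200 lifetimes. These
sizes give 3-sigma-resolvable statistics for every effect tested while
keeping a full run in minutes on one core.

## Pressure diagnostics (`pressurediag`)

* **Phase averages.** The series is blocked into whole `nstlist`-step
  lifetimes, phase 0 being the first force evaluation after a rebuild (an
  offset parameter realigns series that start mid-lifetime). Standard
  errors come from a seeded block bootstrap (default 1000 resamples) over
  whole lifetimes, because samples within a lifetime share the same stale
  list and are strongly correlated; per-phase z-scores on white noise are
  correctly calibrated (tested). The overall mean equals the plain mean of
  the truncated series exactly.
* **delta_P** = mean(phase `nstlist-1`) − mean(phase 0): the pressure bias
  accumulated over one lifetime, reported per component (scalar, in-plane
  `(P_xx+P_yy)/2`, normal `P_zz`). Positive delta_P indicates missed
  attractive interactions, negative missed repulsive ones.
* **Welch PSD.** Hann window, 50% overlap, mean removal per segment;
  default segment length is 8192 samples or the largest power of two not
  exceeding length/8, whichever is smaller (enough lifetimes per segment
  to resolve the rebuild harmonics at the series lengths the simulator
  produces). Parseval holds within windowing tolerance (tested at 5% on
  white noise).
* **Harmonic detector.** At each multiple of `1/(nstlist*dt)` below
  Nyquist, the PSD at the nearest bin is divided by the median PSD of a
  surrounding band (default 25 bins each side, the 2 bins around the
  harmonic excluded). The median-background ratio is scale-free across
  systems; the default flag threshold of 10 yields a measured
  false-positive rate below 5% on white noise. A series with
  `nstlist = 1` has its first harmonic above Nyquist, so the scan is empty
  and the verdict clean by construction.

## Box-deformation statistics (`boxstats`)

Replicate box-length series are classified by endpoint-window means (first
vs last 10% of the series): contraction vs elongation along z for
semi-isotropic coupling, and the axis of largest relative growth for
anisotropic coupling (exact ties break to the smallest axis index and are
logged; an exactly tied semi-isotropic series raises, prompting a longer
run). The 10% windows average out step noise while the semantics remain
"how did the box end up relative to how it started".

Event counts are tested against the isotropic null (1/2:1/2 or
1/3:1/3:1/3) with Pearson's chi-squared test. Published analyses of such
counts differ in convention, so three are exposed: `standard`
(df = k−1, the library default and the statistically conventional choice),
`yates` (continuity-corrected two-category test, df = 1), and
`df_equals_k` (plain statistic referred to df = k). The non-default
conventions exist to reproduce printed values whose convention is fixed by
the numbers themselves; the package is explicit about which convention
produced which p-value.

## Bending energy (`curvature`)

Monge-gauge mean curvature on a periodic height grid by second-order
central finite differences, and the Helfrich energy with zero spontaneous
curvature and the Gaussian term omitted (topology-invariant):

    E = 2 kappa * integral H^2 dA  =  (kappa/2) * integral (2H)^2 dA,

integrated over the flat xy plane (area-element curvature corrections
ignored, consistent with the small-slope regime). Conventions differing by
whether `H` or `2H` is squared are a recurring factor-of-4 trap; this
package's convention is as written and is pinned by the closed-form test
`E = (kappa/2) a^2 (2 pi/L)^4 L_x L_y / 2` for a single sinusoid
(agreement within 0.2% at a 128^2 grid; finite differences underestimate
`k^2` by a factor `1 - (k dx)^2/12 + ...`, giving second-order
convergence, which is tested). Finite differences rather than spectral
derivatives are the default because binned height fields with interpolated
bins are only piecewise smooth.

Height fields are built from marker coordinates (e.g. lipid phosphate
beads) by periodic xy binning with per-bin mean z. Leaflets can be
selected by sign of `z - median(z)`; `midplane-split` returns the average
of the two leaflet fields, an estimate of the bilayer midsurface. Empty
bins are filled by iterative periodic 4-neighbor averaging to 1e-6 nm and
recorded in a mask; more than 50% empty bins raises, since the grid is
then finer than the sampling supports. Bending rigidities quoted in kB*T
(default 25 kB*T in the CLI, a typical fluid-phosphatidylcholine value)
are converted with kB = 0.0083144621 kJ/(mol K).

**Scope.** Production-scale membrane deformation energies from multi-
million-particle trajectories are not desk-reproducible; the pipeline is
instead validated end to end on membrane-sized synthetic undulations with
known closed-form energy (point sampling -> binning -> curvature ->
energy agrees with the direct-field energy within 5%).

## What the synthetic generators do and do not emulate

The pressure generator (white noise + periodic phase pattern + optional
inner-period sawtooth) reproduces the *stationary, additive* structure of
the artifact: a per-phase mean offset and its spectral harmonics. It does
not emulate the autocorrelation of real pressure fluctuations within a
lifetime, barostat feedback on the box, or slow drifts — so passing the
synthetic recovery tests shows the estimators are correctly calibrated for
additive periodic structure, not that every MD series is this simple. The
free-flight gas reproduces the model's own assumptions exactly (by
construction) and is therefore a validation of the *estimator chain*, not
of the ideal-gas assumption itself; in a dense liquid, caging slows
relative diffusion, so free-flight miss counts are conservative
(upper-bound-leaning) estimates. The LJ-fluid experiments close that gap
empirically for one dense liquid. Both particle generators rescale the
sampled velocities so the kinetic temperature equals the target exactly:
in free flight velocities are never resampled, so the thermal fluctuation
of a raw Maxwell-Boltzmann draw (~1% at N = 2000) would otherwise persist
for the whole run as a quenched offset invisible to interval-based
standard errors.

## Known limitations

* The point and rigid models ignore interactions during the lifetime
  (free flight); for small buffers and long lifetimes in dense systems
  the model is approximate — no correction is attempted.
* The simulator has no electrostatics, constraints, rigid bodies, or
  cluster-based pair lists; engine-specific anisotropies (e.g. from
  clustered neighbor search) and any extra buffering from such clusters
  are out of scope, so simulator miss counts can slightly exceed an
  engine's at identical parameters.
* The Berendsen-type barostat does not sample a rigorous NPT ensemble and
  the diagnostic reports phase-0 deviations against a user-supplied
  target without modelling barostat feedback.
* The chi-squared conventions beyond `standard` are reproduction aids;
  for new analyses, use `standard`.
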