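# Methods

## Model

DNA is treated as a chain of rigid basepair frames `i = 1..N` plus a
fictitious frame `N+1` that turns cyclization into the coincidence of
frames 1 and `N+1`.  The step between consecutive frames is described by
six internal coordinates in the symmetric (midframe) convention: a Cayley
rotation vector `theta` with `|theta| = 2 tan(phi/2)` (components: roll,
tilt, twist) and a translation `a` (shift, slide, rise, in angstroms)
expressed in the frame obtained by rotating frame `i` through half the step
rotation.  The elastic energy is diagonal quadratic in the deviations from
the intrinsic coordinates,

    E = 1/2 sum_{i=1..N} sum_{j=1..3} [K_j (theta_j^i - theta_hat_j^i)^2
                                       + A_j (a_j^i - a_hat_j^i)^2]   (RT),

with no couplings and no sequence dependence.  Because the coordinates are
independent Gaussians under the Boltzmann weight, sampling is exact and
direct — no Markov chain, no equilibration, no autocorrelation.

Intrinsic shapes are concatenations of helical, circular-arc and straight
segments at constant intrinsic twist `beta = 2 pi / helical repeat`.  A
helical segment is parameterized by `psi` (half the bend per bp) and
`alpha` (helicity), with closed forms for the per-step intrinsic
coordinates; `alpha = 0` gives a planar arc and `alpha = psi = 0` a
straight segment.  User-facing knobs are the total bend angle of a segment
(degrees), its pitch-to-circumference ratio
`tan(alpha) sin(psi)/psi` (signed; positive = left-handed here), and the
helical repeat.  Given bend per bp and pitch ratio, `(alpha, psi)` are
recovered by solving `sin(psi) = sin(bend/2)/cos(alpha)` together with the
pitch relation by bracketed root finding (residual < 1e-10).

### Frame-gauge subtlety

With frame 1 fixed at the identity, the composed origins of an intrinsic
helical segment lie on a helix of radius `(ell/2) cos(alpha)/sin(psi)`
advancing `ell sin(alpha)` per bp — but around an axis that is the y-axis
rotated by `alpha` about x, not the y-axis itself.  A y-axis-aligned
closed form and an identity first frame with a tangent third director are
mutually incompatible for `alpha != 0`; this package keeps the identity
gauge (which the Monte Carlo requires) and implements the closed-form
oracle in that gauge.  A global rotation cannot affect any physical
output, and J is separately verified to be invariant under lab rotations
of the sampled end states.

The Cayley chart requires `D = 1 + cos(psi) cos(beta/2) +
sin(psi) sin(beta/2) sin(alpha) > 1`; outside it a step rotation would
reach 180 degrees and the closed forms change branch, so such parameters
are rejected.  All DNA-like regimes (`2 psi` of order a degree, `beta`
around 0.6 rad) sit deep inside the chart.

### Stiffness parameters

| parameter | meaning | default | units |
|---|---|---|---|
| K1 = K2 | bending stiffness (isotropic rod) | 46.3/0.34 ≈ 136.2 | RT per squared Cayley unit |
| K3/K1 | twist-to-bend ratio | 1.5 | – |
| A1, A2, A3 | shear ×2, stretch | 14, 24, 85 | RT/Å² |
| scale_beta | overall scale on all six | 1.0 | – |
| ell | intrinsic rise | 3.4 | Å |
| helical repeat | bp per intrinsic twist turn | 10.5 | bp |

`K1 = Lp/ell` maps bending stiffness to a persistence length; an
`anisotropic_pair` helper splits K1, K2 at fixed harmonic mean, which is
the combination J-factors are insensitive to.  An inextensible mode
freezes the translations at their intrinsic values.

A caveat on the persistence map: for a straight but intrinsically
*twisted* ground state, Gaussian fluctuations in Cayley coordinates
produce tangent correlations decaying with an apparent persistence
`K1 ell / cos^2(beta/2)` (about 50.8 nm at repeat 10.5 for the 46.3 nm
baseline) — the large twist component of each step partially shields the
tangent from roll/tilt noise.  The `K1 = Lp/ell` identity is exact for the
untwisted rod, and the tests check both statements.

## J-factor estimation

J is the probability density of the end state (position and orientation of
frame `N+1`) at perfect closure, reported as a concentration.  The measure
on orientations is the normalized Haar measure; the closure region is a
product of a Euclidean ball of radius `eps` (volume `4/3 pi eps^3`) and a
rotation-group ball of radius `delta` in the metric `d = sin(phi/2)`
(normalized Haar volume `(2/pi)(arcsin(delta) - delta sqrt(1-delta^2))`).
This single rotation tolerance is equivalent, in the small-tolerance
limit, to the older convention of separate tangent and torsion cuts, whose
Haar volume is `nu_eps tau_eps/(2 pi)`; a Monte Carlo cross-check of that
equivalence is part of the test suite.

Half-molecule sampling: `M` independent first halves (steps `1..m-1`) and
`M` second halves (steps `m..N`) yield `M^2` glued molecules.  First-half
end states are stored pre-rotated as `-T_1:m^-1 r_1:m`, so a pair closes
translationally iff the stored points are within `eps`, and rotationally
iff `T_1:m T_m:N+1` is within `delta` of the identity (evaluated as a
single quaternion dot product).  Candidate pairs are pruned by cube
binning: z-slabs (at most 128, widened so every bin is at least `eps`
across — the guard that makes adjacent-bin search exact), x/y bins of
width `eps`, then the scalar z-difference test, the full Euclidean test,
and last the SO(3) test.  The binned count is exactly the all-pairs count
(tested against an O(M^2) oracle).  Then

    J = hits / (M^2 · (4/3) pi eps^3 · V_rot(delta)),

converted to nM via `1 A^-3 = 1e36/N_A nM`.

### Error model

The `M^2` glued molecules share halves, so the hit count is a two-sample
U-statistic, not a Poisson count: a single first half that lands where the
second-half density is high can close against thousands of partners.  The
package therefore records the per-half match multiplicities `h_i, h_j` and
quotes, for rare closures,

    Var(hits) ≈ hits + sum_i h_i (h_i - 1) + sum_j h_j (h_j - 1),

which was validated against seed-to-seed scatter and against a direct
(single-ensemble, genuinely Bernoulli) estimate; at generous tolerances
the inflation over Poisson reaches factors of tens in variance.
`estimate_J` alone defaults to the plain Poisson error; the high-level
drivers always use the corrected one.  Zero hits are reported as the
one-count upper bound and profile points with zero hits are censored out
of fits.

### Tolerances and their bias

The estimator is unbiased for the *ball-averaged* density, which exceeds
the point density at closure when the density grows away from the strained
closed state.  Measured on the reference molecule (90-degree bend, N=147):
log10 J = 1.42 at `(eps, delta) = (30 A, 0.3)`, 1.32 at (21, 0.21), 1.31
at (15, 0.15) — i.e. about +0.11 of ball bias at the default tolerances.
A `convergence_check` halves both tolerances and flags shifts beyond the
combined quoted errors.  Desk-scale choices here: the defaults
`eps = 30 A, delta = 0.3` give abundant hits at `M ~ 2^20` for good
cyclizers; high-accuracy work (0.1 in log10 J) requires both smaller
tolerances and ensembles orders of magnitude larger than a single-CPU run.
A second caveat: the orientation tolerance averages over about
`delta · repeat/pi` bp of twist phase, damping the oscillation of the
profile itself, so runs that compare oscillation shapes should keep
`delta` at 0.4 or below.

Splits default to the balanced `m = ceil((N+1)/2)`; J is split-invariant
(tested), but strongly unbalanced splits concentrate one half's end-state
cloud and inflate the correlated variance, so balanced is also the
statistically efficient choice.  Seeding: one master seed spawns an
independent child stream per (length, half), so every profile point is
reproducible in isolation.

## Profile fitting and calibration

Profiles (log10 J over N = 146..170, a little over two periods) are
summarized by

    y = a + b (N - phi) + c [f(N, phi, p)]^2,
    f = mod(N - phi + p/2, p) - p/2,

with `phi` the first peak after N = 145 (reported uniquely in
`(145, 145+p]`), `p` the period, `a` the peak height, `b` the drift and
`c < 0` the curvature setting the peak-to-trough difference `-c (p/2)^2`.
For fixed `(phi, p)` the model is linear in `(a, b, c)` and solved in
closed form; the outer two parameters are found by exhaustive grid
(`p` step 0.01 over [9.5, 11.5], `phi` step 0.02 over one period) plus a
derivative-free polish — the objective is only piecewise smooth in
`(phi, p)`, so gradient methods are not trusted.  Noiseless synthetic
profiles are recovered to 1e-6 in every parameter.  Fits are unweighted by
default (inverse-variance weights optional); standard errors come from the
local Jacobian and are approximate for `phi` and `p`.

Sweeping one knob at a time around the reference molecule (90-degree
planar bend over 63 bp, repeat 10.5, `K3/K1 = 1.5`, `beta = 1`) and
regressing fitted parameters on the knob gives the response relations kept
as module constants: `a` gains 0.021 per degree of bend (60–120 range) and
loses 4.45 per unit of `beta`; `phi` gains 14.3 bp per unit of helical
repeat and 2.45 bp per unit of pitch ratio; `a` loses 0.3 per unit of
|pitch ratio|; `c` loses 0.077 and `a` gains 0.30 per unit of `K3/K1`.
Combining them yields two degenerate families — mechanically different
molecules with nearly identical profiles: bend = 90 + 212 (beta - 1), and
the trio (repeat, pitch ratio = -5.84 (repeat - 10.5), bend = 90 +
14.3 |pitch ratio|), valid for |pitch ratio| <= 1 and bends of 60–120
degrees.  Family constructors use the published rounded coefficients (212,
-5.84, 14.3) so worked values reproduce to the printed decimals.

Run backwards, the responses calibrate any fitted profile to two numbers:
`K3/K1` from `c`, then `beta` from `a` given an independent estimate of
the intrinsic bend (optionally refining the peak-height baseline by
`0.30 (K3/K1 - 1.5)`).  The calibration flags extrapolation outside the
swept knob ranges.

The reference fit tables bundled in `dnacyclize.reference` were obtained
at full accuracy (beyond desk scale); they anchor the regression layer and
its tests without rerunning the Monte Carlo.

## Synthetic fixtures

`generate_profile_fixture` evaluates the periodic form on a length range
and adds i.i.d. Gaussian noise in log10 J — it emulates the *shape* and
noise scale of a computed profile, not the Monte Carlo's correlated hit
statistics, censoring at troughs, or ball bias.  Tests passing on
fixtures therefore validate the fitting layer in isolation; the Monte
Carlo acceptance checks close the loop on real sampled profiles.

## Problem sizes used by the test suite

Absolute peak-height check: `M = 2^20`, `(30 A, 0.3)`, single length
N = 147.  Knob-trend checks: profiles over N = 146..170 at `M = 2^16`,
`(50 A, 0.35)` — chosen so the bend, twist-stiffness and repeat trends are
resolved several sigma beyond the correlated noise while one profile runs
in under a minute; the closure-ball bias at these tolerances is common
mode across the compared family members.  Structural property tests use
1e6 Haar samples, 1e5 chains for the persistence check, and M = 2000 for
the exact binned-versus-brute-force comparison.

## Known limitations

- Diagonal stiffness only: no roll-twist or twist-stretch couplings, no
  sequence dependence.
- No excluded volume, no knot/link bookkeeping: acceptable for the short
  (~150 bp) constructs targeted here.
- The quoted stderr underestimates scatter when a handful of halves
  dominate the hit count (very unbalanced splits or very fat tolerances);
  the correction handles the observed regimes but is itself a rare-event
  approximation.
- Desk-scale ensembles cannot reach the 0.1-in-log10J accuracy of the
  bundled reference tables; the package reproduces peak heights to ~0.1
  and trends qualitatively at those sizes.
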