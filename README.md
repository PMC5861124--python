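# dnacyclize

Monte Carlo cyclization J-factors for a deliberately simple coarse-grained
DNA model, plus the analysis layer that turns profiles of J versus length
into a handful of interpretable numbers.

## The problem

The propensity of short DNA (~150 bp) to close into a ring is measured by
the J-factor: the effective concentration (nM) of one end in the
cyclization-competent neighborhood — position *and* orientation — of the
other.  Adding basepairs one at a time traces a *cyclization profile*,
log10 J versus N, which oscillates with the helical repeat because the
ends must meet in twist register.  Experiments read DNA bending and
stiffness off such profiles; this package quantifies how each mechanical
ingredient moves the profile in a minimal model, and shows that very
different mechanics can produce experimentally indistinguishable profiles.

## The model and the estimator

Each basepair carries a rigid frame; consecutive frames differ by six
internal coordinates (Cayley rotation vector theta = roll/tilt/twist with
|theta| = 2 tan(phi/2), midframe translation a = shift/slide/rise).  The
energy is diagonal quadratic about an intrinsic shape built from helical /
arc / straight segments at constant twist:

    E = 1/2 Σ_i Σ_j [ K_j (θ_j^i − θ̂_j^i)² + A_j (a_j^i − â_j^i)² ]   (RT)

so Boltzmann sampling is exact, coordinate by coordinate.  J is estimated
by the half-molecule method: M sampled first halves × M second halves give
M² virtual molecules, and

    J = hits / (M² · (4/3)πε³ · V_rot(δ)),    V_rot(δ) = (2/π)(arcsin δ − δ√(1−δ²)),

where a "hit" is a pair whose glued ends coincide within ε (angstroms) and
whose end orientations agree within δ in the rotation-group metric
sin(φ/2), normalized by the Haar measure.  Cube binning makes the pair
search exact but cheap; quoted errors account for the fact that the M²
molecules share halves.  Profiles are then fitted to the periodic form

    log10 J = a + b(N − φ) + c·f(N, φ, p)²,   f = mod(N − φ + p/2, p) − p/2,

(φ first peak after N = 145, p ≈ helical repeat, a peak height, c < 0 the
curvature: peak-to-trough = −c(p/2)²).  Regressing (φ, p, a, b, c) on
model knobs gives linear response relations, degenerate molecule families
(e.g. bend = 90° + 212(β − 1) trades intrinsic bend against an overall
stiffness scale β at nearly constant profile), and a calibration that
condenses any model's profile to two numbers: β and the twist-to-bend
ratio K3/K1.

## Worked example

```python
from dnacyclize import MoleculeSpec, ClosureTolerances, compute_J

spec = MoleculeSpec.single_bend(90.0, 147)   # 90° bend over 63 bp, then straight
est = compute_J(spec, M=1 << 17, tol=ClosureTolerances(30.0, 0.3), seed=1)
print(f"log10 J = {est.log10J:.2f} +/- {est.stderr_log10:.2f}  "
      f"({est.hits} hits from {est.pairs_total:.0e} pairs)")
```

prints

    log10 J = 1.49 +/- 0.14  (430 hits from 2e+10 pairs)

i.e. at its optimal length this strongly bent molecule has J ≈ 30 nM; the
reference (large-ensemble, small-tolerance) peak height is 1.35, and the
difference is dominated by the finite closure region at this desk-scale
setting (see `docs/methods.md`).  Fitting a profile and calibrating:

```python
from dnacyclize import fit_profile, calibrate_simple_model
from dnacyclize.io import generate_profile_fixture
from dnacyclize.fitting import FitParams

df = generate_profile_fixture(FitParams(147.16, 10.48, 1.35, 0.017, -0.112),
                              noise_sigma=0.05, seed=1)
print(fit_profile(df["N"], df["log10J"]).summary())
print(calibrate_simple_model(a_fit=0.847, c_fit=-0.0723, bend_estimate_deg=100.0))
```

    Periodic cyclization-profile fit
    ================================================
    nobs: 25    rss: 0.038655    peak-to-trough: 3.086
     param     estimate      std err
       phi     147.1467       0.0304
         p      10.4855       0.0266
         a       1.3695       0.0184
         b       0.0155       0.0012
         c      -0.1123       0.0014
    K3/K1 = 0.96, beta = 1.15

The fit recovers the planted parameters within its quoted errors; the
calibration says a molecule whose profile has peak height 0.847 and
curvature −0.0723, with a 100° intrinsic bend known independently, behaves
like the simple model at K3/K1 ≈ 1.0 and an overall stiffness ≈ 15% above
baseline (persistence length ≈ 53 nm).

The same workflow is available from the shell:

```sh
dnacyclize profile --config molecule.yaml --M 131072 --seed 7 --out profile.csv
dnacyclize fit profile.csv
dnacyclize calibrate --a 0.847 --c -0.0723 --bend 100
dnacyclize family --kind twist-helicity-bend --knobs 10.4,10.5,10.6
```

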