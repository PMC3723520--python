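# Methods

## The model

`fmbsim` simulates two abstract gene products, *AD* (adaxial-side, *PHB*-like)
and *AB* (abaxial-side, *FIL*/miR165-166-associated), on a one-dimensional
file of `N` cells representing the adaxial→abaxial axis of a leaf primordium
(cell 0 is adaxial-most).  Each product represses the other's production and
promotes the other's degradation, and both move between neighbouring cells by
simple diffusion:

    dAD_i/dt = f1(AB_i) − AD_i·g1(AB_i) + D_AD·L(AD)_i
    dAB_i/dt = f2(AD_i) − AB_i·g2(AD_i) + D_AB·L(AB)_i

with Hill-type rate laws

    f_j(z) = p_j + r_j·K_f^{n_f} / (K_f^{n_f} + z^{n_f})      (decreasing, p_j .. p_j + r_j)
    g_j(z) = d_j + c_j·z^{n_g} / (K_g^{n_g} + z^{n_g})        (increasing, d_j .. d_j + c_j)

and `L` the zero-flux discrete Laplacian (end cells have a single neighbour;
total diffusive exchange sums to zero, so the tissue ends are reflective).

Assumptions worth keeping in mind: concentrations are uniform within a cell;
the tissue neither grows nor divides; kinetics are deterministic; geometry is
strictly 1D.  All of these are simplifications of a real primordium and are
deliberate — the object of study is the generic behaviour of a bistable
mutual-repression front, not a tissue-faithful digital twin.

### Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| `p1`,`p2` | basal production rate | conc·t⁻¹ | 0.1 |
| `r1`,`r2` | repressible production increment | conc·t⁻¹ | 2.0 |
| `d1`,`d2` | basal degradation rate constant | t⁻¹ | 0.1 |
| `c1`,`c2` | inducible degradation increment | t⁻¹ | 2.0 |
| `D_AD`,`D_AB` | intercellular exchange coefficient | t⁻¹ | 0.1 |
| `n_f` | production Hill exponent (repression by dimer-or-larger complexes) | – | 2 |
| `n_g` | degradation Hill exponent (one-to-one small-RNA cleavage) | – | 1 |
| `K_f`,`K_g` | half-saturation constants | conc | 1 |

Concentrations are nondimensionalized so that `K_f = K_g = 1`; with that
choice the default set is bistable, which is the regime of interest.  `r_j`
and `c_j` may be zero (repression-free reductions used as analytic test
cases); `p_j`, `d_j` and `K` must be strictly positive.

### Single-cell analysis

Fixed points of the diffusion-free system are intersections of the
nullclines `AD = f1(AB)/g1(AB)` and `AB = f2(AD)/g2(AD)`.  They are found by
scanning the AB-nullcline residual along the AD-nullcline at 2000 grid points
over `[0, (p2+r2)/d2]` (the analytic supremum of the curve), bracketing sign
changes, refining each bracket with Brent's method and polishing with a
Newton solve of the full 2D system (analytic Jacobian) to residual < 1e−10.
Duplicates within 1e−6 (absolute, concentration units) are merged.
Stability comes from the Jacobian eigenvalues: stable iff both real parts are
below −1e−9; a real part within ±1e−9 raises an error rather than silently
classifying a marginal point.  At the defaults there are exactly three fixed
points: two stable attractors (the AD-expressing and AB-expressing states)
and, between them, a saddle.  Phase-portrait sketches often call that middle
point simply "unstable"; the package reports its actual type (`saddle`, one
positive and one negative eigenvalue).  Every stability label is also
verifiable by an independent oracle — forward integration from ±1%
perturbations — which the test suite applies.

### Integration

Classical fixed-step fourth-order Runge–Kutta with default `dt = 0.2`; the
step is exposed so reference runs can use a much finer one (the suite checks
dt = 0.2 against dt = 0.002 to ≤ 1e−4 max-norm, and fourth-order error
contraction on the linear-decay closed form).  Concentrations are never
clamped: negativity or non-finiteness aborts the run with the offending step,
because in the parameter regimes of interest it indicates a bug rather than
physics.  Recording defaults to every 5 steps (time resolution 1.0).
A cell may be *pinned* (Dirichlet-type clamp): it is reset to a prescribed
state after every RK4 step while still exchanging material with its
neighbour.  This implements the pinned-adaxial-cell scenarios.

### Boundary observables

A cell is AD-dominant iff `AD_i > AB_i`; an exact tie counts as AB (a
deterministic, measure-zero tie-break).  The boundary is the linearly
interpolated zero crossing of `s_i = AD_i − AB_i`, taking the crossing
nearest the adaxial end when there are several; a uniform tissue has no
boundary.  `domain_fraction` (percent of AB-dominant cells) is the in-silico
analog of a measured abaxial-marker area percentage.

`classify_dynamics` integrates a 3+3 initial tissue (both domains at their
stable states) to `t_end = 2000` and compares the net displacement with a
0.5-cell threshold: `FIXED`, `SHIFT_TO_AB_END` (displacement toward higher
indices, AD domain expanding), `SHIFT_TO_AD_END`, `NOT_BISTABLE`, or
`UNRESOLVED` for degenerate outcomes.  A boundary that reaches a tissue end
is classified by the surviving domain, not as unresolved.  Parameter sweeps
run every grid point in one lockstep RK4 batch; batching is elementwise
arithmetic identical to per-point runs (verified bitwise in the tests), it
only removes Python-loop overhead.  Default sweep grids span ±50% of the
base value with 21 points per axis.

### Scenarios

Built-ins reproduce the printed setups: the symmetric set (boundary fixed),
`r2 = 1.8` (abaxial shift), `r1 = 1.8` (adaxial shift, the exact mirror), and
the pinned-cell runs: one adaxial cell clamped to the AD state with five AB
cells, base `r2 = 1.8`, with `c1 = 2.0` (assumed wild type) vs `c1 = 1.9`
(assumed *phb-1d/+* heterozygote, weakened AD degradation).  Shift speed is
measured from first-passage times of the boundary across inter-cell
interfaces, by default between interfaces 1.5 and 3.5 (central crossings,
away from end effects).  Note that changing `c1` moves the fixed points
themselves slightly, so the two pinned runs start from equivalent — not
bitwise identical — initial states; each scenario initializes at its own
parameter set's fixed points.  Scenario `t_end` defaults: 2000 for the 3+3
runs, 4000 for the slower 1+5 pinned geometry.

## Synthetic marker profiles

`synthetic` generates per-cell two-channel fluorescence stand-ins for
confocal sections of an abaxial reporter and an adaxial miRNA-sensor.
Noiseless means are opposing logistic profiles centred on the ground-truth
boundary, scaled to `[baseline_frac, 1]` with `baseline_frac = 0.05`;
steepness defaults to 4 per cell, which keeps the region where both channels
exceed half-max within about one cell — the sharp, at-most-one-cell overlap
regime the marker data show.  Noise is multiplicative lognormal (shape
`noise_sigma`), applied independently per cell and channel: fluorescence
intensities are strictly positive with roughly multiplicative variability,
which additive Gaussian noise would violate.  Replicate seeds derive from a
master seed through a `SeedSequence([master, counter])` scheme (stage-major
counter), so whole collections are reproducible from one integer.

The estimator normalizes each channel to unit maximum and localizes the
interpolated crossing of their difference.  Recovery is exact for a centred
boundary (mirror-symmetric channels); off-centre, max-normalization biases
the crossing by up to a few hundredths of a cell at the default steepness —
an inherent property of the estimator, quantified in the tests.  A
calibration run (200 replicates, N = 6, σ = 0.1) put the mean absolute error
near 0.045 cells; the frozen test tolerance is 0.25 cells.  What these
profiles do **not** emulate: optical blur, segmentation error, 2D section
geometry, cell-size variation, or any measured noise statistics of a real
imaging system — passing recovery tests therefore demonstrates the soundness
of the localization machinery, not imaging-grade performance.

## Numerical and design choices

- The algebraic Hill forms and `K = 1` are package choices satisfying the
  qualitative constraints (monotonicity + ranges) the model imposes; other
  forms meeting those constraints would behave qualitatively alike.
- Problem sizes used by the test suite and acceptance script: N = 6 tissues,
  `t_end` 500–3000, four 11×11 sweep grids, 200-replicate recovery runs.
  These reproduce every qualitative regime at interactive runtimes.
- The fine-reference comparison uses a t = 100 window of the shifting run:
  long enough to include the fastest transients, where step error peaks.
- Equivariance (role swap + reflection) holds bitwise because every operation
  is elementwise or symmetric; the suite asserts exact array equality.
- Boundary continuity: at default recording, the interpolated position moves
  less than one cell between recorded times in every tested regime.

## Known limitations

- No bifurcation continuation: sweeps re-test bistability pointwise.
- No analytic front-speed theory; speeds are measured from trajectories.
- The dynamics-type taxonomy (5 labels) covers all behaviours observed in
  the swept regimes but a finer taxonomy (e.g. splitting extinction from
  travelling) is possible.
- 1D only; no growth, division, stochastic kinetics, or real-image analysis.
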