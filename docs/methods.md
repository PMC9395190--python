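# Methods

`dipolecycle` quantifies how a cell embedded in a soft three-dimensional
matrix converts two locally oscillating contraction units into directed
motion. This note records the models implemented, the conventions chosen
where the underlying procedures leave freedom, and what the synthetic
data do and do not establish about real microscopy data.

## Physical picture

A fibroblast in a cell-derived matrix (CDM) forms acto-myosin contraction
centers on either side of the nucleus. Each center periodically pinches
the surrounding fibronectin meshwork and releases it; the matrix is soft
(modulus of order 50 Pa) and linearly elastic on the relevant amplitudes
and timescales, so matrix displacement is a faithful, memory-free readout
of cell traction. Directed migration at negligible Reynolds number
requires a time-irreversible cycle of shape changes (the scallop
theorem). Here the irreversibility is temporal: a phase shift psi between
the front and back contraction cycles. Two observables diagnose it:

1. the cross-correlation lag between front and back divergence traces,
   psi = 2 pi lag / T, and
2. the area enclosed by the trajectory in the plane spanned by the main
   dipole D and main quadrupole Q of the deformation-rate field; a finite
   area is the geometric signature of broken time-reversal symmetry.

## Multipole moments

For samples n at positions x(n) with displacement rates u(n) and cell
center c, Delta(n) = x(n) - c:

    S_ij   = sym( sum_n Delta_i u_j )        [um^2/min]
    Q_ijk  = sum_n Delta_i Delta_j u_k       [um^3/min]

The main dipole is the eigenvalue of S of largest magnitude with sign
retained (contraction < 0) — Fig-style signed oscillating traces require
keeping the sign; an algebraically-largest rule is available behind
`eigen_rule="signed"`. The main quadrupole is the full contraction
Q_ijk e_i e_j e_k along the cell axis e, the rank-3 analogue of e.S.e and
the only contraction with the right units (um^3/min). Q is
origin-dependent when S is nonzero, so every output records the center
used (the per-frame cell centroid). Degenerate (isotropic) S has no
defined axis; such frames carry the previous frame's axis and are
flagged.

Cycle areas: the D–Q trajectory is cut into consecutive one-period
windows, each closed last-to-first, and the signed shoelace area
computed. The absolute area (um^5/min^2) is the mean |signed area|; the
normalized area is the percentage of the axis-aligned bounding rectangle
of the whole trajectory. Uncertainty over the choice of integration
region is estimated by recomputing over a set of cutoff radii (samples
with |Delta| <= r only) and reporting the spread; the default radius
ensemble is a fraction set {0.6, 0.8, 1.0, 1.2} of the cell half-length.
This ensemble is an approximation of radius-robustness, not a derived
error model.

## Oscillation analysis

Scattered rate vectors are interpolated to a regular grid (cubic, NaN
outside the convex hull), divergence taken by central differences, and
averaged over a band (default half-width 5 um) perpendicular to the cell
axis to form a kymograph. Front and back traces average a 3-um window
(middle of the 2–5 um range) centered on the nucleus front/back; the
temporal mean is subtracted.

Correlograms use the biased estimator with coefficient normalization
(autocorrelation exactly 1 at zero lag, |c| <= 1 everywhere). The period
is the first strict local maximum at positive lag whose amplitude exceeds
a threshold; a trace without such a peak yields "no period" and is
discarded by callers. The threshold is the larger of (a) the standard
deviation of the correlogram values at positive lags and (b) 3/sqrt(N),
the sampling-noise band of the estimator. Choice (a) alone is scale-free
but too permissive: the first local peak of a pure-noise correlogram
almost always clears it, which would defeat the discard rule; (b) is what
actually rejects noise (measured false-positive rate 0/500 on white
noise, with 50/50 recovery at signal-to-noise 5 for periods of 5–11 min
sampled at 0.5 min).

The front–back lag is the extremal-magnitude peak of the normalized
cross-correlogram, positive when the front leads. For near-periodic
traces a positive peak at the true lag and a negative peak half a period
away tie in magnitude up to edge effects; ties within 5% are broken
toward the positive peak, then toward the smaller |lag|. Searching is
restricted to |lag| <= T/2 when a period estimate exists. psi =
2 pi lag / T, wrapped to (-pi, pi].

Speeds: instantaneous speed is the frame-to-frame nucleus displacement
projected on the migration axis over dt; persistent speed is the net
axis-projected displacement over the analysis window divided by its
duration. The speed-oscillation period applies the same
autocorrelation/peak machinery to the projected increments.

## Tracker

Pyramidal Kanade–Lucas–Tomasi tracking, written against numpy with
scikit-image supplying corner detection (minimum-eigenvalue criterion
with non-maximal suppression at `min_distance`) and Gaussian pyramids.
Defaults: 8000 features, window 40 px, 20 iterations, 2 pyramid levels.
Track validation is forward–backward consistency under 1 px — a standard
rejection the source procedure leaves unspecified. Rigid stage drift is
estimated from a sparse 40-feature pass and removed as the per-frame
median displacement (median rather than mean for robustness to cell-
induced motion in the drift feature set). Pixel displacements are
converted to physical um (y-up) at output; "maximal iteration 20" is
implemented as an iteration count. Verified against: exact-zero motion on
identical frames, a uniform 3-px shift (mean error < 0.02 px), and
synthetic warped fiber textures (vector correlation > 0.9 with the
generating field).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it is the test substrate, not a matrix-mechanics model:

* two pinch centers 15 um apart (the nucleus gap), period 8 min within
  the observed 5–11 min range, displacement excursion 2.5 um per
  contraction half-cycle, sampling 0.5 min over 48 min, i.i.d. Gaussian
  noise on each rate component (the simplest model of tracker jitter);
* each pinch is a Gaussian-enveloped sink of width sigma = 5 um (the
  spatial decay of a pinch in a CDM is not characterized; 5 um is a
  default, not a fit), whose direction blends a radial component with
  contraction along the cell axis (anisotropy 0.6). The blend matters:
  a purely radial pinch pair has an exactly isotropic dipole tensor and
  hence no dipole axis, whereas acto-myosin pulls along the polarization
  axis, which is what aligns the main dipole with the direction of
  motion. With anisotropy 0 the divergence has a closed form used as the
  numerical oracle;
* displacement is prescribed directly (linear, memory-free elastic
  response); no fibrous-network mechanics, no strain stiffening, no 3D —
  the analysis operates on the 2D projection;
* image sequences warp a random fiber-plus-speckle texture by the
  cumulative field (bilinear), retaining ground truth per frame.

Because the generator satisfies the analysis assumptions by
construction, passing recovery tests demonstrates correctness of the
estimators (periods within one sampling interval, phase shifts within
2 pi dt / T, areas separating psi = 0 from psi = pi/2 against a
100-replicate noise floor) — not robustness to fibrous heterogeneity,
pore-scale nonlinearity, or out-of-plane motion in real CDMs.

## Bead models

The idealized cell is four collinear beads forming two dipolar units A
and B whose lengths follow L(t) in [D, D+d], unit B lagging A by psi.
Default geometry D = 10 um, d = 0.5 um, a = 1 um (bead radius), unit
separation r = 60 um, satisfying the small-amplitude, weak-coupling
regime d << a << D << r. The gait waveform is a sinusoid by default; a
smoothed square wave reproduces the four-state cycle and is constructed
to be exactly even in time so that reciprocity at psi = 0 is exact.

**Swimmer.** Beads are coupled by an Oseen-type mobility (self-mobility
1/(6 pi eta a), pair term 1/(4 pi eta r_ij)); the gait is kinematically
prescribed and the force-free condition closes a 5x5 linear solve for
the instantaneous cell velocity. The prescribed-gait Stokes problem is
geometric, so V is exactly proportional to 1/T, and the measured
small-amplitude exponent of V versus d is 2.00.

**Crawler.** No hydrodynamics. Each bead adheres through slip bonds whose
stretch delta_i relaxes at rate k_off (1 + |delta_i|/delta_off); the
adhesion velocity scale is v_adh = delta_off k_off. Beads interact
through the elastic matrix: each anchor rides the 1/distance displacement
field generated by the other beads' bond forces (coupling constant
kappa/(4 pi E), default 2 um). Force balance over the inertialess,
externally force-free cell closes the dynamics. The layout is a chain —
an adherent body of fixed length spanning the inner beads with the units
protruding outward — mirroring protrusion at the front and retraction at
the back; it is mirror-symmetric at every instant when psi = 0, making
the scallop result exact. Defaults k_off = 1/min (bond turnover faster
than every gait period studied, the fast-binding regime) and
delta_off = 10 um so that |delta|/delta_off stays deep in the linearized
small-force regime.

Measured behavior of this crawler: |V| T / d < 1e-15 at psi = 0 (both
waveforms), V proportional to T^-2.08 over T in {2,...,32} min, and V
proportional to d^1.96 over d in {0.1,...,0.8} um. The quadratic
amplitude dependence is a genuine property of this model class: with a
sinusoidal gait, any friction law that is an odd function of the local
force or stretch yields exactly zero net velocity at every order (a
harmonic-parity argument), so net crawling is carried by the
position-dependent (geometric) matrix coupling, whose leading term is
quadratic in the gait amplitude — as for the swimmer. Published
minimal-crawler analyses reach a cubic amplitude dependence through a
perturbation structure this model does not reproduce; we report what the
committed model computes rather than engineering an exponent.

Numerics: fixed-step RK4 at T/2000 by default, 3 transient cycles
discarded, 10 cycles averaged; `simulate(check_convergence=True)`
performs a Richardson half-step comparison and rejects timesteps whose
per-cycle displacement shifts by more than 1%.

## Pipeline conventions

A cell is labelled *migrating* when its normalized D–Q area exceeds a
threshold (default 5%, calibratable against `area_noise_floor`, the 95th
percentile over seeded noise-only replicates) AND |lag| exceeds one
sampling interval. This is a reproducible repository convention, not a
biological definition. Statistics are the ones the analysis reports:
Pearson r with two-sided t-distribution p, Kruskal–Wallis with midrank
tie handling, and least-squares log–log slope fits with 95% CIs; p-values
are not multiplicity-corrected. Every run is deterministic under a fixed
seed and embeds a configuration hash in its summary.

## Known limitations

* The analysis treats the 2D projection of an intrinsically 3D
  deformation field, as in the source procedure.
* Q is reported for a single contraction convention; alternative rank-3
  reductions ("projection on the axis" admits several readings) would
  rescale Q but not the vanishing/finite distinction of cycle areas.
* The crawler's absolute velocities carry unknown prefactors (only
  scaling exponents are meaningful), and its amplitude exponent is 2,
  not the cubic value minimal-adhesion theory derives under a different
  perturbation structure (see above).
* The classification threshold interacts with trace length: normalized
  areas of short noisy trajectories are biased upward because the
  bounding rectangle shrinks faster than the enclosed noise area.
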