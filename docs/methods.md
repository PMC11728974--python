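# Methods

## Model

The model couples the AA and EPA (or DHA) branches of prostaglandin
biosynthesis through a single lumped cyclooxygenase pool eCOX
(constitutive COX-1 plus ATP-inducible COX-2).  The state vector holds the
product metabolites and the enzyme pools; the substrate fatty acids and the
ATP stimulus are *inputs*: measured concentrations interpolated in time,
not states with their own balances.

EPA variant (13 states): metabolites PGH2, PGD2, PGE2, dhk-PGD2, PGJ2,
15d-PGD2 ("dPGD2"), PGH3, PGD3, PGE3; enzymes eCOX, ePtgds, ePtges,
edhkPGD2.  DHA variant (11 states): the AA branch unchanged, the 3-series
branch replaced by the single terminal product PD (an electrophilic
oxo-derivative with no further conversions).

Reactions.  The two COX-catalysed conversions AA→PGH2 and EPA→PGH3 (or
DHA→PD) are mass action in substrate and enzyme, multiplied by
`(1 + kATP·[ATP])` for the stimulus response and by the activity control v.
Downstream conversions are plain enzymatic mass action (PGH2→PGD2/PGE2 via
ePtgds/ePtges, PGH3→PGD3/PGE3 via the same two enzymes, PGD2→dhk-PGD2 via
edhkPGD2) or first-order non-enzymatic (PGD2→PGJ2, PGD2→15d-PGD2).  Every
metabolite carries a first-order loss term except dhk-PGD2, which is itself
the stable degradation product of PGD2; that choice fixes the EPA-variant
registry at exactly 41 free parameters (9 rate constants, 8 losses, kATP
and the ATP decay rate, 6 eCOX synthesis constants, 4 constants for each of
the three downstream enzymes, 4 initial enzyme levels).

Control laws.  With fluxes ρ_i = k_i·[eCOX]·[S_i] (the ATP factor cancels
from every ratio and is excluded), the matching law v_i = ρ_i/max_j ρ_j
modulates activity and the proportion law u_i = ρ_i/Σ_j ρ_j allocates
synthesis.  When all fluxes vanish (e.g. t = 0 with zero substrate) the
laws are indeterminate; we take the neutral convention u_i = 1/n, v_i = 1,
under which the model degenerates to unregulated mass action.  The v pair
is analytically independent of the eCOX level, which yields the switch
relation [AA]switch/[EPA]switch = kPGH3/kPGH2.

Enzyme balances.  d[e]/dt = α + Σ k_e·S/(Km+S) − β·[e].  For eCOX the two
induction terms are driven by AA and EPA (or DHA) and gated by u.  The
downstream enzyme balances mirror this shape without u; their drivers are
the total precursor pool [PGH2]+[PGH3] for ePtgds and ePtges (one lumped
induction term each) and [PGD2] for edhkPGD2.  ATP follows
[ATP](t) = ATP0·exp(−dATP·t) with ATP0 fixed per condition and dATP fitted.

Units.  Metabolites are in pmol/µg DNA, time in minutes.  Enzyme levels are
in arbitrary units: only the products k_i·[e] are identifiable, so the
enzyme scale is fixed by bounding the initial levels X0 in [0, 1].  The
ratio kPGH3/kPGH2 — the switch ratio — is the reported identifiable
quantity of the COX branch.

## Estimation

Cost.  The scaled fit error sums, over measured species, the squared
deviation between replicate-mean data and simulation divided by the
species' peak measured level.  With control and supplemented conditions
fitted jointly, one peak scale per species is taken over all fitted data:
a per-condition scale would divide the control condition's 3-series
residuals by their own negligible maximum and amplify replicate noise by
orders of magnitude.  A config switch fits individual replicates instead
of means.  Species measured as identically zero carry no scale and are
excluded with a warning.

Constraint.  The unmeasurable precursors PGH2/PGH3 (PD) are kept below
10 pmol/µg DNA by a smooth quadratic hinge penalty on their trajectory
maxima, weight 10³ by default, scanned on a dense grid (0.5 min inside the
search, 0.1 min for reporting) — a penalty rather than hard rejection so
the local stage stays smooth.

Optimizer.  Stage 1 is a seeded compass pattern search: ± one mesh step per
coordinate in shuffled order, mesh doubling after success and halving after
a failed sweep.  Steps are scaled per parameter by max(|start|, 10⁻³) —
bound-width scaling is useless when bounds span [0, 100] but the constants
live near 10⁻².  Stage 2 is bounded L-BFGS-B with forward-difference
gradients whose steps are likewise magnitude-scaled (10⁻³ relative,
10⁻⁶ floor): the ODE solution carries O(rtol) noise, so a fixed 10⁻⁸
absolute step would differentiate solver noise.  The stage pair can be
repeated (`rounds`); a restart with fresh curvature memory often escapes
line-search stalls.  Default bounds are [0, 100] for kinetic constants and
[0, 1] for X0; the default stage-1 budget is 2000 cost evaluations and
stage 2 runs to ftol 10⁻⁸ within 100 iterations / 3000 evaluations —
desk-scale settings under which a joint two-condition fit takes about one
to two minutes on one core.  Initial enzyme levels sit in the same
parameter vector and are therefore shared across conditions by
construction.

Integration uses LSODA (stiff-capable) at rtol 10⁻⁶ / atol 10⁻⁹.  Inputs
are interpolated linearly (cubic modes can overshoot into negative
concentrations), clipped at zero, with constant extrapolation beyond the
last sample.  A budget on right-hand-side evaluations (50 000 per solve)
turns pathologically stiff candidate parameter sets — which the search
occasionally polls — into a clean infinite-cost failure instead of a
multi-second stall.

## Validation

F-test.  Per metabolite, F is the lack-of-fit mean square of the simulated
profile against the replicate means (both condition groups pooled) over the
pure-error mean square of the replicates, with df₁ = ne·nt and
df₂ = ne·nt·(nr−1) computed from the dataset actually supplied.  The
comparison uses the *lower-tail* critical value: a fit passes when its
error is smaller than the replicate noise, so small F is good.  For the
design dimensions 2 × 8 × 3 the critical value F₀.₀₅(16, 32) is 0.46.

Leave-one-out-metabolite CV sets the held-out species' cost weight to zero
— its kinetics stay in the ODE system — refits, and scores the predicted
profile against the unused measurements with the same scaled error.

Switch analysis evaluates the simplified (eCOX-free) activity surfaces over
an (AA, EPA) grid and reports the analytic switch ratio.

## Synthetic data

The generator emulates the study design: measurements at 0, 2.5, 5, 10, 15,
30 and 60 min post stimulation, 3 replicates, control plus EPA- (or DHA-)
supplemented conditions.  AA rises as A·t/(τ+t) (A = 55 pmol/µg DNA,
τ = 5 min, so the profile plateaus past ~30 min) in every condition; the
supplemented fatty acid starts high (60 pmol/µg DNA) and decays
exponentially (0.02 min⁻¹); the control carries a residual 0.5 pmol/µg DNA;
ATP0 is normalized to 1.  Ground-truth parameters are drawn uniformly from
per-parameter ranges chosen once so that a typical draw gives measured
prostaglandins in the units-to-tens range, intermediates of a few
pmol/µg DNA (respecting the <10 assumption), and kPGH3 > kPGH2 (the
supplemented substrate is the faster COX substrate; the two ranges are
disjoint, 0.008–0.020 vs 0.025–0.060 min⁻¹·[e]⁻¹, giving switch ratios
between ~1.3 and ~7.5).  Replicate noise is multiplicative truncated
Gaussian, value·(1+CV·z) clipped at zero, CV = 0.05: scatter grows with
level and concentrations stay nonnegative.  PGH2/PGH3/PD are never emitted
as measurements.

What this does and does not show: passing tests demonstrate that the
pipeline recovers what is identifiable under the model's own assumptions —
correct noise model, correct input profiles, no model error.  Real
measurements bring structured biological variability, nonzero baselines and
model misspecification that the generator deliberately does not emulate;
magnitudes are not calibrated to any published dataset.

Recovery experiments start the optimizer from a seeded multiplicative
perturbation of the generating truth (±30%, clipped into bounds): the
question asked is local — whether the data re-identify the parameters,
foremost the switch ratio — not whether a global search finds the basin
from an arbitrary cold start.

## Known limitations

- Held-out PGD2 is weakly identified.  With PGD2 removed from the cost,
  kPGD2 appears only in the PGD2 influx and in the outflux of the
  unmeasured (merely bounded) PGH2, so the optimizer can fit PGD2's
  downstream products by compensating constants while PGD2 itself drifts in
  scale.  Leave-one-out predictions of PGD2 are therefore scale-uncertain,
  and increasingly so the harder the reduced cost is optimized; the
  cross-validation report should be read with that caveat.
- The F-test asks the fit error to sit *below* replicate noise.  Refits of
  data simulated from a known model typically achieve that for most
  species, but the peak-scaled cost does not prioritize the absolute
  residuals of low-abundance species, so individual species can sit near
  F ≈ 1 even at convergence; the calibration test in the suite asserts the
  majority/median behavior, not a uniform guarantee.
- The objective is non-smooth at control-law crossovers and carries solver
  noise; L-BFGS-B can stall in narrow valleys.  Restart rounds mitigate
  this but the two-stage search is a heuristic, not a certified global
  optimizer.
- No uncertainty quantification (no MCMC/profile likelihood); no reversible
  or thermodynamic kinetics; COX-1/COX-2 are lumped; no cell-population or
  spatial structure.
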