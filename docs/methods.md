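# Methods

This note records the models implemented in `aucsas`, the defaults and the
reasoning behind them, the numerical choices that matter, and what the
synthetic test bed does and does not establish about real data.

## Scattering model

The measured intensity of an n-component solution is the
concentration-weighted sum of per-mass species intensities,
c·i_exp(q) = Σ_j c_j·i_j(q). All decompositions in the package are exact
consequences of this linearity; the physics enters through two
approximations used in the monomer branch:

**Forward-intensity scaling.** The per-mass forward intensity of a j-mer
built from identical monomers is j times the monomer's (scattering mass
scales with j, per-mass normalization divides by j, coherence at q = 0
multiplies amplitudes). This gives the monomer share
t₁ = w₁ / Σ_j w_j·j with only weight fractions as input; absolute
concentration units cancel, which is why the SV-AUC peak areas suffice.

**High-q identity.** Under orientation averaging and neglecting
inter-monomer form-factor correlations (decoupling approximation), a j-mer
with centre distances d_kl scatters per unit mass as
i_j(q) = i₁(q)·[j + 2Σ_{k<l} sinc(q·d_kl)]/j. Two limiting arrangements
bracket plausible compact aggregates: collinear beads (`linear`,
d_kl = |k−l|·d) and maximally compact clusters (`close_packed`: touching
pair, equilateral triangle, regular tetrahedron — all pairs at d). The
mixture-to-monomer ratio r(q) = Σ_j w_j·i_j/i₁ then decays from
r(0) = Σ w_j·j to 1; above q\* = 1/R_g1 the residual |r − 1| stays below
~2% for a few-percent aggregate load, for either geometry. The package
treats that residual as a *systematic error band*, never as a correction
factor: correcting would assume the very geometry the method is agnostic
about.

The contact distance defaults to d = 2√(5/3)·R_g1, the diameter of the
sphere with the monomer's radius of gyration. It is configurable; for
elongated monomers a user should set it from the known shape.

## Monomer extraction pipeline

Steps: Guinier fit of the mixture (window q·Rg ≤ 1.3, the community
convention for globular particles) → t₁ and i₁(0) → high-q branch
assignment above q\* → slope-matched Guinier bridge → anchored refinement.

The refinement deserves detail because the operator is genuinely open
design space. The low-q branch i₁(0)·exp(−R²q²/3) is a *model*, so letting
it participate in its own refit is circular — an early design that fit an
extended Guinier model to the whole stitched curve drifted systematically
because a free quartic coefficient could trade against the synthetic
branch. The implemented refinement therefore fits

    ln i(q) = ln i₁(0) + b₁q² + b₂q⁴        (intercept fixed)

to *measured* points only, in the deterministic window
[1.15/R_g1, 2.0/R_g1] — from the midpoint of the q\*‥1.3/R_g1 hand-over
region to the extended-Guinier validity edge. The anchored intercept
carries the low-q information (it is the method's anchor, derived from t₁);
the window edges depend on R_g1 only, so the estimate inherits no jitter
from any noise-driven per-curve choice. Within the window, the Debye-model
band |r(q) − 1| (worst case over both geometries) is added in quadrature to
the statistical σ, down-weighting the region where oligomer contamination
is largest. Both edges move with R_g1, so the fit iterates to a fixed point
(tolerance |ΔR_g1|/R_g1 < 1e-4, cap 50; re-entering within tolerance of any
of the last four iterates counts as converged, because single grid points
crossing a window edge can sustain a limit cycle of amplitude above the
tolerance).

The connection point q_c for the output curve is chosen after refinement as
the grid point in [q\*, 1.3/R_g1] where the anchored Guinier branch and the
measured branch agree best in ln-intensity; a residual gap above 0.05 in
ln i triggers a warning (it signals inconsistency between the AUC fractions
and the scattering data, e.g. a wrong concentration). Below q_c the output
is the Guinier branch with σ propagated from the i₁(0) and R_g1
uncertainties; at and above q_c it is the measurement itself, so the
conservation identity c₁i₁ + c_a·i_a = c·i_exp holds exactly on the grid.

Validity policy: warn above 12% total aggregate fraction, refuse above 25%.
With the synthetic generator the mean R_g1 recovery error grows smoothly
from ~0.5% (no aggregates, 1% noise) to ~1.5% at 15%, which is the
quantitative content behind the 12% guideline. A low-q upturn in the
Guinier residuals (mean standardized residual > 1 with ≥ 75% positive signs
in the lowest 20% of the window) aborts the pipeline unless overridden:
upturns indicate large aggregates outside the oligomer model.

## Equilibrium branch

The SE-AUC absorbance model is implemented with molar reference
concentrations and molar extinction coefficients (path length folded into
ε); the complex amplitude ε_AB·c_A(r₀)·c_B(r₀)/K_D is the mass-action
constraint that makes K_D identifiable. This is algebraically identical to
the mass-concentration form with its M_AB/(M_A·M_B·K_D) factor — a unit
convention, not a model change. The buoyant exponent uses
σ_X = ω²M_X(1 − v̄_Xρ)/2RT with M in Da, r in cm, R = 8.314 J/(mol·K);
v̄ of the complex defaults to the mass-weighted mean and ε_AB to
ε_A + ε_B (additive chromophores), both overridable.

The global fit shares log K_D across scans with per-scan free
log-concentrations and, by default, an additive baseline
(standard SE practice; toggleable). Logarithmic parameterization enforces
positivity while keeping the problem unconstrained for Levenberg–Marquardt.
Errors come from the Gauss–Newton covariance scaled by the residual
variance; K_D error by the delta method. Two caveats surfaced by the
simulation suite and worth knowing: free baselines are nearly degenerate
with shallow exponentials at low speed, roughly doubling K_D variance; and
like any nonlinear least-squares estimator, K_D carries an O(σ²)
curvature bias (≈ −5% at 0.005 AU noise on this design, vanishing at
0.001 AU). Neither is a defect of the implementation — fits at several
speeds and the reported σ keep both within the error budget — but
single-scan fits should not be trusted for K_D.

Mass action uses the numerically stable small root
AB = 2·t_A·t_B/(s + √(s² − 4·t_A·t_B)), s = t_A + t_B + K_D. The
subtraction i_AB = (c·i_exp − c_A·i_A − c_B·i_B)/c_AB propagates intensity
σ and concentration uncertainties (from the K_D error through mass action,
by finite differences) in quadrature. Intermolecular structure-factor
effects are neglected throughout, appropriate at the ≤ few mg/mL loadings
the method targets.

## Guinier fitting

Weighted linear least squares of ln I vs q² with σ_lnI = σ/I; points with
I ≤ 0 excluded. The window limit q·Rg ≤ 1.3 depends on the fitted Rg, so
the window iterates to self-consistency (cap 20, widening first if a
noise-positive slope appears on a narrow start window). Parameter errors
are inflated by √χ²_red when χ²_red > 1 — the conservative convention for
possibly misstated σ. The extended fit adds even polynomial terms in q²
(default order 2, i.e. one shape term) over q·Rg ≤ 2.0; on an exact sphere
it recovers Rg to 0.5% where a plain fit on the same wide window errs by
4%. Order 3 is available but overfits anchored windows and is not used by
the pipeline.

## Synthetic test bed

The generator mirrors the reference study conditions: sphere monomer of
radius 35.1 Å (R_g = √(3/5)·R ≈ 27.2 Å), total concentration 2.29 mg/mL,
q-grid 0.010–0.20 Å⁻¹ with 150 log-spaced points, heteroscedastic Gaussian
noise σ(q) = 0.01·I(q) + 10⁻⁴ (typical laboratory SAXS statistics), and an
aggregate table {dimer 4.0%, trimer 1.2%, tetramer 0.7%} = 5.9% total with
decaying weights across four species. The per-j split of the 5.9% is the
package's choice — plausible for a mildly aggregating preparation — and
the Debye bound above q\* is sensitive to it (a pure-dimer 5.9% gives
1.3%, this split 1.9% in the close-packed worst case). The SE generator
uses a 9.5 + 12.5 kDa pair at 20/30/35 krpm and 100/75/50 µM equimolar
loadings on a 6.90–7.15 cm column: a 2.5 mm solution column keeps the
exponential dynamic range within a real absorbance detector's reach, which
a longer column would not at these speeds and masses. Reference
concentrations are normalized by the cell-average exponential factor so
simulated absorbances stay in the 0–1.5 AU working range; any positive
reference pair is a valid model instance, so this biases nothing.

Mixture composition in the generator is a direct weighted sum, while the
analysis side decomposes — the two never share the mixing code path, so
round-trip tests are genuine. What the synthetic bed does *not* emulate:
instrument smearing, buffer-subtraction residuals, inter-particle
interference, concentration-series effects, radiation damage, and real
aggregate geometries beyond the two bracketing models. Recovery numbers on
real data will be correspondingly worse; the test bed establishes
correctness of the decomposition logic and its noise response, not
instrument-level accuracy.

## Known limitations

- Homo-oligomer aggregates only (j ≤ 4 close-packed, j ≤ 8 linear); fibrils,
  amorphous aggregates and hetero-aggregates violate the high-q identity.
- A + B ⇌ AB stoichiometry only; no higher-order or multi-site schemes.
- Weight fractions are trusted as given; errors in the c(s) integration
  propagate directly into t₁ and hence i₁(0).
- The extracted i₁(q) below q_c is model-shaped (Guinier); features there
  (e.g. slight interparticle repulsion) are not recoverable by design.
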