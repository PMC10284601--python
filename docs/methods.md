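# Methods

`oxyhb` analyzes hemoglobin oxygen-equilibrium measurements of the kind
produced by thin-film/tonometric protocols: a hemoglobin solution at a fixed
pH, temperature and effector composition is equilibrated at a handful of
oxygen tensions chosen so that fractional saturation falls between 30 and
70%, and the (PO₂, S) pairs of each series are the raw data. This note
documents the estimators, the forward model used for validation, and the
numerical and design choices behind both.

## Hill-plot estimation of P₅₀ and n₅₀

Each series is linearized to Hill coordinates, y = log₁₀[S/(1−S)] against
x = log₁₀ PO₂, and fitted by ordinary least squares. The slope is the
cooperativity coefficient n₅₀ and the x-intercept, −intercept/slope, is
log₁₀ P₅₀. The fit is unweighted: the logit transform makes the noise
variance depend on S, but within the 30–70% band the induced
heteroscedasticity is mild (the weight would vary by less than a factor of
~1.3), and an unweighted fit is what the Hill-plot protocol implies.

Standard errors are per-fit regression SEs. SE(n₅₀) comes directly from the
OLS covariance; SE(log₁₀ P₅₀) is the first-order (delta-method) propagation
of −a/b through the full 2×2 covariance of (intercept a, slope b),
including their covariance. On the mm Hg scale SE(P₅₀) = ln(10)·P₅₀·SE(log₁₀P₅₀).
These are within-fit precisions, not across-replicate SEMs. Degrees of
freedom are n − 2, so the minimal three-tension series carries one residual
degree of freedom; replicate tensions are kept as independent observations.
P₅₀ outside the measured tension range is allowed but logged as a warning;
a series with a non-positive fitted slope, or all tensions identical, is
rejected as degenerate.

## pH standardization, Bohr coefficient, effector effects

Because P₅₀ depends strongly on pH, per-series estimates are standardized
before comparison: within each (condition, temperature) group, log₁₀ P₅₀ is
regressed on pH (OLS; an inverse-variance-weighted variant is available
behind `weighted_ph_regression`, default off) and the line is evaluated at a
reference pH — 7.20 for adult hemoglobins, 7.10 for embryonic/fetal
isoforms, reflecting the lower pH of prenatal blood. The SE of the
standardized value is the regression-estimate SE
s·sqrt(1/n + (pH−pH̄)²/Sxx), pushed through the 10^x link. Evaluation more
than 0.5 pH units outside the fitted range is logged as an extrapolation
warning but not refused.

The Bohr coefficient φ = ΔlogP₅₀/ΔpH is the slope of the same kind of line
restricted to the inclusive window pH 6.9–7.8, fitted through all points in
the window (not endpoint pairs). Points outside are excluded and counted.

Effector effects are differences of standardized log₁₀ P₅₀ at the reference
pH: DPG effect = logP₅₀(DPG) − logP₅₀(stripped), and likewise for chloride
(0.1 M KCl) and the combined condition. SEs combine the two
regression-estimate SEs in quadrature, treating the condition series as
independent experiments (the protocol gives no shared-preparation
covariance to model). Sub-additivity of the combined effect is expected and
not constrained: the effectors compete for the same allosteric equilibrium.

## van't Hoff enthalpy of oxygenation

The apparent enthalpy between temperatures T₁ < T₂ (default 25 and 37 °C) is

    ΔH = 2.303·R·(log₁₀P₅₀(T₁) − log₁₀P₅₀(T₂)) / (1/T₁ − 1/T₂)

in kJ mol⁻¹ O₂, with R = 8.314 J mol⁻¹ K⁻¹ and the standardized P₅₀ of each
temperature. The orientation pairs (T₁-minus-T₂) in both numerator terms, the
unique reading of the isochore that yields ΔH < 0 (exothermic) whenever P₅₀
rises with temperature — the normal hemoglobin behaviour. The conventional
rounded factor 2.303 is kept rather than ln 10; the difference is 0.02%.

Because P₅₀ is measured as a gas tension, the raw estimate includes the
exothermic heat of dissolving O₂ in water. The overall enthalpy ΔH′ adds
back the solubilization heat, +12.55 kJ mol⁻¹ O₂, moving values toward less
exothermic. The constant (and its sign, via the config value) is
configurable because conventions differ across the literature; the default
produces the sign structure universally reported for mammalian hemoglobins.
ΔH′ is reported at the reference pH per condition; for stripped hemoglobin
an additional evaluation at pH 7.8 is natural, where oxygenation-linked
proton binding is minimal and ΔH′ isolates the intrinsic heme + conformational
contributions. SE(ΔH) propagates the two prediction SEs on the log scale
through the isochore's linear form.

## Solubility analysis

Ammonium-sulfate series are normalized to each sample's own 0 M control, so
percent precipitated at molarity M is 100·(1 − signal(M)/signal(0)); values
at unmeasured molarities are linearly interpolated between bracketing
points, and small negative percentages (signal above control, i.e. read
noise) are clamped to zero and logged. Requests outside the measured range
are refused rather than extrapolated. The whole curve is summarized by a
two-parameter logistic soluble fraction 1/(1+exp((M−midpoint)/slope)),
fitted by least squares (`scipy.optimize.curve_fit`, midpoint initialized
at the first half-precipitation crossing, bounds [0, 20] M × [1e-4, 5]).
A fitted midpoint beyond the highest measured molarity is flagged "no
transition observed". Everything is relative — absolute extinction
coefficients are out of scope — so all outputs are invariant to rescaling
the signal column.

## The two-state forward simulator

Validation is closed-loop: a Monod–Wyman–Changeux (MWC) two-state model with
oxygenation-linked effector binding generates synthetic campaigns with known
ground truth, and the pipeline must recover that truth. The tetramer
switches between T and R quaternary states; saturation is

    Y = [α(1+α)³ + L_eff·c·α(1+cα)³] / [(1+α)⁴ + L_eff(1+cα)⁴]

with α = PO₂/kR, c = kR/kT. Heterotropic effectors act purely through the
allosteric constant:

    L_eff = L0 · Π_e [(1 + [e]/K_T,e)/(1 + [e]/K_R,e)]^m_e

over protons ([H⁺] = 10^−pH against K = 10^−pKa per Bohr group), chloride
and DPG. State-dependent binding with K_T < K_R stabilizes the deoxy (T)
conformation and lowers affinity — the mechanism of the Bohr, chloride and
DPG effects — and equalizing K_T = K_R (the β82 binding-site-deletion
analogue) makes the effector exactly inert. Direct modulation of kR/kT by
effectors is deliberately omitted: the pure-L structure is the simplest one
reproducing every measured phenomenon.

Every equilibrium carries a van't Hoff enthalpy. Dissociation constants
scale as K(T) = K(t_ref)·exp[(ΔH/R)(1/T − 1/t_ref)] with t_ref = 310.15 K,
so exothermic binding (ΔH < 0) weakens on warming; L, being the R→T
equilibrium constant, scales with −ΔH^(T→R). Defaults: ΔH^(O₂) = −59
kJ mol⁻¹ (heme oxygenation), all other heats zero, so the stripped model's
apparent gas-phase enthalpy is −59 and its ΔH′ is −59 + 12.55 — a closed-form
limit used as a test anchor. A large positive ΔH^(T→R) or exothermic T-state
effector binding raises ΔH′ toward zero, which is exactly the mechanism by
which cold-tolerant hemoglobins reduce thermal sensitivity; the strict
monotone version of this statement holds for T-state-only binding at
sub-saturating effector concentrations (with appreciable R-state binding, or
at extreme L, the oxygenation-linked release — and hence its heat — plateaus
and recedes).

Default site counts are 1 DPG site, 4 chloride sites and 2 Bohr groups per
tetramer; recovery tests randomize them, so pipeline correctness does not
depend on these choices. True P₅₀ is the bisection root of Y = 1/2 on
[10⁻⁶, 10⁴] mm Hg (relative tolerance 10⁻⁹); the true Hill slope is the
centered finite difference of the log-odds at P₅₀ with Δlog₁₀PO₂ = 10⁻⁴;
the true Bohr slope is a centered finite difference in pH at 7.35 ± 0.05.

### Experiment emulation

A simulated series places its target saturations evenly strictly inside the
30–70% band (k = 3–5 tensions, default 4), inverts the exact saturation
curve for the tensions, and adds Gaussian read noise to the saturations
(σ = 0.005 by default — consistent with per-fit relative SEs under 3%, the
precision thin-film measurements report). Draws outside (0.01, 0.99) are
redrawn, not clamped, so the logit stays finite without biasing the bulk of
the distribution. All randomness flows through one seeded
`numpy.random.Generator`; fixed seeds give bit-identical series. The
Gaussian-on-saturation choice is ours — the protocol specifies no noise
model — and is isolated behind the generator interface.

### Calibration to published summaries

`calibrate_to_targets` adjusts a chosen subset of parameters so the model's
*true* summaries (P₅₀ under stated conditions, ΔH′ between two
temperatures, Bohr slope) match published values, by bounded least squares
over log-transformed positive parameters with a deterministic seeded
multi-start. Residuals are log-relative for P₅₀ and scaled-absolute for
ΔH′ (per 5 kJ) and Bohr (per 0.05); the result is verified to 0.5% / 0.5 kJ
and a failure raises with the worst residual. The preset library calibrates
sirenian phenotypes this way: Steller's sea cow HbA (DPG-blind via equalized
DPG constants, stripped 8.8 / combined 14.3 mm Hg, ΔH′ targets −34.2
stripped at pH 7.8 and −18.8 with effectors — met with a positive T→R heat
≈ +46 kJ and strongly exothermic chloride binding ≈ −73 kJ, the model's
expression of an intrinsically temperature-insensitive protein), manatee,
dugong and ancestral-dugongid HbA (three P₅₀ targets each, reconstructing
the DPG-only target from the published stripped value and DPG effect), and
embryonic Hb Gower I (combined 3.1 mm Hg at pH 7.1 from a low-L0,
low-cooperativity base).

## What the synthetic data does and does not show

The emulator reproduces the statistical structure the analysis assumes:
protocol tension placement, independent Gaussian saturation noise, separate
series per condition and temperature. It does not emulate instrument drift,
met-hemoglobin formation, pH electrode error, shared-preparation
correlations between conditions, or deviations from two-state allostery
(e.g. chain heterogeneity). Passing recovery tests therefore demonstrates
that the estimators are correct and precise under the stated protocol, not
that real measurements are free of those systematics. One visible
consequence inside the simulator itself: the true logP₅₀–pH relation is
slightly curved, so pH-regression SEs on simulated campaigns absorb a small
lack-of-fit component beyond pure read noise, and the fitted Hill slope is
a band-averaged secant that sits within about 1% of the tangent
cooperativity at half saturation.

## Problem sizes and determinism

The package's own validation runs at desk scale, chosen to exercise the
protocol rather than to stress hardware: 100-series batches for the
Hill-quality statistics, four-pH campaigns (16 series of 4 points) per
recovery target, 1000-draw oracle comparisons for the saturation function,
and a 100-replicate bootstrap for the ratio-SE check. Every stochastic test
and script fixes its seeds; re-running with the same inputs, configuration
and seeds reproduces outputs bit-identically, and each summary records a
hash of the configuration it was produced under.

## Known limitations

* No Adair or tertiary-two-state fitting of experimental curves; the Hill
  linearization is the only experimental estimator, as in the protocol the
  package targets.
* Effector binding constants are not inferred from measured effects; they
  exist only as simulator ground truth.
* The ΔH′ decomposition into conformational/effector components is likewise
  a property of the simulator, not an output of the experimental analysis.
* The solubilization-correction direction is a convention (+12.55 toward
  less exothermic); the constant is configurable for users following the
  opposite sign convention.
* Bohr coefficients are fitted linearly over pH 6.9–7.8; pKa-resolved
  (nonlinear) Bohr analysis of experimental data is out of scope.
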