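# Methods

This note records the models implemented in `dmcycle`, the conventions
and parameter choices behind them, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Thermodynamic conventions

All energies are kJ mol⁻¹, association constants M⁻¹, temperatures K;
unit conversion happens only at I/O boundaries. The working identities
are ΔG° = −RT ln K and TΔS° = ΔH° + RT ln K, with R = 8.314 J mol⁻¹ K⁻¹
and a default T = 298.0 K (RT ≈ 2.478 kJ mol⁻¹). ΔG° and TΔS° are
always derived from (K, ΔH°), never stored, so ΔG° = ΔH° − TΔS° holds
identically.

Quoted `±` values are treated as independent Gaussian standard errors
(1σ) and combined in quadrature. Experimental reports rarely say
whether a `±` is a standard error or a fit confidence interval; the 1σ
reading is the conservative common denominator, and every quadrature
formula in the package is cross-checked against Monte-Carlo resampling
in the test suite. Rounded table output displays integer kJ mol⁻¹ with
σ rounded up; full precision is retained internally and in JSON.

## ITC model

Heats are modelled per injection. After injection *i* of volume *vᵢ*
into active volume V₀, existing concentrations are diluted by
(1 − vᵢ/V₀) — the perfusion-displacement convention of commercial
instruments — and the syringe concentration adds vᵢ/V₀·[G]_syr. The
bound concentration is the Wiseman root of the 1:1 mass-balance
quadratic, evaluated in the cancellation-safe form 2HG/(b + √(b²−4HG));
the molar heat of injection *i* is ΔH°·V₀·([HG]ᵢ − [HG]ᵢ₋₁(1−vᵢ/V₀))
per mole of injected guest, plus a constant baseline representing
dilution heat. Energy conservation therefore reads
Σ qᵢ·nᵢ = ΔH°·V₀·([HG]_N + Σ [HG]ᵢ₋₁ vᵢ/V₀): the second term is the
complex carried out of the active volume by displacement, and the test
suite asserts this identity (the displacement-free form
Σ qᵢ·nᵢ = ΔH°·V₀·[HG]_N is only approximate once cumulative injection
reaches a few percent of V₀).

Fitting minimises squared residuals over (log₁₀K, ΔH°, n, baseline)
with Levenberg–Marquardt, seeded by a coarse grid on log₁₀K (ΔH° and
baseline are linear given K and n, so each grid point is a 2×2 least
squares). Parameter sigmas come from the Gauss–Newton covariance
(JᵀJ)⁻¹·SSR/(N−p). Stoichiometry can be fixed at 1 (`constrain_n`),
and injection 1 can be excluded from the objective (`discard_first`,
off by default) without altering the modelled dilution history. The
default experiment programme is 30 × 10 µL into 1.4 mL (the standard
active volume of a VP-type microcalorimeter; the source experiments do
not state it) at 0.28 mM syringe / 0.04 mM cell.

K is flagged unreliable outside the c-value window [1, 10⁴]
(c = n·K·[H]_cell). The window is deliberately stricter than the
regime where K becomes strictly unmeasurable (c > 10⁶); it is
configurable. In the step regime the fit still recovers ΔH° (the step
height) to better than 2 %, which is exactly how tight binders are
handled in practice: enthalpy by ITC, affinity by competition.

## NMR competition and the affinity ladder

In slow exchange, concentration ∝ integral / protons-per-signal, so the
guest-exchange constant K_exch = [HG₂][G₁]/([HG₁][G₂]) is computed
directly from one spectrum and is invariant to spectrometer gain and to
the absolute concentration scale. Across a titration series the
reported value is the unweighted mean ± sd of per-spectrum values. The
direction convention makes K_exch > 1 mean the second guest binds more
strongly: K(HG₂) = K_exch·K(HG₁). Free host is assumed negligible
(both experiments and the generator operate at host saturation); the
host mass balance fixes the absolute scale when totals are supplied,
and guest mass balances are validated to 5 % relative. A spectrum is
rejected when the minor complex holds < 5 % of bound host
(`dynamic_range_check`): below that, integration error dominates.

The ladder solves min Σ 1/σ_e²·(x_j − x_i − r_e)² + Σ 1/σ_a²·(x_a − v_a)²
over per-complex log₁₀ K, i.e. weighted least squares on the
measurement graph with anchors as priors; node sigmas come from the
inverse normal matrix. On a tree this reduces exactly to multiplying
ratios along paths. Because quoted sigmas may or may not include the
reference value's uncertainty, both are reported: the full sigma and an
anchor-free sigma (anchor variance subtracted in quadrature).
Redundant cycles whose signed ratio sum exceeds 3σ trigger a warning
naming the cycle; nodes not connected to any anchor are an error naming
the node.

## Double mutant cycle

ΔΔ = Δ_A − Δ_B − Δ_C + Δ_D for G, H or TS, with quadrature sigma.
A carries both interaction partners, B and C delete one each, D both;
validation enforces that A/C share the unmutated host, B/D the mutated
host, A/B the full guest, C/D the truncated guest, and that all four
share solvent and temperature. The sign convention (the printed form of
the source's cycle equation is not machine-readable) is verified
constructively: a generator that injects an interaction term into
complex A alone gets exactly that term back, with attractive
interactions negative. Note the cycle algebra is symmetric under
exchanging the two single-mutant complexes (B ↔ C) and changes sign
when both mutation directions are reversed.

## LFER and solvation decomposition

* Hammett: unweighted OLS (the source figures show unweighted fits; a
  per-point weights option exists but is off by default) of ΔΔG° on σ_m,
  or of log K on σ_p for the H-bond effect on the reference-guest end.
  Standard errors from the usual residual-variance formulas; verified
  to 10⁻¹⁰ against statsmodels.
* The chloroform predictor is the fitted line −7.4 − 11.7·σ_m kJ mol⁻¹.
  On the packaged table it has RMSE 1.04 kJ mol⁻¹ with residuals up to
  2.5 kJ mol⁻¹ (NMe₂) — the fidelity its R² = 0.88 implies.
* Non-polar transfer line: OLS of the water−chloroform difference on
  the PhX water→n-hexadecane transfer free energy, restricted to the
  non-polar class {H, Me, Et, iPr, F, Cl, Br}. CF₃ is classed
  non-polar (β = 0) but carries no packaged transfer value and is
  dropped from this fit with a by-name warning (`strict=True` raises
  instead).
* Resolvation energy of a polar substituent = observed difference minus
  the non-polar line's prediction at its transfer free energy
  (negative = extra aqueous stabilisation), compared against
  −α_S·β_X with α_S = 2.8.
* Composite aqueous predictor: Hammett term + transfer-line term −
  α_S·β_X. The line coefficients default to the fitted (1.1, 13.7) so
  the predictor works without refitting; a refit is one call away.
* Diagnostics: RMSE, entropy–enthalpy compensation (OLS of TΔS° on
  ΔH°), and the burial heuristic −0.15 kJ mol⁻¹ Å⁻² × buried area.

### Parameter provenance

σ_m and σ_p ship from the canonical Hammett compilation. β_X (H-bond
acceptor parameters on the α/β scale where water has α_S = 2.8) and the
PhX transfer free energies are literature-derived **approximations**
assembled for this package — they are not values from the study that
produced the packaged ΔΔG° table, whose exact inputs are not printed.
Loading them emits a `ProvenanceWarning`, every row carries a
provenance note, and all checks that depend on them are held at the
property level (transfer-line slope within [0.9, 1.3], every polar
resolvation negative, composite RMSE ≈ 2 kJ mol⁻¹) rather than asserted
as exact reproductions.

## Synthetic-data generator

The generator emulates a 4-host × 14-guest design: full and mutant
hosts in water and chloroform, 13 substituted aryl guests plus one
reference guest. Ground truth is additive —
ΔG° = host term + guest term (+ 2.854·σ_p H-bond term for aryl guests
in chloroform, equivalent to log K_B = −0.5σ_p + const; the effect
cancels in water) (+ interaction term for A-type complexes) — so the
DMC recovers the injected interaction exactly at zero noise. The
interaction term follows the Hammett model in chloroform and the
composite model in water. Enthalpies follow
ΔH° = 0.9·ΔG° − 5 + N(0, 2), giving entropy–enthalpy compensation with
slope ≈ 0.9. Host/guest base terms were chosen once so that the
resulting K values reproduce the study's measurement split: all
aqueous A-type complexes exceed the calorimetric window (K up to
~10¹², sub-picomolar K_d) and route to the NMR ladder, while B/C/D (and
the weaker chloroform A complexes) are ITC-measurable.

Noise model: additive Gaussian heat noise (default 1 % of |ΔH°|),
multiplicative lognormal integral noise (default 2 %), Gaussian
measurement-level ΔG°/ΔH° noise (default 0.5 kJ mol⁻¹ — a ±1 kJ mol⁻¹
four-complex cycle implies ~0.5 per complex) and an anchor sigma of
0.02 log units. Reproducibility: one root seed; each artefact draws
from `default_rng([seed, crc32(label)...])`, so generating one dataset
never perturbs another and every artefact is bit-reproducible.

Instrument-route studies pick, per complex, ITC (auto-ranging the cell
concentration toward c ≈ 50 within instrument-sensible bounds
[5 µM, 5 mM] when the default programme would leave the window — the
in-silico analogue of an experimentalist adjusting concentrations) or
the competition ladder (every A complex is a rung, anchored at a
calibrated reference in water and at the ITC-measured reference-guest
complex in chloroform). Competition concentrations are adapted to the
true affinity gap so both complexes stay observable, as a chemist would
arrange iteratively.

What the generator does **not** emulate: baseline drift and
first-injection artefacts beyond a constant offset, heat-capacity
effects, active-site titration errors (n ≠ 1), NMR peak overlap and
phasing error, fast or intermediate exchange, host aggregation, and
non-1:1 stoichiometries. Passing recovery tests therefore demonstrate
the statistical machinery is unbiased and its uncertainties calibrated
under these idealised conditions — not that real data are free of the
systematic effects above.

## Statistical calibration checks

The seeded benchmarks (`dmcycle.validation`) use fixed problem sizes
chosen to give stable statistics: 200 ITC titrations with c log-uniform
in [5, 500] (observed median relative errors ≈ 3.5 % for K, ≈ 0.6 % for
ΔH° at 1 % heat noise), 500 random ladders of ≤ 8 complexes (3σ
coverage ≈ 99 %), and 200 full instrument-route studies. For the
end-to-end check the injected chloroform Hammett slope should fall in
the regression's 95 % CI at nominal frequency; since a perfectly
calibrated CI covers 190/200 only about half the time, the assertion is
a one-sided 5 % binomial test of nominal coverage (observed 189/200 =
94.5 % with the fixed seed block).

## Numerical choices

* Competitive equilibria solve the host mass balance by bracketed
  Brent root finding on free host (the balance is strictly increasing
  in H) plus Newton polish; residuals < 10⁻¹² relative.
* The Wiseman root uses the multiplied-out form to avoid cancellation
  at K·H ≫ 1; discriminants more negative than rounding error are an
  internal error.
* OLS is closed-form normal equations; an all-identical descriptor
  vector is a singular-design error; R² is defined as 1 when the
  response is exactly constant and exactly reproduced.
* Measurement CSVs round-trip byte-identically (floats parsed with
  round-trip precision, written in shortest-repr form); unknown columns
  pass through untouched, unknown units are row-addressed errors.

## Limitations

Single-site 1:1 binding only; no ΔCp or temperature dependence; no
activity corrections; no raw-thermogram peak integration (inputs are
per-injection heats); no spectral processing; multi-parameter solvation models beyond the composite predictor are
out of scope. The composite aqueous predictor inherits the approximate
provenance of β_X and the transfer free energies and should be read at
the ±2 kJ mol⁻¹ level.
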