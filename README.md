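# oxyhb

Analysis of hemoglobin oxygen-equilibrium and solubility measurements, with
a two-state allosteric simulator for closed-loop validation.

Comparative physiologists characterize a hemoglobin by equilibrating it at a
few oxygen tensions chosen to give 30–70% saturation, under varied pH,
temperature, chloride and 2,3-diphosphoglycerate (DPG) conditions. `oxyhb`
turns those tabulated (PO₂, saturation) series into the standard functional
summaries:

* **P₅₀ and n₅₀** from Hill plots: OLS of log₁₀[S/(1−S)] on log₁₀PO₂ gives
  the cooperativity n₅₀ (slope) and log₁₀P₅₀ (x-intercept), with
  delta-method standard errors from the coefficient covariance.
* **pH-standardized P₅₀** by regressing log₁₀P₅₀ on pH per condition and
  interpolating at a reference pH (7.20 adult, 7.10 prenatal isoforms), and
  the **Bohr coefficient** φ = ΔlogP₅₀/ΔpH over pH 6.9–7.8.
* **Effector effects** as differences of standardized log₁₀P₅₀:
  e.g. DPG effect = logP₅₀^(DPG) − logP₅₀^(stripped).
* **Thermal sensitivity** via the van't Hoff isochore between 25 and 37 °C,
  ΔH = 2.303·R·ΔlogP₅₀·(1/T₁ − 1/T₂)⁻¹, corrected for the heat of O₂
  solubilization (+12.55 kJ mol⁻¹ O₂) to give the overall enthalpy ΔH′.
* **Relative solubility** from ammonium-sulfate precipitation series
  (percent precipitated at 3 M; logistic salting-out midpoint).

Validation is closed-loop: a Monod–Wyman–Changeux two-state forward model
(Y = [α(1+α)³ + Lcα(1+cα)³]/[(1+α)⁴ + L(1+cα)⁴], with oxygenation-linked
H⁺/Cl⁻/DPG binding acting through L and per-equilibrium van't Hoff
enthalpies) generates synthetic measurement campaigns with known ground
truth, including presets calibrated to published sirenian hemoglobin
phenotypes — among them the DPG-insensitive, thermally buffered hemoglobin
of the extinct Steller's sea cow. See `docs/methods.md` for the model and
estimator details.

## Worked example

Simulate a measurement campaign for the manatee-HbA preset (4 conditions ×
2 temperatures × 4 pH values, 4 tensions each) and analyze it:

```
$ oxyhb simulate --preset manatee-hba --out manatee.csv --seed 11
$ oxyhb report manatee.csv --out-dir out
$ oxyhb recover --preset manatee-hba --seed 11
condition   true P50   est P50  true n50  est n50
stripped       5.400     5.465     3.311    3.366
KCl            7.873     7.938     3.152    3.140
DPG            7.454     7.530     3.181    3.167
KCl+DPG       10.900    10.982     2.945    2.879
```

`recover` prints the simulator's exact standardized values next to the
pipeline's estimates at pH 7.2, 37 °C: the stripped P₅₀ of 5.4 mm Hg and
the combined KCl+DPG value of 10.9 mm Hg are recovered within about 1%
under protocol noise (σ = 0.005 on saturation). `out/summary.csv` holds one
row per (condition, temperature) with P₅₀ ± SE, n₅₀ ± SE, Bohr coefficient,
effector effects (here the DPG effect comes out as 0.139 ± 0.006 against a
ground truth of 0.140), ΔH raw and corrected, all with full provenance in
`out/summary.json`.

The same machinery is available as a library:

```python
from oxyhb import fit_hill, summarize_series, simulate_protocol
from oxyhb.presets import steller_hba_params

series = simulate_protocol(steller_hba_params(), "hgigas",
                           ph_values=[6.9, 7.2, 7.5, 7.8], seed=7)
(summary,) = summarize_series(series)
print(summary.conditions[("stripped", 37.0)].p50)  # ~8.8 mm Hg
```

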