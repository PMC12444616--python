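# cubioleach

Process model and sustainability toolkit for copper bioleaching of shredded
printed-circuit-board (PCB) powder in a fixed-bed column coupled to a stirred
bioreactor.

Waste PCBs carry ~20–25% w/w Cu as metallic copper, which ferric iron
dissolves chemically while an iron-oxidizing culture (*Acidithiobacillus
ferrooxidans*) regenerates the oxidant:

    Cu(0) + 2 Fe³⁺  →  Cu²⁺ + 2 Fe²⁺        (column, chemical)
    Fe²⁺ + ¼ O₂ + H⁺  →  Fe³⁺ + ½ H₂O       (bioreactor, microbial)

The package implements, as a tested library plus CLI:

- **Column model** — the packed bed as a well-mixed compartment (optional
  tanks-in-series), with volumetric dissolution rate
  `r = k (Cu⁰ − Cu²⁺) Fe³⁺` and CSTR flow terms `(Q/V)(C_in − C)`; the
  leachable solid Cu inventory is an explicit depleting state.
- **Coupled loop** — the bioreactor (Monod growth on Fe²⁺ with quadratic
  Fe³⁺/Cu²⁺ toxicity, discrete dilution update through the residual volume
  `V_rim = V − QΔt`) exchanging solution with the column every Δt = 0.1 min,
  with a trigger-driven schedule engine (medium replacement, flow changes,
  metabolic-rate and Fe²⁺ = Fe³⁺ crossing triggers).
- **Calibration** — `ColumnLeachModel(data, …).fit()` estimates the rate
  constant k from outflow time series by joint least squares over
  Cu²⁺/Fe³⁺/Fe²⁺, with confidence half-widths and per-species R².
- **Energy & carbon footprint** — stirred-tank vs pump energy demand and a
  Monte Carlo global-warming assessment (inventory per 1 L of bioreactor,
  characterization factors with 10% uncertainty, avoided-burden credits for
  recovered Cu and Zn). The shipped factor table is an explicitly labelled
  synthetic placeholder: only structure (shares, signs, monotonicity) is
  meaningful with it.
- **Synthetic data** — noisy outflow series, schedules and the placeholder
  factor table, so the whole pipeline runs offline.

## Worked example

```sh
$ cubioleach column --flow-ml-min 5 --duration-h 38
extracted 47.0 g Cu | efficiency 92.9% | rate 1.24 g/h | outflow -> column_outflow.csv
```

A 38 h chemical leaching run at 5 mL/min with a ~10 g/L ferric feed through
the 200 g PCB column (50.6 g leachable Cu) extracts 47 g of Cu — 92.9% of the
inventory — at an average 1.24 g/h, with the characteristic mid-run Cu
outflow plateau near 4 g/L.

```sh
$ cubioleach bioleach --scenario sim2
sim2: 164.2 h simulated | final efficiency 95.8% | 95% reached at 161.0 h (6.71 d) | ...
```

The two shipped operating scenarios compare a clock-driven baseline (48 h
growth, 5 mL/min, one 80% medium replacement) with a trigger-driven redesign
(recirculation from the metabolic-rate peak at ~20 h, progressive flow
halving, 65% replacement, flow doubling at the Fe²⁺ = Fe³⁺ crossing). Under
the shipped calibrated defaults the baseline reaches 95% Cu extraction in
7.13 days and the redesign in 6.71 days.

From Python:

```python
import cubioleach as cb

model = cb.ColumnLeachModel(series_df, cb.default_geometry(),
                            cb.InflowProgram.ferric_feed(10.0), q_ml_min=25.0)
result = model.fit()
print(result.summary())        # k estimate, 95% CI, per-species R²
```

## Scope notes

Kinetic and biological parameters for this feedstock/strain are not publicly
documented; the shipped defaults are calibrated stand-ins (marked as such)
that reproduce the qualitative process milestones. Absolute carbon-footprint
values require a licensed characterization-factor database and are out of
scope. See `docs/methods.md` for the model equations, assumptions, parameter
rationale and known limitations.
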