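# qpop

Combinatorial drug-screen design and analysis: construct a compact
orthogonal-array composite design (OACD) for an n-drug panel, fit a
second-order polynomial viability surface to the readouts, exhaustively
rank every k-drug combination from the fitted surface, and run follow-up
pharmacodynamics (4PL dose-response / IC50 fitting, median-effect analysis,
Chou–Talalay combination indices, two-drug response-surface maps).

A synthetic-data module generates viability datasets with known ground
truth (quadratic surfaces; two-drug Hill systems with a tunable Loewe
interaction parameter), so the whole pipeline is testable end to end
without experimental data. The bundled 11-drug panel is a synthetic
fixture — drug names echo a T-cell-lymphoma screening context, but all
concentrations are invented.

## Layout

| module | contents |
| --- | --- |
| `qpop.panel` | `Drug`, `DrugPanel`, `DoseVector`, `DesignTable`; `build_oacd`, `validate_design`, coded/concentration mapping |
| `qpop.surface` | `QuadraticSurface`; `fit_surface` (OLS, optional ridge), `predict_viability` |
| `qpop.ranking` | `enumerate_combinations`, `rank_combinations`, `locate_regimen`, `top_combinations` |
| `qpop.pharmacodynamics` | `fit_4pl`, `fit_median_effect`, `combination_index`, `response_surface_map` |
| `qpop.synthetic` | `SurfaceTruth`, `HillComboTruth`, `simulate_screen`, `simulate_combo_series`, fixtures |
| `qpop.io` / `qpop.pipeline` / `qpop.cli` | CSV schemas with provenance headers, full-pipeline runner, `qpop` CLI |

Key conventions:

* Doses are **coded levels** `0..L` (0 = vehicle). On the regression scale
  the vehicle is the origin (the intercept is the predicted all-vehicle
  viability) and the two non-zero levels map to −1/+1.
* A "combination" is a drug subset plus one non-zero level per member:
  an 11-drug, 2-level panel has C(11,5)·2⁵ = 14,784 five-drug and
  C(11,3)·2³ = 1,320 three-drug combinations.
* Rankings are ascending in predicted viability (rank 1 = most
  efficacious); ties keep enumeration order, so ranks are deterministic.
* Combination index: CI = Σ dᵢ/Dᵢ(fa) (mutually-exclusive / Loewe form;
  CI < 1 synergy). The sham self-combination identity CI ≡ 1 holds to
  machine precision.

## CLI

```bash
qpop simulate panel --out panel.csv               # synthetic fixture panel
qpop design --panel panel.csv --out design.csv    # OACD (OA ⊕ axial ⊕ center)
qpop validate-design --panel panel.csv --design design.csv
qpop simulate screen --truth truth.csv --panel panel.csv \
     --design design.csv --noise 0.05 --seed 1 --out readout.csv
qpop fit-surface --panel panel.csv --design readout.csv --out surface.csv
qpop rank --surface surface.csv --panel panel.csv -k 3 \
     --regimens regimens.csv --out ranking.csv
qpop fit-dr --data dr.csv --out curves.json
qpop simulate combo --alpha 0.5 --out combo.csv
qpop ci --single combo_singles.csv --combo combo.csv --out ci.csv
qpop surface-map --surface surface.csv --panel panel.csv \
     --pair bortezomib panobinostat --res 25 --out grid.csv --png map.png
qpop run --config config.yaml                     # full pipeline
```

`qpop run` reads a flat YAML config (`panel`, `readout` or
`truth_surface`+`noise_sd`, `k`, `regimens`, `out_dir`, `seed`, ...) and
writes the design, fitted surface, complete rankings, regimen lookups and
a human-readable summary, all with provenance headers. Exit codes: 0 ok,
2 schema/validation, 3 fit failure, 4 design/estimability failure.

## Notes on the design generator

`build_oacd` concatenates a two-level orthogonal array over the non-zero
levels, axial runs (each drug alone at each level) and vehicle-control
center runs. `--oa-strength` selects the array family: 2 =
Plackett–Burman/Hadamard screening array, 3 = its fold-over, 4 (default) =
a regular resolution-V fraction from a machine-verified generator
catalogue (up to 11 drugs, 128 OA runs), which makes the full quadratic
model — including all pairwise interactions — estimable. User-supplied
design tables are accepted verbatim by every downstream stage;
`validate_design` reports level coverage, OA orthogonality and model-matrix
rank either way.
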