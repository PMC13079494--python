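# pfasquant

Targeted LC-MS/MS monitoring of per-/polyfluoroalkyl substances (PFAS) in
influent wastewater: internal-standard quantification, detection-limit
determination, method validation, wastewater-based-epidemiology (WBE) mass
loads, and environmental risk quotients — as one tested, reusable pipeline.

## Who this is for

Analytical chemists and environmental scientists running multi-residue PFAS
panels (here: 35 targets across sulfonic acids, carboxylic acids, their
precursors, phosphonic/phosphinic acids and novel ethers such as Gen X,
ADONA and 9ClPF₃ONS) by multiple-reaction-monitoring (MRM) tandem MS, who
need the downstream arithmetic — from integrated peak areas to risk bands —
to be explicit, unit-safe and reproducible. The pipeline starts at
integrated peak tables; it does no chromatogram processing.

## The model

Quantification uses the analyte/ISTD response ratio against a least-squares
calibration line, with back-calculation `c = (A_quant/A_ISTD − b)/m`.
Identification requires a quantifier trace and (where available) a
qualifier trace whose area ratio stays within ±40 % of the band mean.

Limits and validation metrics:

- **IQL** (instrumental quantification limit): lowest calibration level at
  which a strict majority of replicate injections has quantifier S/N ≥ 10
  and qualifier S/N ≥ 3.3; **IDL = IQL × 0.33** (the 3.3/10 S/N ratio).
- **MQL = IQL[ng/L] × 100 / (Recovery[%] × Cf)** with concentration factor
  Cf = 100 for influent wastewater; MDL likewise from IDL.
- **Accuracy (%) = C_exp/C_theo × 100**, **Precision** = %RSD,
  **Recovery (%) = (C_ss − C_us)/C_theo × 100** (native background
  subtracted; values < 0 or > 100 are reported as computed).
- Classification: quantitative for accuracy 50–120 % and precision < 30 %,
  semi-quantitative for accuracy 30–50 % or precision 30–50 %, else
  qualitative; single-transition compounds can be capped per analyte.

WBE and risk, per analyte and sampling day (censored days contribute 0):

    DL [mg/day] = C [mg/L] × V [L/day]
    PNDL [µg/day/1000 inh] = DL/P × 1000
    RQ = MEC / (lowest freshwater PNEC × dilution)

with risk bands low (RQ < 0.1), medium (0.1 ≤ RQ < 1), high (RQ ≥ 1).

The published target list, MRM transitions, instrument/method performance
tables, PNEC registry and the three-day influent campaign ship as CSV
fixtures in `pfasquant/data/`; site flow/population records are a synthetic
stand-in (`site_days_synthetic.csv`). A synthetic campaign generator
(`pfasquant.simulate`) produces full injection tables with known ground
truth so every stage is testable end to end.

## Worked example

```bash
pfasquant report
```

prints the packaged three-day campaign summary:

```
analyte            freq  cumulative conc (ng/L)
PFBS                  2  43.9 ± 13.5
PFOA                  3  8.5 ± 0.7
8:2 diPAP             3  198.1 ± 109.1
PFOPA                 3  85.5 ± 23.1
PFDPA                 3  92.9 ± 28.4
...
headline risk quotients (max single-day MEC):
PFDA               RQ 0.13 (medium)
8:2 diPAP          RQ 2.4 (high)
PFOPA              RQ 0.0057 (low)
PFDPA              RQ 0.22 (medium)
```

`freq` counts days the compound was seen (a < LOQ day counts, < LOD does
not); cumulative concentration sums detected days with ± the across-day
standard deviation. The headline risk quotient uses each compound's
maximum single-day concentration against its lowest freshwater PNEC — the
8:2 diPAP value of 2.4 means its day-1 influent concentration exceeds the
no-effect concentration even before any dilution into receiving water
(`--dilution 10` shows the usual tenfold-dilution scenario, which drops it
to 0.24, medium).

Other entry points: `pfasquant simulate` (synthetic campaign with ground
truth), `pfasquant run-all` (simulate → calibrate → limits → validate →
loads → risk, writing all report CSVs plus a manifest), `pfasquant limits`,
`pfasquant loads`, `pfasquant risk`.

From Python:

```python
import pfasquant as pq
from pfasquant.registry import packaged_influent_days, packaged_pnec_registry

results = pq.assess_campaign(packaged_influent_days(), packaged_pnec_registry())
```

## Layout

- `src/pfasquant/model.py` — domain types, unit conventions
- `src/pfasquant/units.py` — exact decimal unit conversion
- `src/pfasquant/registry.py` — analyte/PNEC/site registries + packaged data
- `src/pfasquant/simulate.py` — synthetic campaign generator
- `src/pfasquant/calibration.py` — calibration, back-calculation, ion ratios
- `src/pfasquant/limits.py` — IQL/IDL and MQL/MDL
- `src/pfasquant/validation.py` — accuracy/precision/recovery, classification
- `src/pfasquant/loads.py` — censoring, detection frequency, DL/PNDL
- `src/pfasquant/risk.py` — risk quotients and bands
- `src/pfasquant/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the methods note (assumptions, parameter
defaults, numerical choices, known limitations).
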