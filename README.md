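# bogflux

Chamber and eddy-covariance (EC) CO₂ flux processing for patterned
peatlands: from raw closed-chamber concentration traces through empirical
flux models, chamber↔EC comparison, daily source-contribution partitioning,
and annual carbon / greenhouse-gas balances.  The package ships a synthetic
data generator that emulates the statistical structure of a two-site bog
study (an open, fully rewetted site and a birch-encroached site), so the
entire pipeline is testable without field data.

All fluxes use the atmospheric sign convention (negative = ecosystem
uptake; `NEE = GPP + Reco` with `GPP ≤ 0`, `Reco ≥ 0`).

## Modules

| module                | role |
|-----------------------|------|
| `bogflux.synthetic`   | drivers, true per-microform fluxes, EC series, 1 Hz chamber traces |
| `bogflux.chamber`     | moving-window OLS flux computation, minimal detectable flux, QC, GPP derivation |
| `bogflux.models`      | Lloyd-Taylor respiration and rectangular-hyperbola light-response fitting; daily reconstruction |
| `bogflux.pairing`     | hummock–hollow composite assembly, EC matching, method-comparison regression |
| `bogflux.partition`   | daily EC GPP/Reco attribution to microforms and trees; annual contributions |
| `bogflux.balances`    | carbon and GHG balances with quadrature error propagation (GWP 27 for CH₄) |
| `bogflux.tables`      | packaged annual-balance table fixtures and their cell-by-cell validation |
| `bogflux.pipeline` / `bogflux.cli` | end-to-end orchestration, CSV I/O, YAML config |

## CLI

```bash
bogflux run --seed 1 --out out/               # full two-site synthetic pipeline
bogflux simulate --out out/sim                # drivers, EC series, chamber traces
bogflux chamber --traces s.csv --meta m.csv --out obs.csv
bogflux models --obs obs.csv --drivers d.csv --out daily.csv
bogflux compare --obs obs.csv --ec ec.csv --site tree --out report.json
bogflux partition --daily daily.csv --ec ec_gapfilled.csv --site tree --out part.csv
bogflux balance --balances annual.csv --gwp 27 --out balances.csv
bogflux validate-tables                       # recompute published table cells
```

`bogflux run` writes per-site CSVs (drivers, EC, traces, observations,
fitted models, daily source fluxes, partitioned days, annual
contributions, chamber↔EC pairs), a comparison report, a run log and a
deterministic `summary.json`.  A YAML config (`--config`) can override any
documented default; unknown keys are rejected.

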