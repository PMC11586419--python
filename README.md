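# carbonrisk

Climate-disaster incidence modelling: a logistic (logit) transfer links the
annual probability of a climate-related disaster in a country-year to current
and lagged growth in atmospheric CO2 concentration. On top of that transfer
the package provides

- **model_core** — the transfer mathematics: logistic map, certainty-equivalent
  incidence, intercept calibration, uncertainty wedge, cumulative response
  coefficients, disaster-count growth projections and doubling times;
- **carbon_dynamics** — estimation and simulation of a stationary AR(p)
  process for annual CO2 growth, with closed-form Yule–Walker stationary
  moments and iid bootstrap moment CIs;
- **panel_estimation** — dynamic panel logit with one-/two-way fixed effects
  on a country-year disaster panel, Mann–Whitney AUROC and McFadden pseudo-R²;
- **monte_carlo** — pushes AR carbon paths through the transfer to decompose
  expected disaster risk into a certainty-equivalent part and a
  Jensen-inequality "uncertainty wedge", with beta-benchmark RMSE and
  coefficient-CI convexity robustness runs;
- **scenarios** — evaluation under the IPCC RCP pathways (scenario mean CO2
  growth, baseline vs stabilised volatility) including discrete
  "decarbonisation dividend" gradients;
- **synthetic_data** — seeded generators for CO2 growth histories and
  disaster panels with the statistical structure the analysis assumes, so the
  whole pipeline is testable offline.

Unit convention: CO2 growth rates are carried in percent p.a. everywhere
except `cumulative_response`, which takes mean growth as a fraction
(e.g. `0.01624`). See the `model_core` docstring.

## CLI

The `carbonrisk` command chains the pipeline stages:

```sh
carbonrisk make-synthetic -o fixtures --seed 0            # carbon.csv, panel.csv, manifest.yaml
carbonrisk fit-ar -i fixtures/carbon.csv -o ar.yaml --order 3
carbonrisk fit-logit --panel fixtures/panel.csv --carbon fixtures/carbon.csv \
    --fe one -o coefs.csv --summary logit.yaml
carbonrisk calibrate --preset one_way:urban -o calibrated.yaml
carbonrisk simulate --params calibrated.yaml --ar ar.yaml -o sim.csv \
    --runs 2000 --years 2000 --seed 1
carbonrisk scenarios --params calibrated.yaml --ar ar.yaml -o scenarios.csv
carbonrisk report -o report.csv
```

All tabular I/O is comma-separated UTF-8 with a header row; outputs carry a
`# key: value` metadata header (version, seed, config hash) so any artifact
can be regenerated from its recorded configuration.

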