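"""Run the whole analysis — contest, selection, fit, diagnostics, forecast —
from one configuration, writing every artifact to scratch/example_run/.

Uses a reduced chain so the example finishes in seconds; swap in the
default MCMCConfig() for a production-length run.
"""

import json

import obesity_elasticity as oe

config = oe.AnalysisConfig(
    outdir="scratch/example_run",
    seed=1,
    synthetic=oe.GeneratorConfig(strata=("overall",)),
    strata=("overall",),
    mcmc=oe.MCMCConfig(n_iter=2000, burn_in=1000, thin=1, seed=1),
    n_forecast_draws=500,
)

report = oe.run_full_analysis(config)

print(f"config hash: {report['config_hash']}")
print("stages:")
for name, info in report["stages"].items():
    print(f"  {name}: {json.dumps(info)}")
print(f"warnings: {len(report['warnings'])}")
print("artifacts in scratch/example_run/: mape_table.csv selection_trace.csv "
      "summary.csv elasticities.csv forecast.csv run_report.json")
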