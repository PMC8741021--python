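"""File-based workflow: CSV in, JSON report out.

Writes a simulated dataset with an offset and group labels to CSV, then
fits a mixed model specified by column names — the shape of a real
surveillance analysis (counts, population offset, covariate, group
effects) — and prints the report.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

import lgpois as lg

tmp = Path(tempfile.mkdtemp())
cfg = lg.ScenarioConfig(n=150, beta0=-1.0, beta=(1.0,), sigma2=3.0, seed=11,
                        n_iter=1, groups=lg.GroupConfig(n_groups=8,
                                                        effect_sd=0.7))
dataset, _ = next(lg.build_scenario(cfg))
csv_path = tmp / "counts.csv"
lg.write_dataset(dataset, csv_path)

spec = lg.ModelSpec(response="y", offset="z", fixed_terms=["x2"],
                    group_terms=["group"], method="proposed")
report = lg.fit_model(lg.read_dataset(csv_path, spec), spec)
lg.save_report(report, tmp / "report.json")

print(f"zero ratio: {report['zero_ratio']:.2f}")
for coef in report["coefficients"]:
    print(f"{coef['name']:<12} est {coef['estimate']:7.3f}  "
          f"se {coef['se']:6.3f}  t {coef['t_value']:6.2f}")
print(f"sigma2 {report['sigma2']:.2f}, edof {report['edof']:.1f}, "
      f"tau2 {np.round(report['tau2'], 3)}")
print(f"report written to {tmp / 'report.json'}")
print(json.dumps({k: report[k] for k in ('method', 'n', 'converged')}))
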