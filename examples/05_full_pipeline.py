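"""Run the complete analysis end to end.

Generates the ensemble, normalizes, classifies, fits the constitutive model
to T6, trains six networks (three training-curve kinds x two directions),
simulates every network closed-loop on every specimen, and prints the
resulting per-test score table and across-kind ANOVA.
"""

import logging

from esomech import PipelineConfig, run_full_analysis

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

result = run_full_analysis(PipelineConfig(seed=1, outdir="results/pipeline_demo"))

print("\nper-test fit errors and correlations (closed-loop NARX):")
print(result.fit_table.round(4).to_string())
for direction, res in result.anova.items():
    print(f"\n{direction} across-kind ANOVA: F={res.f_stat:.4f} p={res.p_value:.4f} "
          f"({'significant' if res.significant else 'not significant'} at 0.05)")
print("\nOutputs (params.csv, fit_table.csv, anova_*.csv, weights/, strain_energy.csv)")
print("written to results/pipeline_demo; rerunning with the same seed reproduces")
print("them byte for byte.")
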