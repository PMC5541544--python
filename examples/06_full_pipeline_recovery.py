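"""The whole indicator suite in one call, plus the recovery summary.

Runs every stage on the default scenario and reports how far each metric has
recovered by the final survey year (100 = back at the 1981 reference value,
0 = at the historical minimum).
"""

import warnings

from trawlkit import AnalysisConfig, default_collapse_scenario, recovery_summary, run_pipeline

warnings.simplefilter("ignore")

report = run_pipeline(AnalysisConfig(rng_seed=1),
                      scenario=default_collapse_scenario(seed=1))

print("output families:", ", ".join(k for k, v in report.families().items()
                                    if v is not None))
print("provenance:", report.provenance)
print()
print("Recovery by 2013 (percent of the 1981-referenced range regained):")
print(recovery_summary(report, 2013).round(1).to_string())
print()
print("Composition recovers faster than total biomass, and the dominant")
print("species lags both - the same ordering of recovery rates the indicator")
print("suite is designed to resolve.")
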