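"""Run the full analysis grid: primary + secondary variants per outcome.

Mirrors a results-table workflow: one row per analysis with RMTL ratio,
CI, P and additional event-free days.
"""
import pandas as pd

import natexp
from natexp.pipeline import default_grid
from natexp.scenarios import paper_like

cohort = natexp.generate_cohorts(paper_like(6000, 7200, seed=7))
grid = default_grid(seed=7)
results = natexp.run_grid(cohort, grid)

cols = ["analysis_id", "outcome", "n_comparator", "rmtl_ratio",
        "ci_low", "ci_high", "p_value", "additional_days", "status"]
with pd.option_context("display.width", 140):
    print(results[[c for c in cols if c in results.columns]].round(3).to_string(index=False))
print(
    "\nThe dementia rows should show a protective ratio (< 1) that is"
    "\nrobust across matching and alignment variants, while the"
    "\nmortality and negative-control rows are null-expected (CI"
    "\ncovering 1): residual confounding would show up there first."
)
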