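"""Recover the mutant differentiation multiplier from synthetic cohorts.

Generates mutant-condition clone data with a known doubled RG->IPC rate,
then fits only that multiplier by simulated summary statistics (grid
search with common random numbers).
"""

import numpy as np

from corticlone import inference, io as cio
from corticlone.lineage import LineageParams
from corticlone.synthetic import StudyDesign, generate_clone_dataset

base = LineageParams()
design = StudyDesign(conditions=("mutant",), t_labels=(40.0,),
                     t_obs=(2.0, 6.0, 10.0), n_range=(500, 500), seed=11)
table, _ = generate_clone_dataset(design, base, diff_multiplier=2.0)
observations = cio.observations_by_design(table, condition="mutant")
summaries = inference.summarize_design(observations, hist_cap=16)

spec = inference.FitSpec(base=base,
                         free={"diff_multiplier": np.arange(1.0, 3.51, 0.1)},
                         n_sim=500, seed=3)
result = inference.fit(spec, summaries)
print("grid profile around the optimum:")
prof = result.profile.sort_values("diff_multiplier")
near = prof[(prof.diff_multiplier > 1.5) & (prof.diff_multiplier < 2.6)]
for _, row in near.iterrows():
    print(f"  m = {row.diff_multiplier:.1f}   loss = {row.loss:8.1f}")
print(f"\nfitted multiplier: {result.best_params.diff_multiplier:.2f} (truth 2.0)")
print("The loss minimum at the generating value shows the summary-statistic "
      "objective identifies the differentiation rate from clone data alone.")
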