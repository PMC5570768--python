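"""Representative sample selection and batch allocation.

Simulates a cohort described by 205 clinical/personal descriptors, maps one
group onto a two-component PCA score plane, fits the factorial square
(4 corners + center), selects 5 + 5 + 5 + 5 + 3 = 23 representative samples
and splits them into four analytical batches.
"""

import pandas as pd

from metabatch import (SimulationConfig, allocate_batches, build_design,
                       characterize, select_representative,
                       simulate_descriptors)

cfg = SimulationConfig(seed=42, n_per_group=60)   # 60 candidates per group
table = simulate_descriptors(cfg)

model = characterize(table, "control", n_components=2)
print("control group PCA: R2X per component =",
      [round(float(v), 3) for v in model.r2x_per_component])

scores = model.scores
design = build_design(scores, width_mode="quantile", width_parameter=0.95)
selected = select_representative(scores, design)
print(f"selected {len(selected)} of {len(scores)} controls:")
print(selected["design_point"].value_counts().to_string())

batch = allocate_batches(scores.loc[selected.index],
                         pd.Series("control", index=selected.index),
                         n_batches=4, design=design)
print("batch sizes:", sorted(batch.value_counts().tolist()))
print("Each batch now spans the descriptor space, so a lost batch does not"
      " bias the remaining study.")
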