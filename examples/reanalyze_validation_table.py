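"""Reanalyze the bundled published per-participant validation table.

The package ships the per-participant overall accuracy and Cohen's
kappa from a 15-infant laboratory validation of this pipeline (both
individual and leave-one-subject-out group models).  This script
recomputes the summary statistics from those printed values: mean
accuracy/kappa per model type, Landis-Koch agreement bins, and the
paired t-test comparing model types (negative t = individual models
better).
"""

import json

from posturekit import lab_validation_table, reanalyze_lab_validation

print(lab_validation_table().to_string())
print()
print(json.dumps(reanalyze_lab_validation(), indent=2, default=str))
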