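"""Cross-check classifier outcomes against leaf physiology.

Classifier predictions are joined with per-sample physiology (soil
volumetric water content, PSII efficiency, leaf water potential) and each
sample is tested against the quartile fences of its own treatment group. A
mislabeled leaf whose physiology is also anomalous for its treatment
suggests the treatment label, not the classifier, was misleading.
"""

import numpy as np
import pandas as pd

from thermoleaf.physio import (
    flag_physio_outliers,
    flag_rates_by_outcome,
    join_predictions_physio,
)

rng = np.random.default_rng(5)
n = 40

# DD plants dry down to ~12% soil VWC — except four whose pots stayed wet
# (microclimate variation); the thermal classifier called those four WW.
soil_dd = rng.normal(12, 1.5, n)
soil_dd[:4] = rng.normal(34, 1.5, 4)
predictions = pd.DataFrame(
    {
        "sample_id": [f"dd{i}" for i in range(n)] + [f"ww{i}" for i in range(n)],
        "true_label": ["DD"] * n + ["WW"] * n,
        "predicted_label": ["WW"] * 4 + ["DD"] * (n - 4) + ["WW"] * n,
    }
)
physio = pd.DataFrame(
    {
        "sample_id": predictions["sample_id"],
        "soil_vwc": np.concatenate([soil_dd, rng.normal(34, 1.5, n)]),
        "psii_eff": rng.uniform(0.72, 0.84, 2 * n),
        "leaf_wp": -rng.uniform(0.4, 1.8, 2 * n),
    }
)

joined = join_predictions_physio(predictions, physio)
diagnoses = flag_physio_outliers(joined)
print(flag_rates_by_outcome(diagnoses).to_string(index=False))
print("\nOutcome tags are true-label_predicted-label. A higher flag rate in "
      "DD_WW than DD_DD means the 'misclassified' dry-down leaves were the "
      "ones whose soil never actually dried — their physiology sides with "
      "the classifier, not the label.")
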