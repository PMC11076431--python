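"""From signal to concentration: the variable-flip-angle T1 chain.

Renders noiseless spoiled-gradient-echo volumes for a tiny cohort,
re-estimates each lesion's T1 from the two-flip-angle pair (2/10 deg)
and inverts the dynamic signal back into concentration. Without noise
the chain is an identity.
"""

import numpy as np

from ufdce import CohortSpec, render_signal, simulate_cohort
from ufdce.pipeline import measure_curves_from_volumes

cohort = CohortSpec(n_benign=2, n_malignant=2, noise_sigma=0.0, seed=2)
study = render_signal(simulate_cohort(cohort), cohort)
print(f"dynamic volume: {study.volumes.dynamic.shape} (x, y, z, phases)")

recovered = measure_curves_from_volumes(study)
for (series, label), les in zip(recovered, study.lesions):
    err = np.max(np.abs(series.values - les.curve))
    print(f"{les.lesion_id} ({label:>9}): max |recovered - true| = {err:.2e} mmol/L")

# The worst-case error is at machine precision: the two-point VFA fit and
# the SPGR inversion are exact closed forms on noiseless data.
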