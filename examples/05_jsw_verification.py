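"""Measure joint-space width/narrowing from synthetic radiograph contours
and check whether simulated degeneration explains the narrowing.
"""

import numpy as np
import pandas as pd

import kneedeg as kd
from kneedeg.radiograph import JSWRecord

rng = np.random.default_rng(0)
records = kd.generate_cohort(40, seed=9)

jsn_rows, deg_rows = [], []
for i, (subject, meas) in enumerate(records):
    # synthetic truth: narrowing loosely follows the medial load imbalance
    true_jsn = {
        "medial": max(0.0, rng.normal(8.0 + subject.joint_alignment, 4.0)),
        "lateral": max(0.0, rng.normal(5.0, 4.0)),
    }
    base, follow = kd.generate_contours(meas, true_jsn, noise=0.05, seed=100 + i)
    jb = JSWRecord(kd.measure_jsw(base, "medial"), kd.measure_jsw(base, "lateral"))
    jf = JSWRecord(
        kd.measure_jsw(follow, "medial"),
        kd.measure_jsw(follow, "lateral"),
        "followup",
    )
    jsn = kd.compute_jsn(jb, jf)
    jsn_rows.append(
        {"knee_id": subject.id, "jsn_medial": jsn["medial"], "jsn_lateral": jsn["lateral"]}
    )
    med = 0.01 * subject.joint_alignment + rng.normal(0.02, 0.01)
    deg_rows.append(
        {
            "knee_id": subject.id,
            "fraction_medial": max(med, 0.0),
            "fraction_lateral": max(rng.normal(0.01, 0.01), 0.0),
            "fraction_overall": max(med, 0.0) / 2,
        }
    )

r2, crosstab = kd.verify_jsn_vs_degeneration(
    pd.DataFrame(jsn_rows), pd.DataFrame(deg_rows)
)
print(f"adjusted R^2 of max-knee JSN on overall degenerated fraction: {r2:.3f}")
print("\ncompartment agreement cross-tab:")
print(crosstab)
# A low adjusted R^2 with diagonal-heavy cross-tabulation means the model
# ranks compartments consistently even when it does not explain the
# magnitude of radiographic narrowing.
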