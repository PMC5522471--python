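"""Screen a simulated patient cohort with the wash-out index.

Simulates 20 patients (20 % malignant, matching the reference cohort's
prevalence) with class-conditional nodule retention — benign nodules keep
a mean 70 % of their early count rate, malignant 90 % — quantifies every
study from its Poisson-noise images, and compares the WOind calls at the
-19 % cutoff against the known truth labels.
"""

import mibiquant as mq
from mibiquant import Call, IndexMethod

patients = mq.simulate_cohort(mq.CohortSimConfig(n_patients=20, seed=7))

print(" id  truth      f_nodule  WOind(%)  call")
tp = fp = tn = fn = 0
for p in patients:
    wo, _ = mq.quantify_study(p.phantom.study)
    call = mq.classify_value(IndexMethod.WOIND, wo.value)
    suspicious = call is Call.SUSPICIOUS
    tp += suspicious and p.malignant
    fp += suspicious and not p.malignant
    fn += (not suspicious) and p.malignant
    tn += (not suspicious) and not p.malignant
    truth = "cancer" if p.malignant else "benign"
    print(
        f"{p.patient_id:3d}  {truth:9s}  {p.kinetics.f_nodule:8.3f}  "
        f"{wo.value:8.2f}  {call.value}"
    )

print(f"\nconfusion: tp={tp} fp={fp} tn={tn} fn={fn}")
print(
    "Malignant phantoms retain more MIBI, so their WOind sits above the "
    "-19 % cutoff; benign ones wash out to around -30 % and fall below it."
)
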