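"""Quantify a simulated dual-time-point study and check the closed form.

Builds the default benign-kinetics phantom (nodule retains 70 % of its
early count rate over the +10 to +60 min window, parenchyma 50 %), first
noiseless and then with Poisson counting noise, and runs both indices.
The noiseless pipeline must match the analytic oracle; the noisy one
scatters around it.  Toggling physical Tc-99m decay shifts WOind by a
known factor and leaves R.I. untouched.
"""

import dataclasses

import mibiquant as mq
from mibiquant import DecaySpec, IndexMethod

phantom = mq.build_phantom(noise="none")
wo, ri = mq.quantify_study(phantom.study)
print("noiseless phantom:")
print(f"  WOind = {wo.value:8.3f} %   analytic {mq.analytic_index(phantom.kinetics, IndexMethod.WOIND):8.3f} %")
print(f"  R.I.  = {ri.value:8.3f}     analytic {mq.analytic_index(phantom.kinetics, IndexMethod.RI):8.3f}")

noisy = mq.build_phantom(seed=17)
wo_n, ri_n = mq.quantify_study(noisy.study)
print(f"Poisson phantom (seed 17): WOind = {wo_n.value:.2f} %, R.I. = {ri_n.value:.2f}")

decayed = mq.build_phantom(
    kinetics=dataclasses.replace(phantom.kinetics, apply_physical_decay=True),
    noise="none",
)
raw_wo, raw_ri = mq.quantify_study(decayed.study)
cor_wo, cor_ri = mq.quantify_study(decayed.study, decay=DecaySpec(enabled=True))
print("with physical decay simulated:")
print(f"  uncorrected WOind = {raw_wo.value:.3f} %, corrected = {cor_wo.value:.3f} %")
print(f"  R.I. uncorrected  = {raw_ri.value:.3f},  corrected = {cor_ri.value:.3f}")
print(
    "Decay correction restores the biological wash-out (-30 %); R.I. is "
    "invariant because the common per-frame factor cancels in its ratios."
)
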