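"""The quantile-distance statistic (PDDM) on sparse theta abnormality.

Compares a healthy subject to one whose theta power quadruples in ~8% of
epochs at temporal channels only.  The session-mean TAR barely moves, but
the right tail of the theta power distribution does — which is exactly
what PDDM95 = integral of [F_theta^-1(u) - F_alpha^-1(u)] du over
u in [0.95, 1] measures.
"""

import numpy as np

import rseeg
from rseeg.distribution import channel_distributions, pddm_result

healthy = rseeg.generate_subject(rseeg.healthy_profile(), duration_s=60, seed=8)
bursty = rseeg.generate_subject(rseeg.mci_like_profile(), duration_s=60, seed=8)

for name, sess in (("healthy", healthy), ("sparse theta bursts", bursty)):
    epm = rseeg.epoch_psd(rseeg.bandpass_filter(sess))
    _, tar = rseeg.theta_alpha_ratio(epm)
    vals, pddm_t = rseeg.pddm_per_channel(epm)  # PDDM95(theta, alpha)

    t6 = epm.channel_index("T6")
    theta = channel_distributions(epm, "theta")[t6]
    alpha = channel_distributions(epm, "alpha")[t6]
    res = pddm_result(theta, alpha)
    tail = res.pddf[res.u_grid >= 0.95]

    print(f"--- {name} ---")
    print(f"temporal TAR          : {tar:.3f}")
    print(f"temporal PDDM95       : {pddm_t:+.4f}  (log10-power x probability)")
    print(f"PDDF at T6, tail mean : {tail.mean():+.3f} log10 units")
    print()

print(
    "Both subjects share the same seed, so the only difference is the\n"
    "bursts.  They lift the theta tail (PDDF tail mean rises) and with it\n"
    "PDDM95, while the session-mean TAR moves comparatively little —\n"
    "bursts in ~8% of epochs are diluted 12-fold in a mean.  Across whole\n"
    "cohorts this tail sensitivity is what gives PDDM95 its larger group\n"
    "effect sizes in the sparse regime."
)
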