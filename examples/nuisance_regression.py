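"""Nuisance regression with the traditional motion-regressor families.

Removes each family (mot6 ... mot36) from every voxel by ordinary least
squares and reports the median fraction of variance left: nested families
can only remove more.
"""

import numpy as np

from motregress import SyntheticConfig, build_regressor_set, synthesize_subject
from motregress.nuisance import explained_variance_between_sets, regress_out

subject = synthesize_subject(
    SyntheticConfig(T=135, n_gm=300, n_wm=1000, n_csf=400, seed=5)
)
for family in ("mot6", "mot12", "mot24", "mot36"):
    rset = build_regressor_set(subject.motion, family)
    fit = regress_out(subject.data.data, rset)
    print(f"{family}: median remaining variance "
          f"{100 * np.median(fit.remaining_variance_fraction):.1f}%")

m6 = build_regressor_set(subject.motion, "mot6")
m12 = build_regressor_set(subject.motion, "mot12")
print(f"variance of mot6 explained by mot12: "
      f"{explained_variance_between_sets(m12, m6):.1f}% (nested -> 100%)")
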