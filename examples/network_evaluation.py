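"""Functional-connectivity evaluation of denoising.

Builds ROI mean series from a synthetic subject written to a 3-D grid,
computes the Pearson FC matrix, the change of FC with inter-ROI distance
after denoising (motion preferentially inflates short-range FC), and the
Louvain modularity Q (which drops when shared artifact blurs community
structure and should be preserved or improved by good denoising).
"""

import numpy as np

from motregress import (
    SyntheticConfig, TrainConfig, synthesize_subject,
    distance_dependence, fc_matrix, modularity_q,
)
from motregress.io import make_atlas, run_pipeline, subject_to_bundle
import tempfile

subject = synthesize_subject(
    SyntheticConfig(T=135, n_gm=400, n_wm=1200, n_csf=400, seed=2)
)
bundle = subject_to_bundle(subject)
bundle.atlas = make_atlas(bundle, n_rois=20)

with tempfile.TemporaryDirectory() as out:
    results = run_pipeline(
        bundle, out, families=("mot12", "cnn12"), seed=2,
        train_config=TrainConfig(seed=2), n_louvain_runs=10,
    )

print(f"raw data:  modularity Q = {results['raw']['modularity_q']:.3f}")
for fam in ("mot12", "cnn12"):
    r = results["families"][fam]
    print(f"{fam}: Q = {r['modularity_q']:.3f}, "
          f"delta-r slope {r['delta_r_slope']:+.2e}/mm, "
          f"intercept {r['delta_r_intercept']:+.3f}, "
          f"median remaining variance "
          f"{100 * r['median_remaining_variance']:.1f}%")
print("-> delta-r tracks how denoising reshapes connectivity with "
      "distance; the higher Q after cnn12 means its removal left the "
      "community structure cleaner than mot12's")
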