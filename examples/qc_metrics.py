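"""Motion and data-quality metrics for one subject.

FD sums absolute parameter changes (rotations converted via a 50 mm head
radius); rmsFD is the RMS displacement over a spherical head shell under
the relative rigid transform; DVARS is the RMS temporal derivative of the
signal across voxels. Together they summarize how much the head moved and
how hard the signal was hit.
"""

from motregress import SyntheticConfig, qc_summary, synthesize_subject

subject = synthesize_subject(
    SyntheticConfig(T=135, n_gm=200, n_wm=800, n_csf=300, seed=8)
)
s = qc_summary(subject.motion, subject.data.data)
print(f"mean FD:    {s.mean_fd:.3f} mm ({s.motion_group}-motion group, "
      f"0.25 mm split)")
print(f"peak FD:    {s.fd.max():.3f} mm at volume {s.fd.argmax()}")
print(f"peak rmsFD: {s.rmsfd.max():.3f} mm")
print(f"mean DVARS: {s.mean_dvars:.3f} (signal units / volume)")
print(f"mean whole-brain variance: {s.mean_whole_brain_variance:.3f}")
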