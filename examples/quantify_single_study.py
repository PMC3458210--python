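"""Quantify one early/delayed planar MIBG pair.

Builds a noise-free synthetic study with known uptake, applies the ideal ROI
set (manual cardiac polygon + 13x20 mediastinal rectangle) and prints the
quantities a clinician reads off a planar MIBG report: early and delayed
heart-to-mediastinum (H/M) ratio and the washout rate by both methods.
"""

from mibgplanar import PhantomConfig, generate_phantom, quantify_study

early, delayed, truth = generate_phantom(PhantomConfig(noise="none"))
m = quantify_study(early, delayed, truth.true_roi_set)

print(f"early  H/M ratio : {m.hm_early:.3f}   (heart {m.H_e:.1f} / mediastinum {m.M_e:.1f} counts/px)")
print(f"delayed H/M ratio: {m.hm_delayed:.3f}   (heart {m.H_l:.1f} / mediastinum {m.M_l:.1f} counts/px)")
print(f"washout, method 1 (no background correction) : {m.wr_m1_pct:.1f} %")
print(f"washout, method 2 (mediastinum-corrected)    : {m.wr_m2_pct:.1f} %")
print()
print("An early H/M near 1.56 with ~40 % washout is typical of a heart-failure")
print("patient; a delayed H/M at or below 1.4 marks severe sympathetic denervation.")
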