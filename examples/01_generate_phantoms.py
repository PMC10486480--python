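"""Generate one normal and one NPH-like brain phantom and compare their CSF.

The two shipped presets differ in where CSF accumulates: the NPH preset has
enlarged central ventricles (mid-axial levels) and enlarged focal sulcal
pockets near the vertex, while the normal preset's CSF is dominated by the
peripheral rim and basal cisterns.
"""

from nphct import phantom

for name, preset in (("normal", phantom.NORMAL_PRESET), ("nph", phantom.NPH_PRESET)):
    vol = phantom.generate_label_volume(preset.replace(seed=42))
    n_csf = int((vol.labels == phantom.CSF).sum())
    n_wg = int((vol.labels == phantom.WHITE_GREY).sum())
    print(f"{name:>6}: {n_csf:6d} CSF voxels, {n_wg:6d} white/grey voxels, "
          f"global CSF fraction {n_csf / (n_csf + n_wg):.3f}")

print("\nThe NPH phantom carries a visibly larger CSF fraction; the features"
      "\nmodule localizes *where* along the axial axis that excess sits.")
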