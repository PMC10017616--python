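"""Quantify EAT on one synthetic phantom patient.

Generates a four-series cardiac phantom (TNC, VNC_Conv, VNC_PC, CTA) with a
known fat shell, segments epicardial adipose tissue with the inclusive
[-190, -30] HU window inside the pericardial mask, and prints the per-series
volume, mean attenuation and noise alongside the ground truth.
"""

from eatquant import PhantomParams, generate_phantom, quantify_series

params = PhantomParams()  # 84^3 grid, 1.5 mm voxels, ~195 mL fat shell
series, mask, truth = generate_phantom(params, seed=1, patient_id="demo")

print(f"ground-truth fat volume: {truth.true_fat_volume_ml:.1f} mL "
      f"({truth.true_fat_voxel_count} voxels)")
print(f"{'series':>10} {'volume mL':>10} {'mean HU':>9} {'noise HU':>9}")
for label in ("TNC", "VNC_Conv", "VNC_PC", "CTA"):
    m, _ = quantify_series(series[label], mask)
    print(f"{label:>10} {m.volume_ml:>10.1f} {m.mean_hu:>9.1f} {m.noise_sd_hu:>9.1f}")

# The measured volumes fall below the ground truth because part of each
# series' fat attenuation distribution lies outside the segmentation window;
# the in-window means/SDs reproduce the calibrated per-series targets.
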