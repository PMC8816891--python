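"""Plate-level quality control on one simulated 384-well screening plate.

Builds a single plate under the standard antagonist-screen layout (12 DMSO
zero controls, 12 EC90-agonist positive controls, a 12-point reference-
antagonist titration, 204 test wells, 2-well edge exclusion), then computes
the three gate statistics every plate must clear: control CV < 10%,
signal-to-background > 4, and Z'-factor > 0.5.
"""

import nachr_hts as nh

manifest = nh.make_manifest(204)
truth = {cid: nh.CompoundTruth(cid) for cid in manifest.compound_ids}
reads, layouts, _ = nh.generate_screen(
    manifest, truth, nh.DEFAULT_CONTEXTS["A4B2"], nh.NoiseModel(seed=0), n_runs=1)

read = reads[0]
net, flagged = nh.subtract_background(read)
plate = nh.normalize_plate(net, layouts[read.plate_id], plate_id=read.plate_id)
report = nh.qc_plate(plate)

print(f"plate {report.plate_id}")
print(f"  CV (positive controls):  {report.cv_pos:.4f}   (gate: < 0.10)")
print(f"  CV (zero controls):      {report.cv_zero:.4f}")
print(f"  S:B ratio:               {report.sb_ratio:.1f}    (gate: > 4)")
print(f"  Z'-factor:               {report.z_prime:.3f}    (gate: > 0.5)")
print(f"  control outliers removed: {report.outliers_removed or 'none'}")
print(f"  passed QC gate:          {report.passed}")
# The Z'-factor folds control variability and dynamic range into one score:
# values above 0.5 mean the zero- and full-signal control bands are separated
# by more than 6 combined SDs, i.e. an excellent screening assay.
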