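"""Molecular-weight calibration from a marker ladder.

Fits the cubic log10(MW)-vs-Rf curve on an 11-marker ladder (10-250
kDa), estimates MWs back, then shows the internal-standard correction
removing a deliberate bias, the way albumin and the FLC dimer/monomer
anchor a curve built from a commercial standard.
"""

import dataclasses

from uripage import calibration, densitometry, synthetic

model = synthetic.GelModel()
markers = (250, 150, 100, 80, 60, 50, 40, 30, 25, 15, 10)
pairs = [(mw, model.migration_rf(mw)) for mw in markers]
curve = calibration.fit_mw_curve(pairs, degree=3)
print(f"degree-{curve.degree} fit, residual rms {curve.residual_rms:.2e} log10 units")
print(f"valid range: {curve.mw_range[0]:.1f} - {curve.mw_range[1]:.1f} kDa")
for mw in (200, 69.23, 20, 12):
    rf = model.migration_rf(mw)
    print(f"  Rf {rf:.3f} -> {calibration.estimate_mw(curve, rf):7.2f} kDa (true {mw})")

# inject an 11% multiplicative MW bias, then correct with internal anchors
coeffs = list(curve.coeffs)
coeffs[-1] += 0.045
biased = dataclasses.replace(curve, coeffs=tuple(coeffs))
anchors = [(69.23, "albumin"), (46.0, "flc_dimer"), (23.0, "flc_monomer")]
bands = [
    densitometry.Band(center=model.migration_rf(mw) * 1199, rf=model.migration_rf(mw),
                      integrated_signal=100.0, amplitude=0, prominence=0, width=6, snr=10)
    for mw, _ in anchors
]
corrected = calibration.calibrate_internal(biased, bands, anchors)
for (mw, label), b in zip(anchors, bands):
    before = calibration.estimate_mw(biased, b.rf)
    after = calibration.estimate_mw(corrected, b.rf)
    print(f"  {label:<11s} biased {before:6.2f} kDa -> corrected {after:6.2f} kDa (true {mw})")
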