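"""Fit and invert the fluorescence-to-pH standard curve.

Generates standards (pH 4.0-7.0) from the indicator forward model with
realistic read noise, fits the 4-parameter log-sigmoid, and shows the
round trip pH -> RFU -> pH.
"""

import phlux as px

standards = px.make_calibration_standards(noise_sd=300.0, seed=7)
print("standards (ph, rfu):")
print(standards.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

curve = px.fit_calibration(list(zip(standards["ph"], standards["rfu"])))
print(
    f"\nfitted sigmoid: r_min={curve.r_min:.0f}  r_max={curve.r_max:.0f}  "
    f"apparent pKa={curve.apparent_pka:.3f}  hill={curve.hill_slope:.3f}\n"
    f"residual RMS {curve.fit_residual_rms:.0f} RFU over "
    f"pH {curve.valid_ph_range[0]}-{curve.valid_ph_range[1]}"
)
# the true generator used pKa 6.4 and hill 1; the fit recovers them from
# 7 noisy standards to a few hundredths of a pH unit.

for ph in (5.0, 6.0, 6.5):
    rfu = curve.ph_to_rfu(ph)
    back = curve.rfu_to_ph(rfu)
    print(f"pH {ph} -> {rfu:8.0f} RFU -> pH {back:.4f}")
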