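"""How well does the mother's uterus dose stand in for the fetal dose?

The mother's uterus equivalent dose rate coefficient is a practical
surrogate for the fetal total-body dose.  This report computes, per
nuclide, the ratio of the two from the packaged ground-contamination
coefficients: values a few percent above 1 mean the uterus estimate is
mildly conservative; large ratios flag low-energy emitters whose photons
are attenuated before reaching the fetus.
"""

from fetodose import Geometry, nuclide_summary, uterus_fetus_ratio

summary = nuclide_summary(Geometry.GROUND_PLANE)
report = uterus_fetus_ratio(
    list(summary.index),
    summary["uterus"].to_dict(),
    summary["total_body"].to_dict(),
)

print("uterus (mother) / total body (fetus), ground plane source")
print(report[["ratio_raw", "ratio"]].sort_values("ratio_raw").to_string())
print()
print(f"median ratio: {report['ratio_raw'].median():.3f}")
print(f"maximum:      {report['ratio_raw'].max():.3f} "
      f"({report['ratio_raw'].idxmax()})")
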