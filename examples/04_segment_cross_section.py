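"""Segment a synthetic muscle cross-section into IMCT vs muscle.

Renders a cross-section photograph with a 12% connective-tissue network,
trains the threshold classifier on a labeled pixel sample, segments the
full image, and regresses IMCT percentage on MGV_00 for a small
simulated cohort.
"""

import numpy as np

import spatialgain as sg
from spatialgain.segmentation import regress_imct_on_mgv00, segment, train_threshold

config = sg.CrossSectionConfig(seed=3, imct_fraction_true=12.0)
image, mask = sg.render_cross_section(config)

rng = np.random.default_rng(1)
idx = rng.choice(mask.size, size=10_000, replace=False)
clf = train_threshold(image.reshape(-1, 3)[idx], mask.reshape(-1)[idx])
result = segment(image, clf)

print(f"true IMCT fraction      : {100 * mask.mean():.2f}%")
print(f"recovered IMCT fraction : {result.imct_percent:.2f}%")
print(f"classifier              : channel {clf.channel}, threshold "
      f"{clf.threshold:.1f}, IMCT {'above' if clf.imct_above else 'below'}")

# a small cohort where IMCT weakly drives MGV_00, plus noise
imct = rng.uniform(4, 25, 40)
mgv00 = 60.0 + 0.8 * imct + rng.normal(0, 5.0, 40)
report = regress_imct_on_mgv00(list(zip(imct, mgv00)))
print()
print(f"IMCT% ~ MGV_00 regression: r = {report.r:.2f} "
      f"({report.magnitude_label}), adj r2 = {report.adjusted_r2:.3f}, "
      f"P = {report.p_value:.3g}")
print()
print("Brighter muscles (higher MGV_00) carry more connective tissue; the")
print("correlation magnitude is judged on the standard |r| bins.")
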