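"""Estimate orientations, pennation angle and MGV from a speckled frame.

Renders one noisy frame with pennation 12 degrees seen through a +12
degree gel pad (so the true FPA is 0), runs the epimysium and fascicle
estimators, places the study ROI below the epimysium and extracts the
mean gray value.
"""

import spatialgain as sg

config = sg.PhantomConfig(seed=7, pennation_deg=12.0)
frame, truth = sg.render_frame(config, gel_pad_deg=12.0, frame_index=0)

epi = sg.estimate_epimysium_angle(frame)
roi = sg.place_roi(frame, sg.ROISpec(0, 0, 400, 200), epimysium_deg=epi)
fas = sg.estimate_fascicle_angle(frame, roi)
angles = sg.derive_angles(fas, epi, gel_pad_deg=12.0)
mgv = sg.compute_mgv(frame, roi)

print(f"epimysium angle : {epi:+6.2f} deg  (truth {truth.epimysium_deg:+.1f})")
print(f"fascicle angle  : {fas:+6.2f} deg  (truth {truth.fascicle_deg:+.1f})")
print(f"pennation alpha : {angles.alpha_deg:6.2f} deg  (truth {truth.alpha_true_deg:.1f})")
print(f"FPA             : {angles.fpa_deg:+6.2f} deg  (truth {truth.fpa_true_deg:+.1f})")
print(f"ROI center y    : {roi.center_y:6.1f} px")
print(f"MGV             : {mgv:6.2f}      (target {truth.mgv_target:.2f})")
print()
print("With the gel pad matching the pennation angle, the fascicles are")
print("parallel to the probe (FPA ~ 0) and the ROI is at its brightest.")
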