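"""Fit the sine and linear spatial-gain models and compare them.

Simulates one specimen's sweep observations (FPA grid +-24 degrees,
three frames per angle, ROI-level noise sigma = 3 gray values) from the
sine model with MGV_00 = 80, fits both families, and prints MGV_00, the
tilt echo gain, and the model-selection diagnostics.  Also evaluates the
analytic acoustics that bound what the method can resolve.
"""

import numpy as np

import spatialgain as sg

rng = np.random.default_rng(1)
fpa, mgv = sg.simulate_mgv_observations(rng, beta0=80.0, beta1=33.5, noise_sd=3.0)
obs = sg.observations_from_arrays(fpa, mgv)

sine = sg.fit_sine(obs)
linear = sg.fit_linear(obs)
comp = sg.compare_models(sine, linear)

print(f"sine fit  : MGV_00 = {sine.beta0:6.2f}, beta1 = {sine.beta1:6.2f}, "
      f"adj r2 = {sine.adjusted_r2:.3f}, AIC = {sine.aic:7.2f}")
print(f"linear fit: MGV_00 = {linear.beta0:6.2f}, beta1 = {linear.beta1:6.3f} "
      f"gray/deg, adj r2 = {linear.adjusted_r2:.3f}, AIC = {linear.aic:7.2f}")
print(f"TEG = 100*beta1/beta0 = {linear.teg:.2f} %/deg")
print(f"preferred family by AIC: {comp.preferred} (delta AIC {comp.delta_aic:+.2f})")
print()
print(f"linear-vs-sine deviation at 20 deg: {sg.linearization_error(20.0):.1f}%")
print(f"wavelength at 15 MHz in muscle    : {sg.acoustic_wavelength(1580, 15e6):.0f} um")
print(f"best axial resolution             : {sg.axial_resolution(105):.1f} um")
print()
print("MGV_00 estimates the echo intensity free of pennation bias; TEG is")
print("the percent drop in brightness per degree of probe tilt.")
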