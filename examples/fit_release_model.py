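"""Fit the release kinetics to a (synthetic) calibration campaign.

Generates noisy glucose measurements from six designs of the 24-run
calibration campaign, then recovers the kinetic constants by bounded
nonlinear least squares from a deliberately wrong starting point. The full
campaign with the global differential-evolution stage is exercised by
scripts/acceptance.py; the local fit here runs in seconds.
"""

from enzfeed import ReleaseParameters
from enzfeed.estimation import fit_local
from enzfeed.kinetics import ModelVariant
from enzfeed.synth import NoiseModel, dataset1_designs, dataset1_measurements

truth = ReleaseParameters()
designs = dataset1_designs()[::4][:6]
data = dataset1_measurements(designs, truth, noise=NoiseModel(sigma=0.2, seed=7))

start = truth.replace(k_s=0.08, k_r=0.005, ws0=0.6)
fit = fit_local(start, designs, data, ModelVariant.TWO_SUBSTRATE)

print(f"{'parameter':<10}{'truth':>10}{'estimate':>12}{'std dev':>12}")
for name, true_val in [("k_s", truth.k_s), ("k_r", truth.k_r), ("ws0", truth.ws0)]:
    sd = fit.stderr[name]
    print(f"{name:<10}{true_val:>10.4g}{fit.estimates[name]:>12.4g}"
          f"{(f'{sd:.2g}' if sd else 'n/a'):>12}")
print(f"\nRSS over {fit.n_obs} glucose observations: {fit.rss:.2f}")
print("With sigma = 0.2 g/L noise the expected RSS is ~n*sigma^2 ="
      f" {fit.n_obs * 0.04:.1f}; estimates land within a few percent of truth"
      " (k_r, the slow pool, is the least identifiable).")
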