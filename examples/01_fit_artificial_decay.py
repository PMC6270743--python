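"""Fit a Poisson-noise donor decay and read off the distance distribution.

Generates an artificial TCSPC decay for a donor quenched by FRET at a
Gaussian-distributed inter-dye distance (mean 60 A, width 6 A) with a 20%
donor-only fraction, fits it by the total donor model with support-plane
confidence intervals, and prints the recovered parameters.
"""

from fretwav.decay_sim import StudyConfig, generate_synthetic_decay
from fretwav.tcspc_fit import fit_decay, support_plane_interval

cfg = StudyConfig()
truth = cfg.true_params(60.0, 0.20)
decay = generate_synthetic_decay(truth, None, seed=1, grid=cfg.grid)

start = cfg.start_params(60.0, 0.20)  # offset start guesses, I0/BG fixed at truth
fit = fit_decay(decay, None, start, window=cfg.window, fixed={"I0", "BG"})

print(f"reduced chi2 = {fit.reduced_chi2:.3f} (converged: {fit.converged})")
for name, truth_val in (("mean_R", 60.0), ("sigma_R", 6.0), ("x_D0", 0.20)):
    lo, hi = support_plane_interval(decay, None, fit, name, window=cfg.window)
    est = fit.params.get(name)
    print(f"{name:8s} = {est:7.3f}  (68.3% CI [{lo:.3f}, {hi:.3f}], truth {truth_val})")

# The mean distance comes back to a fraction of an Angstrom; width and
# donor-only fraction are strongly anti-correlated, so their intervals are
# wider -- exactly why removing the donor-only population experimentally
# pays off.
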