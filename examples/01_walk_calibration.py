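"""Calibrate mass-action trafficking rates from single-particle walks.

Simulates ensembles of biased motor walks (with and without sustained
unidirectional runs) and moment-matches the anterograde/retrograde rate
constants a and b of the bulk transport model.
"""

from sushibelt import WalkParams, analytic_rates, fit_rates, simulate

params = WalkParams(p_minus=0.2, p_zero=0.35, p_plus=0.45)

a, b = analytic_rates(params)
print(f"closed-form moment matching:   a = {a:.3f} /s, b = {b:.3f} /s")

fit = fit_rates(simulate(params, n_particles=1000, n_steps=600, seed=1))
print(
    f"memoryless ensemble fit:       a = {fit.a:.3f} /s, b = {fit.b:.3f} /s, "
    f"velocity = {fit.drift_um_per_s * 60:.1f} um/min, "
    f"variance growth = {fit.variance_rate_um2_per_s:.3f} um^2/s"
)

runs = WalkParams(p_minus=0.2, p_zero=0.35, p_plus=0.45, k=0.5)
fit_runs = fit_rates(simulate(runs, n_particles=1000, n_steps=100, seed=2))
print(
    f"run-length ensemble fit (k=.5): a = {fit_runs.a:.3f} /s, b = {fit_runs.b:.3f} /s"
)
print(
    "\nThe drift (a - b ~ 0.25 um/s = 15 um/min) matches kinesin-scale cargo"
    "\nspeeds; sustained runs leave the drift unchanged but raise the"
    "\neffective diffusion (a + b), i.e. faster spreading of bulk cargo."
)
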