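"""Multi-condition parameter fitting on synthetic mean curves.

Generates noiseless population-mean curves for the full 5-concentration +
4-duration design (with a plate/chip gain difference), normalizes them the
way imaging data are prepared (chip-to-plate scale factor, rescale to a
peak of 40), then refits the model by bounded Nelder-Mead from a perturbed
start and reports how closely the fitted curves recover the truth.
"""

import numpy as np

from chromopulse import fit, integrate, prepare_dataset, preset
from chromopulse.synth import gen_condition_suite

kin, adapt = preset("CXCL10")
suite = gen_condition_suite(kin, adapt, mode="ode", include_two_pulse=False,
                            plate_gain=2.0, chip_gain=1.0, cxcl10_plate_mask_h=12.0)
prepared, info = prepare_dataset(suite["dataset"], target=40.0,
                                 plate_ref_label="conc_10", chip_ref_label="dur_constant")
print(f"chip-to-plate scale factor: {info['chip_scale']:.4f} (generated with 2.0)")
print(f"rescale-to-40 factor:       {info['rescale']:.4f}")

truth = kin.replace(k6=kin.k6 * info["rescale"] * 2.0)
rng = np.random.default_rng(0)
names = ("k1", "k2", "k3", "k4", "k5", "k6", "deltaM", "deltaP")
start = truth.replace(**{n: getattr(truth, n) * 10 ** rng.normal(0, 0.15) for n in names})

res = fit(prepared, start, adapt, maxfev=2000)
print(f"\nfit converged={res.converged}  SSE={res.loss:.3g}  evaluations={res.n_evals}")
print(f"{'condition':>14s} {'rel RMS %':>9s}")
for cd in prepared:
    traj = integrate(res.kinetics, adapt, cd.condition.protocol, cd.time, method="rk4")
    m = cd.condition.mask_for(cd.time)
    rms = 100 * np.sqrt(np.mean((traj["P"][m] - cd.mean[m]) ** 2)) / 40.0
    print(f"{cd.condition.label:>14s} {rms:9.2f}")

print("\nSub-percent RMS per condition: the fitted model reproduces the"
      "\ngenerating curves even though individual rate constants may trade off.")
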