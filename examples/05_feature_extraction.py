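"""Single-cell trace features on a synthetic imaging dataset.

Generates a fluorescence-like population (stochastic trajectories times a
per-cell gain, plus baseline and frame noise), writes/reads it as the
standard trace CSV, and extracts the per-cell features used to summarize
time-lapse reporter data: baseline, maximum amplitude, lag time to 1.5x
baseline, and the tanh-rise slope (a*c) and pulse amplitude (2*c).
"""

import tempfile
from pathlib import Path

import numpy as np

from chromopulse import StimulusProtocol, preset, read_traces, write_traces
from chromopulse.features import extract_features, feature_cv
from chromopulse.synth import NoiseModel, gen_population

kin, adapt = preset("CXCL10")
noise = NoiseModel(baseline_mean=20.0, baseline_cv=0.2, additive_sd=2.0, gain=1.0, gain_cv=0.2)
pop = gen_population(kin, adapt, StimulusProtocol.constant(10.0), n_cells=400,
                     noise=noise, seed=5, metadata={"gene": "CXCL10"})

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "traces.csv"
    write_traces(pop.traces, path)
    tm = read_traces(path)

feats = extract_features(tm, tanh_window=13.0)
lags = feats["lag_time"].dropna()
print(f"cells analysed:            {len(feats)}")
print(f"mean baseline:             {feats['baseline'].mean():.1f} (generated around 20)")
print(f"mean max amplitude:        {feats['max_amplitude'].mean():.1f}")
print(f"amplitude CV across cells: {feature_cv(feats['max_amplitude'].to_numpy()):.2f}")
print(f"lag detected in:           {100 * len(lags) / len(feats):.0f}% of cells")
print(f"median lag time:           {lags.median():.1f} h")
print(f"median tanh slope (a*c):   {feats['slope'].median():.2f} fluorescence/h")

print("\nHigh amplitude CV and a sizeable never-crossing fraction reflect the"
      "\nall-or-none single-cell response of the slow-chromatin gene.")
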