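"""Two-pulse stimulation: stochastic re-randomization versus reproducible
response.

Exposes 1000 simulated cells to two 4-h pulses of 10 ng/ml with a 10-h off
period, scores the protein amplitude change in each pulse window (pulse
onset to 9 h after pulse end), and classifies responders.  For the
slow-opening gene the response to each pulse is an independent coin flip —
cells silent in pulse 1 respond to pulse 2 at nearly the same rate as
pulse-1 responders — arguing against permanent silencing of the
nonresponders.
"""

from chromopulse import StochasticConfig, preset, two_pulse_experiment
from chromopulse.features import classify_responders, responder_stats

for gene in ("IRF1", "CXCL10", "CXCL9"):
    kin, adapt = preset(gene)
    _, amps = two_pulse_experiment(kin, adapt, StochasticConfig(n_cells=1000, seed=2))
    stats = responder_stats(classify_responders(amps, threshold=5.0))
    c = stats["counts"]
    print(f"{gene}: +/+ {c['+/+']:4d}  +/- {c['+/-']:4d}  -/+ {c['-/+']:4d}  -/- {c['-/-']:4d}")
    print(f"    P(resp pulse1) = {stats['p_resp1']:.2f}   P(resp pulse2) = {stats['p_resp2']:.2f}")
    print(f"    P(resp2 | resp1) = {stats['p_resp2_given_resp1']:.2f}   "
          f"P(resp2 | no resp1) = {stats['p_resp2_given_nonresp1']:.2f}   "
          f"gap = {stats['independence_gap']:.3f}\n")

print("A small conditional-probability gap means pulse responses are"
      "\nindependent (stochastic chromatin opening), not a fixed subpopulation.")
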