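"""Polar-coordinate analysis of joint (Tbx21, Gata3) cell states.

Each cell maps to (r, θ): r is expression magnitude, θ ∈ [0, π/2] the
lineage bias (0 = Th1-like, π/2 = Th2-like).  Cells with r < 10 are excluded
because θ is unstable at low counts.  A uniform θ distribution indicates no
mutual exclusion; a U-shaped one indicates exclusive states.
"""

import numpy as np

from thfish import polar, synth

for regime in ("mixed", "exclusive"):
    counts, _ = synth.make_count_table(synth.RegimeParams(regime=regime, seed=1), 10_000)
    tab = polar.polar_table(counts["tbx21"].to_numpy(), counts["gata3"].to_numpy())
    kept, n_excl = polar.filter_r(tab, r_min=10.0)
    summary = polar.theta_summary(kept["theta"].to_numpy(), n_excluded=n_excl)
    d, p = polar.uniformity_test(kept["theta"].to_numpy())
    print(f"{regime:9s}: kept {summary.n_kept} (excluded {n_excl}), "
          f"median theta {summary.median_theta:.3f} (pi/4 = {np.pi/4:.3f}), "
          f"U-index {summary.u_index:.2f}, KS-vs-uniform p = {p:.3g}")

# The mixed regime is consistent with uniform θ (p above 0.01, U-index near
# 0.5); the exclusive regime is strongly rejected with a U-index near 1.
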