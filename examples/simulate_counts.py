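"""Generate synthetic per-cell count tables for the two expression regimes.

The mixed regime draws the cell-state angle θ uniformly on [0, π/2] — cells
occupy every intermediate Th1/Th2 state; the exclusive regime concentrates θ
near the axes — cells express predominantly one lineage factor.
"""

from thfish import synth

for regime in ("mixed", "exclusive"):
    params = synth.RegimeParams(regime=regime, seed=0)
    counts, truth = synth.make_count_table(params, n_cells=2000)
    on = truth["on_ifng"].mean()
    print(f"{regime:9s}: {len(counts)} cells, mean Tbx21 {counts['tbx21'].mean():.1f}, "
          f"mean Gata3 {counts['gata3'].mean():.1f}, Ifng ON fraction {on:.3f}")
    print(counts.head(3).to_string(index=False))

# Mean TF counts sit near the ~33-35 transcripts/cell observed at 24 h of
# activation; the Ifng ON fraction reflects the rare (few-percent) population
# of cytokine-producing cells.
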