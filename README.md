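# thfish

Quantitative analysis of single-molecule FISH (smFISH) measurements of
T-helper-cell fate decisions: per-cell transcript counting from microscopy
stacks, a polar-coordinate statistic for joint transcription-factor states,
and transcriptional burst-size inference under the two-state model.

## The scientific problem

During early CD4 T-cell activation the lineage-defining transcription
factors *Tbx21* (Th1) and *Gata3* (Th2) are co-expressed in single cells,
while their hallmark cytokines *Ifng* and *Il4* are transcribed only in a
rare, strongly expressing subpopulation.  Testing these claims requires
absolute per-cell transcript counts and statistics built on them:

- **Counting.**  Cells are segmented from a bright-field image
  (edge detection → marker-guided watershed on the boundary distance
  transform); diffraction-limited mRNA spots are enhanced with a per-slice
  Laplacian-of-Gaussian filter, thresholded (automatic plateau criterion),
  and assigned to cells.  Cells above ~200 transcripts cannot be resolved
  spot by spot; their counts are extrapolated from total fluorescence via a
  linear calibration on resolvable cells.
- **Cell states.**  Each cell's joint count (t, g) = (*Tbx21*, *Gata3*)
  maps to polar coordinates r = √(t²+g²), θ = arctan(g/t) ∈ [0, π/2].
  θ near 0 is Th1-like, near π/2 Th2-like.  Cells with r < 10 are excluded
  (θ is unstable at low counts).  A uniform θ distribution means cells
  occupy every intermediate state; a U-shaped distribution means mutual
  exclusion.  Distributions are compared with Kolmogorov–Smirnov tests.
- **Bursting.**  Under the telegraph model (promoter OFF↔ON at k_on/k_off,
  transcription at k_tx while ON, degradation at k_deg), the steady-state
  count in the bursty limit is Gamma-distributed with shape k_on/k_deg
  (burst frequency per mRNA lifetime) and scale k_tx/k_off (mean burst
  size).  Fitting a Gamma to ON-cell counts therefore reads the burst size
  off the fitted scale.
- **Population statistics.**  ON fractions (strict thresholds: >20 *Ifng*,
  >50 *Il4* transcripts), knockout percent reductions, Pearson
  correlations, nearest-producer distances in the monolayer, and
  conditional-invariance checks of TF distributions across cytokine strata.

Everything is exercised end-to-end on synthetic data with known ground
truth (`thfish.synth`): count tables under a *mixed* (uniform θ) or
*exclusive* (U-shaped θ) regime, and rendered microscopy scenes with
planted spots.

## Worked example

```python
from thfish import burst
from thfish.burst import TwoStateParams

params = TwoStateParams(k_on=1.0, k_off=100.0, k_tx=15900.0, k_deg=1.0)
counts = burst.simulate_two_state(params, n_cells=5000, seed=0)
fit = burst.fit_gamma(counts, on_threshold=0, truncated=True)
print(fit.scale_b, fit.shape_a)
```

Running `python examples/burst_inference.py` prints:

```
Ifng  : true burst size  159.0  ->  fitted scale  157.5 (shape 1.01, n_on = 4968)
Il4   : true burst size  176.0  ->  fitted scale  177.4 (shape 1.00, n_on = 4972)
Tbx21 : true burst size   18.0  ->  fitted scale   17.8 (shape 1.02, n_on = 4727)
Gata3 : true burst size   36.0  ->  fitted scale   34.1 (shape 1.03, n_on = 4848)
```

The fitted Gamma scale recovers each simulated mean burst size within a few
percent, and the fitted shape recovers the burst frequency k_on/k_deg = 1.
The other scripts in `examples/` demonstrate count-table synthesis, the θ
statistic (`polar_states.py` shows the mixed regime passing the uniformity
test and the exclusive regime rejected with U-index 0.90), planted-truth
image quantification, and population statistics.

A thin CLI mirrors the main entry points:

```bash
thfish simulate-counts --n-cells 2000 --seed 1 --out cells.csv
thfish analyze --counts cells.csv --out report.json
thfish quantify --brightfield bf.tif --channel tbx21=ch1.tif --out cells.csv
thfish burst fit --counts cells.csv --gene ifng
```

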