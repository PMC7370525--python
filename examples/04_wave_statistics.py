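"""Traveling-wave statistics under weak vs strong superdriver selection.

Runs 5-replicate ensembles at s = 0.01 for c = 1.1 (weak) and c = 3.0
(strong superdriver selection) and prints the wave statistics that shift
with c: driver waves per superdriver epoch, spacing between superdriver
peaks, and quadratic-fit parameters (location, height, curvature) of the
first superdriver waves.
"""

import numpy as np

import tumorwave as tw

THRESHOLD = 0.01  # a wave is an episode above 1% population frequency

for c in (1.1, 3.0):
    ens = tw.run_ensemble(tw.ModelParams(s=0.01, c=c), replicates=5,
                          master_seed=44)
    n_waves = tw.count_driver_waves(ens, k=1, threshold=THRESHOLD)
    spacings = tw.peak_spacings(ens, l=0, threshold=THRESHOLD)
    print(f"\nc = {c}:")
    print(f"  driver waves within the k=1 epoch: {n_waves}")
    print(f"  mean generations between superdriver peaks (l=0): "
          f"{np.mean(spacings):.0f}")
    for k in (1, 2):
        series = tw.clone_series(ens, k, 0)
        segs = tw.detect_waves(series, THRESHOLD, k=k)
        if not segs:
            continue
        fit = tw.fit_wave_quadratic(series, max(segs, key=lambda s: s.span))
        print(f"  wave (k={k}, l=0): location {fit.location:.0f}, "
              f"height {np.exp(fit.height):.3f} (freq), "
              f"curvature {fit.curvature:.2e}")

print("\nStronger superdriver selection sweeps faster: fewer driver waves "
      "ride each superdriver epoch, peaks follow each other sooner, and "
      "waves are narrower (more negative curvature).")
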