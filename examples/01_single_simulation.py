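"""Simulate one tumor and watch superdrivers take over.

Runs a single replicate at the study defaults (10 superdriver loci with
advantage r = c*s = 0.02, 100 driver loci with s = 0.01, growth from 1e6 to
1e9 cells over 4500 generations) and prints when each superdriver class
first appears and when it peaks.
"""

import tumorwave as tw

params = tw.ModelParams(s=0.01, c=2.0)
print(f"alpha = {params.alpha:.6f}  (population x{params.NT / params.N0:.0f} "
      f"over {params.T} generations)")

traj = tw.simulate(params, seed=1)

print(f"{'k':>2} {'first cell (gen)':>17} {'peak gen':>9} {'peak freq':>10}")
for k in range(5):
    series = tw.clone_series(traj, k, 0, scale="frequency")
    first = traj.first_hit[k, 0]
    print(f"{k:>2} {first:>17} {series.argmax():>9} {series.max():>10.3f}")

print("\nEach row is the clone with k superdrivers and no drivers: later "
      "classes appear and peak later — the traveling-wave succession.")
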