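"""Compare simulated waiting times with the analytic sum approximation.

The waiting time to a cell with k superdrivers and l drivers is approximated
by the sum of the two single-class traveling-wave waiting times,
tau_kl ~= T_k^S + T_l^D.  This script measures the empirical waiting times in
a 10-replicate ensemble at s = 0.01, c = 2 and prints both, with the
relative deviation.
"""

import tumorwave as tw

params = tw.ModelParams(s=0.01, c=2.0)
ens = tw.run_ensemble(params, replicates=10, master_seed=43)

print(f"{'(k,l)':>6} {'simulated':>10} {'approx':>8} {'rel.dev':>8}")
for k in range(3):
    for l in range(3):
        if (k, l) == (0, 0):
            continue
        tau_sim, censored = tw.empirical_waiting_time(ens, k, l)
        approx = tw.tau_approx(k, l, params)
        rel = abs(tau_sim - approx) / tau_sim if tau_sim else float("nan")
        print(f"({k},{l})  {tau_sim:>9.0f} {approx:>8.0f} {rel:>8.2f}"
              + ("  (censored in %d reps)" % censored if censored else ""))

print("\nFor k, l >= 1 the sum approximation tracks the simulation; it has "
      "no establishment delay for the very first mutant, so single-mutation "
      "rows (k or l = 0) are dominated by the first-arrival time instead.")
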