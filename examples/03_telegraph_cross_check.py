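"""Cross-check the simulator against the telegraph-model master equation.

In the limit of one-step transcripts with near-instant consumption after
RNase binding, the number of unbound molecules follows the classical
two-state telegraph birth-death law, whose stationary distribution can be
solved exactly from a truncated master equation.  This script simulates
10,000 cells to stationarity and prints the total variation distance to
that independent solution.
"""

import numpy as np

from txnsim import KineticParameters, ProbeSpec, make_turn_on_protocol, simulate_ensemble
from txnsim.telegraph import empirical_pmf, stationary_pmf, total_variation

k_on, k_off, k_ini, k_deg = 1.2, 0.8, 10.0, 1.0
# one elongation step, step rate 100x the fastest kinetic rate
params = KineticParameters(k_on=k_on, k_off=k_off, k_ini=k_ini, k_deg=k_deg,
                           v_el=100 * k_ini * 100.0 / 60.0, L=100.0, N=1)
protocol = make_turn_on_protocol(t_end=12.0, sample_times=(12.0,))

ensemble = simulate_ensemble(params, protocol, ProbeSpec(), n_cells=10_000,
                             seed=1)
counts = ensemble.df["n_unbound"].to_numpy()
oracle = stationary_pmf(k_on, k_off, k_ini, k_deg)
pmf = empirical_pmf(counts, len(oracle) - 1)

print("count :  simulated  master-equation")
for m in range(13):
    print(f"{m:5d} : {pmf[m]:9.4f}  {oracle[m]:9.4f}")
tv = total_variation(pmf, oracle)
print(f"\ntotal variation distance over the full support: {tv:.4f}")
print("Values below ~0.02 are consistent with pure Monte-Carlo error at "
      "10,000 cells.")
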