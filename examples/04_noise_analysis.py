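"""Stationary noise analysis of a macroscopic current.

Simulates a steady patch of 100 channels at Po 0.81 with 1 pA unitary
current and recovers the channel count, maximum current and open
probability from the mean and variance alone.
"""

import patchkit as pk

samples = pk.simulate_macroscopic_patch(n_channels=100, p_open=0.81,
                                        unitary_current=1.0,
                                        n_samples=100_000, seed=3)
stats = pk.segment_stats(samples)
est = pk.analyze_segment(samples, unitary_current=1.0)

print(f"mean current I   = {stats.mean_current:8.2f} pA   (true 81.00)")
print(f"variance sigma^2 = {stats.variance:8.2f} pA^2 (true 15.39)")
print(f"N = I^2/(iI - sigma^2) = {est.n_channels:6.1f}    (true 100)")
print(f"I_max = N*i      = {est.i_max:8.1f} pA")
print(f"Po = I/(N*i)     = {est.p_open:8.3f}      (true 0.81)")
print()
print("For N independent channels the binomial relation between current")
print("mean and variance pins down N; the measured current relative to the")
print("predicted maximum N*i gives the open probability.")
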