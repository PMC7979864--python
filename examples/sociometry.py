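"""Colony-level sociometry on a simulated two-week timelapse.

Generates bee/brood/cell-bee count series sampled every 2 minutes, then runs
the spectral, circular and correlation analyses a long-term hive recording
would get.
"""

from combtrack import analytics, simulator

counts = simulator.simulate_count_series(days=14, seed=11)

_, _, period = analytics.periodogram(counts["visible"].to_numpy(), 120.0)
print(f"dominant period of visible-bee counts: {period:.1f} h")

r, p = analytics.windowed_correlation(counts["t"], counts["visible"],
                                      counts["t"], counts["brood"])
print(f"bee-brood correlation in 12-h windows: r = {r:.2f} (p = {p:.2g})")

hist, mean_hour, hours = analytics.nightly_high_counts(
    counts["t"].to_numpy(), counts["cell"].to_numpy())
z, p_ray = analytics.rayleigh_test(hours)
print(f"above-median cell-bee counts cluster at {mean_hour:.1f} h "
      f"(Rayleigh p = {p_ray:.2g})")
# A ~24-h rhythm, a strong bee-brood anticorrelation and a nightly excess of
# bees inside comb cells around 02:00 are the generator's built-in structure;
# the analytics recover all three from the counts alone.
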