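"""Coverage QC: depth-threshold fractions, 100-kb window SD, AT/GC dropout.

FFPE libraries are overdispersed and GC-biased: a smaller fraction of the
genome reaches the 70x target, window SDs inflate, and AT-rich windows
lose depth (AT dropout).
"""

from ffconcord import SimulationConfig, simulate_coverage, summarize_coverage

config = SimulationConfig(seed=1, cna_segments=[])  # copy-neutral QC genome

for specimen in ("FF", "FFPE"):
    bins = simulate_coverage(config, specimen)
    s = summarize_coverage(bins, thresholds=[30, 50, 70])
    print(f"{specimen}: mean depth {s.mean_depth:6.1f}x | "
          f"frac >=70x {s.fraction_at_threshold[70.0]:.3f} | "
          f"window SD {s.window_sd:5.1f} | "
          f"AT dropout {s.at_dropout:5.2f} | GC dropout {s.gc_dropout:5.2f}")

print()
print("Higher window SD means poorer uniformity; positive AT dropout means")
print("AT-rich windows hold less than their share of the depth mass.")
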