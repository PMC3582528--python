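"""The full experiment: simulate, call, trim, evaluate, compare.

Runs the standard study conditions (10 Mb genome, 50 homozygous deletions
of 100-10,000 bp, coverage 5, 100 bp reads at inner distance 200 +/- 50)
through the whole pipeline and prints the before/after-trimming accuracy
summary.
"""

from deltrim.pipeline import RunConfig, run_pipeline, summary_frame
from deltrim.simulate import SimConfig
from deltrim.trim import TrimParams

config = RunConfig(
    sim=SimConfig(seed=1),           # 10 Mb, 50 deletions, coverage 5
    trim=TrimParams(k=2, f=0.5),
    sd_multiplier=3.0,
    min_support=2,
)
result = run_pipeline(config)

print(summary_frame(result).round(3).to_string(index=False))
comp = result.comparison_upstream
print(
    f"\npaired upstream medians: raw {comp.median_before} bp -> "
    f"trimmed {comp.median_after} bp "
    f"({comp.fraction_improved:.0%} of calls improved, "
    f"{comp.fraction_overtrimmed:.0%} over-trimmed)"
)
print(
    "\nRead-pair calls here are already the tightest interval bounded by"
    "\ndiscordant reads, and coverage thins out over the last read length"
    "\nbefore each true breakpoint, so the trimmer finds little above its"
    "\nthreshold to remove: it is guaranteed harmless, and its gains appear"
    "\non calls that overshoot further (see trim_overshooting_call.py)."
)
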