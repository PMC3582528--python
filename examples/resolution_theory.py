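"""Expected breakpoint resolution as a function of coverage.

Tabulates, for 100 bp reads with a 200 bp inner pair distance, the expected
distance (in bases) between a true deletion breakpoint and the nearest
informative read: using discordant pairs only (`e_rp`), discordant pairs at
doubled coverage (`e_rp_2c`), and discordant plus concordant reads
(`e_concordant`).  A Monte-Carlo simulation of the same placement model is
run alongside as a sanity check.
"""

from deltrim.theory import resolution_table

table = resolution_table(
    coverages=[0.5, 1, 2, 5, 10, 20], r=100, d=200, monte_carlo=50_000, seed=0
)
cols = ["c", "q", "p_detect", "e_rp", "e_rp_2c", "e_concordant", "mc_mean_concordant"]
print(table[cols].round(3).to_string(index=False))

print(
    "\nReading the table: at each coverage, exploiting concordant reads"
    "\n(e_concordant) tightens the expected breakpoint offset to almost"
    "\nexactly what discordant-only calling would need double the coverage"
    "\nto reach (e_rp_2c); the Monte-Carlo column reproduces the closed form."
)
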