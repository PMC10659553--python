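"""Full synthetic WT-vs-AD cohort study, end to end.

Simulates the three study arms at their configured group parameters
(CVR: 8 WT / 12 AD animals; vessels: 6 + 6; density: 9 + 6), extracts
every metric through the analysis pipeline and prints the group summary
with pooled t-tests and significance stars.
"""

from vasoreact import pipeline

cfg = pipeline.RunConfig(seed=1)
table = pipeline.run_pipeline(cfg)

for _, row in table[table.group == "WT"].iterrows():
    ad = table[(table.group == "AD") & (table.roi_class == row.roi_class)
               & (table.metric == row.metric)].iloc[0]
    star = pipeline.significance_stars(row["p"])
    print(f"{row['metric']:9s} {row['roi_class']:9s} "
          f"WT {row['mean']:9.3f}+/-{row['sem']:6.3f} (n={row['n']:2d})  "
          f"AD {ad['mean']:9.3f}+/-{ad['sem']:6.3f} (n={ad['n']:2d})  "
          f"p={row['p']:.2g} {star}")
print()
print("Values are mean +/- SEM per group; p from the pooled two-tailed")
print("t-test. Units: peak %, ir %*min, rt min, cbfv mm/s, diameter um,")
print("ff_max/ff_mean unitless fill factor.")
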