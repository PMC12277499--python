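"""Method-agreement summaries from the packaged per-patient SUV tables.

Mean absolute per-patient difference (± population sd) per organ, plus the
unweighted cross-organ aggregate with its range. Whole-organ contours
disagree with the commercial single-VOI reading about twice as much as two
single-VOI implementations disagree with each other — the VOI-choice effect.
"""

from petquant.compare import agreement_report
from petquant.tables import load_table_fixture

table2 = load_table_fixture("table2")
df, (grand, lo, hi) = agreement_report(table2, "MIM", "contour")
print("SUVmax, commercial single VOI vs whole-organ contour:")
print(df[["organ", "mean", "sd"]].to_string(index=False))
print(f"aggregate {grand:.2f} (range, {lo:.2f}-{hi:.2f})\n")

table3 = load_table_fixture("table3")
for method, label in (("one VOI", "single-VOI"), ("contour", "whole-organ contour")):
    df, (grand, lo, hi) = agreement_report(table3, "MIM", method)
    print(f"SUVmean, commercial vs {label}: aggregate {grand:.3f} (range, {lo:.2f}-{hi:.2f})")
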