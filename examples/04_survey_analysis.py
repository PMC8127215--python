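"""Before/after survey analysis: did the simulation shift student estimates?

Students estimated how many first-year cases of a 1/10,000 condition their
graduating class would see.  Underestimates ('0 to 5', '6 to 9') are grouped
against the rest and tested with Pearson chi-squared on the 2x2 table.
"""

from rarecareer import group_to_2x2, load_table1, pearson_chi2, relative_percentages

table = load_table1()
print(relative_percentages(table).to_string())

grouped = group_to_2x2(table, split_after=2)
stat, df, p = pearson_chi2(grouped)
print(f"\ngrouped 2x2 (rows before/after, cols under/at-or-over):\n{grouped}")
print(f"chi-squared = {stat:.2f}, df = {df}, p = {p:.2e}")
print("\nBefore the class most students underestimated (57% answered <= 9); "
      "after it, 83% answered 10 or more - a highly significant shift "
      "(p < 0.0001). The simulator's own answer is ~14 cases.")
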