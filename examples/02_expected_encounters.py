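"""Closed-form desk arithmetic: expected case encounters by prevalence.

These linear expectations (prevalence x panel x years x clinicians) are the
deterministic oracle that the Monte Carlo simulator must agree with in mean.
"""

from rarecareer import (
    expected_annual_cases,
    expected_career_cases,
    expected_cohort_cases,
)
from rarecareer.expectations import expectation_table

print("one case per year:   ",
      expected_annual_cases(1 / 2000, panel_size=2000))
print("one case per career: ",
      expected_career_cases(1 / 60000, panel_size=2000, years=30))
print("cohort of 200, 1-in-a-million condition:",
      expected_cohort_cases(1e-6, panel_size=2000, years=30, n_clinicians=200))

# a grid for a 95-student dental cohort (panel 1500, 40-year careers)
print()
print(expectation_table([1e-3, 1e-4, 1e-5, 1e-6],
                        panel_size=1500, years=40, n_clinicians=95).to_string(index=False))
print("\nEven at prevalence 1e-6 the cohort expects ~5.7 career encounters.")
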