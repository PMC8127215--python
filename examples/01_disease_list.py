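"""Build the theoretical disease list and inspect its prevalence anchors.

462 conditions span prevalence 0.641 (code 1) down to 1e-6 (code 462) along a
decaying exponential; 73 are congenital/persistent.  Code 200 sits at the
1/500 = 2e-3 rare-disease threshold.
"""

from rarecareer import build_disease_list

dl = build_disease_list(seed=0)
print(f"{len(dl)} conditions, {dl.n_congenital} congenital/persistent")
for code in (1, 200, 303, 382, 462):
    c = dl[code - 1]
    print(f"  code {code:3d}: prevalence {c.prevalence:.3e}  ({c.acquisition_class})")

# prevalence at code 200 is the threshold below which a condition is 'rare';
# everything from there to code 462 is rare yet numerous in aggregate
rare_burden = sum(c.prevalence for c in dl if c.prevalence <= 2e-3)
print(f"summed prevalence of all rare conditions: {rare_burden:.3f}")
print("(a panel of 1500 therefore holds on the order of 100 rare-disease patients)")
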