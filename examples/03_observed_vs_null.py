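"""Test an observed association frequency against the random expectation.

Builds the 2x2 contingency table (observed vs. expected counts at the
same sample size) and applies the two-sided Fisher's exact test with the
conventional significance tiers (*P<0.05, **P<0.01, ***P<0.001).
"""

from nucassoc import FrequencySummary, compare_to_null, reference_null

# a trans pair associated in 27 of 200 2C nuclei (13.5%)
observed = FrequencySummary("association_trans", k=27, n=200)
null = reference_null("2C", "trans")  # 9.9%

result = compare_to_null(observed, null)
print(f"observed: {observed}")
print(f"null expectation: {null:.1f}%")
print(f"2x2 table: {result.table.as_list()}")
print(f"Fisher two-sided p = {result.p_value:.4f}  stars = {result.stars!r}")

strong = FrequencySummary("association_trans", k=60, n=200)
result = compare_to_null(strong, null)
print(f"\nobserved: {strong}")
print(f"Fisher two-sided p = {result.p_value:.3g}  stars = {result.stars!r}")

print("\nAn empty stars field means the observed frequency is compatible")
print("with random placement; stars mark frequencies unlikely under it.")
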