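"""Classify HpaII/MspI lane triplets and compute pattern ratios.

Builds the four canonical lane triplets by hand, classifies each, then
reproduces a published-style pattern-ratio row from per-type percentages.
"""

from credra import (
    LaneTriplet,
    classify_band,
    pattern_ratios_from_percent_vector,
)

print("Lane triplets (X, HpaII, MspI) -> methylation type")
for bits in [(1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1), (0, 1, 1)]:
    t = classify_band(LaneTriplet(*bits))
    label = f"Type {t.value} ({t.pattern_label})" if t else "unclassifiable"
    print(f"  {bits} -> {label}")

# Average type percentages of a control group (Type I..IV); the pattern
# ratios are the linear sums of the type shares.
pI, pII, pIII, pIV = 2.60, 3.40, 5.10, 86.60
r = pattern_ratios_from_percent_vector(pI, pII, pIII, pIV)
print(f"\nType shares (%): I={pI} II={pII} III={pIII} IV={pIV}")
print(f"  total methylation = II+III+IV = {r.total_methylation_percent:.2f} %")
print(f"  full  methylation = III+IV    = {r.full_methylation_percent:.2f} %")
print(f"  semi  methylation = II        = {r.semi_methylation_percent:.2f} %")
print("A total near 95 % says almost all scored CCGG loci carry some "
      "cytosine methylation; the semi share isolates hemi-methylated loci.")
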