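"""Median-split subgroup analysis: are EAT measures higher in the stiffer
half of the cohort, and do the aortic indices differ across EAT halves?"""

from aortastat import default_spec, derive_frame, generate
from aortastat.analysis import (
    AO_VARIABLES,
    EAT_VARIABLES,
    comparisons_to_frame,
    correlation_table,
    subgroup_table,
)

derived = derive_frame(generate(default_spec(seed=1)).frame)

comps = subgroup_table(derived, ["ao_stiffness_index"], EAT_VARIABLES)
print("EAT measures across the aortic-stiffness median split:")
print(comparisons_to_frame(comps).round(3).to_string(index=False))
print()
print("Each row compares the >= median subgroup against the < median one;")
print("test_used shows whether Shapiro-Wilk let Student's t run or forced")
print("the Mann-Whitney U.")
print()
print("EAT x aorta Pearson correlations (one cohort):")
print(correlation_table(derived, columns=AO_VARIABLES).round(2).to_string())
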