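"""Measure a selection-stringency frequency from simulated platings.

The culture is quantified by serial dilutions on permissive plates, then
1e10 cells are spread under restrictive conditions; breakthrough colonies
divided by cells plated is the stringency frequency (lower = better
selection).  Replicates are averaged geometrically.
"""
from negselect import (
    PlatingRecord,
    aggregate_replicates,
    cfu_from_dilution_counts,
    simulate_dilution_plating,
    simulate_stringency_assay,
    stringency_frequency,
)

true_escape = 1.1e-8
plated = 10**10

counts = simulate_dilution_plating(1e10, [1e6, 1e7, 1e8], 0.1, seed=1)
plates = [
    PlatingRecord(f"N{i}", "nonrestrictive", f, 0.1, c)
    for i, (f, c) in enumerate(zip([1e6, 1e7, 1e8], counts))
]
reference = cfu_from_dilution_counts(plates)
print(f"dilution counts       : {counts}")
print(f"reference density     : {reference.cfu_per_ml:.3g} CFU/ml")

replicates = []
for seed in (11, 12, 13):
    colonies = simulate_stringency_assay(true_escape, plated, seed=seed)
    result = stringency_frequency(colonies, plated)
    replicates.append(result.frequency)
    print(f"replicate seed {seed}     : {colonies} colonies -> frequency {result.frequency:.3g}")

summary = aggregate_replicates(replicates)
print(f"geometric mean        : {summary.geometric_mean:.3g}  (log10 SD {summary.log10_sd:.3f})")
print(f"true escape frequency : {true_escape:.3g}")
# A zero-colony replicate would instead be reported as the rule-of-three
# upper bound 3 / cells plated and kept out of the geometric mean.
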