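"""The integrative candidate chain on the published worked-example tables.

Feeds the published 12-gene integrative screening table (direction of
differential expression, AR-ChIP detection, qRT-PCR validation) through
``integrate_candidates`` and recomputes the published cross-study overlap
percentages and Venn totals from their count pairs.
"""

from cistroscreen import datasets
from cistroscreen.cistrome import cross_study_overlap, venn_counts
from cistroscreen.screen import integrate_candidates

records = integrate_candidates(**datasets.candidate_inputs())
final = sorted(r.gene for r in records if r.final_pass)
print(f"{len(records)} genes entered the chain; {len(final)} final candidates:")
print(" ", ", ".join(final))
for r in records:
    if not r.final_pass:
        reason = "no AR-binding site" if not r.arbs_pass else "failed qRT-PCR validation"
        print(f"  dropped {r.gene}: {reason}")

print()
for label, (n_overlap, n_ref) in datasets.cross_study_overlap_counts().items():
    query = [f"q{i}" for i in range(n_overlap)]
    reference = query + [f"r{i}" for i in range(n_ref - n_overlap)]
    _, _, pct = cross_study_overlap(query, reference)
    print(f"overlap with {label}: {n_overlap}/{n_ref} = {pct}%")

for label, counts in datasets.venn_partition_counts().items():
    print(f"venn total {label}: {venn_counts(counts)[3]} bound genes")
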