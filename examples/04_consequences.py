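"""Classify the functional impact of each clone's edits.

The reference is annotated with a Kozak window, the main ORF (exon) and the
2-nt splice donor; each clone is scored for Kozak disruption, reading-frame
status and splice-donor integrity.
"""

from nhejscope import GuideRNA, NhejModel, call_cohort, cohort_consequences, make_reference, simulate_cohort
from nhejscope.indelcall import INDEL_FAITHFUL_SCORING

guide = GuideRNA("gRNA1", "GCCTCCGGGGACTGCCGTGC")
ref, cut = make_reference(
    40, guide, "TGG", 80,
    features=[
        ("kozak", 66, 76),        # initiation context: [ATG-6, ATG+4)
        ("start_codon", 72, 75),
        ("exon", 72, 130),
        ("splice_donor", 130, 132),
    ],
    seed=31,
)
clones, _ = simulate_cohort(ref, cut, NhejModel(w_small=0.3), 20, seed=32)
records = call_cohort(ref, clones, INDEL_FAITHFUL_SCORING)

table, fractions = cohort_consequences(records, ref)
print(table.to_string(index=False))
print()
for key, pct in fractions.items():
    shown = "not annotated" if pct is None else f"{pct:.0f}%"
    print(f"  {key}: {shown}")
# A clone is 'disrupted' for a feature when an edit overlaps it positionally;
# 'frameshift' means the net length change inside the ORF is not a multiple
# of 3. No strength scoring is attempted.
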