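"""Parse cloning-oligo pairs into guides and predict their cut sites.

Builds a synthetic reference with each protospacer embedded next to an NGG
PAM, locates the site and prints where SpCas9 would cut (3 nt 5' of the
PAM, as an inter-base coordinate).
"""

from nhejscope import locate_protospacer, make_reference, parse_cloning_oligo, predict_cut_site

OLIGOS = {
    "gRNA1": ("CACCGGCCTCCGGGGACTGCCGTGC", "CCGGAGGCCCCTGACGGCACGCAAA"),
    "gRNA2": ("CACCGGGTTCGTGTCGCCGGCCCGC", "CCCAAGCACAGCGGCCGGGCGCAAA"),
}

for name, (top, bottom) in OLIGOS.items():
    guide = parse_cloning_oligo(top, bottom, name=name)
    print(f"{name}: protospacer {guide.protospacer} ({len(guide)} nt), "
          f"bottom oligo orientation: {guide.bottom_orientation}")

    ref, cut = make_reference(40, guide, "TGG", 40, seed=7)
    match = locate_protospacer(guide, ref)
    s, e = match.target_interval
    print(f"  embedded at [{s},{e}) strand {match.strand}, PAM {match.pam_seq}; "
          f"cut between positions {cut.interbase - 1} and {cut.interbase} "
          f"({match.pam_interval[0] - cut.interbase} nt 5' of the PAM)")

# The cut index is inter-base: a deletion [cut-u, cut+d) removes u bases
# upstream and d bases downstream of the double-strand break.
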