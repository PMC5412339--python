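"""Guides, reference amplicons, protospacer location and cut-site prediction.

This module models the DNA side of a CRISPR-Cas9 editing experiment:

* :class:`GuideRNA` — a 20-nt protospacer (21 nt when the scaffold-appended
  leading G of the cloning oligo is retained), either given raw or parsed
  from the top/bottom oligo pair used for BsmBI golden-gate cloning into a
  lentiCRISPR-style vector.
* :class:`ReferenceAmplicon` — the genotyping amplicon the edited clones are
  aligned against, with optional feature annotations (Kozak window, start
  codon, uORF, splice donor, primers).
* :func:`locate_protospacer` / :func:`predict_cut_site` — exact-match search
  for protospacer + NGG PAM on either strand, and the SpCas9 blunt-cut rule:
  the double-strand break falls 3 nt 5' of the PAM on the protospacer strand.
* :func:`virtual_pcr` — extract the amplicon a primer pair would produce.

Coordinates are 0-based half-open on the + strand throughout; a cut site is
an inter-base index (the break falls between positions ``interbase - 1`` and
``interbase``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio.Seq import reverse_complement

from .errors import (
    AmbiguousTargetError,
    FeatureError,
    MalformedOligoError,
    OligoValidationError,
    OrientationError,
    SequenceError,
    TargetNotFoundError,
)

DNA_ALPHABET = frozenset("ACGT")

#: 4-nt 5' overhang left by BsmBI digestion of the vector, present on every
#: top cloning oligo.
TOP_OVERHANG = "CACC"
#: overhang of the conventional bottom oligo (5'->3': AAAC + revcomp(guide)).
BOTTOM_OVERHANG = "AAAC"

FeatureLabel = Literal[
    "kozak", "start_codon", "uORF", "splice_donor", "exon", "intron",
    "primer_fwd", "primer_rev", "other",
]
FEATURE_LABELS = (
    "kozak", "start_codon", "uORF", "splice_donor", "exon", "intron",
    "primer_fwd", "primer_rev", "other",
)


def _check_dna(seq: str, what: str, alphabet: frozenset = DNA_ALPHABET) -> str:
    if not seq:
        raise SequenceError(f"{what} is empty")
    bad = set(seq) - alphabet
    if bad:
        raise SequenceError(
            f"{what} contains characters outside {{{','.join(sorted(alphabet))}}}: "
            f"{sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class GuideRNA:
    """A guide's protospacer, 20 nt (21 with the scaffold G retained)."""

    name: str
    protospacer: str
    source: Literal["raw", "oligo_pair"] = "raw"
    #: how the bottom oligo validated, when parsed from an oligo pair:
    #: "conventional" (5'->3' AAAC + revcomp) or "written_3to5"
    #: (the printed string is the 3'->5' reading of that same strand).
    bottom_orientation: str | None = None

    def __post_init__(self) -> None:
        _check_dna(self.protospacer, f"protospacer of guide {self.name!r}")
        if len(self.protospacer) not in (20, 21):
            raise SequenceError(
                f"protospacer of guide {self.name!r} must be 20 or 21 nt, "
                f"got {len(self.protospacer)}"
            )

    def __len__(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A labelled interval on the + strand of a reference amplicon."""

    label: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.label not in FEATURE_LABELS:
            raise FeatureError(
                f"unknown feature label {self.label!r}; expected one of {FEATURE_LABELS}"
            )
        if not (0 <= self.start < self.end):
            raise FeatureError(
                f"feature {self.label}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A reference sequence plus its feature annotations."""

    id: str
    seq: str
    features: tuple[FeatureAnnotation, ...] = ()

    def __post_init__(self) -> None:
        _check_dna(self.seq, f"reference {self.id!r}", DNA_ALPHABET | {"N"})
        for f in self.features:
            if f.end > len(self.seq):
                raise FeatureError(
                    f"feature {f.label} [{f.start},{f.end}) exceeds reference "
                    f"{self.id!r} of length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, label: str) -> FeatureAnnotation | None:
        """First feature with the given label, or None if not annotated."""
        for f in self.features:
            if f.label == label:
                return f
        return None

    def with_features(self, features: Sequence[FeatureAnnotation]) -> "ReferenceAmplicon":
        return ReferenceAmplicon(self.id, self.seq, tuple(features))


@dataclass(frozen=True)
class ProtospacerMatch:
    """An exact protospacer+PAM occurrence in a reference.

    ``target_interval`` and ``pam_interval`` are + strand coordinates even
    for - strand matches; ``pam_seq`` is reported on the protospacer strand,
    so it reads NGG for a valid match on either strand.
    """

    guide_name: str
    target_interval: tuple[int, int]
    strand: Literal["+", "-"]
    pam_interval: tuple[int, int]
    pam_seq: str


@dataclass(frozen=True)
class CutSite:
    """Blunt double-strand break as an inter-base index on the + strand."""

    interbase: int
    strand_of_guide: Literal["+", "-"]


def parse_cloning_oligo(
    top: str,
    bottom: str,
    keep_scaffold_g: bool = False,
    name: str = "guide",
    strict: bool = False,
) -> GuideRNA:
    """Recover the protospacer from a top/bottom cloning-oligo pair.

    The top oligo is ``CACC`` + protospacer (a leading G is appended during
    design when the genomic 20-mer does not start with G, so the insert may
    be 21 nt). The bottom oligo is validated in two orientations:

    * conventional: bottom (5'->3') == ``AAAC`` + revcomp(insert);
    * written 3'->5': the printed string is that same strand spelled
      backwards, i.e. reverse(bottom) == ``AAAC`` + revcomp(insert).

    ``strict=True`` accepts only the conventional orientation. With
    ``keep_scaffold_g=False`` (default) a 21-nt insert beginning with G is
    reported as the 20-nt genomic protospacer; validation always uses the
    full insert, which is what anneals to the bottom oligo.
    """
    _check_dna(top, "top oligo")
    _check_dna(bottom, "bottom oligo")
    if not top.startswith(TOP_OVERHANG):
        raise MalformedOligoError(
            f"top oligo must begin with the {TOP_OVERHANG} overhang; got {top[:4]!r}"
        )
    insert = top[len(TOP_OVERHANG):]
    if len(insert) not in (20, 21):
        raise MalformedOligoError(
            f"insert after the {TOP_OVERHANG} overhang must be 20 or 21 nt, "
            f"got {len(insert)}"
        )

    expected = BOTTOM_OVERHANG + reverse_complement(insert)
    diagnostics = []
    orientation = None
    if bottom == expected:
        orientation = "conventional"
    else:
        diagnostics.append(
            f"conventional 5'->3': expected {expected}, got {bottom}"
        )
        if not strict and bottom[::-1] == expected:
            orientation = "written_3to5"
        else:
            diagnostics.append(
                f"written 3'->5' (string reversed): expected {expected}, "
                f"got {bottom[::-1]}"
                + (" [rejected: strict mode]" if strict else "")
            )
    if orientation is None:
        raise OligoValidationError(
            "bottom oligo inconsistent with protospacer under every accepted "
            "orientation:\n  " + "\n  ".join(diagnostics)
        )

    protospacer = insert
    if len(insert) == 21 and insert.startswith("G") and not keep_scaffold_g:
        protospacer = insert[1:]
    return GuideRNA(
        name=name,
        protospacer=protospacer,
        source="oligo_pair",
        bottom_orientation=orientation,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_protospacer(
    guide: GuideRNA,
    ref: ReferenceAmplicon,
    pam: str = "NGG",
) -> ProtospacerMatch:
    """Find the unique protospacer+PAM site on either strand.

    Exact match only (no mismatch tolerance): the intended use is a designed
    perfect site in an amplicon, not off-target scanning. The PAM pattern may
    use N as a wildcard; it must sit immediately 3' of the protospacer on the
    protospacer strand, so on the - strand the + strand shows
    revcomp(PAM) immediately 5' of the matched interval (CCN for NGG).
    """
    proto = guide.protospacer
    if len(ref) < len(proto) + len(pam):
        raise SequenceError(
            f"reference {ref.id!r} shorter than protospacer + PAM "
            f"({len(ref)} < {len(proto) + len(pam)})"
        )

    def pam_ok(s: str) -> bool:
        return len(s) == len(pam) and all(
            p == "N" or p == b for p, b in zip(pam, s)
        )

    matches: list[ProtospacerMatch] = []
    for s in _find_all(ref.seq, proto):
        e = s + len(proto)
        pam_obs = ref.seq[e:e + len(pam)]
        if pam_ok(pam_obs):
            matches.append(ProtospacerMatch(
                guide_name=guide.name, target_interval=(s, e), strand="+",
                pam_interval=(e, e + len(pam)), pam_seq=pam_obs,
            ))
    rc = reverse_complement(proto)
    for s in _find_all(ref.seq, rc):
        e = s + len(rc)
        p0 = s - len(pam)
        if p0 >= 0 and pam_ok(reverse_complement(ref.seq[p0:s])):
            matches.append(ProtospacerMatch(
                guide_name=guide.name, target_interval=(s, e), strand="-",
                pam_interval=(p0, s), pam_seq=reverse_complement(ref.seq[p0:s]),
            ))

    if not matches:
        raise TargetNotFoundError(
            f"protospacer of guide {guide.name!r} not found with a {pam} PAM "
            f"in reference {ref.id!r}"
        )
    if len(matches) > 1:
        sites = ", ".join(
            f"[{m.target_interval[0]},{m.target_interval[1]}){m.strand}"
            for m in matches
        )
        raise AmbiguousTargetError(
            f"guide {guide.name!r} matches reference {ref.id!r} at "
            f"{len(matches)} sites: {sites}"
        )
    return matches[0]


def predict_cut_site(match: ProtospacerMatch) -> CutSite:
    """SpCas9 blunt cut: 3 nt between the break and the PAM.

    On the + strand (PAM at [e, e+3)) the break falls at inter-base ``e - 3``
    (between protospacer positions 17 and 18 of a 20-mer); on the - strand
    (revcomp PAM at [s-3, s)) it falls at ``s + 3``. The rule is anchored on
    the PAM, so retaining a scaffold G does not move the cut.
    """
    s, e = match.target_interval
    if match.strand == "+":
        return CutSite(interbase=e - 3, strand_of_guide="+")
    return CutSite(interbase=s + 3, strand_of_guide="-")


def virtual_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    amplicon_id: str = "amplicon",
) -> ReferenceAmplicon:
    """Extract the product a primer pair would amplify from a template.

    The forward primer must match the + strand exactly and uniquely; the
    reverse primer anneals to the + strand as its reverse complement,
    downstream of the forward match. Both primers are included in the
    product, which is annotated with ``primer_fwd`` / ``primer_rev``
    features in product coordinates.
    """
    _check_dna(template, "template", DNA_ALPHABET | {"N"})
    for p, what in ((fwd_primer, "forward primer"), (rev_primer, "reverse primer")):
        _check_dna(p, what)
        if len(p) < 15:
            raise SequenceError(f"{what} shorter than 15 nt ({len(p)})")

    fwd_hits = _find_all(template, fwd_primer)
    rev_rc = reverse_complement(rev_primer)
    rev_hits = _find_all(template, rev_rc)
    if not fwd_hits:
        raise TargetNotFoundError("forward primer has no exact match in template")
    if not rev_hits:
        raise TargetNotFoundError(
            "reverse primer has no exact match (as reverse complement) in template"
        )
    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        raise AmbiguousTargetError(
            f"multiple products possible: forward primer at {fwd_hits}, "
            f"reverse-primer complement at {rev_hits}"
        )
    f, r = fwd_hits[0], rev_hits[0]
    r_end = r + len(rev_rc)
    if r_end <= f + len(fwd_primer):
        raise OrientationError(
            f"reverse-primer match [{r},{r_end}) lies upstream of the forward "
            f"primer at {f}; primers do not converge"
        )
    product = template[f:r_end]
    n = len(product)
    return ReferenceAmplicon(
        id=amplicon_id,
        seq=product,
        features=(
            FeatureAnnotation("primer_fwd", 0, len(fwd_primer), "+"),
            FeatureAnnotation("primer_rev", n - len(rev_primer), n, "-"),
        ),
    )


def guide_feature_distances(
    match: ProtospacerMatch, feature: FeatureAnnotation
) -> dict[str, int]:
    """Signed gaps between each guide end and each feature end.

    Reported because "distance from guide to feature" is ambiguous: four
    numbers are returned (guide 5'/3' end on the + strand vs feature
    start/end), positive when the feature lies downstream of that guide end.
    The caller chooses the convention; no default is imposed.
    """
    s, e = match.target_interval
    return {
        "guide_start_to_feature_start": feature.start - s,
        "guide_start_to_feature_end": feature.end - s,
        "guide_end_to_feature_start": feature.start - e,
        "guide_end_to_feature_end": feature.end - e,
    }
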