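"""Functional-consequence classification of called edits.

Classification is purely positional — does an edit touch the annotated
feature — with no attempt to score how badly translation or splicing is
affected:

* Kozak / uORF-start disruption: any deletion overlapping the feature
  interval, or an insertion strictly inside it. Edits 5' of the start codon
  matter because the translation-initiation context (the Kozak sequence)
  and any upstream ORF regulate initiation of the main ORF.
* Reading-frame status: net length change of the edits inside the ORF,
  modulo 3.
* Splice-donor disruption: loss or interruption of the first two intron
  bases (the canonical GT), whose removal yields mis-spliced or truncated
  products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import FeatureError, NhejscopeError
from .indelcall import CloneEditRecord
from .refmodel import FeatureAnnotation, ReferenceAmplicon

Disruption = Literal["intact", "disrupted", "not_annotated"]
Frame = Literal["in_frame", "frameshift", "not_applicable"]


@dataclass(frozen=True)
class ConsequenceCall:
    clone_id: str
    kozak: Disruption
    uorf_start: Disruption
    frame: Frame
    splice_donor: Disruption


def feature_disruption(
    record: CloneEditRecord, feature: FeatureAnnotation
) -> Disruption:
    """"disrupted" iff a deletion overlaps the feature (half-open overlap)
    or an insertion point lies strictly inside it.

    An insertion exactly at the feature boundary leaves the feature's own
    bases contiguous and is counted intact.
    """
    for call in record.deletions:
        if call.start < feature.end and call.end > feature.start:
            return "disrupted"
    for call in record.insertions:
        if feature.start < call.start < feature.end:
            return "disrupted"
    return "intact"


def frameshift_status(
    record: CloneEditRecord, orf: FeatureAnnotation
) -> Frame:
    """Frame status of the ORF: net signed length change of the edits that
    touch the ORF, modulo 3.

    Deletions contribute only their bases inside the ORF; insertions
    contribute their full length when the point is strictly inside.
    Edits entirely outside the ORF give "not_applicable".
    """
    net = 0
    touched = False
    for call in record.deletions:
        ov = min(call.end, orf.end) - max(call.start, orf.start)
        if ov > 0:
            net -= ov
            touched = True
    for call in record.insertions:
        if orf.start < call.start < orf.end:
            net += call.length
            touched = True
    if not touched:
        return "not_applicable"
    return "in_frame" if net % 3 == 0 else "frameshift"


def splice_donor_check(
    record: CloneEditRecord, donor: FeatureAnnotation
) -> Disruption:
    """Disruption of the 2-nt splice donor (the GT at the exon-intron
    boundary).

    Disrupted when either donor base is deleted, or an insertion separates
    the two bases (point between G and T) or separates the donor from its
    exon (point immediately 5' of the G) — either way the donor no longer
    follows the exon intact.
    """
    if len(donor) != 2:
        raise FeatureError(
            f"splice donor feature must span exactly 2 nt, got "
            f"[{donor.start},{donor.end})"
        )
    g = donor.start
    for call in record.deletions:
        if call.start < donor.end and call.end > g:
            return "disrupted"
    for call in record.insertions:
        if call.start in (g, g + 1):
            return "disrupted"
    return "intact"


def classify_clone(
    record: CloneEditRecord, ref: ReferenceAmplicon
) -> ConsequenceCall:
    """All consequence calls for one clone, "not_annotated" where the
    reference lacks the feature."""
    kozak = ref.feature("kozak")
    uorf = ref.feature("uORF")
    donor = ref.feature("splice_donor")
    exon = ref.feature("exon")
    return ConsequenceCall(
        clone_id=record.clone_id,
        kozak="not_annotated" if kozak is None else feature_disruption(record, kozak),
        uorf_start="not_annotated" if uorf is None else feature_disruption(record, uorf),
        frame="not_applicable" if exon is None else frameshift_status(record, exon),
        splice_donor=(
            "not_annotated" if donor is None else splice_donor_check(record, donor)
        ),
    )


def cohort_consequences(
    records: Sequence[CloneEditRecord],
    ref: ReferenceAmplicon,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Per-clone consequence table plus disrupted/frameshift fractions.

    Fractions are percentages of the cohort; a category whose feature is
    not annotated on the reference reports None.
    """
    if not records:
        raise NhejscopeError("cohort_consequences requires at least one record")
    calls = [classify_clone(r, ref) for r in records]
    df = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in calls],
            "kozak": [c.kozak for c in calls],
            "uorf_start": [c.uorf_start for c in calls],
            "frame": [c.frame for c in calls],
            "splice_donor": [c.splice_donor for c in calls],
        }
    )
    n = len(calls)

    def frac(col: str, value: str, absent: str) -> float | None:
        if (df[col] == absent).all():
            return None
        return 100.0 * (df[col] == value).sum() / n

    fractions = {
        "kozak_disrupted_pct": frac("kozak", "disrupted", "not_annotated"),
        "uorf_start_disrupted_pct": frac("uorf_start", "disrupted", "not_annotated"),
        "frameshift_pct": frac("frame", "frameshift", "not_applicable"),
        "splice_donor_disrupted_pct": frac(
            "splice_donor", "disrupted", "not_annotated"
        ),
    }
    return df, fractions
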