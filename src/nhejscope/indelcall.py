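"""Indel calling in edited clones by global alignment to a reference.

The workflow mirrors how Sanger-sequenced clones from a TA-cloned genotyping
amplicon are scored: each clone is globally aligned to the reference
(Needleman-Wunsch with affine gaps), maximal gap runs become individual
insertion/deletion calls, calls are left-aligned so placements inside repeat
tracts are canonical, and each clone is classified as unmodified / deletion /
insertion / both. A cohort summary reports the class census and the
minimum/maximum total deletion, the headline numbers of an NHEJ spectrum.

Default scoring (+2 / -3, gap open -5, extend -1) deliberately favours one
contiguous gap over scattered small ones, so a single NHEJ event is reported
as a single call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from . import _align
from .errors import NhejscopeError, SequenceError
from .refmodel import ReferenceAmplicon, _check_dna, DNA_ALPHABET

EditClass = Literal["unmodified", "deletion", "insertion", "both"]
EDIT_CLASSES: tuple[str, ...] = ("unmodified", "deletion", "insertion", "both")


@dataclass(frozen=True)
class CloneSequence:
    """One sequenced clone; N is tolerated and never matches."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_dna(self.seq, f"clone {self.id!r}", DNA_ALPHABET | {"N"})

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if abs(self.gap_open) < abs(self.gap_extend):
            raise ValueError("|gap_open| must be >= |gap_extend|")


DEFAULT_SCORING = ScoringScheme()

#: Scheme for error-free (Sanger-grade) clones, where an apparent
#: substitution is implausible and every edit should surface as an indel:
#: the mismatch penalty is made prohibitive (it must beat 2*gap_open/L +
#: 2*gap_extend for every event size L, down to the 1-nt deletion + 1-nt
#: insertion that a tolerant scheme would report as a point substitution).
#: Use this to recover ground-truth indel sizes; the default scheme, which
#: tolerates substitutions, will absorb small junction insertions into
#: mismatch columns instead.
INDEL_FAITHFUL_SCORING = ScoringScheme(match=2.0, mismatch=-50.0,
                                       gap_open=-5.0, gap_extend=-1.0)


@dataclass(frozen=True)
class Alignment:
    """Gapped rows of a global alignment; ref with gaps removed is the
    original reference, likewise for the query."""

    ref_row: str
    query_row: str
    score: float

    @property
    def ref(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")


@dataclass(frozen=True)
class IndelCall:
    """One indel. Deletions delete ``ref[start:end)``; insertions insert
    ``inserted_seq`` immediately before reference position ``start``
    (start == end)."""

    kind: Literal["deletion", "insertion"]
    start: int
    end: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind == "deletion":
            if not (self.start < self.end) or self.inserted_seq:
                raise ValueError(f"malformed deletion call {self}")
        elif self.kind == "insertion":
            if self.start != self.end or not self.inserted_seq:
                raise ValueError(f"malformed insertion call {self}")
        else:
            raise ValueError(f"unknown call kind {self.kind!r}")

    @property
    def length(self) -> int:
        if self.kind == "deletion":
            return self.end - self.start
        return len(self.inserted_seq)

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __str__(self) -> str:
        if self.kind == "deletion":
            return f"del:{self.start}-{self.end}"
        return f"ins:{self.start}:{self.inserted_seq}"


@dataclass(frozen=True)
class CloneEditRecord:
    clone_id: str
    calls: tuple[IndelCall, ...]
    net_change: int
    edit_class: EditClass
    substitutions: int = 0
    flags: tuple[str, ...] = ()

    @property
    def total_deleted(self) -> int:
        return sum(c.length for c in self.calls if c.kind == "deletion")

    @property
    def total_inserted(self) -> int:
        return sum(c.length for c in self.calls if c.kind == "insertion")

    @property
    def deletions(self) -> tuple[IndelCall, ...]:
        return tuple(c for c in self.calls if c.kind == "deletion")

    @property
    def insertions(self) -> tuple[IndelCall, ...]:
        return tuple(c for c in self.calls if c.kind == "insertion")


@dataclass(frozen=True)
class EditSummary:
    n_clones: int
    class_counts: dict
    min_deletion: int | None
    max_deletion: int | None


def global_align(
    ref: str, query: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Optimal Needleman-Wunsch global alignment with affine gap penalties.

    Deterministic: score ties are broken diagonal > up > left in the dynamic
    program, so identical inputs always give an identical alignment.
    """
    if not ref or not query:
        raise SequenceError("cannot align empty sequences")
    score, ops = _align.gotoh_align(
        ref, query, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    r_parts, q_parts = [], []
    i = j = 0
    for op in ops:
        if op == _align.OP_DIAG:
            r_parts.append(ref[i]); q_parts.append(query[j])
            i += 1; j += 1
        elif op == _align.OP_UP:
            r_parts.append(ref[i]); q_parts.append("-")
            i += 1
        else:
            r_parts.append("-"); q_parts.append(query[j])
            j += 1
    return Alignment("".join(r_parts), "".join(q_parts), float(score))


def _raw_calls(alignment: Alignment) -> tuple[list[IndelCall], int]:
    """Gap runs -> calls in alignment order, plus the substitution count."""
    calls: list[IndelCall] = []
    subs = 0
    ref_pos = 0
    gap_kind: str | None = None
    gap_start = 0
    gap_seq: list[str] = []

    def flush() -> None:
        nonlocal gap_kind, gap_seq
        if gap_kind == "deletion":
            calls.append(IndelCall("deletion", gap_start, ref_pos))
        elif gap_kind == "insertion":
            calls.append(IndelCall("insertion", gap_start, gap_start, "".join(gap_seq)))
        gap_kind, gap_seq = None, []

    for rc, qc in zip(alignment.ref_row, alignment.query_row):
        if rc != "-" and qc != "-":
            flush()
            if rc != qc:
                subs += 1
            ref_pos += 1
        elif qc == "-":
            if gap_kind != "deletion":
                flush()
                gap_kind, gap_start = "deletion", ref_pos
            ref_pos += 1
        else:  # rc == "-": insertion
            if gap_kind != "insertion":
                flush()
                gap_kind, gap_start = "insertion", ref_pos
            gap_seq.append(qc)
    flush()
    return calls, subs


def left_align_calls(ref: str, calls: Sequence[IndelCall]) -> list[IndelCall]:
    """Shift every call to its smallest reference coordinate that leaves the
    implied edited sequence unchanged (canonical placement in repeats).

    Calls are processed left to right and never shifted past an earlier
    call, which preserves exact reconstruction of the query.
    """
    out: list[IndelCall] = []
    bound = 0
    for call in calls:
        if call.kind == "deletion":
            s, e = call.start, call.end
            while s > bound and ref[s - 1] == ref[e - 1]:
                s -= 1; e -= 1
            out.append(IndelCall("deletion", s, e))
            bound = e
        else:
            p = call.start
            seq = call.inserted_seq
            while p > bound and ref[p - 1] == seq[-1]:
                seq = ref[p - 1] + seq[:-1]
                p -= 1
            out.append(IndelCall("insertion", p, p, seq))
            bound = p
    return out


def normalize_indels(alignment: Alignment) -> list[IndelCall]:
    """Turn each maximal gap run into one left-aligned IndelCall."""
    calls, _ = _raw_calls(alignment)
    return left_align_calls(alignment.ref, calls)


def apply_calls(ref: str, calls: Sequence[IndelCall]) -> str:
    """Reconstruct the edited sequence implied by a set of calls.

    Calls must be sorted and non-overlapping (as produced by
    :func:`normalize_indels`); used for round-trip verification.
    """
    out: list[str] = []
    pos = 0
    for call in calls:
        if call.start < pos:
            raise NhejscopeError(f"overlapping or unsorted calls at {call}")
        out.append(ref[pos:call.start])
        if call.kind == "insertion":
            out.append(call.inserted_seq)
            pos = call.start
        else:
            pos = call.end
    out.append(ref[pos:])
    return "".join(out)


def classify(calls: Sequence[IndelCall]) -> EditClass:
    has_del = any(c.kind == "deletion" for c in calls)
    has_ins = any(c.kind == "insertion" for c in calls)
    if has_del and has_ins:
        return "both"
    if has_del:
        return "deletion"
    if has_ins:
        return "insertion"
    return "unmodified"


def call_edits(
    ref: ReferenceAmplicon | str,
    clone: CloneSequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
    length_tolerance: float = 0.9,
) -> CloneEditRecord:
    """Align one clone to the reference and call its edits.

    A clone whose length differs from the reference by more than
    ``length_tolerance`` (fraction of the reference length) is flagged
    ``length_out_of_bounds`` — likely a truncated read or wrong amplicon —
    but is still aligned and reported, never dropped.
    """
    ref_seq = ref.seq if isinstance(ref, ReferenceAmplicon) else ref
    flags: tuple[str, ...] = ()
    if abs(len(clone.seq) - len(ref_seq)) > length_tolerance * len(ref_seq):
        flags = ("length_out_of_bounds",)
    aln = global_align(ref_seq, clone.seq, scoring)
    raw, subs = _raw_calls(aln)
    calls = tuple(left_align_calls(ref_seq, raw))
    net = sum(c.length for c in calls if c.kind == "insertion") - sum(
        c.length for c in calls if c.kind == "deletion"
    )
    return CloneEditRecord(
        clone_id=clone.id,
        calls=calls,
        net_change=net,
        edit_class=classify(calls),
        substitutions=subs,
        flags=flags,
    )


def call_cohort(
    ref: ReferenceAmplicon | str,
    clones: Iterable[CloneSequence],
    scoring: ScoringScheme = DEFAULT_SCORING,
    length_tolerance: float = 0.9,
) -> list[CloneEditRecord]:
    return [call_edits(ref, c, scoring, length_tolerance) for c in clones]


def summarize_cohort(records: Sequence[CloneEditRecord]) -> EditSummary:
    """Cohort census: class counts and the min/max total deletion per clone.

    Clones with no deleted bases are excluded from the min/max; when no
    clone deletes anything both extremes are None.
    """
    if not records:
        raise NhejscopeError("summarize_cohort requires at least one record")
    counts = Counter(r.edit_class for r in records)
    class_counts = {c: counts.get(c, 0) for c in EDIT_CLASSES}
    totals = [r.total_deleted for r in records if r.total_deleted > 0]
    return EditSummary(
        n_clones=len(records),
        class_counts=class_counts,
        min_deletion=min(totals) if totals else None,
        max_deletion=max(totals) if totals else None,
    )
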