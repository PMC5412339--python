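"""File I/O: FASTA sequences, BED-like feature tables, CSV data tables.

Thin wrappers over Bio.SeqIO and pandas that translate between files and
the package's domain objects. All text, no binary formats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, FeatureError
from .indelcall import CloneEditRecord, CloneSequence
from .profile import PositionalProfile
from .refmodel import FeatureAnnotation, ReferenceAmplicon
from .synthetic_data import TruthRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"FASTA file not found: {path}")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ConfigError(f"no sequences in FASTA file {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_clones(path: str | Path) -> list[CloneSequence]:
    return [CloneSequence(name, seq) for name, seq in read_fasta(path)]


def read_features_tsv(path: str | Path, amplicon_id: str | None = None) -> list[FeatureAnnotation]:
    """BED-like 4-column TSV: amplicon id, start, end, label (0-based
    half-open); an optional 5th column is the strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label", "strand"],
        usecols=range(5), engine="python",
    )
    feats = []
    for row in df.itertuples(index=False):
        if amplicon_id is not None and row.chrom != amplicon_id:
            continue
        strand = row.strand if row.strand in ("+", "-") else "+"
        feats.append(FeatureAnnotation(row.label, int(row.start), int(row.end), strand))
    if amplicon_id is not None and not feats and len(df):
        raise FeatureError(
            f"no features for amplicon {amplicon_id!r} in {path}"
        )
    return feats


def read_reference(
    fasta_path: str | Path, features_path: str | Path | None = None
) -> ReferenceAmplicon:
    """First sequence of a FASTA as the reference, with optional features."""
    name, seq = read_fasta(fasta_path)[0]
    feats = (
        tuple(read_features_tsv(features_path, amplicon_id=name))
        if features_path else ()
    )
    return ReferenceAmplicon(name, seq, feats)


def calls_to_frame(
    records: Sequence[CloneEditRecord],
    consequences: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-clone table: class, calls (del:start-end / ins:pos:seq),
    net change, total deleted, substitutions, flags — plus consequence
    columns when provided."""
    df = pd.DataFrame(
        {
            "clone_id": [r.clone_id for r in records],
            "edit_class": [r.edit_class for r in records],
            "calls": [";".join(str(c) for c in r.calls) for r in records],
            "net_change": [r.net_change for r in records],
            "total_deleted": [r.total_deleted for r in records],
            "substitutions": [r.substitutions for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
    if consequences is not None:
        df = df.merge(consequences, on="clone_id", how="left")
    return df


def write_calls_tsv(
    path: str | Path,
    records: Sequence[CloneEditRecord],
    consequences: pd.DataFrame | None = None,
) -> None:
    calls_to_frame(records, consequences).to_csv(path, sep="\t", index=False)


def profile_to_frame(profile: PositionalProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "percent_deleted": profile.percent_deleted,
            "n_clones": profile.n_clones,
        }
    )


def write_profile_tsv(path: str | Path, profile: PositionalProfile) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def write_truth_tsv(path: str | Path, truths: Sequence[TruthRecord]) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "clone_id": t.clone_id,
                "edit_class": t.edit_class,
                "deletions": ";".join(f"{s}-{e}" for s, e in t.deletions),
                "insertion": (
                    f"{t.insertion[0]}:{t.insertion[1]}" if t.insertion else ""
                ),
                "total_deleted": t.total_deleted,
                "net_change": t.net_change,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise ConfigError(f"Ct table not found: {path}")
    return pd.read_csv(path)


def read_densitometry_csv(path: str | Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise ConfigError(f"densitometry table not found: {path}")
    return pd.read_csv(path)
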