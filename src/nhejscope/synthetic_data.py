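"""Ground-truthed synthetic inputs for every pipeline stage.

The clone generator emulates the outcome of NHEJ repair at a single Cas9
cut in a clonal amplicon cohort: each clone is unmodified, carries an
insertion at the cut, a deletion spanning the cut, or both. Deletion sizes
come from a two-component mixture — a geometric bulk of small events plus a
uniform tail of large ones — spanning roughly 1-72 nt, and a single
``alpha`` parameter sets the share of deleted bases taken 3' (downstream)
of the cut, so directional skew can be dialed in and recovered. Deletions
always contain or abut the cut; detached deletions are not modeled.

qPCR Ct tables are simulated under the 2^-ddCt measurement model (a true
fold change shifts the target-gene Ct by -log2(fold) cycles; Gaussian cycle
noise), and densitometry tables under multiplicative log-normal noise on
the optical densities. Every generator is reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FeatureError, SimulationError
from .indelcall import CloneSequence, IndelCall, apply_calls
from .refmodel import (
    CutSite,
    FeatureAnnotation,
    GuideRNA,
    ReferenceAmplicon,
    locate_protospacer,
    predict_cut_site,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass(frozen=True)
class NhejModel:
    """Parameters of the simulated NHEJ outcome distribution.

    Class probabilities: ``p_unmodified``, ``p_insertion_only``, ``p_both``;
    the remainder is deletion-only. Deletion size: with probability
    ``w_small`` geometric with mean ``small_mean`` nt, otherwise uniform on
    ``large_range`` (inclusive). ``alpha`` is the downstream share of each
    deletion; ``min_downstream`` forces at least that many downstream bases
    (0 disables). Insertion length is geometric with mean ``ins_len_mean``.

    Defaults emulate a Sanger-clone cohort from a single-guide experiment:
    no wild-type contamination beyond 5%, a small insertion-only minority,
    roughly one clone in six with both an insertion and a deletion, small
    deletions dominating but a heavy tail up to 72 nt, and a mild upstream
    skew of the deleted bases.
    """

    p_unmodified: float = 0.05
    p_insertion_only: float = 0.05
    p_both: float = 0.17
    w_small: float = 0.7
    small_mean: float = 3.0
    large_range: tuple[int, int] = (20, 72)
    alpha: float = 0.4
    min_downstream: int = 0
    ins_len_mean: float = 2.0

    def __post_init__(self) -> None:
        ps = (self.p_unmodified, self.p_insertion_only, self.p_both)
        if any(p < 0 for p in ps) or sum(ps) > 1.0 + 1e-12:
            raise SimulationError("class probabilities must be >= 0 and sum <= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise SimulationError("alpha must lie in [0, 1]")
        if not (0.0 <= self.w_small <= 1.0):
            raise SimulationError("w_small must lie in [0, 1]")
        lo, hi = self.large_range
        if not (1 <= lo <= hi):
            raise SimulationError("large_range must satisfy 1 <= lo <= hi")
        if self.small_mean < 1 or self.ins_len_mean < 1:
            raise SimulationError("geometric means must be >= 1 nt")

    @property
    def p_deletion_only(self) -> float:
        return 1.0 - self.p_unmodified - self.p_insertion_only - self.p_both


@dataclass(frozen=True)
class TruthRecord:
    """As-simulated edits for one clone; applying them to the reference
    reproduces the emitted sequence exactly."""

    clone_id: str
    deletions: tuple[tuple[int, int], ...]
    insertion: tuple[int, str] | None
    edit_class: str

    @property
    def total_deleted(self) -> int:
        return sum(e - s for s, e in self.deletions)

    @property
    def net_change(self) -> int:
        ins = len(self.insertion[1]) if self.insertion else 0
        return ins - self.total_deleted

    def as_calls(self) -> list[IndelCall]:
        """Sorted, applicable calls (an insertion at a deletion's start
        precedes the deletion, so apply_calls reproduces the clone)."""
        calls: list[IndelCall] = [
            IndelCall("deletion", s, e) for s, e in self.deletions
        ]
        if self.insertion:
            p, seq = self.insertion
            calls.append(IndelCall("insertion", p, p, seq))
        return sorted(calls, key=lambda c: (c.start, c.kind == "deletion"))


def make_reference(
    flank5: int,
    guide: GuideRNA,
    pam: str = "TGG",
    flank3: int = 40,
    features: Sequence[tuple[str, int, int]] = (),
    seed: int | np.random.Generator = 0,
    max_redraws: int = 50,
) -> tuple[ReferenceAmplicon, CutSite]:
    """Random reference with the protospacer+PAM embedded once.

    Layout: ``flank5`` random nt, protospacer, concrete 3-nt PAM, ``flank3``
    random nt. Flanks are redrawn until the protospacer occurs exactly once
    on either strand. Features are given as (label, start, end) in final
    coordinates; a ``start_codon`` feature forces ATG at its start, a
    ``splice_donor`` forces GT. Returns the amplicon and the predicted cut.
    """
    if flank5 < 10 or flank3 < 10:
        raise SimulationError("flanks must be at least 10 nt")
    if len(pam) != 3 or "N" in pam:
        raise SimulationError("pam must be a concrete 3-nt sequence")
    rng = _rng(seed)
    total = flank5 + len(guide) + 3 + flank3
    for label, start, end in features:
        if not (0 <= start < end <= total):
            raise FeatureError(
                f"feature {label} [{start},{end}) outside reference of length {total}"
            )

    for _ in range(max_redraws):
        seq = list(
            _random_dna(rng, flank5) + guide.protospacer + pam + _random_dna(rng, flank3)
        )
        for label, start, end in features:
            if label == "start_codon":
                seq[start:start + 3] = "ATG"
            elif label == "splice_donor":
                seq[start:start + 2] = "GT"
        ref = ReferenceAmplicon(
            id=f"synthetic_{guide.name}",
            seq="".join(seq),
            features=tuple(
                FeatureAnnotation(label, start, end) for label, start, end in features
            ),
        )
        try:
            match = locate_protospacer(guide, ref)
        except Exception:
            continue
        if match.target_interval != (flank5, flank5 + len(guide)):
            continue
        return ref, predict_cut_site(match)
    raise SimulationError(
        f"could not embed a unique protospacer site in {max_redraws} draws"
    )


def kozak_window(atg_start: int) -> tuple[str, int, int]:
    """Conventional annotation helper: the initiation context spanning 6 nt
    5' of the ATG through the first nt after it, [ATG-6, ATG+4)."""
    if atg_start < 6:
        raise FeatureError("ATG too close to the reference start for a Kozak window")
    return ("kozak", atg_start - 6, atg_start + 4)


def _draw_deletion(
    rng: np.random.Generator, model: NhejModel, cut: CutSite, ref_len: int,
    max_tries: int = 100,
) -> tuple[int, int]:
    for _ in range(max_tries):
        if rng.random() < model.w_small:
            length = int(rng.geometric(1.0 / model.small_mean))
        else:
            lo, hi = model.large_range
            length = int(rng.integers(lo, hi + 1))
        length = max(length, model.min_downstream)
        down = int(np.floor(model.alpha * length + 0.5))
        down = min(max(down, model.min_downstream), length)
        up = length - down
        start, end = cut.interbase - up, cut.interbase + down
        if 0 <= start and end <= ref_len:
            return start, end
    raise SimulationError(
        "could not draw an in-bounds deletion; reference too short for the model"
    )


def simulate_cohort(
    ref: ReferenceAmplicon,
    cut: CutSite,
    model: NhejModel,
    n: int,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "clone",
) -> tuple[list[CloneSequence], list[TruthRecord]]:
    """Simulate ``n`` clone sequences with recorded ground truth."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = _rng(seed)
    clones: list[CloneSequence] = []
    truths: list[TruthRecord] = []
    cum = np.cumsum(
        [model.p_unmodified, model.p_insertion_only, model.p_both]
    )
    for k in range(n):
        cid = f"{id_prefix}_{k + 1:03d}"
        u = rng.random()
        deletions: tuple[tuple[int, int], ...] = ()
        insertion: tuple[int, str] | None = None
        if u < cum[0]:
            edit_class = "unmodified"
        elif u < cum[1]:
            edit_class = "insertion"
            ins_len = int(rng.geometric(1.0 / model.ins_len_mean))
            insertion = (cut.interbase, _random_dna(rng, ins_len))
        else:
            s, e = _draw_deletion(rng, model, cut, len(ref))
            if u < cum[2]:
                edit_class = "both"
                # identifiability: an inserted base also present in the
                # deleted segment makes the true event sizes unrecoverable
                # (the clone string equals one with smaller edits), so the
                # junction insertion is drawn from the complement alphabet;
                # the deletion is redrawn while no letter is free
                for _ in range(100):
                    avail = sorted(set("ACGT") - set(ref.seq[s:e]))
                    if avail:
                        break
                    s, e = _draw_deletion(rng, model, cut, len(ref))
                else:
                    raise SimulationError(
                        "could not draw an identifiable insertion+deletion event"
                    )
                ins_len = int(rng.geometric(1.0 / model.ins_len_mean))
                ins_seq = "".join(
                    avail[int(i)] for i in rng.integers(0, len(avail), size=ins_len)
                )
                insertion = (s, ins_seq)
            else:
                edit_class = "deletion"
            deletions = ((s, e),)
        truth = TruthRecord(cid, deletions, insertion, edit_class)
        seq = apply_calls(ref.seq, truth.as_calls())
        clones.append(CloneSequence(cid, seq))
        truths.append(truth)
    return clones, truths


def simulate_ct_table(
    true_folds: Mapping[str, float],
    control_group: str = "control",
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    noise_sd: float = 0.1,
    n_reps: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate Ct table under the 2^-ddCt measurement model.

    ``true_folds`` maps each treated group to its true expression fold
    change vs control (0.21 means 79% knockdown); the control group is
    implicitly fold 1. Target-gene Ct of a group with fold f is
    Normal(base_ct_target - log2(f), noise_sd); the reference (housekeeping)
    gene is Normal(base_ct_reference, noise_sd) for every group.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise SimulationError("true folds must be positive")
    if n_reps < 2:
        raise SimulationError("n_reps must be >= 2")
    rng = _rng(seed)
    truth = {control_group: 1.0, **{g: float(f) for g, f in true_folds.items()}}
    rows = []
    for group, fold in truth.items():
        mu_t = base_ct_target - np.log2(fold)
        for rep in range(1, n_reps + 1):
            rows.append(
                (group, f"{group}_s1", "target", rep,
                 float(rng.normal(mu_t, noise_sd)))
            )
        for rep in range(1, n_reps + 1):
            rows.append(
                (group, f"{group}_s1", "reference", rep,
                 float(rng.normal(base_ct_reference, noise_sd)))
            )
    table = pd.DataFrame(
        rows, columns=["group", "sample", "gene_role", "replicate", "ct"]
    )
    return table, truth


def simulate_densitometry(
    true_ratios: Mapping[str, float],
    control_group: str = "control",
    base_od: float = 1.0,
    noise_sd: float = 0.1,
    n_reps: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Optical-density table with multiplicative log-normal noise.

    ``true_ratios`` maps treated groups to the true target/loading band
    ratio relative to control (control implicitly 1).
    """
    if any(r <= 0 for r in true_ratios.values()):
        raise SimulationError("true ratios must be positive")
    if n_reps < 2:
        raise SimulationError("n_reps must be >= 2")
    rng = _rng(seed)
    truth = {control_group: 1.0, **{g: float(r) for g, r in true_ratios.items()}}
    rows = []
    for group, ratio in truth.items():
        for rep in range(1, n_reps + 1):
            loading = base_od * float(np.exp(rng.normal(0.0, noise_sd)))
            target = ratio * base_od * float(np.exp(rng.normal(0.0, noise_sd)))
            rows.append((group, rep, target, loading))
    table = pd.DataFrame(
        rows, columns=["group", "replicate", "od_target", "od_loading"]
    )
    return table, truth


def truth_to_record(truth: TruthRecord) -> "CloneEditRecord":
    """A CloneEditRecord holding the as-simulated calls.

    Useful when a downstream statistic should reflect the generated event
    placements rather than the caller's canonical (left-aligned) ones: in a
    repeat tract the two differ even though they imply the same sequence.
    """
    from .indelcall import CloneEditRecord

    return CloneEditRecord(
        clone_id=truth.clone_id,
        calls=tuple(truth.as_calls()),
        net_change=truth.net_change,
        edit_class=truth.edit_class,
    )


# ---------------------------------------------------------------------------
# presets

def preset_default() -> NhejModel:
    """The default single-guide clone-cohort model (see class docstring)."""
    return NhejModel()


def preset_downstream_skew(alpha: float = 0.8) -> NhejModel:
    """Large deletions only, with a downstream-heavy split — the regime in
    which big NHEJ deletions preferentially remove 3' sequence."""
    return NhejModel(
        p_unmodified=0.0, p_insertion_only=0.0, p_both=0.0,
        w_small=0.0, alpha=alpha,
    )


def preset_cut_proximal() -> NhejModel:
    """Every clone deleted, every deletion covering the second downstream
    base — the saturated cut-proximal regime."""
    return NhejModel(
        p_unmodified=0.0, p_insertion_only=0.0, p_both=0.0,
        min_downstream=2, alpha=0.5,
    )


PRESETS = {
    "default": preset_default,
    "downstream-skew": preset_downstream_skew,
    "cut-proximal": preset_cut_proximal,
}
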