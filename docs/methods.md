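# Methods

This note documents the models, conventions and numerical choices behind
`nhejscope`, and what its synthetic-data tests do and do not demonstrate.

## Coordinates and the cut site

All internals use 0-based, half-open intervals on the + strand. A
double-strand break is an **inter-base index**: `CutSite.interbase = k`
means the break falls between reference positions `k − 1` and `k`. For a
protospacer match `[s, e)` with an NGG PAM at `[e, e+3)` the cut is
`e − 3`; for a − strand match (the + strand shows CCN at `[s−3, s)`) it is
`s + 3`. Both cases leave exactly three protospacer-strand bases between
the break and the PAM, and because the rule is anchored on the PAM, keeping
or stripping the scaffold-appended leading G of a cloning oligo never moves
the predicted cut.

Reports use break-centric offsets: +k is the k-th base 5′ (upstream) of
the break, −k the k-th base 3′ (downstream); there is no offset 0. This
matches how per-position editing figures are usually labelled when the
break is the frame of reference. The sign convention can be flipped to
downstream-positive (`convention="genomic"`) without changing any
percentage.

## Oligo parsing

Top cloning oligos are `CACC` + insert (20 nt, or 21 when a G was appended
for U6 transcription). Bottom oligos validate in two orientations: the
conventional 5′→3′ form `AAAC + revcomp(insert)`, and the same strand
written 3′→5′ (its plain string reversal equals the conventional form).
The second orientation exists because published oligo tables sometimes
print the bottom strand in the annealed, antiparallel direction; a strict
mode accepts only the conventional form. Validation always uses the full
insert (which is what anneals), with scaffold-G stripping applied
afterwards to the reported protospacer.

## Alignment and indel normalization

Clones are aligned with a Gotoh three-state global dynamic program (affine
gaps; a gap of length L costs `gap_open + L·gap_extend`). Ties are broken
diagonal > up > left at every choice point, so output is deterministic.
Each maximal gap run becomes one call; deletions and insertions are then
left-aligned — shifted to the smallest reference coordinate that leaves the
implied sequence unchanged — with the shift bounded by the previous call so
that applying the calls always reconstructs the clone exactly.

Two scoring schemes are provided:

* **default** (`match +2, mismatch −3, gap open −5, extend −1`): favours
  contiguous gaps so one NHEJ event appears as one call, while still
  calling isolated base changes as substitutions (e.g. `AAA` vs `TTT` is
  three mismatch columns, not six gap columns).
* **`INDEL_FAITHFUL_SCORING`** (`mismatch −50`): for error-free
  Sanger-grade clones, where an apparent substitution is implausible. The
  two goals are mathematically incompatible in one scheme: representing a
  junction deletion+insertion as two indels beats the substitution
  representation only when `mismatch < 2·gap_open/L + 2·gap_extend` for
  every event size L (the binding case is a 1-nt deletion plus 1-nt
  insertion, which any substitution-tolerant scheme will — correctly, for
  noisy data — report as a point substitution). Ground-truth recovery
  suites therefore use the faithful scheme.

Substitution columns are counted per clone but never interpreted.

## Identifiability of simulated edits

The generator guarantees that every simulated event is recoverable from the
clone sequence alone. For combined deletion+insertion clones the inserted
bases are drawn from the alphabet complement of the deleted segment (the
deletion is redrawn while no letter is free). This is necessary, not
cosmetic: if an inserted base also occurs in the deleted segment, the
emitted sequence is *identical* to one carrying smaller edits, so no
aligner could return the generated sizes. Insertion-only clones use
uniform ACGT (pure insertions are always size-identifiable; only their
placement can shift within repeats).

Placement, by contrast, is only defined up to the repeat-ambiguity class:
the caller reports the left-aligned (canonical) placement, which in repeat
tracts sits 5′ of where the generator put the event. Consequently
per-position profiles computed from canonical calls are slightly
upstream-shifted relative to the generated footprints; statistics that
depend on exact placement (such as "every clone deleted the −2 base") are
evaluated against the generator's truth placements (`truth_to_record`),
while sizes, net changes and class labels are required to match exactly
after re-calling.

## NHEJ outcome model (generator defaults)

Per clone: unmodified with p = 0.05, insertion-only 0.05, deletion +
insertion 0.17 (roughly one in six, as small clone cohorts from single-guide
experiments tend to show), otherwise deletion-only. Deletion size is a
mixture: with weight 0.7 geometric with mean 3 nt, else uniform on
20–72 nt, spanning the single-digit bulk and the large-deletion tail such
cohorts exhibit. The downstream share α (default 0.4, mildly
upstream-skewed) fixes `d = round(αL)`, `u = L − d`, with the deletion
anchored at the cut (`[cut−u, cut+d)`); detached deletions are not
modelled. Insertion length is geometric with mean 2 nt; insertions sit at
the cut (at the deletion start for combined events). `min_downstream`
(default 0) forces every deletion to cover at least that many downstream
bases and raises the minimum size accordingly — the `cut-proximal` preset
uses 2 to model cohorts where the second downstream base is always lost.

Ct tables follow the comparative-threshold measurement model: the target
gene of a group with true fold f has Ct ~ Normal(base − log2 f, σ), the
housekeeping gene Ct ~ Normal(base_ref, σ) in every group; defaults
base 24/18 cycles, σ = 0.1 cycle, 3 replicates. Densitometry tables apply
multiplicative log-normal noise (σ = 0.1 on the log scale) to both the
target and loading optical densities.

What the generator does **not** emulate: sequencing error and chromatogram
artefacts, microhomology-directed deletion biases, multi-event clones
(more than one deletion), PCR/cloning bias among outcomes, and qPCR
amplification-efficiency deviations from 2. Passing tests therefore show
the pipeline's arithmetic and inference are correct under the stated
model, not that real cohorts satisfy the model.

## Knockdown quantification

Group ΔCt uses replicate-mean Ct per gene role; replicate-wise pairing
(target replicate i vs reference replicate i) is available behind a flag
since plate layouts differ. Per-replicate folds (against the control's mean
ΔCt) feed the dispersion estimates and the group statistics; both the SEM
of the per-replicate folds and of the per-replicate ΔΔCt are reported,
since error bars are quoted both ways in practice. ANOVA is computed from
the standard sums of squares with p from the F distribution; Tukey HSD
uses the studentized-range implementation in scipy. With fewer than two
replicates per group, or zero variance everywhere, densitometry reports
ratios with statistics omitted rather than failing.

## Problem sizes and numerics

Default test and acceptance runs use references of ~180 nt (80-nt flanks
around protospacer + PAM), cohorts of 24 for figure-style summaries and
1,000 clones for recovery rates, 500 simulated Ct tables for fold-recovery
means — sizes at which every suite completes in seconds while keeping
binomial/Monte-Carlo error well inside the asserted tolerances. The
alignment kernel is numba-compiled; scores are float64 and exact for
integer-valued schemes. Window fractions and profiles are exact counts, not
estimates. Reference synthesis redraws flanks (up to 50 times) until the
protospacer occurs exactly once on either strand, so locating is never
ambiguous by construction.

## Known limitations

* Exact-match protospacer and primer search only; mismatch-tolerant search
  is off-target analysis and out of scope.
* One deletion and at most one insertion per simulated clone; the caller
  itself handles arbitrarily many calls.
* Left-alignment biases per-position deletion profiles 5′ within repeats
  (see above); the canonical placement is reported, not a cut-anchored one.
* Consequence calls are purely positional (overlap/containment); no
  splice-strength or translation-efficiency scoring.
* The 20-nt threshold for "large deletion" in the skew statistic is a
  package default, stated not derived; set it explicitly when comparing
  spectra.
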