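"""Somatic hypermutation spectrum analysis.

Clone sequences (Sanger sequencing of cloned Smu or IgV amplicons) are
aligned to a reference, substitutions are called and classified by the AID
hotspot context — C:G pairs inside a WRC motif (W = A/T, R = A/G; the
bottom-strand mirror reads GYW on the top strand, Y = C/T), C:G pairs
outside it, and A:T pairs — and summarised as a mutation frequency
(mutations per base pair), a per-sequence mutation-load histogram and
class proportions.

Coordinates are 1-based and inclusive on the reference top strand.  The
hotspot classifier here is the single source of truth also used by the
clone simulator, so generated truth sets round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

CG_WRC = "CG_WRC"
CG_NONWRC = "CG_nonWRC"
AT = "AT"
MUT_CLASSES = (CG_WRC, CG_NONWRC, AT)

_W = set("AT")
_R = set("AG")
_Y = set("CT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "MUT_CLASSES",
    "CloneSet",
    "MutationRecord",
    "AlignedClone",
    "SpectrumSummary",
    "CloneRejected",
    "reverse_complement",
    "classify_mutation",
    "hotspot_positions",
    "align_clone",
    "call_mutations",
    "summarize_spectrum",
    "analyze_clone_set",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CloneSet:
    """A reference sequence plus sequenced clones (possibly containing N)."""

    reference: str
    clones: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if not self.reference:
            raise ValueError("empty reference")
        if set(self.reference) - set("ACGT"):
            raise ValueError("reference must be over {A,C,G,T}")
        self.clones = [(cid, seq.upper()) for cid, seq in self.clones]
        ids = [cid for cid, _ in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate clone ids")
        for cid, seq in self.clones:
            if set(seq) - set("ACGTN"):
                raise ValueError(f"clone {cid}: non-IUPAC characters")


@dataclass(frozen=True)
class MutationRecord:
    clone_id: str
    position: int  # 1-based on the reference
    ref_base: str
    obs_base: str
    mut_class: str

    def __post_init__(self) -> None:
        if self.ref_base == self.obs_base:
            raise ValueError("ref and observed base identical")


class CloneRejected(Exception):
    """Clone alignment below the identity threshold (likely wrong amplicon)."""

    def __init__(self, clone_id: str, identity: float):
        self.clone_id = clone_id
        self.identity = identity
        super().__init__(
            f"clone {clone_id}: alignment identity {identity:.1%} < 80%"
        )


def classify_mutation(reference: str, position: int) -> str:
    """Hotspot class of a substitution at a 1-based reference position.

    A mutated C is in the hotspot when positions (pos-2, pos-1, pos) read
    W, R, C; a mutated G when (pos, pos+1, pos+2) read G, Y, W (the
    bottom-strand WRC).  A and T sites are the AT class.  Contexts that run
    off the sequence end are classified non-hotspot with a warning.
    """
    n = len(reference)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of range 1..{n}")
    base = reference[position - 1]
    if base in "AT":
        return AT
    if base == "C":
        if position < 3:
            warnings.warn(f"WRC context truncated at position {position}")
            return CG_NONWRC
        w, r = reference[position - 3], reference[position - 2]
        return CG_WRC if (w in _W and r in _R) else CG_NONWRC
    # base == "G"
    if position > n - 2:
        warnings.warn(f"GYW context truncated at position {position}")
        return CG_NONWRC
    y, w = reference[position], reference[position + 1]
    return CG_WRC if (y in _Y and w in _W) else CG_NONWRC


def hotspot_positions(reference: str) -> np.ndarray:
    """Boolean mask (0-based) of C/G positions inside the WRC/GYW hotspot."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array(
            [
                reference[i] in "CG"
                and classify_mutation(reference, i + 1) == CG_WRC
                for i in range(len(reference))
            ]
        )


@dataclass
class AlignedClone:
    """Column-level view of a clone aligned to the reference.

    ``ref_positions`` / ``clone_bases`` list the reference position (1-based)
    and clone base for every gap-free aligned column; N columns are kept out
    of ``usable`` so they enter neither the mutation calls nor denominators.
    """

    clone_id: str
    reference: str
    ref_positions: np.ndarray
    clone_bases: np.ndarray
    identity: float
    n_indel_events: int
    usable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.usable = self.clone_bases != "N"


def _make_aligner(match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_clone(
    reference: str,
    clone: str,
    clone_id: str = "clone",
    min_identity: float = 0.80,
    **scores,
) -> AlignedClone:
    """Global pairwise alignment of a clone to the reference.

    Columns with gaps or N are excluded from downstream substitution
    calling; runs of gaps are counted as single indel events.  Raises
    :class:`CloneRejected` below ``min_identity`` (matches over reference
    length).
    """
    reference, clone = reference.upper(), clone.upper()
    if not reference or not clone:
        raise ValueError("empty sequence")
    aligner = _make_aligner(**scores)
    aln = aligner.align(reference, clone)[0]
    idx = aln.indices  # (2, L), -1 marks gap
    ref_idx, clone_idx = idx[0], idx[1]
    both = (ref_idx >= 0) & (clone_idx >= 0)
    ref_pos = ref_idx[both] + 1
    clone_b = np.array(list(clone))[clone_idx[both]]
    ref_b = np.array(list(reference))[ref_idx[both]]
    matches = int(np.sum((clone_b == ref_b) & (clone_b != "N")))
    identity = matches / len(reference)
    gap = ~both
    n_indels = int(np.sum(gap & ~np.concatenate([[False], gap[:-1]])))
    if identity < min_identity:
        raise CloneRejected(clone_id, identity)
    return AlignedClone(
        clone_id=clone_id,
        reference=reference,
        ref_positions=ref_pos,
        clone_bases=clone_b,
        identity=identity,
        n_indel_events=n_indels,
    )


def call_mutations(aligned: AlignedClone) -> list[MutationRecord]:
    """One record per mismatching gap-free, N-free aligned column."""
    records = []
    ref = aligned.reference
    for pos, obs, ok in zip(
        aligned.ref_positions, aligned.clone_bases, aligned.usable
    ):
        if not ok:
            continue
        ref_base = ref[pos - 1]
        if obs != ref_base:
            records.append(
                MutationRecord(
                    clone_id=aligned.clone_id,
                    position=int(pos),
                    ref_base=ref_base,
                    obs_base=str(obs),
                    mut_class=classify_mutation(ref, int(pos)),
                )
            )
    return records


@dataclass
class SpectrumSummary:
    """Aggregate mutation spectrum over a clone set."""

    n_sequences: int
    total_bp: int
    n_mutations: int
    frequency: float
    load_histogram: dict[int, float]
    class_counts: dict[str, int]
    class_proportions: dict[str, float]


def summarize_spectrum(
    records: list[MutationRecord],
    n_sequences: int,
    analyzed_length: int,
    clone_ids: list[str] | None = None,
    excluded_bp: int = 0,
) -> SpectrumSummary:
    """Frequency (mutations per bp), load histogram and class proportions.

    ``excluded_bp`` removes N-masked sites from the denominator (applied by
    :func:`analyze_clone_set` when a clone's N fraction exceeds 1%).
    """
    if n_sequences == 0:
        raise ValueError("no sequences")
    for rec in records:
        if not 1 <= rec.position <= analyzed_length:
            raise ValueError(f"record position {rec.position} outside reference")
    total_bp = n_sequences * analyzed_length - excluded_bp
    n_mut = len(records)

    per_clone: dict[str, int] = {}
    if clone_ids is not None:
        per_clone = {cid: 0 for cid in clone_ids}
    for rec in records:
        per_clone[rec.clone_id] = per_clone.get(rec.clone_id, 0) + 1
    loads = list(per_clone.values())
    loads += [0] * (n_sequences - len(loads))
    hist: dict[int, float] = {}
    for k in loads:
        hist[k] = hist.get(k, 0) + 1
    hist = {k: v / n_sequences for k, v in sorted(hist.items())}

    class_counts = {c: 0 for c in MUT_CLASSES}
    for rec in records:
        class_counts[rec.mut_class] += 1
    props = {
        c: (class_counts[c] / n_mut if n_mut else 0.0) for c in MUT_CLASSES
    }
    return SpectrumSummary(
        n_sequences=n_sequences,
        total_bp=total_bp,
        n_mutations=n_mut,
        frequency=n_mut / total_bp,
        load_histogram=hist,
        class_counts=class_counts,
        class_proportions=props,
    )


def analyze_clone_set(
    clone_set: CloneSet, min_identity: float = 0.80, **scores
) -> tuple[list[MutationRecord], SpectrumSummary, list[tuple[str, float]], int]:
    """Full pipeline: align, call, classify, summarise.

    Returns (records, summary, rejected clones as (id, identity), total
    indel events).  A clone's N-masked sites are removed from the frequency
    denominator when they exceed 1% of the reference length.
    """
    records: list[MutationRecord] = []
    rejected: list[tuple[str, float]] = []
    accepted_ids: list[str] = []
    excluded_bp = 0
    n_indels = 0
    L = len(clone_set.reference)
    for cid, seq in clone_set.clones:
        try:
            aligned = align_clone(
                clone_set.reference, seq, clone_id=cid,
                min_identity=min_identity, **scores,
            )
        except CloneRejected as exc:
            rejected.append((exc.clone_id, exc.identity))
            continue
        accepted_ids.append(cid)
        n_indels += aligned.n_indel_events
        n_masked = int(np.sum(~aligned.usable)) + (L - len(aligned.ref_positions))
        if n_masked / L > 0.01:
            excluded_bp += n_masked
        records.extend(call_mutations(aligned))
    if not accepted_ids:
        raise ValueError("all clones rejected")
    summary = summarize_spectrum(
        records,
        n_sequences=len(accepted_ids),
        analyzed_length=L,
        clone_ids=accepted_ids,
        excluded_bp=excluded_bp,
    )
    return records, summary, rejected, n_indels
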