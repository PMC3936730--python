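"""Registration of bisulfite clone sequences to an amplicon reference.

Alignment is global with free end gaps against the fully converted
reference (every C read as T).  At reference-cytosine columns a clone C
or T both count as a match — the C/T degeneracy of bisulfite data,
applied asymmetrically on the top strand only.  Identity QC is computed
over the non-degenerate columns, where bisulfite chemistry predicts a
perfect match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .reference import AmpliconReference

__all__ = ["CloneAlignment", "CloneRejected", "align_clone"]

GAP = "-"


class CloneRejected(ValueError):
    """Raised when a clone fails pre-alignment or identity QC."""

    def __init__(self, clone_id: str, reason: str):
        self.clone_id = clone_id
        self.reason = reason
        super().__init__(f"clone {clone_id!r} rejected: {reason}")


@dataclass
class CloneAlignment:
    """Per-reference-column registration of one clone.

    ``column_bases[i]`` is the clone base aligned to reference position
    ``i`` ('-' where the clone has a gap).  ``identity`` is the match
    fraction over aligned non-degenerate (reference non-C) columns.
    """

    clone_id: str
    reference_name: str
    column_bases: np.ndarray
    identity: float
    score: float
    n_gap_columns: int


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTYN", dims=2)
    for a in "ACGTYN":
        for b in "ACGTYN":
            matrix[a, b] = match if a == b else mismatch
    # Y marks reference cytosines: clone C or T both match
    for b in "CT":
        matrix["Y", b] = matrix[b, "Y"] = match
    for a in "ACGTY":  # N never rewards a match
        matrix["N", a] = matrix[a, "N"] = mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_internal_gap_score = gap_open
    aligner.extend_internal_gap_score = gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_clone(clone_seq: str, reference: AmpliconReference,
                clone_id: str = "clone",
                max_length_deviation: float = 0.2,
                min_identity: float = 0.8,
                match: float = 1.0, mismatch: float = -1.0,
                gap_open: float = -4.0, gap_extend: float = -1.0
                ) -> CloneAlignment:
    """Globally align a bisulfite clone to the reference.

    The target is the reference with every C replaced by the degenerate
    symbol Y (matching clone C or T); end gaps are free so incomplete
    reads register without penalty.  Raises :class:`CloneRejected` when
    the clone length deviates from the reference by more than
    ``max_length_deviation`` or identity over non-degenerate columns
    falls below ``min_identity``.
    """
    clone_seq = clone_seq.upper()
    ref_len = len(reference)
    deviation = abs(len(clone_seq) - ref_len) / ref_len
    if deviation > max_length_deviation:
        raise CloneRejected(
            clone_id,
            f"length {len(clone_seq)} deviates {deviation:.0%} from "
            f"reference length {ref_len} (limit {max_length_deviation:.0%})")

    target = "".join("Y" if b == "C" else b for b in reference.sequence)
    query = "".join(b if b in "ACGT" else "N" for b in clone_seq)
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(target, query)[0]

    column_bases = np.full(ref_len, GAP, dtype="<U1")
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            column_bases[t0 + offset] = clone_seq[q0 + offset]

    is_c = np.frombuffer(reference.sequence.encode(), dtype="S1") == b"C"
    aligned = column_bases != GAP
    nondeg = aligned & ~is_c
    ref_arr = np.frombuffer(reference.sequence.encode(),
                            dtype="S1").astype("<U1")
    matches = int(np.sum(nondeg & (column_bases == ref_arr)))
    n_nondeg = int(nondeg.sum())
    identity = matches / n_nondeg if n_nondeg else 0.0
    if identity < min_identity:
        raise CloneRejected(
            clone_id,
            f"identity {identity:.1%} over {n_nondeg} non-degenerate "
            f"columns below threshold {min_identity:.0%}")

    return CloneAlignment(
        clone_id=clone_id, reference_name=reference.name,
        column_bases=column_bases, identity=identity,
        score=float(alignment.score),
        n_gap_columns=int((~aligned).sum()))
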