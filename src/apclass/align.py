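"""Global pairwise alignment helper shared by topology numbering, motif
transfer and superposition correspondence.

Thin wrapper around Biopython's PairwiseAligner: Needleman-Wunsch with
BLOSUM62, gap open 10 / extend 0.5 by default.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["global_alignment_pairs"]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_alignment_pairs(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                           gap_open: float = 10.0, gap_extend: float = 0.5,
                           ) -> list[tuple[int, int]]:
    """1-based (pos_in_a, pos_in_b) pairs at match columns of the best
    global alignment.  Deterministic: the aligner's first optimal alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            pairs.append((a_start + offset + 1, b_start + offset + 1))
    return pairs
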