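"""Iterative position-specific scoring (PSSM) homology search.

Family identification follows a two-round scheme: a profile built from a
seed alignment is slid over every candidate sequence (ungapped), sequences
scoring above threshold become round-1 hits, the profile is rebuilt from the
hit windows, and a second round is run with the family-derived profile.
The point of the second round is recall: divergent members that a generic
seed profile misses are recovered once the profile reflects the family
itself.

Scores are in bits (log2 odds against a fixed background).  This is a plain
PSSM, not a profile HMM — no insert/delete states, no E-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Profile", "SearchHit", "build_profile", "search", "iterative_search",
           "ROBINSON_BACKGROUND", "AA_ALPHABET"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# Robinson & Robinson amino-acid background frequencies
ROBINSON_BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216])
ROBINSON_BACKGROUND /= ROBINSON_BACKGROUND.sum()

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_THRESHOLD_FRACTION = 0.6  # of the profile's self-score
MAX_GAP_COLUMN_FRACTION = 0.5


@dataclass
class Profile:
    """L x 20 log-odds matrix (bits) with consensus and background."""

    columns: np.ndarray
    consensus: str
    background: np.ndarray
    pseudocount_weight: float

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != 20 or len(self) < 1:
            raise ValueError("columns must be L x 20 with L >= 1")

    def __len__(self) -> int:
        return self.columns.shape[0]

    @property
    def self_score(self) -> float:
        """Sum of per-column maxima: the best achievable window score."""
        return float(self.columns.max(axis=1).sum())

    def score_sequence(self, seq: str) -> tuple[float, int]:
        """Best ungapped window score and its 0-based start offset.

        Unknown/ambiguous residues score 0 bits; sequences shorter than the
        profile are right-padded with unknowns.
        """
        L = len(self)
        idx = np.array([_AA_INDEX.get(aa, -1) for aa in seq], dtype=int)
        if idx.size < L:
            idx = np.concatenate([idx, np.full(L - idx.size, -1)])
        n = idx.size
        safe = np.where(idx >= 0, idx, 0)
        # per_pos[i, j] = score of placing profile column j on sequence pos i
        per_pos = np.where(idx[:, None] >= 0, self.columns.T[safe, :], 0.0)
        n_windows = n - L + 1
        scores = np.zeros(n_windows)
        for j in range(L):
            scores += per_pos[j:j + n_windows, j]
        best_start = int(np.argmax(scores))
        return float(scores[best_start]), best_start


@dataclass(frozen=True)
class SearchHit:
    seq_id: str
    best_score: float
    start: int  # 1-based window start
    end: int    # 1-based inclusive window end
    round: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.best_score) or self.start > self.end:
            raise ValueError("invalid hit")


def build_profile(alignment: list[tuple[str, str]] | dict[str, str] | list[str],
                  pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
                  background: np.ndarray = ROBINSON_BACKGROUND) -> Profile:
    """Build a log-odds profile from aligned sequences.

    Columns with more than 50% gaps are dropped; per-column probabilities
    use background-proportional pseudocounts:
    p_a = (c_a + w * q_a) / (n_obs + w).
    """
    if isinstance(alignment, dict):
        seqs = list(alignment.values())
    elif alignment and isinstance(alignment[0], tuple):
        seqs = [s for _, s in alignment]
    else:
        seqs = list(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must share one length")
    width = len(seqs[0])
    n = len(seqs)
    cols = []
    consensus = []
    for j in range(width):
        residues = [s[j].upper() for s in seqs]
        gaps = sum(1 for r in residues if r in "-.")
        if gaps / n > MAX_GAP_COLUMN_FRACTION:
            continue
        counts = np.zeros(20)
        for r in residues:
            if r in _AA_INDEX:
                counts[_AA_INDEX[r]] += 1
        n_obs = counts.sum()
        if n_obs == 0:
            continue
        probs = (counts + pseudocount_weight * background) / (n_obs + pseudocount_weight)
        with np.errstate(divide="ignore"):
            scores = np.log2(probs / background)
        scores[np.isneginf(scores)] = -20.0  # zero-probability floor
        cols.append(scores)
        consensus.append(AA_ALPHABET[int(np.argmax(scores))])
    if not cols:
        raise ValueError("no usable columns after gap filtering")
    return Profile(columns=np.array(cols), consensus="".join(consensus),
                   background=background, pseudocount_weight=pseudocount_weight)


def resolve_threshold(profile: Profile, threshold: float | str) -> float:
    if threshold == "auto":
        return DEFAULT_THRESHOLD_FRACTION * profile.self_score
    return float(threshold)


def search(profile: Profile, sequences: dict[str, str],
           threshold: float | str = "auto", round_number: int = 1) -> list[SearchHit]:
    """Best ungapped window per sequence; hits score >= threshold,
    sorted by descending score (ties by id)."""
    cutoff = resolve_threshold(profile, threshold)
    hits = []
    for seq_id, seq in sequences.items():
        if not seq:
            continue
        score, start = profile.score_sequence(seq)
        if score >= cutoff:
            hits.append(SearchHit(seq_id=seq_id, best_score=score,
                                  start=start + 1, end=start + len(profile),
                                  round=round_number))
    return sorted(hits, key=lambda h: (-h.best_score, h.seq_id))


@dataclass
class IterativeSearchResult:
    rounds: list[list[SearchHit]]
    gained: list[str] = field(default_factory=list)
    lost: list[str] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def final_hits(self) -> list[SearchHit]:
        return self.rounds[-1] if self.rounds else []


def iterative_search(seed_profile: Profile, sequences: dict[str, str],
                     threshold: float | str = "auto", rounds: int = 2,
                     ) -> IterativeSearchResult:
    """Two-round (or n-round) search: after each round the profile is rebuilt
    from the hit windows (ungapped hits all span the profile length, so the
    windows stack into a trivially aligned block)."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    profile = seed_profile
    all_rounds: list[list[SearchHit]] = []
    for r in range(1, rounds + 1):
        hits = search(profile, sequences, threshold=threshold, round_number=r)
        all_rounds.append(hits)
        if not hits:
            return IterativeSearchResult(rounds=all_rounds, stopped_early=True)
        if r < rounds:
            windows = [sequences[h.seq_id][h.start - 1:h.end] for h in hits]
            profile = build_profile(windows,
                                    pseudocount_weight=profile.pseudocount_weight,
                                    background=profile.background)
    first = {h.seq_id for h in all_rounds[0]}
    last = {h.seq_id for h in all_rounds[-1]}
    return IterativeSearchResult(rounds=all_rounds,
                                 gained=sorted(last - first),
                                 lost=sorted(first - last))
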