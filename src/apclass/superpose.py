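"""Sequence-guided rigid-body superposition with iterative outlier rejection.

The procedure mirrors the "align"-style command of interactive structure
viewers: build a residue correspondence from a global sequence alignment,
fit the least-squares (Kabsch) rotation on Cα atoms, discard pairs deviating
by more than a cutoff, and refit for a fixed number of cycles.  The RMSD is
reported over the retained pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_alignment_pairs
from .struct_io import StructureModel, sequence_of

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "SuperpositionError",
    "kabsch",
    "align_correspondence",
    "superpose_models",
]

DEFAULT_CYCLES = 5
DEFAULT_REJECT_CUTOFF = 2.0  # Å per-pair deviation


class SuperpositionError(RuntimeError):
    """Raised when fewer than three usable pairs remain."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class Correspondence:
    """Aligned residue index pairs (1-based seq_index in A, in B)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if any(y <= x for x, y in zip(a, a[1:])) or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("pairs must be strictly increasing in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    """Rotation/translation mapping B onto A plus fit statistics.

    ``rotation @ b + translation`` approximates the matching coordinate in A.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_start: int
    n_retained: int
    cycles_run: int = 1
    rejected_pairs: list[tuple[int, int]] = field(default_factory=list)
    rmsd_all_pairs: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if self.rmsd < 0 or self.n_retained > self.n_start:
            raise ValueError("inconsistent fit statistics")


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Single-cycle least-squares superposition of B onto A.

    Standard Kabsch: centroids removed, SVD of the covariance, reflection
    corrected so det(R) = +1.  Collinear/degenerate point sets (rank < 2
    covariance) are fitted anyway but flagged.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    cov = bb.T @ aa
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cen_a - rotation @ cen_b
    moved = (rotation @ b.T).T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    degenerate = int(np.linalg.matrix_rank(np.vstack([aa, bb]), tol=1e-6)) < 2
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_start=n, n_retained=n,
                               cycles_run=1, degenerate=degenerate)


def align_correspondence(model_a: StructureModel | str, model_b: StructureModel | str,
                         matrix: str = "BLOSUM62", gap_open: float = 10.0,
                         gap_extend: float = 0.5) -> Correspondence:
    """Residue correspondence from a global sequence alignment.

    Accepts models (pairs restricted to Cα-bearing residues) or raw
    sequences.  Positions are 1-based seq_index values.
    """
    def seq_and_ca(m):
        if isinstance(m, str):
            return m, None
        return sequence_of(m), set(m.ca_coords())

    seq_a, ca_a = seq_and_ca(model_a)
    seq_b, ca_b = seq_and_ca(model_b)
    raw = global_alignment_pairs(seq_a, seq_b, matrix=matrix,
                                 gap_open=gap_open, gap_extend=gap_extend)

    def to_index(m, ordinal):
        return ordinal if isinstance(m, str) else m.residues[ordinal - 1].seq_index

    pairs = []
    for pa, pb in raw:
        ia = to_index(model_a, pa)
        ib = to_index(model_b, pb)
        if (ca_a is None or ia in ca_a) and (ca_b is None or ib in ca_b):
            pairs.append((ia, ib))
    return Correspondence(pairs=pairs)


def superpose_models(model_a: StructureModel, model_b: StructureModel,
                     cycles: int = DEFAULT_CYCLES,
                     reject_cutoff: float = DEFAULT_REJECT_CUTOFF,
                     matrix: str = "BLOSUM62", gap_open: float = 10.0,
                     gap_extend: float = 0.5) -> SuperpositionResult:
    """Iterative Cα superposition of model B onto model A with rejection.

    Each cycle fits Kabsch on the retained pairs, then drops every pair whose
    Cα deviation exceeds ``reject_cutoff``; iteration stops when no pair is
    dropped or after ``cycles`` cycles.
    """
    corr = align_correspondence(model_a, model_b, matrix=matrix,
                                gap_open=gap_open, gap_extend=gap_extend)
    if len(corr) < 3:
        raise SuperpositionError(
            f"only {len(corr)} aligned Cα pairs between {model_a.id} and {model_b.id}",
            diagnostics={"n_pairs": len(corr)})
    ca_a = model_a.ca_coords()
    ca_b = model_b.ca_coords()
    retained = list(corr.pairs)
    coords_a = np.array([ca_a[i] for i, _ in retained])
    coords_b = np.array([ca_b[j] for _, j in retained])
    n_start = len(retained)
    rejected: list[tuple[int, int]] = []
    result = None
    cycles_run = 0
    total_cycles = max(1, cycles)
    for cycle in range(total_cycles):
        if len(retained) < 3:
            raise SuperpositionError(
                f"fewer than 3 pairs retained after rejection "
                f"({model_a.id} vs {model_b.id})",
                diagnostics={"n_start": n_start, "n_retained": len(retained),
                             "cycles_run": cycles_run, "rejected": rejected})
        result = kabsch(coords_a, coords_b)
        cycles_run += 1
        if cycle == total_cycles - 1:
            break  # final fit is not followed by another rejection pass
        moved = (result.rotation @ coords_b.T).T + result.translation
        dev = np.sqrt(np.sum((moved - coords_a) ** 2, axis=1))
        keep = dev <= reject_cutoff
        if keep.all():
            break
        rejected.extend(p for p, k in zip(retained, keep) if not k)
        retained = [p for p, k in zip(retained, keep) if k]
        coords_a = coords_a[keep]
        coords_b = coords_b[keep]

    # RMSD over all starting pairs under the final transform, for the log
    all_a = np.array([ca_a[i] for i, _ in corr.pairs])
    all_b = np.array([ca_b[j] for _, j in corr.pairs])
    moved_all = (result.rotation @ all_b.T).T + result.translation
    rmsd_all = float(np.sqrt(np.mean(np.sum((moved_all - all_a) ** 2, axis=1))))

    return SuperpositionResult(rotation=result.rotation,
                               translation=result.translation,
                               rmsd=result.rmsd, n_start=n_start,
                               n_retained=len(retained), cycles_run=cycles_run,
                               rejected_pairs=rejected, rmsd_all_pairs=rmsd_all,
                               degenerate=result.degenerate)
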