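"""Structure- and profile-level distance kernels.

Hamming distance serves state profiles, cosine distance serves fragment
frequency profiles, and Kabsch superposition RMSD / MaxSub serve raw
coordinates.  All kernels are deterministic and symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import FrequencyProfile, StateProfile

__all__ = [
    "Superposition",
    "hamming",
    "cosine_distance",
    "kabsch_rmsd",
    "maxsub",
    "pairwise_hamming_matrix",
    "write_distance_matrix",
]


@dataclass
class Superposition:
    """Optimal least-squares rigid superposition of one point set onto another.

    ``rotation`` is a proper rotation (det = +1; reflections are excluded so
    chirality is preserved) and ``translation`` the accompanying shift such
    that ``q ~ p @ rotation.T + translation`` after superposition.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def hamming(a: StateProfile, b: StateProfile) -> int:
    """Number of positions at which two aligned state profiles differ."""
    if len(a) != len(b) or a.alphabet.states != b.alphabet.states:
        raise ValueError("profiles must share length and alphabet")
    return int(np.sum(a.states != b.states))


def cosine_distance(a: FrequencyProfile, b: FrequencyProfile) -> float:
    """1 - cosine similarity between two non-zero frequency vectors."""
    if len(a) != len(b):
        raise ValueError("frequency profiles must share dimension")
    na, nb = np.linalg.norm(a.counts), np.linalg.norm(b.counts)
    if na == 0:
        raise ValueError(f"zero frequency vector: {a.model_id}")
    if nb == 0:
        raise ValueError(f"zero frequency vector: {b.model_id}")
    cos = float(np.dot(a.counts, b.counts) / (na * nb))
    return 1.0 - min(cos, 1.0)


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Core Kabsch: returns (R, pc, qc, rmsd) with R proper."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    P = p - pc
    Q = q - qc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = P @ R.T - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, pc, qc, rmsd


def kabsch_rmsd(p, q) -> Superposition:
    """Least-squares optimal proper rotation + translation of p onto q.

    Reflections are excluded via the determinant correction.  Degenerate
    (e.g. colinear) point sets still return a solution; the rotation is
    then not unique.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    if len(p) < 3:
        raise ValueError("at least 3 points are required for superposition")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    R, pc, qc, rmsd = _kabsch(p, q)
    translation = qc - R @ pc
    return Superposition(rotation=R, translation=translation, rmsd=rmsd)


def maxsub(model, reference, d0: float = 3.5, seed_len: int = 4,
           refine_iters: int = 4) -> float:
    """MaxSub similarity score in [0, 1].

    Searches for the largest superimposable residue subset: every contiguous
    ``seed_len``-residue window seeds a superposition; the match set is then
    extended over ``refine_iters`` rounds with a growing distance threshold
    (reaching ``d0`` in the final round), re-superimposing on the current
    match set each round.  The retained subset M maximises
    sum_{i in M} 1 / (1 + (d_i / d0)^2), and the score is that sum divided
    by the chain length.
    """
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError("model and reference must have equal shapes")
    L = len(model)
    if L < seed_len:
        raise ValueError(f"length {L} shorter than seed length {seed_len}")

    def _score_from_subset(mask: np.ndarray) -> tuple[float, np.ndarray]:
        if mask.sum() < 3:
            return 0.0, mask
        R, pc, qc, _ = _kabsch(model[mask], reference[mask])
        d = np.linalg.norm((model - pc) @ R.T - (reference - qc), axis=1)
        final = d < d0
        if final.sum() < 3:
            return 0.0, final
        s = float(np.sum(1.0 / (1.0 + (d[final] / d0) ** 2)))
        return s, final

    best = 0.0
    for start in range(L - seed_len + 1):
        mask = np.zeros(L, dtype=bool)
        mask[start:start + seed_len] = True
        for it in range(1, refine_iters + 1):
            threshold = d0 * it / refine_iters
            R, pc, qc, _ = _kabsch(model[mask], reference[mask])
            d = np.linalg.norm((model - pc) @ R.T - (reference - qc), axis=1)
            new_mask = d < threshold
            # always retain the seed so the superposition never degenerates
            new_mask[start:start + seed_len] = True
            mask = new_mask
        s, _ = _score_from_subset(mask)
        best = max(best, s)
    return best / L


def pairwise_hamming_matrix(matrix: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distances between the rows of a state matrix.

    Binary matrices use the |x| + |y| - 2 x.y identity (BLAS matmul); general
    alphabets fall back to per-state equality accumulation, still O(S)
    matmuls rather than an O(N^2 L) Python loop.
    """
    X = np.asarray(matrix)
    n, L = X.shape
    states = np.unique(X)
    if states.size <= 2 and X.max(initial=0) <= 1:
        B = X.astype(np.float64)
        pop = B.sum(axis=1)
        G = B @ B.T
        D = pop[:, None] + pop[None, :] - 2 * G
    else:
        agree = np.zeros((n, n))
        for s in states:
            I = (X == s).astype(np.float64)
            agree += I @ I.T
        D = L - agree
    D = np.rint(D)
    np.fill_diagonal(D, 0)
    return np.maximum(D, 0)


def write_distance_matrix(ids: list[str], matrix: np.ndarray, path: str) -> None:
    """Write a square distance matrix as TSV with id row/column headers."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for mid, row in zip(ids, np.asarray(matrix)):
            fh.write(mid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
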