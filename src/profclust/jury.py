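"""Linear-time 1D-jury consensus ranking.

The jury score of a model is the sum, over profile positions, of how many
models in the set (itself included) occupy the same state at that position.
This equals the sum over all pairs (m, m') of per-position agreements, so a
single pass that tallies per-position state frequencies replaces the
quadratic loop over model pairs: O(N*L) time, O(L*S + N) memory.

For fixed-dimension frequency profiles (bag-of-fragments) the analogous
score is the sum of cosine similarities to all models, computed against the
accumulated sum of unit vectors in O(N*D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import FrequencyProfile, ProfileSet

__all__ = [
    "StateFrequencyTable",
    "JuryResult",
    "state_frequency_table",
    "jury_rank",
    "jury_rank_frequency",
    "write_ranking",
]


@dataclass
class StateFrequencyTable:
    """L x S table of per-position state occupancy counts; rows sum to N."""

    counts: np.ndarray
    n_models: int


@dataclass
class JuryResult:
    """Scores and ranking from a jury pass.

    ``ranking`` sorts ids by descending score with ties broken by input
    order; ``reference_id`` is the top-ranked id and serves as the hashing
    reference profile.
    """

    scores: dict[str, float]
    ranking: list[str]

    @property
    def reference_id(self) -> str:
        return self.ranking[0]


def state_frequency_table(profiles: ProfileSet) -> StateFrequencyTable:
    """Tally counts[p][s] = number of models in state s at position p."""
    X = profiles.matrix()
    N, L = X.shape
    S = profiles.alphabet.size
    counts = np.zeros((L, S), dtype=np.int64)
    np.add.at(counts, (np.arange(L)[None, :].repeat(N, 0), X), 1)
    return StateFrequencyTable(counts=counts, n_models=N)


def _rank_from_scores(ids: list[str], scores: np.ndarray) -> JuryResult:
    # stable sort on negated scores preserves input order among ties
    order = np.argsort(-scores, kind="stable")
    return JuryResult(
        scores={ids[i]: scores[i].item() for i in range(len(ids))},
        ranking=[ids[i] for i in order],
    )


def jury_rank(profiles: ProfileSet) -> JuryResult:
    """Consensus-rank state profiles by implicit all-pairs agreement.

    score(m) = sum_p counts[p][state_m(p)], identical to the explicit
    pairwise match-count sum including the self-match (which adds the
    constant L to every model and leaves the ranking unchanged).
    """
    table = state_frequency_table(profiles)
    X = profiles.matrix()
    L = profiles.length
    scores = table.counts[np.arange(L)[None, :], X].sum(axis=1)
    return _rank_from_scores(profiles.ids, scores.astype(np.float64))


def jury_rank_frequency(vectors: list[FrequencyProfile]) -> JuryResult:
    """Consensus-rank frequency profiles by summed cosine similarity.

    Each vector is normalised to unit length; score(m) = v_m . sum_m' v_m',
    the sum of cosine similarities of m to every model (self included).
    """
    if not vectors:
        raise ValueError("empty vector set")
    D = len(vectors[0])
    V = np.zeros((len(vectors), D))
    for i, v in enumerate(vectors):
        if len(v) != D:
            raise ValueError(f"vector {v.model_id} has dimension {len(v)}, expected {D}")
        norm = np.linalg.norm(v.counts)
        if norm == 0:
            raise ValueError(f"zero frequency vector: {v.model_id}")
        V[i] = v.counts / norm
    total = V.sum(axis=0)
    scores = V @ total
    return _rank_from_scores([v.model_id for v in vectors], scores)


def write_ranking(result: JuryResult, path: str, header: str | None = None) -> None:
    """Write the ranking TSV: rank, model_id, jury_score."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("rank\tmodel_id\tjury_score\n")
        for rank, mid in enumerate(result.ranking, 1):
            score = result.scores[mid]
            text = f"{score:.6g}" if isinstance(score, float) and not score.is_integer() \
                else f"{int(score)}"
            fh.write(f"{rank}\t{mid}\t{text}\n")
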