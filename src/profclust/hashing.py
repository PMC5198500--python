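"""Consensus-referenced binary profile hashing.

Each model's profile is reduced to a bitstring against a reference profile
(normally the top 1D-jury model): bit p is 0 where the model shares the
reference's state at position p and 1 otherwise, so the popcount of a key
equals the Hamming distance to the reference.  Models with identical keys
form micro-clusters.  Because the jury reference is the geometric consensus
of the set, many mutually consistent models collapse onto the same key,
giving a far less granular partition than a random reference would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import FrequencyProfile, ProfileSet, StateProfile, Alphabet

__all__ = [
    "HashKey",
    "MicroClusterIndex",
    "make_hash_keys",
    "key_matrix",
    "quantize_frequency",
    "group_by_key",
    "key_entropy",
    "write_keys",
]


@dataclass
class HashKey:
    """Binary mismatch pattern of one model against the reference profile."""

    model_id: str
    bits: np.ndarray  # (L,) uint8 vector of 0/1

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D vector")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def pattern(self) -> bytes:
        return self.bits.tobytes()

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class MicroClusterIndex:
    """Partition of models into groups sharing an identical key pattern.

    Group order follows first appearance in the input; member order follows
    input order.
    """

    groups: dict[bytes, list[str]]
    reference_id: str | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(v) for v in self.groups.values()]

    def __len__(self) -> int:
        return len(self.groups)


def make_hash_keys(profiles: ProfileSet, reference: StateProfile) -> list[HashKey]:
    """Build one binary key per model: bit p = 0 iff the model matches the
    reference state at position p.  The reference's own key is all zeros."""
    if len(reference) != profiles.length or reference.alphabet.states != profiles.alphabet.states:
        raise ValueError("reference must share length and alphabet with the profile set")
    X = profiles.matrix()
    bits = (X != reference.states[None, :]).astype(np.uint8)
    return [HashKey(mid, row) for mid, row in zip(profiles.ids, bits)]


def key_matrix(keys: list[HashKey]) -> np.ndarray:
    """Stack keys into an (N, L) uint8 matrix."""
    return np.stack([k.bits for k in keys])


def quantize_frequency(vector: FrequencyProfile,
                       bin_edges=(1, 2, 4, 8)) -> StateProfile:
    """Discretise a frequency vector into per-dimension count bins so that
    fragment profiles can flow through the binary-key hashing path.

    Default edges (1, 2, 4, 8) produce bins 0, 1, 2-3, 4-7, >=8.
    """
    edges = np.asarray(bin_edges)
    if edges.ndim != 1 or len(edges) == 0 or np.any(np.diff(edges) <= 0) or edges[0] != 1:
        raise ValueError("bin_edges must be ascending and start at 1")
    states = np.searchsorted(edges, vector.counts, side="right")
    alphabet = Alphabet("count-bins", [str(i) for i in range(len(edges) + 1)])
    return StateProfile(vector.model_id, alphabet, states)


def group_by_key(keys: list[HashKey], reference_id: str | None = None,
                 positions: np.ndarray | None = None) -> MicroClusterIndex:
    """Group models by exact key pattern (optionally restricted to a subset
    of key positions, used when coarsening key granularity)."""
    groups: dict[bytes, list[str]] = {}
    for k in keys:
        pat = (k.bits if positions is None else k.bits[positions]).tobytes()
        groups.setdefault(pat, []).append(k.model_id)
    return MicroClusterIndex(groups=groups, reference_id=reference_id)


def key_entropy(keys: list[HashKey]) -> np.ndarray:
    """Per-position Shannon entropy (bits) of the key bit across all models."""
    B = key_matrix(keys).astype(np.float64)
    f1 = B.mean(axis=0)
    ent = np.zeros_like(f1)
    for f in (f1, 1.0 - f1):
        nz = f > 0
        ent[nz] -= f[nz] * np.log2(f[nz])
    return ent


def write_keys(keys: list[HashKey], path: str) -> None:
    """Export keys as TSV (model_id, bitstring) for inspection."""
    with open(path, "w") as fh:
        fh.write("model_id\tkey\n")
        for k in keys:
            fh.write(k.model_id + "\t" + "".join(map(str, k.bits.tolist())) + "\n")
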