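"""Projection of 3D structures into 1D state profiles and fragment
frequency profiles.

A *state profile* assigns each residue (or each long-range residue pair, for
contact-map profiles) to one discrete state of a shared alphabet; equal-length
models of the same molecule then become rows of an N x L categorical matrix.
A *frequency profile* is a fixed-dimension bag-of-fragments count vector and
is length-independent, so it also applies to structures of different size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .structio import Trace

__all__ = [
    "Alphabet",
    "StateProfile",
    "ProfileSet",
    "FrequencyProfile",
    "FragmentLibrary",
    "ResidueAnnotation",
    "ss_sa_profile",
    "ca_ss_nc_profile",
    "ca_cm_profile",
    "rna_p_cm_profile",
    "rna_ss_lw_profile",
    "rna_ss_ta_profile",
    "fragbag_profile",
    "read_user_profiles",
    "write_profiles",
    "read_dssp",
    "read_rna_annotation",
    "read_fragment_library",
    "write_fragment_library",
    "LW_CLASSES",
    "MAX_ASA",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of state labels with bijective label<->index encoding."""

    name: str
    states: tuple

    def __init__(self, name: str, states) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "states", tuple(states))
        if len(set(self.states)) != len(self.states):
            raise ValueError("alphabet labels must be unique")
        if len(self.states) < 2:
            raise ValueError("alphabet must have at least 2 states")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})

    @property
    def size(self) -> int:
        return len(self.states)

    def encode(self, label) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise ValueError(f"unknown state label {label!r} for alphabet {self.name}") from None

    def decode(self, index: int):
        return self.states[index]


BINARY = Alphabet("binary", ("0", "1"))


@dataclass
class StateProfile:
    """Per-position discrete state vector for one model."""

    model_id: str
    alphabet: Alphabet
    states: np.ndarray  # (L,) int array

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or len(self.states) == 0:
            raise ValueError("states must be a non-empty 1-D vector")
        if self.states.min() < 0 or self.states.max() >= self.alphabet.size:
            raise ValueError(
                f"profile {self.model_id}: state index out of range for alphabet "
                f"{self.alphabet.name} (size {self.alphabet.size})"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ProfileSet:
    """N aligned state profiles of equal length over a shared alphabet."""

    alphabet: Alphabet
    profiles: list[StateProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("empty profile set")
        L = len(self.profiles[0])
        for p in self.profiles:
            if len(p) != L:
                raise ValueError(
                    f"profile {p.model_id} has length {len(p)}, expected {L}"
                )
            if p.alphabet.states != self.alphabet.states:
                raise ValueError(f"profile {p.model_id} uses a different alphabet")

    @property
    def ids(self) -> list[str]:
        return [p.model_id for p in self.profiles]

    @property
    def length(self) -> int:
        return len(self.profiles[0])

    def matrix(self) -> np.ndarray:
        """The N x L state-index matrix."""
        return np.stack([p.states for p in self.profiles])

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, alphabet: Alphabet, ids=None) -> "ProfileSet":
        matrix = np.asarray(matrix)
        if ids is None:
            ids = [f"m{i}" for i in range(len(matrix))]
        return cls(alphabet, [StateProfile(i, alphabet, row) for i, row in zip(ids, matrix)])


@dataclass
class FrequencyProfile:
    """Fixed-dimension non-negative fragment count vector (bag of fragments)."""

    model_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError(f"profile {self.model_id}: negative count")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class FragmentLibrary:
    """Library of fixed-length backbone fragments used for bag-of-fragments
    encoding (e.g. 400 CA 11-mers for proteins, 92 P-trace 5-mers for RNA)."""

    name: str
    window_length: int
    fragments: list[np.ndarray]  # each (w, 3)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment library is empty")
        frags = []
        for i, f in enumerate(self.fragments):
            f = np.asarray(f, dtype=float)
            if f.shape != (self.window_length, 3):
                raise ValueError(
                    f"fragment {i} has shape {f.shape}, expected ({self.window_length}, 3)"
                )
            frags.append(f)
        self.fragments = frags

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class ResidueAnnotation:
    """Per-residue annotation ingested from external assignment tools.

    Proteins carry ``ss`` (DSSP 8-class char) and ``rsa`` (relative solvent
    accessibility in [0, 1]).  RNAs carry ``ss2`` (stem/loop), ``lw_class``
    (coarse base-pair type) and ``torsion_state`` (0..4 backbone/chi class).
    """

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Protein profiles
# ---------------------------------------------------------------------------

# Theoretical maximum accessible surface areas (A^2), Tien et al. scale.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

_SS3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
_SS3_ORDER = ("H", "E", "C")


def collapse_ss8(ss: str) -> str:
    """Collapse the 8-class DSSP secondary structure to helix/strand/coil."""
    return _SS3.get(ss, "C")


def _composite_alphabet(name: str, primary, secondary) -> Alphabet:
    return Alphabet(name, tuple(f"{a}{b}" for a in primary for b in secondary))


def ss_sa_profile(annotation: ResidueAnnotation, n_sa_bins: int = 10,
                  model_id: str = "model") -> StateProfile:
    """Secondary-structure / solvent-accessibility composite profile.

    Each residue maps to one of ``3 * n_sa_bins`` states: DSSP secondary
    structure collapsed to {H, E, C} crossed with the relative solvent
    accessibility binned into ``n_sa_bins`` equal-width bins on [0, 1]
    (rsa = 1.0 clamps into the top bin).
    """
    if not (2 <= n_sa_bins <= 10):
        raise ValueError("n_sa_bins must be in 2..10")
    states = []
    for rec in annotation.records:
        rsa = rec["rsa"]
        if not (0.0 <= rsa <= 1.0):
            raise ValueError(
                f"residue {rec.get('seq_index', '?')}: rsa {rsa} outside [0, 1]"
            )
        ss_index = _SS3_ORDER.index(collapse_ss8(rec["ss"]))
        sa_bin = min(int(rsa * n_sa_bins), n_sa_bins - 1)
        states.append(ss_index * n_sa_bins + sa_bin)
    alphabet = _composite_alphabet(f"ss-sa-{n_sa_bins}", _SS3_ORDER, range(n_sa_bins))
    return StateProfile(model_id, alphabet, np.asarray(states))


def ca_ss_nc_profile(trace: Trace, contact_radius: float = 10.0,
                     n_nc_bins: int = 10,
                     helix_d13_max: float = 6.0,
                     strand_d02_min: float = 6.2) -> StateProfile:
    """Pseudo secondary structure + contact number profile from a CA trace.

    The pseudo-SS state of residue i is H when d(CA_i, CA_{i+3}) <
    ``helix_d13_max`` (ideal helices give ~5.1 A), E when d(CA_i, CA_{i+2})
    > ``strand_d02_min`` (extended chains give ~7.6 A), else C; residues too
    close to the C-terminus for the test default to C.  The contact number
    counts CA atoms within ``contact_radius``, excluding chain neighbours
    |i-j| <= 2, and saturates at ``n_nc_bins - 1``.
    """
    L = len(trace)
    if L < 5:
        raise ValueError(f"trace length {L} < 5")
    X = trace.coords
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    states = []
    for i in range(L):
        if i + 3 < L and d[i, i + 3] < helix_d13_max:
            ss = 0  # H
        elif i + 2 < L and d[i, i + 2] > strand_d02_min:
            ss = 1  # E
        else:
            ss = 2  # C
        sep = np.abs(np.arange(L) - i)
        nc = int(np.sum((d[i] < contact_radius) & (sep > 2)))
        states.append(ss * n_nc_bins + min(nc, n_nc_bins - 1))
    alphabet = _composite_alphabet(f"ca-ss-nc-{n_nc_bins}", _SS3_ORDER, range(n_nc_bins))
    return StateProfile(trace.model_id, alphabet, np.asarray(states))


def _contact_map_profile(trace: Trace, cutoff: float, min_sep: int) -> StateProfile:
    L = len(trace)
    if L <= min_sep:
        raise ValueError(f"trace length {L} must exceed min_sep {min_sep}")
    X = trace.coords
    ii, jj = contact_pairs(L, min_sep)
    d = np.linalg.norm(X[ii] - X[jj], axis=1)
    states = (d < cutoff).astype(np.int64)
    return StateProfile(trace.model_id, BINARY, states)


def contact_pairs(length: int, min_sep: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Row-major (i, j) pairs with i < j and j - i >= min_sep (0-based)."""
    ii, jj = np.triu_indices(length, k=min_sep)
    return ii, jj


def ca_cm_profile(trace: Trace, cutoff: float = 8.5, min_sep: int = 12) -> StateProfile:
    """Binary CA contact-map profile: positions are the long-range pairs
    (i, j) with |i - j| > 11, state 1 iff d(CA_i, CA_j) < 8.5 A (strict)."""
    return _contact_map_profile(trace, cutoff, min_sep)


def rna_p_cm_profile(trace: Trace, cutoff: float = 15.5, min_sep: int = 12) -> StateProfile:
    """Binary phosphorus contact-map profile for RNA backbones: state 1 iff
    d(P_i, P_j) < 15.5 A (strict) at sequence separation |i - j| > 11."""
    return _contact_map_profile(trace, cutoff, min_sep)


# ---------------------------------------------------------------------------
# RNA annotation profiles
# ---------------------------------------------------------------------------

LW_CLASSES = (
    "cWW", "tWW", "cWH", "tWH", "cWS", "tWS", "cHH", "tHH",
    "cHS", "tHS", "cSS", "tSS", "bifurcated", "water-inserted", "Other",
)
_SS2_ORDER = ("stem", "loop")


def rna_ss_lw_profile(annotation: ResidueAnnotation, model_id: str = "model",
                      lw_classes=LW_CLASSES) -> StateProfile:
    """RNA stem/loop x coarse base-pair-class composite profile (30 states:
    2 secondary-structure states crossed with 15 Leontis-Westhof-style
    base-pair classes; unpaired residues carry the 'Other' class)."""
    lw_classes = tuple(lw_classes)
    states = []
    for rec in annotation.records:
        ss2 = rec["ss2"]
        if ss2 not in _SS2_ORDER:
            raise ValueError(f"ss2 must be 'stem' or 'loop', got {ss2!r}")
        lw = rec.get("lw_class") or "Other"
        if lw not in lw_classes:
            raise ValueError(
                f"unknown base-pair class {lw!r}; accepted: {', '.join(lw_classes)}"
            )
        states.append(_SS2_ORDER.index(ss2) * len(lw_classes) + lw_classes.index(lw))
    alphabet = _composite_alphabet("rna-ss-lw", _SS2_ORDER, lw_classes)
    return StateProfile(model_id, alphabet, np.asarray(states))


def rna_ss_ta_profile(annotation: ResidueAnnotation, model_id: str = "model") -> StateProfile:
    """RNA stem/loop x torsion-state composite profile (10 states: 2
    secondary-structure states crossed with 5 backbone/chi torsion classes)."""
    states = []
    for rec in annotation.records:
        ss2 = rec["ss2"]
        if ss2 not in _SS2_ORDER:
            raise ValueError(f"ss2 must be 'stem' or 'loop', got {ss2!r}")
        ta = rec.get("torsion_state")
        if ta is None or not (0 <= int(ta) <= 4):
            raise ValueError(
                f"residue {rec.get('seq_index', '?')}: missing or invalid torsion state"
            )
        states.append(_SS2_ORDER.index(ss2) * 5 + int(ta))
    alphabet = _composite_alphabet("rna-ss-ta", _SS2_ORDER, range(5))
    return StateProfile(model_id, alphabet, np.asarray(states))


# ---------------------------------------------------------------------------
# Fragment (bag-of-fragments) profiles
# ---------------------------------------------------------------------------

def fragbag_profile(trace: Trace, library: FragmentLibrary) -> FrequencyProfile:
    """Bag-of-fragments frequency profile.

    Slides a window of the library's fragment length along the trace; each
    of the L - w + 1 windows is assigned to the library fragment with the
    minimum superposition RMSD (ties break to the lowest fragment index)
    and that fragment's count is incremented.
    """
    from .similarity import kabsch_rmsd

    w = library.window_length
    L = len(trace)
    if L < w:
        raise ValueError(f"trace length {L} shorter than fragment window {w}")
    counts = np.zeros(len(library), dtype=float)
    for start in range(L - w + 1):
        window = trace.coords[start:start + w]
        rmsds = np.array([kabsch_rmsd(window, frag).rmsd for frag in library.fragments])
        counts[int(np.argmin(rmsds))] += 1
    return FrequencyProfile(trace.model_id, counts)


def read_fragment_library(path: str, name: str | None = None) -> FragmentLibrary:
    """Read a fragment library: blocks of ``> fragment_name`` headers each
    followed by one ``x y z`` line per backbone point."""
    fragments: list[np.ndarray] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if current is not None:
                    fragments.append(np.asarray(current))
                current = []
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: coordinates before first header")
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 coordinates")
                current.append([float(p) for p in parts])
    if current is not None:
        fragments.append(np.asarray(current))
    if not fragments:
        raise ValueError(f"no fragments found in {path}")
    w = len(fragments[0])
    return FragmentLibrary(name or path, window_length=w, fragments=fragments)


def write_fragment_library(library: FragmentLibrary, path: str) -> None:
    with open(path, "w") as fh:
        for i, frag in enumerate(library.fragments):
            fh.write(f"> frag{i}\n")
            for x, y, z in frag:
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")


# ---------------------------------------------------------------------------
# User profiles (TSV)
# ---------------------------------------------------------------------------

def read_user_profiles(path: str) -> ProfileSet:
    """Read a user-defined profile table.

    Format: a header line ``#alphabet<TAB>name<TAB>label1,label2,...``
    followed by one row per model: ``model_id<TAB>state<TAB>state...``.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        m = re.match(r"#alphabet\t([^\t]+)\t(.+)$", header)
        if not m:
            raise ValueError(
                f"{path}: first line must be '#alphabet<TAB>name<TAB>comma-separated labels'"
            )
        alphabet = Alphabet(m.group(1), [s.strip() for s in m.group(2).split(",")])
        profiles: list[StateProfile] = []
        expected_len: int | None = None
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            mid, labels = parts[0], parts[1:]
            if expected_len is None:
                expected_len = len(labels)
                if expected_len == 0:
                    raise ValueError(f"{path}:{lineno}: row has no states")
            elif len(labels) != expected_len:
                raise ValueError(
                    f"{path}:{lineno}: row {mid!r} has {len(labels)} states, "
                    f"expected {expected_len}"
                )
            try:
                states = [alphabet.encode(lab) for lab in labels]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            profiles.append(StateProfile(mid, alphabet, np.asarray(states)))
    if not profiles:
        raise ValueError(f"{path}: no profile rows")
    return ProfileSet(alphabet, profiles)


def write_profiles(profile_set: ProfileSet, path: str) -> None:
    alphabet = profile_set.alphabet
    with open(path, "w") as fh:
        fh.write(f"#alphabet\t{alphabet.name}\t{','.join(map(str, alphabet.states))}\n")
        for p in profile_set:
            labels = [str(alphabet.decode(s)) for s in p.states]
            fh.write(p.model_id + "\t" + "\t".join(labels) + "\n")


# ---------------------------------------------------------------------------
# DSSP / RNA annotation ingestion
# ---------------------------------------------------------------------------

def read_dssp(path: str) -> ResidueAnnotation:
    """Parse a standard DSSP output file into per-residue (ss, rsa) records.

    rsa = ACC / max-ASA(residue type), clipped to [0, 1]; chain-break ('!')
    rows are skipped.
    """
    records = []
    with open(path) as fh:
        in_data = False
        for lineno, line in enumerate(fh, 1):
            if not in_data:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_data = True
                continue
            if len(line) < 39:
                raise ValueError(f"{path}:{lineno}: truncated DSSP residue line")
            aa = line[13]
            if aa == "!":
                continue
            ss = line[16]
            if ss == " ":
                ss = "C"
            try:
                acc = float(line[34:38])
                seq_index = int(line[5:10])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed DSSP residue line") from None
            max_asa = MAX_ASA.get(aa.upper(), 200.0)
            rsa = min(acc / max_asa, 1.0)
            records.append({"seq_index": seq_index, "aa": aa, "ss": ss, "rsa": rsa})
    if not in_data:
        raise ValueError(f"{path}: no DSSP data header ('#  RESIDUE') found")
    return ResidueAnnotation(records)


def read_rna_annotation(path: str) -> ResidueAnnotation:
    """Read the RNA annotation TSV: residue, ss2, lw_class, torsion_state."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            idx, ss2, lw, ta = parts
            records.append({
                "seq_index": int(idx),
                "ss2": ss2,
                "lw_class": lw if lw not in ("", "-") else "Other",
                "torsion_state": int(ta) if ta not in ("", "-") else None,
            })
    return ResidueAnnotation(records)
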