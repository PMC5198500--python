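"""Structure I/O and synthetic ensemble generation.

Models are stored as ordered residue lists with named-atom coordinates so
that both all-atom and reduced (CA-only / P-only) structures share one
container.  All models of an ensemble are aligned *positionally*: residue i
of one model corresponds to residue i of every other, regardless of author
numbering in the source PDB files.  Fixed-length profile comparison requires
this positional identity.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Model",
    "ModelSet",
    "Trace",
    "read_models",
    "write_models",
    "read_xyz_table",
    "write_xyz_table",
    "extract_trace",
    "helix_trace",
    "generate_ensemble",
    "generate_profile_set",
]


@dataclass
class Model:
    """One 3D conformation: ordered residues with named-atom coordinates.

    Parameters
    ----------
    id : str
        Unique model identifier (PDB MODEL number or filename stem).
    kind : str
        ``"protein"`` or ``"rna"``.
    residues : list of (int, str, dict)
        Ordered ``(seq_index, residue_name, {atom_name: (x, y, z)})``
        records; ``seq_index`` is 1-based and strictly increasing.
    """

    id: str
    kind: str
    residues: list[tuple[int, str, dict[str, np.ndarray]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "rna"):
            raise ValueError(f"kind must be 'protein' or 'rna', got {self.kind!r}")
        prev = 0
        for seq_index, _name, atoms in self.residues:
            if seq_index <= prev:
                raise ValueError(
                    f"model {self.id}: residue seq_index not strictly increasing at {seq_index}"
                )
            prev = seq_index
            for aname, coord in atoms.items():
                c = np.asarray(coord, dtype=float)
                if c.shape != (3,) or not np.all(np.isfinite(c)):
                    raise ValueError(
                        f"model {self.id}: non-finite or malformed coordinate for "
                        f"atom {aname} of residue {seq_index}"
                    )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ModelSet:
    """An ordered collection of models of the same molecule.

    In fixed-length mode (the default) all members must have the same
    residue count, so per-residue profiles align across models.
    """

    models: list[Model]
    fixed_length: bool = True

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("empty model set")
        ids = [m.id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids are not unique")
        if self.fixed_length:
            L = len(self.models[0])
            for m in self.models:
                if len(m) != L:
                    raise ValueError(
                        f"fixed-length mode: model {m.id} has {len(m)} residues, expected {L}"
                    )

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.models]

    @property
    def length(self) -> int:
        return len(self.models[0])

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass
class Trace:
    """Backbone trace: coordinates of one named atom per residue, in order."""

    model_id: str
    coords: np.ndarray  # (L, 3) float array, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("trace coords must be an (L, 3) array")

    def __len__(self) -> int:
        return len(self.coords)


# ---------------------------------------------------------------------------
# PDB / xyz ingestion
# ---------------------------------------------------------------------------

_RNA_RESNAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU", "ADE", "CYT", "GUA", "URA"}


def _guess_kind(residue_names: list[str]) -> str:
    n_rna = sum(1 for r in residue_names if r.strip() in _RNA_RESNAMES)
    return "rna" if residue_names and n_rna > len(residue_names) / 2 else "protein"


def _biopdb_to_model(struct_model, model_id: str, atom_subset=None) -> Model:
    residues = []
    names = []
    seq = 0
    for chain in struct_model:
        for res in chain:
            if res.id[0] != " ":  # skip HETATM / water
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                name = atom.get_name()
                if atom_subset is not None and name not in atom_subset:
                    continue
                if name in atoms:
                    continue  # first altloc kept
                atoms[name] = np.asarray(atom.get_coord(), dtype=float)
            if not atoms:
                continue
            seq += 1
            residues.append((seq, res.get_resname().strip(), atoms))
            names.append(res.get_resname())
    return Model(id=model_id, kind=_guess_kind(names), residues=residues)


def read_models(path: str, atom_subset=None, fixed_length: bool = True) -> ModelSet:
    """Read a multi-MODEL PDB file or a directory of single-model PDB files.

    Parameters
    ----------
    path : str
        Path to a PDB file (one model per MODEL/ENDMDL record, or a single
        implicit model) or a directory of ``*.pdb`` files.
    atom_subset : set of str, optional
        Keep only these atom names (e.g. ``{"CA"}``).
    fixed_length : bool
        Require all models to share the residue count.

    Returns
    -------
    ModelSet
        One Model per MODEL record or per file; ids are MODEL numbers or
        filename stems.  The first altloc of each atom is kept; insertion
        codes are honoured in residue ordering (file order).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    models: list[Model] = []
    if os.path.isdir(path):
        files = sorted(f for f in os.listdir(path) if f.lower().endswith(".pdb"))
        if not files:
            raise ValueError(f"no .pdb files found in directory {path}")
        for fname in files:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                structure = parser.get_structure(fname, os.path.join(path, fname))
            stem = os.path.splitext(fname)[0]
            sub = list(structure)
            if len(sub) == 1:
                models.append(_biopdb_to_model(sub[0], stem, atom_subset))
            else:
                for sm in sub:
                    models.append(_biopdb_to_model(sm, f"{stem}_{sm.id + 1}", atom_subset))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(os.path.basename(path), path)
        for sm in structure:
            models.append(_biopdb_to_model(sm, str(sm.id + 1), atom_subset))
    models = [m for m in models if len(m) > 0]
    if not models:
        raise ValueError(f"no models with atoms read from {path}")
    return ModelSet(models, fixed_length=fixed_length)


def write_models(model_set: ModelSet, path: str) -> None:
    """Write a ModelSet as a multi-MODEL PDB file (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for model_number, model in enumerate(model_set, 1):
            fh.write(f"MODEL     {model_number:>4}\n")
            serial = 1
            for seq_index, resname, atoms in model.residues:
                for aname, coord in atoms.items():
                    pdb_name = f" {aname:<3}" if len(aname) < 4 else aname
                    fh.write(
                        f"ATOM  {serial:>5} {pdb_name} {resname:>3} A{seq_index:>4}    "
                        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_xyz_table(path: str, kind: str = "protein", atom_name: str = "CA") -> ModelSet:
    """Read the lightweight whitespace table: model_id residue_index x y z."""
    per_model: dict[str, list[tuple[int, np.ndarray]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            mid, idx, x, y, z = parts
            per_model.setdefault(mid, []).append(
                (int(idx), np.array([float(x), float(y), float(z)]))
            )
    models = []
    for mid, rows in per_model.items():
        rows.sort(key=lambda r: r[0])
        residues = [(idx, "GLY" if kind == "protein" else "A", {atom_name: c})
                    for idx, c in rows]
        models.append(Model(id=mid, kind=kind, residues=residues))
    return ModelSet(models)


def write_xyz_table(model_set: ModelSet, path: str, atom_name: str = "CA") -> None:
    with open(path, "w") as fh:
        for model in model_set:
            for seq_index, _name, atoms in model.residues:
                c = atoms[atom_name]
                fh.write(f"{model.id}\t{seq_index}\t{c[0]:.3f}\t{c[1]:.3f}\t{c[2]:.3f}\n")


def extract_trace(model: Model, atom_name: str) -> Trace:
    """Extract the ordered coordinates of one named atom per residue.

    Raises
    ------
    ValueError
        If any residue lacks ``atom_name`` (the error names its seq_index).
    """
    coords = []
    for seq_index, _resname, atoms in model.residues:
        if atom_name not in atoms:
            raise ValueError(
                f"model {model.id}: residue {seq_index} has no atom {atom_name!r}"
            )
        coords.append(atoms[atom_name])
    return Trace(model_id=model.id, coords=np.asarray(coords))


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def helix_trace(n_residues: int, rise: float = 1.5, radius: float = 2.3,
                twist_deg: float = 100.0, model_id: str = "template") -> Trace:
    """Ideal alpha-helical CA trace (default: 1.5 A rise, 2.3 A radius,
    100 degrees per residue)."""
    t = np.arange(n_residues)
    ang = np.deg2rad(twist_deg) * t
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])
    return Trace(model_id=model_id, coords=coords)


def compact_trace(n_residues: int, seed: int = 0, bond: float = 3.8,
                  radius: float | None = None, model_id: str = "template") -> Trace:
    """Compact globular CA-like trace: a smooth fixed-bond random walk
    confined to a sphere, so long-range contacts exist (unlike an ideal
    helix, whose contact map at |i-j| > 11 is empty).

    The confinement radius defaults to ``2.2 * n**0.38`` A, the empirical
    radius-of-gyration scaling of globular proteins.
    """
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = 2.2 * n_residues ** 0.38
    coords = np.zeros((n_residues, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n_residues):
        # correlated direction change keeps the walk locally smooth
        direction = direction + 0.6 * rng.normal(size=3)
        # steer back toward the centre when outside the confinement sphere
        r = np.linalg.norm(coords[i - 1])
        if r > radius:
            direction -= 0.8 * (r / radius - 1.0) * coords[i - 1] / r * 3.0
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + bond * direction
    return Trace(model_id=model_id, coords=coords - coords.mean(axis=0))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _deform_template(coords: np.ndarray, shift: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth deformation: rigid hinge at a random interior residue plus a
    low-frequency sinusoidal displacement, scaled to overall magnitude
    ``shift`` (Angstrom RMS over residues)."""
    L = len(coords)
    out = coords.copy()
    # hinge: rotate the tail about a random axis through the pivot
    pivot = int(rng.integers(L // 4, 3 * L // 4))
    axis = rng.normal(size=3)
    angle = rng.uniform(0.35, 1.0) * rng.choice([-1.0, 1.0])
    R = _rotation_about_axis(axis, angle)
    out[pivot:] = (out[pivot:] - out[pivot]) @ R.T + out[pivot]
    # low-frequency sinusoid along a random direction
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    freq = rng.integers(1, 4)
    phase = rng.uniform(0, 2 * np.pi)
    amp = shift / 2.0
    wave = amp * np.sin(2 * np.pi * freq * np.arange(L) / L + phase)
    out += wave[:, None] * direction
    # rescale total displacement to the requested magnitude
    disp = out - coords
    rms = math.sqrt(float(np.mean(np.sum(disp**2, axis=1))))
    if rms > 0:
        out = coords + disp * (shift / rms)
    return out


def generate_ensemble(template: Trace, n_clusters: int, per_cluster: int,
                      conformer_shift: float, noise_sigma: float,
                      seed: int) -> tuple[ModelSet, np.ndarray]:
    """Planted-cluster decoy ensemble around deformed copies of a template.

    ``n_clusters`` distinct base conformers are made by applying independent
    smooth deformations (random hinge + low-frequency bend) of RMS magnitude
    ``conformer_shift`` to the template trace; each cluster consists of
    ``per_cluster`` noisy copies of its base conformer (i.i.d. Gaussian
    noise, sigma ``noise_sigma`` per coordinate).

    Returns
    -------
    (ModelSet, ndarray)
        The ensemble (CA-only protein models, ids ``c<k>_m<j>``) and the
        true cluster label of each model.
    """
    if n_clusters < 1 or per_cluster < 1:
        raise ValueError("n_clusters and per_cluster must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    bases = [_deform_template(template.coords, conformer_shift, rng)
             for _ in range(n_clusters)]
    models, labels = [], []
    for k, base in enumerate(bases):
        for j in range(per_cluster):
            coords = base + rng.normal(scale=noise_sigma, size=base.shape) \
                if noise_sigma > 0 else base.copy()
            residues = [(i + 1, "GLY", {"CA": coords[i]}) for i in range(len(coords))]
            models.append(Model(id=f"c{k}_m{j}", kind="protein", residues=residues))
            labels.append(k)
    return ModelSet(models), np.asarray(labels)


def generate_profile_set(n: int, length: int, n_states: int, n_clusters: int,
                         flip_prob: float, seed: int):
    """Planted-cluster categorical profile matrix.

    ``n_clusters`` archetype profiles are drawn uniformly over the alphabet;
    each member copies its archetype (round-robin assignment) and then
    independently resamples each position to a uniformly random *other*
    state with probability ``flip_prob``.

    Returns
    -------
    (ProfileSet, ndarray)
        The profiles (ids ``m0..m<n-1>``) and the true cluster labels.
    """
    from .profiles import Alphabet, ProfileSet, StateProfile

    if not (0 <= flip_prob < 1):
        raise ValueError("flip_prob must be in [0, 1)")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if n_clusters > n:
        raise ValueError("n_clusters may not exceed n")
    rng = np.random.default_rng(seed)
    archetypes = rng.integers(0, n_states, size=(n_clusters, length))
    labels = np.arange(n) % n_clusters
    states = archetypes[labels].copy()
    if flip_prob > 0:
        flips = rng.random(size=states.shape) < flip_prob
        # resample to a uniformly random *other* state
        offsets = rng.integers(1, n_states, size=states.shape)
        states[flips] = (states[flips] + offsets[flips]) % n_states
    alphabet = Alphabet("synthetic", [str(s) for s in range(n_states)])
    profiles = [StateProfile(f"m{i}", alphabet, states[i]) for i in range(n)]
    return ProfileSet(alphabet, profiles), labels
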