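"""Structure data model, PDB I/O, coarse-graining and geometric descriptors.

Conformers are stored as flat numpy arrays (one row per atom/bead).  The
ensemble pipeline works at one-bead-per-residue (Cα) resolution, but the
model holds arbitrary atom records so that all-atom crystal structures can
be read and coarse-grained on the fly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = [
    "Conformer",
    "ResidueSet",
    "RigidDomain",
    "FlexibleSegment",
    "Tether",
    "ComplexTopology",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "radius_of_gyration",
    "center_of_mass_distance",
    "random_rotation",
]


class EmptyStructureError(ValueError):
    """Raised when a structure contains no usable atom records."""


@dataclass
class Conformer:
    """One structural model: atom/bead records with coordinates in Å.

    ``is_coarse`` marks one-bead-per-residue models (bead at the Cα
    position).  Invariants: coordinates finite, (chain, residue, atom)
    unique, residue indices non-decreasing within a chain.
    """

    model_id: str
    chain_ids: np.ndarray        # (n,) str
    residue_indices: np.ndarray  # (n,) int, 1-based
    residue_names: np.ndarray    # (n,) str, 3-letter codes
    atom_names: np.ndarray       # (n,) str
    coords: np.ndarray           # (n, 3) float, Å
    is_coarse: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise EmptyStructureError(f"conformer {self.model_id!r} has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.residue_indices, self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue, atom) records are not unique")
        for chain in dict.fromkeys(self.chain_ids):
            resi = self.residue_indices[self.chain_ids == chain]
            if np.any(np.diff(resi) < 0):
                raise ValueError(f"residue indices decrease within chain {chain!r}")

    def mask(self, chain_id: str | None = None,
             residues: Iterable[int] | None = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            m &= self.chain_ids == chain_id
        if residues is not None:
            m &= np.isin(self.residue_indices, np.fromiter(residues, dtype=int))
        return m

    def centroid(self, mask: np.ndarray | None = None) -> np.ndarray:
        xyz = self.coords if mask is None else self.coords[mask]
        if len(xyz) == 0:
            raise LookupError("selection matches no atoms")
        return xyz.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "Conformer":
        """Return a copy with coordinates x -> R x + t."""
        new = replace(self, coords=self.coords @ np.asarray(rotation).T
                      + np.asarray(translation))
        if model_id is not None:
            new.model_id = model_id
        return new

    def coarse_grained(self) -> "Conformer":
        """One bead per residue at the Cα position; non-Cα records dropped."""
        keep = self.atom_names == "CA"
        n_res = len({(c, r) for c, r in zip(self.chain_ids, self.residue_indices)})
        if keep.sum() < n_res:
            warnings.warn(
                f"{n_res - int(keep.sum())} residue(s) lack a CA atom; skipped",
                stacklevel=2)
        cg = Conformer(
            model_id=self.model_id,
            chain_ids=self.chain_ids[keep],
            residue_indices=self.residue_indices[keep],
            residue_names=self.residue_names[keep],
            atom_names=self.atom_names[keep],
            coords=self.coords[keep],
            is_coarse=True,
        )
        if cg.n_atoms == 0:
            raise EmptyStructureError(
                f"conformer {self.model_id!r} has no CA atoms to coarse-grain")
        return cg


@dataclass(frozen=True)
class ResidueSet:
    """A named selection of residues on one chain (inclusive indices)."""

    chain_id: str
    residues: tuple[int, ...]

    @classmethod
    def from_range(cls, chain_id: str, start: int, end: int) -> "ResidueSet":
        return cls(chain_id, tuple(range(start, end + 1)))


# ---------------------------------------------------------------------------
# topology

@dataclass
class RigidDomain:
    """A rigid body: residue range whose internal geometry comes from a
    source structure (crystal structure or synthetic body).

    ``numbering_offset`` maps construct-local numbering to the numbering
    used in external data (residue_in_data = residue_in_construct + offset).
    """

    name: str
    chain_id: str
    start: int
    end: int
    source: Conformer
    numbering_offset: int = 0

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def source_mask(self) -> np.ndarray:
        return self.source.mask(self.chain_id, self.residues)


@dataclass
class FlexibleSegment:
    """A flexible stretch grown as a self-avoiding Cα chain.

    ``residue_names`` optionally assigns 3-letter codes (e.g. to place
    lysines in linkers); defaults to GLY.
    """

    chain_id: str
    start: int
    end: int
    residue_names: tuple[str, ...] | None = None

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def name_of(self, resi: int) -> str:
        if self.residue_names is None:
            return "GLY"
        return self.residue_names[resi - self.start]


@dataclass
class Tether:
    """Anchor constraint: the relative pose of two rigid domains is fixed,
    as taken from a shared crystal-structure frame (their source coordinates
    are interpreted in one common frame and move as one body)."""

    domain_a: str
    domain_b: str
    note: str = ""


@dataclass
class ComplexTopology:
    """Declaration of rigid domains, flexible segments and tethers."""

    chains: list[str]
    rigid_domains: list[RigidDomain]
    flexible_segments: list[FlexibleSegment]
    tethers: list[Tether] = field(default_factory=list)

    def domain(self, name: str) -> RigidDomain:
        for d in self.rigid_domains:
            if d.name == name:
                return d
        raise LookupError(f"no rigid domain named {name!r}")

    def validate(self) -> None:
        names = [d.name for d in self.rigid_domains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate rigid-domain names")
        for chain in self.chains:
            spans = sorted(
                [(d.start, d.end, "rigid") for d in self.rigid_domains
                 if d.chain_id == chain]
                + [(s.start, s.end, "flex") for s in self.flexible_segments
                   if s.chain_id == chain])
            if not spans:
                raise ValueError(f"chain {chain!r} declares no segments")
            for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
                if s2 != e1 + 1:
                    raise ValueError(
                        f"chain {chain!r}: ranges {s1}-{e1} and {s2}-{e2} do not"
                        " tile the construct (gap or overlap)")
        for t in self.tethers:
            self.domain(t.domain_a)
            self.domain(t.domain_b)

    def chain_residues(self, chain: str) -> range:
        spans = ([(d.start, d.end) for d in self.rigid_domains if d.chain_id == chain]
                 + [(s.start, s.end) for s in self.flexible_segments
                    if s.chain_id == chain])
        return range(min(s for s, _ in spans), max(e for _, e in spans) + 1)

    def domain_of_residue(self, chain: str, resi: int) -> str | None:
        for d in self.rigid_domains:
            if d.chain_id == chain and d.start <= resi <= d.end:
                return d.name
        return None


# ---------------------------------------------------------------------------
# PDB I/O (gemmi)

def read_structure(path: str | Path, coarse: bool = False) -> Conformer:
    """Read a PDB file into a Conformer (first MODEL; ATOM records only).

    With ``coarse`` the result has one bead per residue at the Cα position;
    residues lacking a Cα are skipped with a warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]
    chains, resis, resns, atoms, xyz = [], [], [], [], []
    for chain in model:
        for res in chain:
            if res.het_flag != "A":     # skip HETATM
                continue
            for atom in res:
                chains.append(chain.name)
                resis.append(res.seqid.num)
                resns.append(res.name)
                atoms.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    conf = Conformer(
        model_id=path.stem,
        chain_ids=np.array(chains, dtype=object),
        residue_indices=np.array(resis, dtype=int),
        residue_names=np.array(resns, dtype=object),
        atom_names=np.array(atoms, dtype=object),
        coords=np.array(xyz, dtype=float).reshape(-1, 3),
    )
    if conf.n_atoms == 0:
        raise EmptyStructureError(f"{path} has no ATOM records")
    return conf.coarse_grained() if coarse else conf


def write_structure(conf: Conformer, path: str | Path) -> None:
    """Write a Conformer as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = conf.model_id
    model = gemmi.Model("1")
    for chain_name in dict.fromkeys(conf.chain_ids):
        chain = gemmi.Chain(str(chain_name))
        sel = conf.chain_ids == chain_name
        for resi in dict.fromkeys(conf.residue_indices[sel]):
            rsel = sel & (conf.residue_indices == resi)
            res = gemmi.Residue()
            res.seqid = gemmi.SeqId(int(resi), " ")
            res.name = str(conf.residue_names[rsel][0])
            res.het_flag = "A"
            for aname, pos in zip(conf.atom_names[rsel], conf.coords[rsel]):
                atom = gemmi.Atom()
                atom.name = str(aname)
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*pos)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# descriptors

def radius_of_gyration(conf: Conformer) -> float:
    """Mass-uniform radius of gyration, sqrt(mean squared distance to the
    centroid), in Å."""
    if conf.n_atoms == 0:
        raise EmptyStructureError("empty conformer")
    d = conf.coords - conf.coords.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _resolve_set(conf: Conformer, sel) -> np.ndarray:
    if isinstance(sel, ResidueSet):
        m = conf.mask(sel.chain_id, sel.residues)
    else:
        m = conf.mask(residues=sel)
    if not m.any():
        raise LookupError(f"residue set {sel!r} not found in conformer")
    return m


def center_of_mass_distance(conf: Conformer, domain_a, domain_b) -> float:
    """Distance (Å) between the centroids of two residue selections.

    Selections are ResidueSet objects or plain iterables of residue indices
    (matched on any chain).
    """
    ca = conf.centroid(_resolve_set(conf, domain_a))
    cb = conf.centroid(_resolve_set(conf, domain_b))
    return float(np.linalg.norm(ca - cb))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (via random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
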