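"""Cross-linking MS data model and distance-based validation.

Cross-links are identified residue pairs (DSS chemistry: lysine–lysine or
protein N-terminus).  On Cα-coarse models the geometric realization is
the Cα–Cα distance; the default satisfaction cutoff of 30 Å reflects the
DSS spacer (11.4 Å) plus two lysine side chains and backbone flexibility.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CrossLink", "XlParseError", "ConsistencyReport",
           "DEFAULT_DSS_CUTOFF", "xl_distance", "conformer_satisfaction",
           "ensemble_consistency", "read_crosslinks", "write_crosslinks"]

DEFAULT_DSS_CUTOFF = 30.0    # Å, Cα–Cα


class XlParseError(ValueError):
    """Malformed cross-link table row."""


@dataclass(frozen=True)
class CrossLink:
    """One identified residue-pair linkage (unordered pair; canonical order
    is enforced at construction, and self-links are rejected)."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    linker: str = "DSS"
    kind: str = "inter"     # "intra" | "inter"

    def __post_init__(self):
        a = (str(self.protein_a), int(self.residue_a))
        b = (str(self.protein_b), int(self.residue_b))
        if a == b:
            raise ValueError("self cross-link rejected")
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"kind must be intra/inter, got {self.kind!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "protein_a", a[0])
        object.__setattr__(self, "residue_a", a[1])
        object.__setattr__(self, "protein_b", b[0])
        object.__setattr__(self, "residue_b", b[1])

    @classmethod
    def make(cls, protein_a, residue_a, protein_b, residue_b,
             linker: str = "DSS", kind: str = "inter") -> "CrossLink":
        return cls(protein_a, residue_a, protein_b, residue_b, linker, kind)


def _resolve(resolver, protein: str, residue: int) -> tuple[str, int]:
    if resolver is None:
        return protein, residue
    return resolver(protein, residue)


def xl_distance(conf, xl: CrossLink, resolver=None) -> float:
    """Cα–Cα distance (Å) of a cross-link on a conformer.

    ``resolver`` maps (protein, residue-in-data-numbering) to
    (chain_id, residue_index) of the conformer; by default protein names
    are chain ids and numbering is shared.
    """
    pts = []
    for prot, resi in ((xl.protein_a, xl.residue_a), (xl.protein_b, xl.residue_b)):
        chain, ri = _resolve(resolver, prot, resi)
        m = conf.mask(chain, [ri]) & (conf.atom_names == "CA")
        if not m.any():
            m = conf.mask(chain, [ri])
        if not m.any():
            raise LookupError(f"residue {prot}:{resi} (chain {chain} {ri}) "
                              "not found in conformer")
        pts.append(conf.coords[m][0])
    return float(np.linalg.norm(pts[0] - pts[1]))


def conformer_satisfaction(conf, xls, cutoff: float = DEFAULT_DSS_CUTOFF,
                           resolver=None) -> tuple[list[CrossLink], int]:
    """Subset of cross-links satisfied (distance ≤ cutoff) on one conformer."""
    if cutoff <= 0 and cutoff != 0:
        raise ValueError("cutoff must be positive")
    satisfied = [xl for xl in xls
                 if xl_distance(conf, xl, resolver=resolver) <= cutoff]
    return satisfied, len(satisfied)


@dataclass
class ConsistencyReport:
    flags: np.ndarray            # per-XL: satisfied by >=1 support member
    n_consistent: int
    n_total: int
    mean_per_member: float       # weighted mean satisfied count per member

    @property
    def fraction(self) -> float:
        return self.n_consistent / self.n_total if self.n_total else 1.0


def ensemble_consistency(sol, pool, xls, cutoff: float = DEFAULT_DSS_CUTOFF,
                         resolver=None) -> ConsistencyReport:
    """Ensemble-level cross-link consistency.

    A cross-link is consistent iff at least one support member (weight > 0)
    satisfies it; the ensemble as a whole may thus satisfy restraints that
    no single conformer does.
    """
    support = [int(i) for i, w in zip(sol.member_indices, sol.weights) if w > 0]
    if not support:
        raise ValueError("ensemble support is empty")
    xls = list(xls)
    sat = np.zeros((len(support), len(xls)), dtype=bool)
    for i, idx in enumerate(support):
        for j, xl in enumerate(xls):
            sat[i, j] = xl_distance(pool[idx], xl, resolver=resolver) <= cutoff
    flags = sat.any(axis=0)
    wsup = np.array([w for w in sol.weights if w > 0])
    mean_per_member = float((wsup / wsup.sum()) @ sat.sum(axis=1)) if len(xls) else 0.0
    return ConsistencyReport(flags=flags, n_consistent=int(flags.sum()),
                             n_total=len(xls), mean_per_member=mean_per_member)


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["protein_a", "residue_a", "protein_b", "residue_b", "linker", "kind"]


def read_crosslinks(path: str | Path, sequences=None) -> list[CrossLink]:
    """Read a cross-link CSV (header: protein_a,residue_a,protein_b,
    residue_b,linker,kind).  Duplicate unordered pairs are collapsed with a
    warning.  With ``sequences`` (protein -> one-letter string), linked
    residues must be lysines or the protein N-terminus."""
    links: list[CrossLink] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise XlParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                xl = CrossLink.make(row["protein_a"], int(row["residue_a"]),
                                    row["protein_b"], int(row["residue_b"]),
                                    row["linker"].strip() or "DSS",
                                    row["kind"].strip())
            except (ValueError, KeyError, TypeError) as exc:
                raise XlParseError(f"{path}:{lineno}: {exc}") from exc
            key = (xl.protein_a, xl.residue_a, xl.protein_b, xl.residue_b)
            if key in seen:
                warnings.warn(f"{path}:{lineno}: duplicate cross-link "
                              f"{key}; collapsed", stacklevel=2)
                continue
            if sequences is not None:
                for prot, resi in ((xl.protein_a, xl.residue_a),
                                   (xl.protein_b, xl.residue_b)):
                    seq = sequences.get(prot)
                    if seq is None:
                        continue
                    if resi != 1 and (resi > len(seq) or seq[resi - 1] != "K"):
                        raise XlParseError(
                            f"{path}:{lineno}: residue {prot}:{resi} is not a "
                            "lysine or N-terminus in the provided sequence")
            seen.add(key)
            links.append(xl)
    return links


def write_crosslinks(xls, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for xl in xls:
            writer.writerow([xl.protein_a, xl.residue_a, xl.protein_b,
                             xl.residue_b, xl.linker, xl.kind])


def arc_map_table(xls, offsets=None):
    """Arc-diagram data (sequence mapping of intra/inter links): rows of
    (position_a, position_b, kind) with optional per-protein offsets."""
    offsets = offsets or {}
    return [(xl.residue_a + offsets.get(xl.protein_a, 0),
             xl.residue_b + offsets.get(xl.protein_b, 0), xl.kind)
            for xl in xls]
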