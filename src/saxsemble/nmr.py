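"""Chemical shift perturbation (CSP) analysis of ¹H-¹⁵N titrations.

The weighted amide displacement is Δppm = sqrt(ΔδH² + (ΔδN/5)²): the
nitrogen axis is compressed by 1/5 to put both nuclei on a comparable ppm
scale.  Interfaces are mapped by thresholding Δppm between the free and
ligand-bound (or end-point) spectra.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PeakList", "CspTable", "compute_csp", "select_perturbed",
           "track_titration", "weighted_csp"]

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]{0,3}?)(\d+)(?:N)?(?:[-–]?H.*)?$")


def weighted_csp(delta_h, delta_n):
    """Δppm = sqrt(ΔδH² + (ΔδN/5)²)."""
    return np.sqrt(np.asarray(delta_h, dtype=float) ** 2
                   + (np.asarray(delta_n, dtype=float) / 5.0) ** 2)


@dataclass
class PeakList:
    """Assigned amide peaks of one titration point."""

    residue_index: np.ndarray    # (n,) int, unique
    delta_h: np.ndarray          # ppm
    delta_n: np.ndarray          # ppm
    residue_type: np.ndarray | None = None
    label: str = ""
    molar_ratio: float | None = None   # ligand:protein

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.delta_h = np.asarray(self.delta_h, dtype=float)
        self.delta_n = np.asarray(self.delta_n, dtype=float)
        if len(set(self.residue_index.tolist())) != len(self.residue_index):
            raise ValueError("duplicate residue indices in peak list")
        odd_h = (self.delta_h < 5) | (self.delta_h > 12)
        odd_n = (self.delta_n < 100) | (self.delta_n > 140)
        if odd_h.any() or odd_n.any():
            warnings.warn("peaks outside plausible amide ranges "
                          "(δH 5–12, δN 100–140 ppm)", stacklevel=2)

    def __len__(self) -> int:
        return len(self.residue_index)

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {int(r): (float(h), float(n)) for r, h, n in
                zip(self.residue_index, self.delta_h, self.delta_n)}

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None,
                  molar_ratio: float | None = None) -> "PeakList":
        """Read a whitespace-delimited peak list (assignment, δH, δN).

        Assignment strings may be bare residue numbers or Sparky-style
        (e.g. "A123N-H"); '#' starts a comment.
        """
        resi, rtype, dh, dn = [], [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: need assignment, δH, δN")
                m = _ASSIGNMENT_RE.match(parts[0])
                if not m:
                    raise ValueError(f"{path}:{lineno}: cannot parse "
                                     f"assignment {parts[0]!r}")
                rtype.append(m.group(1) or "")
                resi.append(int(m.group(2)))
                dh.append(float(parts[1]))
                dn.append(float(parts[2]))
        return cls(np.array(resi), np.array(dh), np.array(dn),
                   residue_type=np.array(rtype, dtype=object),
                   label=label or Path(path).stem, molar_ratio=molar_ratio)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# assignment  dH[ppm]  dN[ppm]\n")
            types = (self.residue_type if self.residue_type is not None
                     else [""] * len(self))
            for t, r, h, n in zip(types, self.residue_index,
                                  self.delta_h, self.delta_n):
                fh.write(f"{t}{r}N-H  {h:.4f}  {n:.4f}\n")


@dataclass
class CspTable:
    """Per-residue shift differences between two titration points."""

    residue_index: np.ndarray
    d_h: np.ndarray
    d_n: np.ndarray
    dppm: np.ndarray
    unmatched_free: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    unmatched_bound: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def validate(self) -> None:
        if np.any(self.dppm < 0):
            raise ValueError("Δppm must be non-negative")
        zero = (self.d_h == 0) & (self.d_n == 0)
        if np.any((self.dppm == 0) != zero):
            raise ValueError("Δppm is 0 iff both deltas are 0")


def compute_csp(free: PeakList, bound: PeakList) -> CspTable:
    """Weighted CSPs between matched residues of two peak lists.

    Residues are matched by index; residues present in only one list are
    reported as unmatched, not scored.
    """
    fd, bd = free.as_dict(), bound.as_dict()
    common = sorted(set(fd) & set(bd))
    if not common:
        raise ValueError("peak lists share no residues")
    d_h = np.array([bd[r][0] - fd[r][0] for r in common])
    d_n = np.array([bd[r][1] - fd[r][1] for r in common])
    table = CspTable(
        residue_index=np.array(common, dtype=int),
        d_h=d_h, d_n=d_n, dppm=weighted_csp(d_h, d_n),
        unmatched_free=np.array(sorted(set(fd) - set(bd)), dtype=int),
        unmatched_bound=np.array(sorted(set(bd) - set(fd)), dtype=int))
    return table


def select_perturbed(table: CspTable, threshold: float) -> list[int]:
    """Residues with Δppm strictly above the threshold, sorted by Δppm
    descending (the interface candidates)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hit = table.dppm > threshold
    order = np.argsort(-table.dppm[hit])
    return [int(r) for r in table.residue_index[hit][order]]


def track_titration(series: list[PeakList]) -> dict[int, dict]:
    """Per-residue Δppm trajectory across a titration series, relative to
    the first point.  Residues missing at a point leave a NaN gap (no
    interpolation).  Returns {residue: {"ratios": array, "dppm": array}}."""
    if len(series) < 2:
        raise ValueError("need at least two titration points")
    ref = series[0].as_dict()
    ratios = np.array([pl.molar_ratio if pl.molar_ratio is not None else i
                       for i, pl in enumerate(series)], dtype=float)
    out: dict[int, dict] = {}
    for r, (h0, n0) in ref.items():
        traj = np.full(len(series), np.nan)
        for i, pl in enumerate(series):
            d = pl.as_dict().get(r)
            if d is not None:
                traj[i] = weighted_csp(d[0] - h0, d[1] - n0)
        out[r] = {"ratios": ratios, "dppm": traj}
    return out


def nearest_peak_match(free: PeakList, bound: PeakList,
                       gate: float = 0.05) -> CspTable:
    """Assignment-free matching: each free peak is paired with the nearest
    bound peak under the weighted metric, gated at ``gate`` ppm.  An
    extension for unassigned lists; assigned-index matching is the default
    pipeline behaviour."""
    used = set()
    resi, d_h, d_n = [], [], []
    for r, h, n in zip(free.residue_index, free.delta_h, free.delta_n):
        d = weighted_csp(bound.delta_h - h, bound.delta_n - n)
        for j in np.argsort(d):
            if j in used:
                continue
            if d[j] > gate:
                break
            used.add(int(j))
            resi.append(int(r))
            d_h.append(float(bound.delta_h[j] - h))
            d_n.append(float(bound.delta_n[j] - n))
            break
    d_h, d_n = np.array(d_h), np.array(d_n)
    return CspTable(residue_index=np.array(resi, dtype=int), d_h=d_h, d_n=d_n,
                    dppm=weighted_csp(d_h, d_n))
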