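"""Sparse ensemble selection (SES) and ensemble descriptors.

Given a pool of theoretical profiles and an experimental curve, selects a
small set of conformers and non-negative, sum-to-one weights so the
weighted average profile fits the data.  The selector is a greedy
matching-pursuit: at each step the candidate whose inclusion most lowers
χ (after re-solving the non-negative least-squares weights on the current
support) is added, with multiple restarts and randomized tie-breaking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .saxscalc import SaxsProfile
from .structmodel import center_of_mass_distance

__all__ = ["EnsembleSolution", "RgDistribution", "ses_select",
           "brute_force_select", "ensemble_average_profile",
           "rg_distribution", "compact_fraction"]


@dataclass
class EnsembleSolution:
    """Indices + non-negative weights over a conformer pool."""

    member_indices: np.ndarray    # (K,) indices into the pool
    weights: np.ndarray           # (K,) non-negative, sum to 1
    chi: float
    rg_hist: "RgDistribution | None" = None

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def K(self) -> int:
        return int(np.count_nonzero(self.weights > 0))

    def validate(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("negative ensemble weight")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")
        if self.chi < 0:
            raise ValueError("chi must be non-negative")

    def weight_of(self, pool_index: int) -> float:
        hit = np.nonzero(self.member_indices == pool_index)[0]
        return float(self.weights[hit[0]]) if len(hit) else 0.0


@dataclass
class RgDistribution:
    counts: np.ndarray      # weighted histogram, unit mass
    edges: np.ndarray
    mode: float             # center of the most occupied bin

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _as_matrix(profiles, exp: SaxsProfile) -> np.ndarray:
    """Pool profiles as a (n_pool, n_q) matrix on the experimental grid."""
    if isinstance(profiles, np.ndarray):
        if profiles.shape[1] != len(exp.q):
            raise ValueError("profile matrix not aligned to the data grid")
        return profiles
    return np.array([np.interp(exp.q, p.q, p.I) for p in profiles])


def _support_chi(A_w: np.ndarray, b_w: np.ndarray, support, n_q: int):
    """NNLS weights and reduced χ for a candidate support.

    The overall intensity scale is free (absorbed into the unnormalized
    NNLS solution), matching SAXS practice.
    """
    M = A_w[list(support)].T
    w, rnorm = nnls(M, b_w)
    if w.sum() <= 0:
        return None, np.inf
    chi = rnorm / np.sqrt(n_q)
    return w, chi


def ses_select(profiles, exp: SaxsProfile, k_max: int = 20,
               n_restarts: int = 2, seed: int = 0,
               tol: float = 0.01, beam_width: int = 8) -> EnsembleSolution:
    """Sparse ensemble selection by beam-search matching pursuit.

    A beam of the ``beam_width`` best supports is kept; at each step every
    beam support is extended by every pool member, the non-negative
    weighted least squares re-solved, and the best extensions retained.
    The search stops when the best χ improves by less than ``tol`` or
    supports reach ``k_max``.  ``n_restarts`` repeats the search with a
    different randomized candidate order (which breaks exact χ ties);
    deterministic given ``seed``.
    """
    A = _as_matrix(profiles, exp)
    n_pool, n_q = A.shape
    if n_pool < 1:
        raise ValueError("empty pool")
    sigma = exp.sigma if exp.sigma is not None else np.ones_like(exp.I)
    A_w = A / sigma
    b_w = exp.I / sigma
    rng = np.random.default_rng(seed)

    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        order = [int(c) for c in rng.permutation(n_pool)]
        singles = []
        for c in order:
            w, chi = _support_chi(A_w, b_w, (c,), n_q)
            if w is not None:
                singles.append((chi, (c,), w))
        if not singles:
            continue
        singles.sort(key=lambda t: t[0])
        beam = singles[:beam_width]
        incumbent = beam[0]
        while len(incumbent[1]) < min(k_max, n_pool) and incumbent[0] > tol * 1e-6:
            seen = {sup for _, sup, _ in beam}
            extensions = []
            for _, sup, _ in beam:
                for c in order:
                    if c in sup:
                        continue
                    new = tuple(sorted(sup + (c,)))
                    if new in seen:
                        continue
                    seen.add(new)
                    w, chi = _support_chi(A_w, b_w, new, n_q)
                    if w is not None:
                        extensions.append((chi, new, w))
            if not extensions:
                break
            extensions.sort(key=lambda t: t[0])
            if incumbent[0] - extensions[0][0] < tol:
                break
            beam = extensions[:beam_width]
            incumbent = beam[0]
        if best is None or incumbent[0] < best[0]:
            best = incumbent

    if best is None:
        # no candidate gave a solvable fit; fall back to best single member
        warnings.warn("no candidate improved the fit; returning the best "
                      "single-member solution", stacklevel=2)
        chis = [_support_chi(A_w, b_w, [i], n_q)[1] for i in range(n_pool)]
        i = int(np.argmin(chis))
        return EnsembleSolution(np.array([i]), np.array([1.0]), float(chis[i]))

    chi, support, w = best
    keep = w > 0
    idx = np.asarray(support)[keep]
    weights = w[keep] / w[keep].sum()
    order = np.argsort(-weights)
    sol = EnsembleSolution(idx[order], weights[order], float(chi))
    sol.validate()
    return sol


def brute_force_select(profiles, exp: SaxsProfile, k_max: int = 3) -> EnsembleSolution:
    """Exhaustive search over all supports of size ≤ k_max (small pools
    only); the oracle counterpart of ses_select."""
    A = _as_matrix(profiles, exp)
    n_pool, n_q = A.shape
    sigma = exp.sigma if exp.sigma is not None else np.ones_like(exp.I)
    A_w, b_w = A / sigma, exp.I / sigma
    best = None
    for k in range(1, k_max + 1):
        for support in itertools.combinations(range(n_pool), k):
            w, chi = _support_chi(A_w, b_w, list(support), n_q)
            if w is None:
                continue
            if best is None or chi < best[0]:
                best = (chi, support, w)
    chi, support, w = best
    keep = w > 0
    idx = np.asarray(support)[keep]
    weights = w[keep] / w[keep].sum()
    return EnsembleSolution(idx, weights, float(chi))


def ensemble_average_profile(sol: EnsembleSolution, profiles,
                             q=None, label: str = "ensemble") -> SaxsProfile:
    """Pointwise weighted mean of the member profiles."""
    if isinstance(profiles, np.ndarray):
        if q is None:
            raise ValueError("q grid required with a profile matrix")
        I = sol.weights @ profiles[sol.member_indices]
        return SaxsProfile(np.asarray(q, dtype=float), I, label=label)
    q0 = profiles[sol.member_indices[0]].q
    I = sum(w * profiles[i].I for w, i in zip(sol.weights, sol.member_indices))
    return SaxsProfile(q0, I, label=label)


def rg_distribution(sol: EnsembleSolution, pool_rgs, bins=30) -> RgDistribution:
    """Weighted histogram of member Rg values; mode = most occupied bin."""
    pool_rgs = np.asarray(pool_rgs, dtype=float)
    rgs = pool_rgs[sol.member_indices]
    counts, edges = np.histogram(rgs, bins=bins, weights=sol.weights)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    return RgDistribution(counts=counts, edges=edges, mode=float(mode))


def compact_fraction(sol: EnsembleSolution, pool, domain_a, domain_b,
                     cutoff: float) -> float:
    """Weighted fraction of ensemble members whose interdomain centroid
    distance (domain_a vs domain_b) is ≤ cutoff Å."""
    frac = 0.0
    for w, i in zip(sol.weights, sol.member_indices):
        d = center_of_mass_distance(pool[i], domain_a, domain_b)
        if d <= cutoff:
            frac += w
    return float(frac)
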