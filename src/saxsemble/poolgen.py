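"""Conformer-pool generation.

Rigid domains keep their source geometry exactly (rigid-body transforms
only); tethered domains move as one body in their shared crystal frame.
Flexible segments are grown as self-avoiding Cα chains with a fixed
bond length.  Pools are fully reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structmodel import (ComplexTopology, Conformer, FlexibleSegment,
                          RigidDomain, random_rotation)

__all__ = ["PoolConfig", "SamplingError", "sample_pool", "apply_xl_bias",
           "XlBiasResult"]


class SamplingError(RuntimeError):
    """Chain growth failed after the configured number of regrow attempts."""


@dataclass
class PoolConfig:
    """Parameters of pool sampling.

    bond_length is the consecutive Cα–Cα distance (3.8 Å, trans peptide);
    clash_distance the minimum allowed distance between non-bonded beads.
    """

    n_models: int = 100
    seed: int = 0
    bond_length: float = 3.8
    clash_distance: float = 4.0
    max_regrow_attempts: int = 100
    bead_max_tries: int = 50
    closure_tolerance: float = 0.5
    xl_restraints: list | None = None   # [(CrossLink, max_distance_Å), ...]

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not self.clash_distance < 2 * self.bond_length:
            raise ValueError("clash_distance must be < 2 * bond_length")


# ---------------------------------------------------------------------------
# internal assembly state for one model


class _Assembly:
    """Bead positions being assembled for one model.

    Beads are keyed by (chain_id, residue_index).  Clash checks exclude
    chain-bonded neighbours (|Δresi| == 1 on the same chain); all checks
    are vectorized over the placed beads.
    """

    def __init__(self, clash_distance: float, chain_codes: dict[str, int]):
        self.clash = clash_distance
        self.codes = chain_codes
        self.keys: list[tuple[str, int]] = []
        self.index: dict[tuple[str, int], int] = {}
        self._xyz = np.empty((256, 3))
        self._chain = np.empty(256, dtype=int)
        self._resi = np.empty(256, dtype=int)
        self.n = 0

    def _ensure(self, extra: int) -> None:
        while self.n + extra > len(self._xyz):
            self._xyz = np.vstack([self._xyz, np.empty_like(self._xyz)])
            self._chain = np.concatenate([self._chain, np.empty_like(self._chain)])
            self._resi = np.concatenate([self._resi, np.empty_like(self._resi)])

    def add(self, key: tuple[str, int], p) -> None:
        self._ensure(1)
        self.index[key] = self.n
        self.keys.append(key)
        self._xyz[self.n] = p
        self._chain[self.n] = self.codes[key[0]]
        self._resi[self.n] = key[1]
        self.n += 1

    def remove_last(self, count: int) -> None:
        for _ in range(count):
            self.n -= 1
            del self.index[self.keys.pop()]

    def pos_of(self, key: tuple[str, int]) -> np.ndarray:
        return self._xyz[self.index[key]].copy()

    def coords(self) -> np.ndarray:
        return self._xyz[:self.n]

    def clashes(self, key: tuple[str, int], p) -> bool:
        if self.n == 0:
            return False
        d2 = ((self._xyz[:self.n] - p) ** 2).sum(axis=1)
        bonded = ((self._chain[:self.n] == self.codes[key[0]])
                  & (np.abs(self._resi[:self.n] - key[1]) == 1))
        return bool((d2[~bonded] < self.clash ** 2).any())

    def group_clashes(self, keys: list[tuple[str, int]], pts: np.ndarray) -> bool:
        """Clash check for a rigid body against already-placed beads
        (internal contacts of the body are exempt)."""
        if self.n == 0:
            return False
        chain = np.array([self.codes[c] for c, _ in keys])
        resi = np.array([r for _, r in keys])
        d2 = ((pts[:, None, :] - self._xyz[None, :self.n, :]) ** 2).sum(axis=2)
        bonded = ((chain[:, None] == self._chain[None, :self.n])
                  & (np.abs(resi[:, None] - self._resi[None, :self.n]) == 1))
        d2[bonded] = np.inf
        return bool((d2 < self.clash ** 2).any())


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _biased_unit(rng: np.random.Generator, toward: np.ndarray,
                 strength: float) -> np.ndarray:
    """Random unit vector with a bias toward ``toward``; strength 0 is
    uniform, large strength is nearly deterministic."""
    v = rng.normal(size=3) + strength * toward
    return v / np.linalg.norm(v)


def _rigid_groups(topology: ComplexTopology) -> list[list[RigidDomain]]:
    """Union of domains over tethers; each group moves as one rigid body."""
    parent = {d.name: d.name for d in topology.rigid_domains}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in topology.tethers:
        parent[find(t.domain_a)] = find(t.domain_b)
    groups: dict[str, list[RigidDomain]] = {}
    for d in topology.rigid_domains:
        groups.setdefault(find(d.name), []).append(d)
    return list(groups.values())


def _group_records(group: list[RigidDomain]):
    """(keys, names, coords) of all beads of a rigid group in its source frame."""
    keys, names, xyz = [], [], []
    for d in group:
        m = d.source_mask()
        src = d.source
        for c, r, n, p in zip(src.chain_ids[m], src.residue_indices[m],
                              src.residue_names[m], src.coords[m]):
            keys.append((str(c), int(r)))
            names.append(str(n))
            xyz.append(p)
    return keys, names, np.array(xyz)


def sample_pool(topology: ComplexTopology, cfg: PoolConfig) -> list[Conformer]:
    """Sample cfg.n_models conformers of the topology.

    Each model satisfies: rigid-domain internal geometry identical to the
    source (rigid-body transform only), tether constraints exact,
    consecutive flexible beads at bond_length, no non-bonded pair closer
    than clash_distance.  Deterministic given cfg.seed.
    """
    topology.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = _rigid_groups(topology)
    dom2group = {d.name: gi for gi, g in enumerate(groups) for d in g}
    res2name = {}
    for seg in topology.flexible_segments:
        for r in seg.residues:
            res2name[(seg.chain_id, r)] = seg.name_of(r)

    models = []
    for imodel in range(cfg.n_models):
        models.append(_sample_one(topology, cfg, rng, groups, dom2group,
                                  res2name, f"model_{imodel:05d}"))
    return models


def _sample_one(topology, cfg, rng, groups, dom2group, res2name,
                model_id) -> Conformer:
    asm = _Assembly(cfg.clash_distance,
                    {c: i for i, c in enumerate(topology.chains)})
    placed_groups: set[int] = set()

    def place_group(gi: int, rotation, translation) -> list[tuple[str, int]]:
        keys, names, xyz = _group_records(groups[gi])
        pts = xyz @ rotation.T + translation
        for key, p in zip(keys, pts):
            asm.add(key, p)
        placed_groups.add(gi)
        return keys

    pending = list(topology.flexible_segments)
    if topology.rigid_domains:
        # root group: the one containing the first domain of the first chain
        first = min(topology.rigid_domains,
                    key=lambda d: (topology.chains.index(d.chain_id), d.start))
        place_group(dom2group[first.name], np.eye(3), np.zeros(3))
    else:
        # purely flexible construct: seed each segment at a well-separated
        # origin and grow the rest as a free self-avoiding chain
        for i, seg in enumerate(list(pending)):
            _grow_unanchored(seg, asm, cfg, rng,
                             origin=np.array([300.0 * i, 0.0, 0.0]))
            pending.remove(seg)
    for _ in range(len(pending) + len(groups) + 2):
        progressed = False
        for seg in list(pending):
            left = (seg.chain_id, seg.start - 1)
            right = (seg.chain_id, seg.end + 1)
            left_ok = left in asm.index
            right_ok = right in asm.index
            if not (left_ok or right_ok):
                continue
            _grow_segment(seg, asm, cfg, rng, topology, groups, dom2group,
                          placed_groups, place_group, left_ok, right_ok)
            pending.remove(seg)
            progressed = True
        if not pending and len(placed_groups) == len(groups):
            break
        if not progressed:
            raise SamplingError(
                "topology is not connected: cannot reach segments "
                f"{[(s.chain_id, s.start, s.end) for s in pending]}")

    # assemble the conformer, sorted by chain then residue
    order = sorted(range(len(asm.keys)),
                   key=lambda i: (topology.chains.index(asm.keys[i][0]),
                                  asm.keys[i][1]))
    chains, resis, resns, xyz = [], [], [], []
    for i in order:
        c, r = asm.keys[i]
        chains.append(c)
        resis.append(r)
        dom = topology.domain_of_residue(c, r)
        if dom is not None:
            d = topology.domain(dom)
            m = d.source.mask(c, [r])
            resns.append(str(d.source.residue_names[m][0]))
        else:
            resns.append(res2name.get((c, r), "GLY"))
        xyz.append(asm.coords()[i])
    xyz = np.array(xyz)
    # random global pose
    rot = random_rotation(rng)
    trans = rng.normal(scale=20.0, size=3)
    xyz = xyz @ rot.T + trans
    return Conformer(
        model_id=model_id,
        chain_ids=np.array(chains, dtype=object),
        residue_indices=np.array(resis, dtype=int),
        residue_names=np.array(resns, dtype=object),
        atom_names=np.array(["CA"] * len(resis), dtype=object),
        coords=xyz,
        is_coarse=True,
    )


def _grow_unanchored(seg: FlexibleSegment, asm: _Assembly, cfg: PoolConfig,
                     rng, origin: np.ndarray) -> None:
    """Grow a segment with no rigid anchors: first bead at ``origin``."""
    bl = cfg.bond_length
    for attempt in range(cfg.max_regrow_attempts):
        asm.add((seg.chain_id, seg.start), origin)
        placed = 1
        prev = origin
        ok = True
        for resi in list(seg.residues)[1:]:
            key = (seg.chain_id, resi)
            for _ in range(cfg.bead_max_tries):
                p = prev + bl * _unit(rng)
                if not asm.clashes(key, p):
                    asm.add(key, p)
                    placed += 1
                    prev = p
                    break
            else:
                ok = False
                break
        if ok:
            return
        asm.remove_last(placed)
    raise SamplingError(
        f"failed to grow flexible segment {seg.chain_id}:{seg.start}-{seg.end} "
        f"after {cfg.max_regrow_attempts} regrow attempts")


def _grow_segment(seg: FlexibleSegment, asm: _Assembly, cfg: PoolConfig, rng,
                  topology, groups, dom2group, placed_groups, place_group,
                  left_ok: bool, right_ok: bool) -> None:
    bl = cfg.bond_length
    if left_ok and right_ok:
        _grow_closure(seg, asm, cfg, rng)
        return

    # orient growth so that we always grow away from the placed anchor
    if left_ok:
        residues = list(seg.residues)
        anchor = (seg.chain_id, seg.start - 1)
        far_dom = topology.domain_of_residue(seg.chain_id, seg.end + 1)
    else:
        residues = list(reversed(list(seg.residues)))
        anchor = (seg.chain_id, seg.end + 1)
        far_dom = topology.domain_of_residue(seg.chain_id, seg.start - 1)

    for attempt in range(cfg.max_regrow_attempts):
        placed = 0
        prev = asm.pos_of(anchor)
        ok = True
        for resi in residues:
            key = (seg.chain_id, resi)
            for _ in range(cfg.bead_max_tries):
                p = prev + bl * _unit(rng)
                if not asm.clashes(key, p):
                    asm.add(key, p)
                    placed += 1
                    prev = p
                    break
            else:
                ok = False
                break
        if ok and far_dom is not None and dom2group[far_dom] not in placed_groups:
            ok = _attach_group(far_dom, prev, residues[-1], seg, asm, cfg, rng,
                               topology, groups, dom2group, place_group)
        if ok:
            return
        asm.remove_last(placed)
    raise SamplingError(
        f"failed to grow flexible segment {seg.chain_id}:{seg.start}-{seg.end} "
        f"after {cfg.max_regrow_attempts} regrow attempts")


def _attach_group(dom_name, linker_end, linker_resi, seg, asm, cfg, rng,
                  topology, groups, dom2group, place_group) -> bool:
    """Place an unplaced rigid group so the domain's junction bead sits at
    bond_length from the last linker bead, with a random orientation."""
    dom = topology.domain(dom_name)
    # junction residue of the domain: the one adjacent to the linker
    junction = dom.start if linker_resi < dom.start else dom.end
    gi = dom2group[dom_name]
    keys, _, xyz = _group_records(groups[gi])
    j = keys.index((dom.chain_id, junction))
    for _ in range(cfg.bead_max_tries):
        rot = random_rotation(rng)
        target = linker_end + cfg.bond_length * _unit(rng)
        trans = target - xyz[j] @ rot.T
        pts = xyz @ rot.T + trans
        if not asm.group_clashes(keys, pts):
            place_group(gi, rot, trans)
            return True
    return False


def _grow_closure(seg: FlexibleSegment, asm: _Assembly, cfg: PoolConfig,
                  rng) -> None:
    """Grow a segment whose both anchors are already placed (chain closure).

    Beads are grown from the left anchor with a feasibility bias toward the
    right anchor; the final bead is placed exactly on the circle at
    bond_length from both its neighbours.
    """
    bl = cfg.bond_length
    u0 = asm.pos_of((seg.chain_id, seg.start - 1))
    v0 = asm.pos_of((seg.chain_id, seg.end + 1))
    n = len(seg)
    residues = list(seg.residues)
    for attempt in range(cfg.max_regrow_attempts):
        # grow alternately from both anchors toward each other; the last
        # bead bridges the two half-chains exactly
        left, right = 0, n - 1      # next residue offsets to place
        pl, pr = u0, v0
        placed_keys: list[tuple[str, int]] = []
        ok = True
        while left < right:
            from_left = (left - 0) <= (n - 1 - right)
            key = (seg.chain_id, residues[left if from_left else right])
            prev = pl if from_left else pr
            other = pr if from_left else pl
            remaining = right - left + 1   # bonds between the two ends
            gap = np.linalg.norm(other - prev)
            # bias growth toward the far end as the chain becomes taut,
            # so the closure constraint stays satisfiable
            tau = gap / (remaining * bl)
            strength = 4.0 * tau * tau / max(1.0 - tau, 0.1)
            e = (other - prev) / max(gap, 1e-9)
            accepted = False
            for _ in range(cfg.bead_max_tries):
                p = prev + bl * _biased_unit(rng, e, strength)
                if (np.linalg.norm(p - other)
                        > remaining * bl - cfg.closure_tolerance):
                    continue
                if not asm.clashes(key, p):
                    asm.add(key, p)
                    placed_keys.append(key)
                    accepted = True
                    break
            if not accepted:
                ok = False
                break
            if from_left:
                pl, left = p, left + 1
            else:
                pr, right = p, right - 1
        if ok:
            key = (seg.chain_id, residues[left])
            if _place_bridge_bead(key, pl, pr, asm, cfg, rng):
                return
        asm.remove_last(len(placed_keys))
    raise SamplingError(
        f"failed to close flexible segment {seg.chain_id}:{seg.start}-{seg.end} "
        f"after {cfg.max_regrow_attempts} regrow attempts")


def _place_bridge_bead(key, u, v, asm, cfg, rng) -> bool:
    """Place one bead at distance bond_length from both u and v (sphere-
    sphere intersection circle), clash-checked."""
    bl = cfg.bond_length
    d = np.linalg.norm(v - u)
    if d <= 1e-9 or d > 2 * bl:
        return False
    e = (v - u) / d
    center = u + e * (d / 2)
    rho2 = bl * bl - (d / 2) ** 2
    if rho2 < 0:
        return False
    rho = np.sqrt(rho2)
    a = np.cross(e, [1.0, 0.0, 0.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(e, [0.0, 1.0, 0.0])
    a /= np.linalg.norm(a)
    b = np.cross(e, a)
    for _ in range(cfg.bead_max_tries):
        t = rng.uniform(0, 2 * np.pi)
        p = center + rho * (np.cos(t) * a + np.sin(t) * b)
        if not asm.clashes(key, p):
            asm.add(key, p)
            return True
    return False


# ---------------------------------------------------------------------------
# cross-link biased filtering


@dataclass
class XlBiasResult:
    pool: list[Conformer]
    kept_fraction: float
    per_restraint_rate: np.ndarray   # satisfaction rate over the input pool
    min_satisfied: int


def apply_xl_bias(pool: list[Conformer], restraints,
                  min_satisfied: int = 1, resolver=None) -> XlBiasResult:
    """Rejection-filter a pool on cross-link distance restraints.

    ``restraints`` is a list of (CrossLink, max_distance_Å).  A model is
    retained iff it satisfies at least ``min_satisfied`` restraints.
    """
    from .xlms import xl_distance

    if not restraints:
        return XlBiasResult(list(pool), 1.0, np.empty(0), min_satisfied)
    sat = np.zeros((len(pool), len(restraints)), dtype=bool)
    for i, conf in enumerate(pool):
        for j, (xl, dmax) in enumerate(restraints):
            sat[i, j] = xl_distance(conf, xl, resolver=resolver) <= dmax
    keep = sat.sum(axis=1) >= min_satisfied
    if not keep.any():
        rates = sat.mean(axis=0)
        raise SamplingError(
            "no model satisfies the minimum number of restraints "
            f"({min_satisfied}); per-restraint satisfaction rates: "
            f"{np.array2string(rates, precision=3)}")
    return XlBiasResult([m for m, k in zip(pool, keep) if k],
                        float(keep.mean()), sat.mean(axis=0), min_satisfied)
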