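import numpy as np
import pytest
from scipy.spatial.distance import pdist

from saxsemble.poolgen import (PoolConfig, SamplingError, apply_xl_bias,
                               sample_pool)
from saxsemble.structmodel import (ComplexTopology, FlexibleSegment,
                                   ResidueSet, center_of_mass_distance)
from saxsemble.synthetic import make_toy_complex, toy_resolver
from saxsemble.xlms import CrossLink


def _segment_coords(conf, chain, residues):
    m = conf.mask(chain, residues)
    order = np.argsort(conf.residue_indices[m])
    return conf.coords[m][order]


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PoolConfig(n_models=0)
        with pytest.raises(ValueError):
            PoolConfig(bond_length=-1)
        with pytest.raises(ValueError):
            PoolConfig(bond_length=3.8, clash_distance=8.0)


class TestSampling:
    def test_same_seed_reproduces_pool_bitwise(self, toy):
        topology, _ = toy
        cfg = PoolConfig(n_models=3, seed=7)
        a = sample_pool(topology, cfg)
        b = sample_pool(topology, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)
        c = sample_pool(topology, PoolConfig(n_models=3, seed=8))
        assert not np.allclose(a[0].coords, c[0].coords)

    def test_rigid_domains_keep_internal_geometry_exactly(self, toy, toy_pool):
        topology, sources = toy
        for conf in toy_pool[:5]:
            for dom in topology.rigid_domains:
                model = _segment_coords(conf, dom.chain_id, dom.residues)
                src = _segment_coords(dom.source, dom.chain_id, dom.residues)
                np.testing.assert_allclose(pdist(model), pdist(src), atol=1e-9)

    def test_linker_bonds_and_clashes(self, toy, toy_pool):
        topology, _ = toy
        seg = topology.flexible_segments[0]
        for conf in toy_pool[:5]:
            xyz = _segment_coords(conf, "A",
                                  range(seg.start - 1, seg.end + 2))
            bonds = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            np.testing.assert_allclose(bonds, 3.8, rtol=0.01)
            # no non-bonded pair below the clash distance (rigid-internal
            # contacts exempt)
            resi = np.sort(conf.residue_indices)
            d = pdist(conf.coords[np.argsort(conf.residue_indices)])
            dom_of = np.array([topology.domain_of_residue("A", int(r)) or ""
                               for r in resi], dtype=object)
            n = len(resi)
            iu = np.triu_indices(n, k=1)
            bonded = np.abs(resi[iu[0]] - resi[iu[1]]) == 1
            same_dom = (dom_of[iu[0]] == dom_of[iu[1]]) & (dom_of[iu[0]] != "")
            assert d[~(bonded | same_dom)].min() >= 4.0 - 1e-9

    def test_end_to_end_below_contour_length(self, toy, toy_pool):
        topology, _ = toy
        seg = topology.flexible_segments[0]
        n = seg.end - seg.start + 1
        for conf in toy_pool:
            xyz = _segment_coords(conf, "A", seg.residues)
            assert np.linalg.norm(xyz[-1] - xyz[0]) <= n * 3.8

    def test_single_rigid_domain_models_identical_internally(self):
        topology, _ = make_toy_complex(n_domains=1, seed=5)
        pool = sample_pool(topology, PoolConfig(n_models=4, seed=6))
        ref = pdist(pool[0].coords)
        for conf in pool[1:]:
            np.testing.assert_allclose(pdist(conf.coords), ref, atol=1e-9)
            # but global poses differ
            assert not np.allclose(conf.coords, pool[0].coords)

    def test_tethered_domains_share_fixed_frame(self):
        topology, _ = make_toy_complex(seed=9, tether=True)
        pool = sample_pool(topology, PoolConfig(n_models=6, seed=10))
        d1, d2 = topology.rigid_domains[:2]
        s1 = ResidueSet.from_range("A", d1.start, d1.end)
        s2 = ResidueSet.from_range("A", d2.start, d2.end)
        dists = [center_of_mass_distance(c, s1, s2) for c in pool]
        assert np.std(dists) < 1e-9
        # the closing linker still honors the bond length
        seg = topology.flexible_segments[0]
        xyz = _segment_coords(pool[0], "A", range(seg.start - 1, seg.end + 2))
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(xyz, axis=0), axis=1), 3.8, rtol=0.01)

    def test_infeasible_closure_raises_naming_segment(self):
        topology, _ = make_toy_complex(seed=9, tether=True,
                                       linker_lengths=(4,))
        with pytest.raises(SamplingError, match="A:"):
            sample_pool(topology, PoolConfig(n_models=1, seed=1,
                                             max_regrow_attempts=5))

    def test_self_avoiding_walk_swelling_is_monotone(self):
        means = []
        for n in (10, 20, 40, 80):
            topo = ComplexTopology(chains=["A"], rigid_domains=[],
                                   flexible_segments=[FlexibleSegment("A", 1, n)])
            pool = sample_pool(topo, PoolConfig(n_models=500, seed=42))
            e2 = [np.sum((_segment_coords(c, "A", range(1, n + 1))[-1]
                          - _segment_coords(c, "A", range(1, n + 1))[0]) ** 2)
                  for c in pool]
            means.append(np.mean(e2))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestXlBias:
    def test_empty_restraints_identity(self, toy_pool):
        res = apply_xl_bias(toy_pool, [])
        assert res.pool == list(toy_pool)
        assert res.kept_fraction == 1.0

    def test_vacuous_restraint_keeps_everything(self, toy, toy_pool):
        topology, _ = toy
        xl = CrossLink.make("D1", 5, "D2", topology.rigid_domains[1].start + 5)
        res = apply_xl_bias(toy_pool, [(xl, 1e6)],
                            resolver=toy_resolver(topology))
        assert len(res.pool) == len(toy_pool)
        assert res.per_restraint_rate[0] == 1.0

    def test_median_cutoff_keeps_about_half(self, toy, toy_pool):
        from saxsemble.xlms import xl_distance
        topology, _ = toy
        resolver = toy_resolver(topology)
        xl = CrossLink.make("D1", 5, "D2", topology.rigid_domains[1].start + 5)
        dists = sorted(xl_distance(c, xl, resolver=resolver) for c in toy_pool)
        cutoff = 0.5 * (dists[len(dists) // 2 - 1] + dists[len(dists) // 2])
        res = apply_xl_bias(toy_pool, [(xl, cutoff)], resolver=resolver)
        assert abs(res.kept_fraction - 0.5) <= 1.0 / len(toy_pool)

    def test_unsatisfiable_minimum_raises_with_diagnostics(self, toy, toy_pool):
        topology, _ = toy
        xl = CrossLink.make("D1", 5, "D2", topology.rigid_domains[1].start + 5)
        with pytest.raises(SamplingError, match="satisfaction rates"):
            apply_xl_bias(toy_pool, [(xl, 0.1)],
                          resolver=toy_resolver(topology))
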