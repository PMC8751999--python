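import numpy as np
import pytest

from motiflattice import (FccLattice, IntegrityError, LatticeConfig,
                          MotifSequence, count_bonds, radius_of_gyration,
                          total_energy)

J = 0.05


def test_single_bond_energy(lat4, ab):
    cfg = LatticeConfig.from_polymers(lat4, ab, [[0, 0]], J=J)
    assert total_energy(cfg) == pytest.approx(-1.0)


def test_adjacent_monomers_nonspecific_energy(lat4, ab):
    v = int(lat4.neighbors(0)[0])
    cfg = LatticeConfig.from_polymers(lat4, ab, [[0, v]], J=J)
    assert total_energy(cfg) == pytest.approx(-J)


def test_bonded_pair_next_to_lone_monomer(lat6):
    # an A.B bonded site (r=2) adjacent to a lone monomer (r=1): -1 - 2J
    u = int(lat6.ravel(2, 2, 2))
    v = int(lat6.neighbors(u)[3])
    # chain ABA: the A,B pair contracted on u, the third monomer on v
    cfg = LatticeConfig.from_polymers(lat6, MotifSequence("ABA"),
                                      [[u, u, v]], J=J)
    assert total_energy(cfg) == pytest.approx(-1.0 - 2 * J)


def test_forbidden_overlaps_rejected(lat4):
    aa = MotifSequence("AA")
    with pytest.raises(IntegrityError):
        LatticeConfig.from_polymers(lat4, aa, [[0, 0]])
    ab = MotifSequence("AB")
    cfg = LatticeConfig(lat4, ab, J=J)
    cfg.add_polymer([0, 0])  # site 0 now holds A and B
    with pytest.raises(IntegrityError):
        cfg.add_polymer([0, int(lat4.neighbors(0)[0])])  # third on site 0


def test_disconnected_chain_rejected(lat6):
    ab = MotifSequence("AB")
    far = int(lat6.ravel(3, 3, 3))
    with pytest.raises(IntegrityError):
        LatticeConfig.from_polymers(lat6, ab, [[0, far]])


def test_count_bonds_classification(lat6):
    seq = MotifSequence("AB")
    u = int(lat6.ravel(1, 1, 1))
    v = int(lat6.neighbors(u)[0])
    x = int(lat6.neighbors(u)[5])
    # hairpin: one polymer bonded with itself on one site
    cfg = LatticeConfig.from_polymers(lat6, seq, [[u, u]])
    s, t = count_bonds(cfg)
    assert list(s) == [1] and t == 0
    # two polymers sharing one A-B site: A of chain 1 with B of chain 2
    cfg2 = LatticeConfig.from_polymers(lat6, seq, [[u, v], [x, u]])
    s, t = count_bonds(cfg2)
    assert list(s) == [0, 0] and t == 1
    # classification is a partition of bonded sites
    assert s.sum() + t == cfg2.Q


def test_energy_cache_matches_recompute_on_random_config(lat6, rng):
    seq = MotifSequence("ABAB")
    cfg = LatticeConfig(lat6, seq, J=J)
    placed = 0
    while placed < 6:
        head = int(rng.integers(lat6.V))
        sites = [head]
        ok = True
        for k in range(1, 4):
            opts = list(lat6.neighbors(sites[-1])) + [sites[-1]]
            site = int(opts[rng.integers(len(opts))])
            sites.append(site)
        try:
            cfg.add_polymer(sites)
            placed += 1
        except IntegrityError:
            continue
    assert total_energy(cfg) == pytest.approx(cfg.energy)
    s, t = count_bonds(cfg)
    assert s.sum() + t == cfg.Q
    assert 0 <= cfg.phi <= 2


def test_radius_of_gyration_geometry(lat6):
    u = int(lat6.ravel(2, 2, 2))
    assert radius_of_gyration([u, u], lat6) == 0.0
    v = int(lat6.neighbors(u)[0])
    assert radius_of_gyration([u, v], lat6) == pytest.approx(0.5)
    # straight trimer with spacing d=1: Rg = sqrt(2/3)
    i, j, k = 2, 2, 2
    s0 = int(lat6.ravel(i, j, k))
    s1 = int(lat6.ravel(i + 1, j, k))
    s2 = int(lat6.ravel(i + 2, j, k))
    assert radius_of_gyration([s0, s1, s2], lat6) == pytest.approx(
        np.sqrt(2.0 / 3.0))


def test_rg_unwraps_periodic_images():
    lat = FccLattice((6, 6, 6))
    # straight dimer across the periodic boundary
    s0 = int(lat.ravel(5, 2, 2))
    s1 = int(lat.ravel(0, 2, 2))
    assert radius_of_gyration([s0, s1], lat) == pytest.approx(0.5)


def test_snapshot_roundtrip(tmp_path, lat4, ab):
    from motiflattice.state import read_snapshots, write_snapshot
    cfg = LatticeConfig.from_polymers(lat4, ab, [[0, 0]])
    path = tmp_path / "snap.jsonl"
    with open(path, "w") as fh:
        write_snapshot(fh, 42, cfg)
    rec = next(read_snapshots(path))
    assert rec["step"] == 42 and rec["N"] == 1
    assert rec["polymers"] == [[0, 0]]
    assert rec["E"] == pytest.approx(cfg.energy)
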