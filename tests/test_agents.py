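import numpy as np
import pytest

from osteovox import agents, rdd
from osteovox.agents import (HSC, IMMUNE, LINING, OBL, OCL, OCY, PREOCY, SSPC,
                             AgentPopulation, Environment, RANK, TGFBR1, LRP56)
from osteovox.config import CellConfig, ProductionConfig, RDDConfig
from osteovox.geometry import EMPTY, SimulationLattice


def make_env(lattice, sed=0.0, eff=0.0, cytokines=None):
    return Environment(
        sed=np.full(lattice.dims, sed),
        eff=np.full(lattice.dims, eff),
        cytokines=cytokines or rdd.CytokineState.create(lattice, RDDConfig()),
    )


def flat(lattice, i, j, k):
    ny, nz = lattice.dims[1], lattice.dims[2]
    return (i * ny + j) * nz + k


class TestMigration:
    def test_mean_path_speed_is_31_5_um_per_h(self, rng):
        """At move-probability 1 a free random walk advances one 10.5-um step
        per 20-min update: mean path speed 31.5 um/h."""
        lat = SimulationLattice.empty((30, 30, 30))
        pop = AgentPopulation.create(lat)
        start = flat(lat, 15, 15, 15)
        pop.add(SSPC, [start])
        env = make_env(lat)
        cfg = CellConfig()
        path = 0.0
        prev = pop.pos[0]
        n_steps = 120
        for _ in range(n_steps):
            agents.migrate(pop, lat, env, rng, cfg)
            if pop.pos[0] != prev:
                path += 10.5
            prev = pop.pos[0]
        hours = n_steps * cfg.dt_h
        assert path / hours == pytest.approx(31.5, rel=1e-9)

    def test_obl_never_swaps_with_ocl(self, rng):
        lat = SimulationLattice.empty((3, 3, 3))
        pop = AgentPopulation.create(lat)
        # fill every voxel except the OBL/OCL pair with immobile osteocytes?
        # simpler: 1D corridor - OBL at one end, OCL adjacent, walls elsewhere
        lat.mineral[:] = 720.0
        lat.mineral[1, 1, :2] = 0.0  # two-voxel soft corridor
        a = pop.add(OBL, [flat(lat, 1, 1, 0)])[0]
        b = pop.add(OCL, [flat(lat, 1, 1, 1)])[0]
        env = make_env(lat)
        for _ in range(50):
            agents.migrate(pop, lat, env, rng, CellConfig(ocl_bias_probability=0,
                                                          obl_bias_probability=0))
            # the only admissible move for either cell is an OBL<->OCL swap,
            # which is forbidden: both must stay put
            assert pop.pos[a] == flat(lat, 1, 1, 0)
            assert pop.pos[b] == flat(lat, 1, 1, 1)

    def test_agent_walled_in_by_mineral_never_moves(self, rng):
        lat = SimulationLattice.empty((3, 3, 3))
        lat.mineral[:] = 720.0
        lat.mineral[1, 1, 1] = 0.0
        pop = AgentPopulation.create(lat)
        pop.add(SSPC, [flat(lat, 1, 1, 1)])
        env = make_env(lat)
        for _ in range(30):
            agents.migrate(pop, lat, env, rng, CellConfig())
        assert pop.pos[0] == flat(lat, 1, 1, 1)
        pop.check_invariants()

    def test_swap_with_mobile_resident(self, rng):
        lat = SimulationLattice.empty((3, 3, 3))
        lat.mineral[:] = 720.0
        lat.mineral[1, 1, :2] = 0.0  # two-voxel corridor
        pop = AgentPopulation.create(lat)
        a = pop.add(SSPC, [flat(lat, 1, 1, 0)])[0]
        b = pop.add(HSC, [flat(lat, 1, 1, 1)])[0]
        env = make_env(lat)
        p0 = (pop.pos[a], pop.pos[b])
        agents.migrate(pop, lat, env, rng, CellConfig())
        # both voxels still occupied by exactly these two agents
        pop.check_invariants()
        assert {pop.pos[a], pop.pos[b]} == set(p0)


class TestDifferentiation:
    def _pop_one(self, lat, cell_type, voxel):
        pop = AgentPopulation.create(lat)
        row = pop.add(cell_type, [voxel])[0]
        return pop, row

    def test_sspc_becomes_obl_in_osteogenic_oxygenated_niche(self, soft_lattice, rng):
        pop, r = self._pop_one(soft_lattice, SSPC, 7)
        pop.o2_ok[r] = True
        pop.recept[r, TGFBR1] = 0.5
        env = make_env(soft_lattice, eff=0.01)
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == OBL

    def test_sspc_below_threshold_stays(self, soft_lattice, rng):
        pop, r = self._pop_one(soft_lattice, SSPC, 7)
        pop.o2_ok[r] = True
        pop.recept[r, TGFBR1] = 0.5
        env = make_env(soft_lattice, eff=0.005)
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == SSPC

    def test_hypoxic_immune_with_rank_over_half_becomes_ocl(self, soft_lattice, rng):
        pop, r = self._pop_one(soft_lattice, IMMUNE, 7)
        pop.o2_ok[r] = False
        pop.recept[r, RANK] = 0.6
        env = make_env(soft_lattice, eff=0.01)
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == OCL

    def test_hypoxic_hsc_cannot_become_ocl(self, soft_lattice, rng):
        pop, r = self._pop_one(soft_lattice, HSC, 7)
        pop.o2_ok[r] = False
        pop.recept[r, RANK] = 0.9
        env = make_env(soft_lattice)
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == HSC

    def test_sclerostin_blocks_lining_to_obl(self, soft_lattice, rng):
        pop, r = self._pop_one(soft_lattice, LINING, 7)
        pop.recept[r, LRP56] = 0.9
        env = make_env(soft_lattice, eff=0.01)
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == LINING
        pop.recept[r, LRP56] = 0.1
        agents.differentiate(pop, soft_lattice, env, rng, CellConfig())
        assert pop.type[r] == OBL

    def test_obl_in_mineralising_voxel_embeds_to_preocy(self, rng):
        lat = SimulationLattice.empty((9, 9, 9))
        # a mineralising front: enough local bone to support an osteocyte
        lat.mineral[2:7, 2:7, 2:7] = 400.0
        pop, r = self._pop_one(lat, OBL, flat(lat, 4, 4, 4))
        env = make_env(lat, eff=0.01)
        cfg = CellConfig(embedding_probability=1.0)
        agents.differentiate(pop, lat, env, rng, cfg)
        assert pop.type[r] == PREOCY

    def test_obl_embedding_blocked_at_target_osteocyte_density(self, rng):
        lat = SimulationLattice.empty((9, 9, 9))
        lat.mineral[2:7, 2:7, 2:7] = 400.0
        pop = agents.AgentPopulation.create(lat)
        # saturate the neighbourhood with osteocytes, then test a fresh OBL
        occupied = [flat(lat, i, j, k) for i in (3, 5) for j in (3, 5)
                    for k in (3, 5)]
        pop.add(agents.OCY, occupied)
        r = pop.add(OBL, [flat(lat, 4, 4, 4)])[0]
        lat.mineral[4, 4, 4] = 400.0
        env = make_env(lat, eff=0.01)
        cfg = CellConfig(embedding_probability=1.0)
        agents.differentiate(pop, lat, env, rng, cfg)
        assert pop.type[r] != PREOCY

    def test_preocy_matures_to_ocy_after_maturation_time(self, rng):
        lat = SimulationLattice.empty((5, 5, 5))
        lat.mineral[2, 2, 2] = 500.0
        pop, r = self._pop_one(lat, PREOCY, flat(lat, 2, 2, 2))
        env = make_env(lat)
        cfg = CellConfig(maturation_h=10.0)
        for _ in range(int(10.0 / cfg.dt_h) + 1):
            agents.differentiate(pop, lat, env, rng, cfg)
        assert pop.type[r] == OCY


class TestPopulationDynamics:
    def test_no_free_neighbour_blocks_division(self, rng):
        lat = SimulationLattice.empty((3, 3, 3))
        lat.mineral[:] = 720.0
        lat.mineral[1, 1, 1] = 0.0
        pop = AgentPopulation.create(lat)
        r = pop.add(SSPC, [flat(lat, 1, 1, 1)])[0]
        pop.o2_ok[r] = True
        env = make_env(lat, eff=0.01)
        cfg = CellConfig(proliferation_per_h=1e9, apoptosis_per_h={})
        flows = agents.proliferate_or_die(pop, lat, env, rng, cfg)
        assert flows["births"] == 0

    def test_osteocytes_never_divide_nor_die_spontaneously(self, rng):
        lat = SimulationLattice.empty((5, 5, 5))
        lat.mineral[:] = 500.0
        pop = AgentPopulation.create(lat)
        pop.add(OCY, [flat(lat, 2, 2, 2)])
        env = make_env(lat)
        cfg = CellConfig(proliferation_per_h=1e9,
                         apoptosis_per_h={t: 1e9 for t in agents.TYPE_NAMES})
        for _ in range(20):
            agents.proliferate_or_die(pop, lat, env, rng, cfg)
        assert pop.n_alive == 1
        assert pop.counts()["OCY"] == 1

    def test_isolated_obl_cohort_decays_exponentially(self):
        """Population decay matches exp(-rate*t) within sampling error."""
        lat = SimulationLattice.empty((40, 40, 10))
        pop = AgentPopulation.create(lat)
        free = np.flatnonzero(lat.occupancy.ravel() == EMPTY)
        pop.add(OBL, free[:4000])
        env = make_env(lat)
        rate = 0.01
        cfg = CellConfig(apoptosis_per_h={"OBL": rate})
        rng = np.random.default_rng(5)
        hours = 0.0
        for _ in range(150):
            agents.proliferate_or_die(pop, lat, env, rng, cfg)
            hours += cfg.dt_h
        expected = 4000 * np.exp(-rate * hours)
        # binomial 3-sigma band around the analytic decay
        sigma = np.sqrt(expected)
        assert abs(pop.n_alive - expected) < 4 * sigma


class TestProduction:
    def test_unloaded_osteocyte_secretes_maximal_rankl(self):
        lat = SimulationLattice.empty((4, 4, 4))
        lat.mineral[:] = 500.0
        pop = AgentPopulation.create(lat)
        pop.add(OCY, [0])
        cfgp = ProductionConfig()
        env = make_env(lat, sed=0.0)
        rates = agents.produce_cytokines(pop, env, cfgp)
        assert rates["RANKL"][0] == pytest.approx(cfgp.ocy_rankl_base)
        assert rates["OPG"][0] == 0.0

    def test_rankl_monotone_nonincreasing_in_sed(self):
        lat = SimulationLattice.empty((4, 4, 4))
        lat.mineral[:] = 500.0
        pop = AgentPopulation.create(lat)
        pop.add(OCY, [0])
        cfgp = ProductionConfig()
        prev = np.inf
        for sed in np.linspace(0, 0.05, 20):
            env = make_env(lat, sed=sed)
            r = agents.produce_cytokines(pop, env, cfgp)["RANKL"][0]
            assert r <= prev + 1e-30
            assert r >= 0.0
            prev = r

    def test_oxygen_saturated_cell_produces_no_vegf(self):
        lat = SimulationLattice.empty((4, 4, 4))
        pop = AgentPopulation.create(lat)
        r = pop.add(SSPC, [0])[0]
        pop.o2_ok[r] = True
        env = make_env(lat)
        env.cytokines.fields["O2"][:] = 1.0
        rates = agents.produce_cytokines(pop, env, ProductionConfig(), o2_need=0.06)
        assert rates["VEGF"][0] == 0.0
        env.cytokines.fields["O2"][:] = 0.0
        rates = agents.produce_cytokines(pop, env, ProductionConfig(), o2_need=0.06)
        assert rates["VEGF"][0] == pytest.approx(ProductionConfig().vegf_max)

    def test_immune_cells_secrete_tgfb_constantly(self):
        lat = SimulationLattice.empty((4, 4, 4))
        pop = AgentPopulation.create(lat)
        pop.add(IMMUNE, [0])
        env = make_env(lat, sed=0.1, eff=0.1)
        rates = agents.produce_cytokines(pop, env, ProductionConfig())
        assert rates["TGFb"][0] == pytest.approx(ProductionConfig().immune_tgfb)


class TestOsteoid:
    def test_no_deposition_below_strain_threshold(self, rng):
        lat = SimulationLattice.empty((5, 5, 5))
        pop = AgentPopulation.create(lat)
        pop.add(OBL, [flat(lat, 2, 2, 2)])
        env = make_env(lat, eff=0.005)
        agents.deposit_osteoid(pop, lat, env, rng, CellConfig())
        assert lat.osteoid.sum() == 0.0

    def test_vessel_neighbours_receive_no_osteoid(self, rng):
        lat = SimulationLattice.empty((5, 5, 5))
        pop = AgentPopulation.create(lat)
        centre = flat(lat, 2, 2, 2)
        pop.add(OBL, [centre])
        lat.vessel[:] = True
        lat.vessel[2, 2, 2] = False
        env = make_env(lat, eff=0.01)
        agents.deposit_osteoid(pop, lat, env, rng, CellConfig())
        assert lat.osteoid.ravel()[centre] > 0
        assert (lat.osteoid * lat.vessel).sum() == 0.0

    def test_uniform_eff_gives_uniform_neighbour_selection(self):
        """With equal neighbour strain the polarisation choice is uniform
        (multinomial check over 10^4 draws)."""
        lat = SimulationLattice.empty((5, 5, 5))
        pop = AgentPopulation.create(lat)
        centre = flat(lat, 2, 2, 2)
        pop.add(OBL, [centre])
        env = make_env(lat, eff=0.01)
        rng = np.random.default_rng(6)
        counts = np.zeros(lat.mineral.size)
        n = 10_000
        for _ in range(n):
            lat.osteoid[:] = 0.0
            agents.deposit_osteoid(pop, lat, env, rng, CellConfig())
            got = np.flatnonzero(lat.osteoid.ravel())
            got = got[got != centre]
            counts[got] += 1
        nbrs = np.flatnonzero(counts)
        assert nbrs.size == 6
        p = 1.0 / 6.0
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts[nbrs] - n * p) < 5 * sigma)


class TestResorption:
    def _cluster_setup(self, n_ocl, occ, sed=0.001):
        lat = SimulationLattice.empty((7, 7, 7))
        lat.mineral[:, :, 0] = 500.0  # mineral floor below the cluster
        pop = AgentPopulation.create(lat)
        rows = pop.add(OCL, [flat(lat, 3, 3 + i, 1) for i in range(n_ocl)])
        pop.recept[rows, RANK] = occ
        env = make_env(lat, sed=sed)
        return lat, pop, env

    def test_two_ocl_cannot_resorb(self, rng):
        lat, pop, env = self._cluster_setup(2, occ=0.9)
        n = agents.resorb(pop, lat, env, rng, CellConfig(resorption_probability=1.0))
        assert n == 0 and (lat.mineral > 0).sum() == 49

    def test_cluster_of_three_resorbs_one_voxel(self, rng):
        lat, pop, env = self._cluster_setup(3, occ=0.6)
        before = (lat.mineral > 0).sum()
        n = agents.resorb(pop, lat, env, rng, CellConfig(resorption_probability=1.0))
        assert n == 1
        assert (lat.mineral > 0).sum() == before - 1

    def test_low_rank_occupancy_blocks_resorption(self, rng):
        lat, pop, env = self._cluster_setup(3, occ=0.4)
        n = agents.resorb(pop, lat, env, rng, CellConfig(resorption_probability=1.0))
        assert n == 0

    def test_high_sed_blocks_resorption_osteolytic_window(self, rng):
        lat, pop, env = self._cluster_setup(3, occ=0.9, sed=0.05)
        n = agents.resorb(pop, lat, env, rng, CellConfig(resorption_probability=1.0))
        assert n == 0

    def test_resorption_releases_stored_tgfb(self, rng):
        lat, pop, env = self._cluster_setup(3, occ=0.9)
        lat.tgfb_store[:, :, 0] = 1e-24
        m0 = env.cytokines.total_moles("TGFb")
        agents.resorb(pop, lat, env, rng, CellConfig(resorption_probability=1.0))
        assert env.cytokines.total_moles("TGFb") - m0 == pytest.approx(1e-24,
                                                                       rel=1e-9)


class TestClusters:
    def test_l_shaped_triple_is_one_cluster(self):
        lat = SimulationLattice.empty((5, 5, 5))
        pop = AgentPopulation.create(lat)
        pop.add(OCL, [flat(lat, 1, 1, 1), flat(lat, 2, 1, 1), flat(lat, 2, 2, 1)])
        clusters = agents.detect_clusters(pop)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_isolated_pairs_are_no_clusters(self):
        lat = SimulationLattice.empty((7, 7, 7))
        pop = AgentPopulation.create(lat)
        pop.add(OCL, [flat(lat, 1, 1, 1), flat(lat, 5, 5, 5)])
        assert agents.detect_clusters(pop) == []

    def test_line_of_ten_matches_bruteforce_components(self):
        lat = SimulationLattice.empty((4, 4, 12))
        pop = AgentPopulation.create(lat)
        positions = [flat(lat, 2, 2, k) for k in range(10)]
        pop.add(OCL, positions)
        clusters = agents.detect_clusters(pop)

        # brute-force union-find oracle over face adjacency
        parent = list(range(10))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        coords = [(2, 2, k) for k in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                if sum(abs(a - b) for a, b in zip(coords[i], coords[j])) == 1:
                    parent[find(i)] = find(j)
        comps = len({find(i) for i in range(10)})
        assert len(clusters) == comps == 1
        assert clusters[0].size == 10


class TestInvariants:
    def test_full_behaviour_cycle_preserves_occupancy_and_tissue_rules(self, rng):
        lat = SimulationLattice.empty((12, 12, 12))
        lat.mineral[:, :, :3] = 500.0
        pop = AgentPopulation.create(lat)
        free = np.flatnonzero((lat.mineral.ravel() == 0)
                              & (lat.occupancy.ravel() == EMPTY))
        rng2 = np.random.default_rng(9)
        pop.add(SSPC, rng2.choice(free, 150, replace=False))
        remaining = np.flatnonzero((lat.mineral.ravel() == 0)
                                   & (lat.occupancy.ravel() == EMPTY))
        pop.add(IMMUNE, rng2.choice(remaining, 100, replace=False))
        env = make_env(lat, sed=0.01, eff=0.01)
        cfg = CellConfig()
        for _ in range(15):
            agents.migrate(pop, lat, env, rng, cfg)
            agents.differentiate(pop, lat, env, rng, cfg)
            agents.proliferate_or_die(pop, lat, env, rng, cfg)
            agents.deposit_osteoid(pop, lat, env, rng, cfg)
            agents.resorb(pop, lat, env, rng, cfg)
            pop.check_invariants()

    def test_population_ledger_decomposition(self, rng):
        """Type-count changes decompose exactly into births - deaths +/-
        differentiation flows."""
        lat = SimulationLattice.empty((10, 10, 10))
        pop = AgentPopulation.create(lat)
        free = np.flatnonzero(lat.occupancy.ravel() == EMPTY)
        rng2 = np.random.default_rng(11)
        pop.add(SSPC, rng2.choice(free, 80, replace=False))
        pop.o2_ok[: pop.n] = True
        pop.recept[: pop.n, TGFBR1] = 0.9
        env = make_env(lat, eff=0.01)
        cfg = CellConfig()
        for _ in range(10):
            before = pop.counts()
            flows = agents.differentiate(pop, lat, env, rng, cfg)
            pd = agents.proliferate_or_die(pop, lat, env, rng, cfg)
            after = pop.counts()
            d_sspc = after["SSPC"] - before["SSPC"]
            # SSPC: +births (all divisions are SSPC here) - deaths(SSPC share)
            # -transitions out
            total_deaths = pd["deaths"]
            out = flows.get("SSPC->OBL", 0) + flows.get("SSPC->Lining", 0)
            # all agents are SSPC or OBL; OBL change is its inflow minus deaths
            d_obl = after["OBL"] - before["OBL"]
            obl_deaths = -(d_obl - flows.get("SSPC->OBL", 0)
                           + flows.get("OBL->Lining", 0)
                           + flows.get("OBL->preOCY", 0))
            sspc_deaths = total_deaths - obl_deaths
            assert d_sspc == pd["births"] - sspc_deaths - out
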