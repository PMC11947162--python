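"""Generator-level tests: packing, contact graph, propagation dynamics,
rendering, GUV kinetics and lipidomics tables."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import ferroprop as fp
from ferroprop.config import Modifiers


# ---------------------------------------------------------------------------
# monolayer
# ---------------------------------------------------------------------------

class TestGenerateMonolayer:
    def test_realized_confluency_near_target(self):
        cfg = fp.SimulationConfig(field_size=500.0, target_confluency=0.5,
                                  diameter_mean=23.0, seed=11)
        cells = fp.generate_monolayer(cfg)
        covered = (np.pi * (cells.diameter / 2) ** 2).sum() / cfg.field_size**2
        assert 0.45 <= covered <= 0.55

    def test_deterministic_for_same_seed(self):
        cfg = fp.SimulationConfig(seed=5)
        a = fp.generate_monolayer(cfg)
        b = fp.generate_monolayer(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = fp.generate_monolayer(fp.SimulationConfig(seed=1))
        b = fp.generate_monolayer(fp.SimulationConfig(seed=2))
        assert not a[["x", "y"]].equals(b[["x", "y"]])

    def test_all_bystander_with_illumination_errors(self):
        cfg = fp.SimulationConfig(transfected_fraction=0.0, n_illuminated=1, seed=0)
        with pytest.raises(ValueError, match="transfected"):
            fp.generate_monolayer(cfg)

    def test_zero_transfected_fraction_all_bystander(self):
        cfg = fp.SimulationConfig(transfected_fraction=0.0, n_illuminated=0, seed=0)
        cells = fp.generate_monolayer(cfg)
        assert (cells.population == "bystander").all()
        assert not cells.illuminated.any()

    def test_geometry_invariants(self):
        cfg = fp.SimulationConfig(seed=3)
        cells = fp.generate_monolayer(cfg)
        r = cells.diameter / 2
        assert cells.id.is_unique
        assert ((cells.x >= r) & (cells.x <= cfg.field_size - r)).all()
        assert ((cells.y >= r) & (cells.y <= cfg.field_size - r)).all()
        # pairwise non-overlap beyond the configured tolerance
        xy = cells[["x", "y"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None], axis=-1)
        lim = (1 - cfg.overlap_tolerance) * (r.to_numpy()[:, None] + r.to_numpy()[None])
        np.fill_diagonal(d, np.inf)
        assert (d >= lim - 1e-9).all()
        assert cells.illuminated.sum() == cfg.n_illuminated
        assert (cells.loc[cells.illuminated, "population"] == "transfected").all()

    def test_unreachable_confluency_raises_packing_error(self):
        cfg = fp.SimulationConfig(target_confluency=0.9, seed=0)
        with pytest.raises(fp.PackingError) as exc:
            fp.generate_monolayer(cfg)
        assert 0 < exc.value.achieved < 0.9


class TestContactGraph:
    def test_two_cells_edge_by_definition(self):
        cells = pd.DataFrame(
            {"id": [0, 1], "x": [0.0, 20.0], "y": [0.0, 0.0],
             "diameter": [23.0, 23.0], "population": ["transfected", "bystander"],
             "illuminated": [False, False]}
        )
        g = fp.build_contact_graph(cells, kappa=1.0)
        assert g.has_edge(0, 1)  # 20 <= 23

    def test_single_cell_graph_no_edges(self):
        cells = pd.DataFrame(
            {"id": [4], "x": [5.0], "y": [5.0], "diameter": [23.0],
             "population": ["bystander"], "illuminated": [False]}
        )
        g = fp.build_contact_graph(cells)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 1

    def test_square_lattice_interior_degree_four(self):
        s = 25.0
        pts = [(i * s + 50, j * s + 50) for i in range(5) for j in range(5)]
        cells = pd.DataFrame(
            {"id": range(25), "x": [p[0] for p in pts], "y": [p[1] for p in pts],
             "diameter": 23.0, "population": "bystander", "illuminated": False}
        )
        g = fp.build_contact_graph(cells, kappa=1.2)  # threshold 27.6 < s*sqrt2
        centre = 12  # (2,2) in row-major 5x5
        assert g.degree[centre] == 4

    def test_matches_all_pairs_oracle(self):
        cfg = fp.SimulationConfig(field_size=300.0, seed=9)
        cells = fp.generate_monolayer(cfg)
        kappa = 1.2
        g = fp.build_contact_graph(cells, kappa=kappa)
        xy = cells[["x", "y"]].to_numpy()
        r = cells.diameter.to_numpy() / 2
        expect = set()
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                if np.hypot(*(xy[i] - xy[j])) <= kappa * (r[i] + r[j]):
                    expect.add((cells.id[i], cells.id[j]))
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == expect


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

class TestSimulatePropagation:
    def test_no_propagation_channel_only_illuminated_die(self, default_run):
        _, cells, graph, _ = default_run
        cfg = fp.SimulationConfig(p_spread=0.0, background_hazard=0.0, seed=7)
        ev = fp.simulate_propagation(cells, graph, cfg)
        dead = set(ev.loc[ev.blebbing_time.notna(), "id"])
        assert dead == set(cells.loc[cells.illuminated, "id"])

    def test_contacts_disabled_equals_p_zero_exactly(self, default_run):
        _, cells, graph, _ = default_run
        base = fp.SimulationConfig(p_spread=0.0, seed=7)
        off = fp.SimulationConfig(
            p_spread=0.6, seed=7,
            modifiers=Modifiers(contacts_enabled=False),
        )
        ev_a = fp.simulate_propagation(cells, graph, base)
        ev_b = fp.simulate_propagation(cells, graph, off)
        pd.testing.assert_frame_equal(ev_a, ev_b)

    def test_percolation_limit_matches_reachability(self):
        cfg = fp.SimulationConfig(p_spread=1.0, background_hazard=0.0,
                                  t_end=4000.0, dt=2.0, seed=3)
        cells = fp.generate_monolayer(cfg)
        graph = fp.build_contact_graph(cells)
        ev = fp.simulate_propagation(cells, graph, cfg)
        reach = set()
        for s in cells.loc[cells.illuminated, "id"]:
            reach |= nx.node_connected_component(graph, s)
        dead = set(ev.loc[ev.blebbing_time.notna(), "id"])
        assert dead == reach

    @pytest.mark.parametrize("mods", [
        Modifiers(fer1_time=0.0, fer1_efficacy=0.0),
        Modifiers(contacts_enabled=False),
        Modifiers(iron_factor=0.0),
    ], ids=["fer1", "no_contacts", "no_iron"])
    def test_modifier_nulls_block_all_propagation(self, default_run, mods):
        _, cells, graph, _ = default_run
        cfg = fp.SimulationConfig(seed=7, modifiers=mods)
        ev = fp.simulate_propagation(cells, graph, cfg)
        assert (ev.cause == "propagated").sum() == 0

    def test_event_table_causal_invariants(self, default_run):
        cfg, cells, graph, ev = default_run
        m = cells.merge(ev, on="id")
        full = m.dropna(subset=["ox_onset_time", "blebbing_time", "draq7_time"])
        assert (full.ox_onset_time <= full.blebbing_time).all()
        assert (full.blebbing_time <= full.draq7_time).all()
        opto = m[m.cause == "opto"]
        assert opto.illuminated.all()
        assert (opto.population == "transfected").all()
        # every propagated cell has a contact neighbour that died earlier
        bleb = ev.set_index("id").blebbing_time
        for _, row in m[m.cause == "propagated"].iterrows():
            nbr_bleb = bleb.reindex(list(graph.neighbors(row.id))).dropna()
            ref = row.blebbing_time if not np.isnan(row.blebbing_time) else np.inf
            assert (nbr_bleb < ref).any()

    def test_mean_propagated_deaths_monotone_in_p(self):
        means = []
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            tot = 0
            for seed in range(50):
                cfg = fp.SimulationConfig(field_size=300.0, n_illuminated=4,
                                          p_spread=p, seed=seed)
                cells = fp.generate_monolayer(cfg)
                graph = fp.build_contact_graph(cells)
                ev = fp.simulate_propagation(cells, graph, cfg)
                tot += int((ev.cause == "propagated").sum())
            means.append(tot / 50)
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_bilayer_range_reaches_noncontact_cells(self):
        # two cells far beyond contact range but inside the bilayer bridge
        cells = pd.DataFrame(
            {"id": [0, 1], "x": [0.0, 60.0], "y": [0.0, 0.0],
             "diameter": [23.0, 23.0],
             "population": ["transfected", "bystander"],
             "illuminated": [True, False]}
        )
        graph = fp.build_contact_graph(cells)
        assert not graph.has_edge(0, 1)
        hits = 0
        for seed in range(40):
            cfg = fp.SimulationConfig(
                p_spread=1.0, background_hazard=0.0, seed=seed,
                modifiers=Modifiers(bilayer_range=120.0),
            )
            ev = fp.simulate_propagation(cells, graph, cfg)
            hits += int(ev.set_index("id").loc[1, "cause"] == "propagated")
        # decayed probability 1 - 60/120 = 0.5 per exposure
        assert 10 <= hits <= 30

    def test_invalid_config_rejected_before_simulation(self, default_run):
        _, cells, graph, _ = default_run
        cfg = fp.SimulationConfig()
        cfg.p_spread = 1.5
        with pytest.raises(ValueError):
            fp.simulate_propagation(cells, graph, cfg)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestRenderFrames:
    def test_empty_cell_table_offset_plus_noise(self):
        cells = pd.DataFrame(columns=["id", "x", "y", "diameter", "population",
                                      "illuminated"])
        events = pd.DataFrame(columns=["id", "ox_onset_time", "blebbing_time",
                                       "draq7_time", "cause"])
        img = fp.ImagingConfig(noise_sd=0.0)
        stack, labels = fp.render_frames(cells, events, img, field_size=50.0,
                                         t_end=12.0)
        for c, name in enumerate(stack.channels):
            assert np.allclose(stack.data[:, c], img.offsets[name])
        assert (labels == 0).all()

    def test_single_cell_blob_centre_and_mass(self):
        cells = pd.DataFrame(
            {"id": [0], "x": [25.0], "y": [30.0], "diameter": [23.0],
             "population": ["transfected"], "illuminated": [False]}
        )
        events = pd.DataFrame(
            {"id": [0], "ox_onset_time": [np.nan], "blebbing_time": [np.nan],
             "draq7_time": [np.nan], "cause": ["none"]}
        )
        img = fp.ImagingConfig(noise_sd=0.0, psf_sigma=0.0)
        stack, _ = fp.render_frames(cells, events, img, field_size=64.0, t_end=0.0)
        marker = stack.channel("marker")[0] - img.offsets["marker"]
        r, c = np.unravel_index(np.argmax(marker), marker.shape)
        assert abs(c - 25.0) <= 1.0 and abs(r - 30.0) <= 1.0
        sigma = 23.0 / 4.0
        analytic = img.gains["marker"] * 2 * math.pi * sigma**2
        assert marker.sum() == pytest.approx(analytic, rel=0.01)

    def test_bodipy_green_red_conservation_and_exchange(self):
        cells = pd.DataFrame(
            {"id": [0], "x": [25.0], "y": [25.0], "diameter": [23.0],
             "population": ["bystander"], "illuminated": [False]}
        )
        events = pd.DataFrame(
            {"id": [0], "ox_onset_time": [10.0], "blebbing_time": [60.0],
             "draq7_time": [64.0], "cause": ["propagated"]}
        )
        img = fp.ImagingConfig(noise_sd=0.0, frame_interval=5.0)
        stack, _ = fp.render_frames(cells, events, img, field_size=50.0, t_end=60.0)
        green = stack.channel("bodipy_green") - img.offsets["bodipy_green"]
        red = stack.channel("bodipy_red") - img.offsets["bodipy_red"]
        g_tot = green.sum(axis=(1, 2))
        r_tot = red.sum(axis=(1, 2))
        # equal gains: the green+red sum is conserved across frames
        assert np.allclose(g_tot + r_tot, (g_tot + r_tot)[0], rtol=1e-5)
        assert g_tot[0] == pytest.approx(0.0, abs=1e-6)
        assert g_tot[-1] > r_tot[-1]  # fully oxidised at the end

    def test_draq7_steps_up_at_death(self):
        cells = pd.DataFrame(
            {"id": [0], "x": [25.0], "y": [25.0], "diameter": [23.0],
             "population": ["bystander"], "illuminated": [False]}
        )
        events = pd.DataFrame(
            {"id": [0], "ox_onset_time": [5.0], "blebbing_time": [20.0],
             "draq7_time": [24.0], "cause": ["propagated"]}
        )
        img = fp.ImagingConfig(noise_sd=0.0, frame_interval=6.0)
        stack, _ = fp.render_frames(cells, events, img, field_size=50.0, t_end=36.0)
        draq = stack.channel("draq7") - img.offsets["draq7"]
        on = draq.max(axis=(1, 2)) > 1.0
        assert list(on) == [t >= 24.0 for t in stack.frame_times]

    def test_label_map_matches_cell_table(self, rendered_run):
        _, cells, _, _, imaging, _, label_map = rendered_run
        ids_in_map = set(np.unique(label_map)) - {0}
        assert ids_in_map == set(cells.id + 1)

    def test_too_small_field_raises(self):
        cells = pd.DataFrame(
            {"id": [0], "x": [1.0], "y": [1.0], "diameter": [23.0],
             "population": ["bystander"], "illuminated": [False]}
        )
        events = pd.DataFrame(
            {"id": [0], "ox_onset_time": [np.nan], "blebbing_time": [np.nan],
             "draq7_time": [np.nan], "cause": ["none"]}
        )
        with pytest.raises(ValueError, match="too small"):
            fp.render_frames(cells, events, fp.ImagingConfig(), field_size=2.0)


# ---------------------------------------------------------------------------
# GUV + lipidomics generators
# ---------------------------------------------------------------------------

class TestGUVPair:
    @pytest.mark.parametrize("kwargs", [{"iron_conc": 0.0}, {"contact": False}],
                             ids=["no_iron", "no_contact"])
    def test_acceptor_flat_without_coupling(self, kwargs):
        cfg = fp.GUVPairConfig(**kwargs)
        tr = fp.simulate_guv_pair(cfg)
        assert np.allclose(tr.acceptor_ratio, cfg.baseline_ratio, atol=1e-9)
        assert tr.donor_ratio.iloc[-1] > cfg.baseline_ratio

    def test_donor_matches_closed_form(self):
        cfg = fp.GUVPairConfig(dt=0.01)
        tr = fp.simulate_guv_pair(cfg)
        exact = cfg.baseline_ratio + (1 - cfg.baseline_ratio) * (
            1.0 - np.exp(-cfg.k_act * tr.time.to_numpy())
        )
        assert np.abs(tr.donor_ratio.to_numpy() - exact).max() < 1e-6

    def test_acceptor_strictly_increasing_with_coupling(self):
        tr = fp.simulate_guv_pair(fp.GUVPairConfig())
        assert (np.diff(tr.acceptor_ratio) > 0).all()

    def test_invalid_dt_rejected(self):
        cfg = fp.GUVPairConfig()
        cfg.dt = -1.0
        with pytest.raises(ValueError):
            fp.simulate_guv_pair(cfg)


class TestSimulateLipidomics:
    def test_noiseless_round_trip_exact(self):
        cfg = fp.LipidSimConfig(cv=0.0)
        table = fp.simulate_lipidomics(cfg)
        fc = fp.fold_changes(fp.normalize_areas(table, per_protein=True))
        truth = {sp.name: sp.true_fold_change for sp in cfg.species}
        got = fc.groupby("species")["mean_fold_change"].first()
        for name, val in truth.items():
            assert got[name] == pytest.approx(val, abs=1e-12)

    def test_internal_standard_scaling_invariance(self):
        cfg = fp.LipidSimConfig(cv=0.0, seed=2)
        base = fp.simulate_lipidomics(cfg)
        scaled = base.copy()
        scaled["area"] = scaled["area"] * 10
        scaled["is_area"] = scaled["is_area"] * 10
        a = fp.fold_changes(fp.normalize_areas(base))
        b = fp.fold_changes(fp.normalize_areas(scaled))
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_mean_concentrates_with_noise(self):
        # Monte-Carlo: with CV 0.1 and 6 replicates, the replicate-mean
        # fold change stays within ±0.5 of truth 3 for >= 95% of seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = fp.LipidSimConfig(
                species=[fp.LipidSpecies("ox-PL", 3.0, standard="IS")],
                n_replicates=6, cv=0.1, seed=seed,
            )
            fc = fp.fold_changes(fp.normalize_areas(fp.simulate_lipidomics(cfg)))
            m = fc["mean_fold_change"].iloc[0]
            hits += int(2.5 <= m <= 3.5)
        assert hits / n_seeds >= 0.95
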