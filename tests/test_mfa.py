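"""Atom-network parsing, EMU decomposition/simulation, flux estimation."""

import numpy as np
import pytest

from cocult.mfa import (
    AtomNetworkError,
    Experiment,
    MFAModel,
    MIDMeasurement,
    Tracer,
    decompose_emus,
    export_intervals,
    fit_fluxes,
    fragment_id,
    make_emu,
    monte_carlo_ci,
    parse_atom_network,
    parse_fragment_id,
    read_mid_csv,
    simulate_mids,
    ssr,
    write_mid_csv,
)
from cocult.synthetic import (
    make_atom_mapped_toynet,
    toy_mfa_model,
    toy_mfa_truth_fluxes,
    toy_target_fragments,
)
from oracles import emu_count_by_reachability, isotopomer_mids


class TestParsing:
    def test_single_reaction(self):
        net = parse_atom_network("v1: A (abc) -> B (ab) + C (c)\n")
        assert len(net.transitions) == 1
        t = net.transitions[0]
        assert t.reactants == [("A", "abc")]
        assert t.products == [("B", "ab"), ("C", "c")]

    def test_symmetric_expansion_half_half(self):
        net = parse_atom_network(
            "symmetric: Suc\nv1: AKG (abcde) -> Suc (bcde) + CO2 (a)\n"
        )
        maps = net.transitions[0].mappings
        assert len(maps) == 2
        assert all(p == pytest.approx(0.5) for p, _ in maps)
        variants = {tuple(prods) for _, prods in maps}
        assert (("Suc", "bcde"), ("CO2", "a")) in variants
        assert (("Suc", "edcb"), ("CO2", "a")) in variants

    def test_unbalanced_letters_name_line(self):
        with pytest.raises(AtomNetworkError, match="line 2"):
            parse_atom_network("v1: A (ab) -> B (ab)\nv2: A (ab) -> B (abc)\n")

    def test_round_trip(self):
        net, _ = make_atom_mapped_toynet()
        again = parse_atom_network(net.to_text())
        assert again.to_text() == net.to_text()
        assert again.external == net.external

    def test_fragment_id_round_trip(self):
        emu = make_emu("Cit", (1, 3, 2))
        assert parse_fragment_id(fragment_id(emu)) == ("Cit", (1, 2, 3))


class TestDecomposition:
    def test_linear_pass_through(self):
        net = parse_atom_network("external: A\nv1: A (ab) -> B (ab)\n")
        emunet = decompose_emus(net, [make_emu("B", (1, 2))])
        assert set(emunet.emus) == {("A", (1, 2)), ("B", (1, 2))}

    def test_condensation_makes_convolution_node(self):
        net = parse_atom_network(
            "external: A1 A2\nv1: A1 (a) + A2 (b) -> B (ab)\n"
        )
        emunet = decompose_emus(net, [make_emu("B", (1, 2))])
        conv = [r for r in emunet.reactions if len(r.sources) == 2]
        assert len(conv) == 1
        assert set(conv[0].sources) == {("A1", (1,)), ("A2", (1,))}

    def test_toy_network_count_matches_reachability_oracle(self):
        net, _ = make_atom_mapped_toynet()
        targets = toy_target_fragments()
        emunet = decompose_emus(net, targets)
        assert len(emunet.emus) == emu_count_by_reachability(net, targets)

    def test_unreachable_fragment_raises(self):
        net = parse_atom_network("external: A\nv1: A (ab) -> B (ab)\n")
        with pytest.raises(AtomNetworkError, match="C"):
            decompose_emus(net, [make_emu("C", (1,))])


class TestSimulation:
    def setup_method(self):
        self.net, _ = make_atom_mapped_toynet()
        self.fluxes = toy_mfa_truth_fluxes()
        self.targets = toy_target_fragments()
        self.emunet = decompose_emus(self.net, self.targets)

    def test_unlabelled_substrates_all_m0(self):
        mids = simulate_mids(self.emunet, self.fluxes, [])
        for m in mids:
            assert m.fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_fully_labelled_linear_chain(self):
        net = parse_atom_network(
            "external: A\nv1: A (abc) -> B (abc)\nv2: B (abc) -> C (abc)\n"
        )
        emunet = decompose_emus(net, [make_emu("C", (1, 2, 3))])
        mids = simulate_mids(
            emunet, {"v1": 1.0, "v2": 1.0}, [Tracer("A", "U", purity=1.0)]
        )
        assert mids[0].fractions[-1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_isotopomer_enumeration_oracle(self, seed):
        rng = np.random.default_rng(800 + seed)
        # random feasible flux vector: scale the reference mode and add a
        # random amount of the internal cycles that preserve steady state
        S, mets = self.net.stoichiometric_matrix()
        base = np.array([self.fluxes[r] for r in self.net.reaction_ids])
        # null-space directions added with rejection to stay positive
        from scipy.linalg import null_space

        N = null_space(S)
        for _ in range(50):
            v = base * rng.uniform(0.5, 2.0) + N @ rng.normal(0, 0.1, N.shape[1])
            if (v > 1e-6).all():
                break
        fluxes = dict(zip(self.net.reaction_ids, v))
        tracers = [Tracer("Glc_x", "U", purity=0.99)]
        mids = simulate_mids(self.emunet, fluxes, tracers)
        oracle = isotopomer_mids(self.net, fluxes, tracers)
        for m in mids:
            assert np.abs(oracle(m.fragment) - m.fractions).max() <= 1e-8

    def test_mid_normalisation_invariants(self):
        mids = simulate_mids(self.emunet, self.fluxes, [Tracer("Glc_x", "U")])
        for m in mids:
            assert m.fractions.sum() == pytest.approx(1.0, abs=1e-9)
            assert m.fractions.min() >= -1e-12

    def test_flux_scaling_invariance(self):
        tracers = [Tracer("Glc_x", "U")]
        a = simulate_mids(self.emunet, self.fluxes, tracers)
        doubled = {k: 2 * v for k, v in self.fluxes.items()}
        b = simulate_mids(self.emunet, doubled, tracers)
        for x, y in zip(a, b):
            assert np.abs(x.fractions - y.fractions).max() <= 1e-12

    def test_zero_inflow_names_fragment(self):
        fluxes = dict(self.fluxes)
        fluxes["v_gls"] = 0.0  # nothing feeds glutamate any more
        emunet = decompose_emus(self.net, [make_emu("Glu", (1, 2, 3, 4, 5))])
        with pytest.raises(ValueError, match="Glu"):
            simulate_mids(emunet, fluxes, [Tracer("Glc_x", "U")])


class TestSSR:
    def test_zero_when_equal(self):
        frag = make_emu("Lac", (1, 2, 3))
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        meas = [MIDMeasurement(frag, vals, np.full(4, 0.01))]
        from cocult.mfa import MIDVector

        sim = [MIDVector(frag, vals)]
        assert ssr(meas, sim) == pytest.approx(0.0)

    def test_two_sigma_entry_counts_four(self):
        frag = make_emu("Lac", (1, 2, 3))
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        off = vals + np.array([0.02, -0.02, 0.0, 0.0])
        off = off / off.sum()
        meas = [MIDMeasurement(frag, np.array([0.12, 0.2, 0.3, 0.38]),
                               np.full(4, 0.01))]
        from cocult.mfa import MIDVector

        sim = [MIDVector(frag, vals)]
        assert ssr(meas, sim) == pytest.approx(4.0 + 4.0)

    def test_matches_naive_recount(self):
        rng = np.random.default_rng(5)
        frag = make_emu("OAA", (1, 2, 3, 4))
        sim_vals = rng.dirichlet(np.ones(5))
        meas_vals = rng.dirichlet(np.ones(5))
        sds = rng.uniform(0.005, 0.02, 5)
        from cocult.mfa import MIDVector

        total = ssr(
            [MIDMeasurement(frag, meas_vals, sds)], [MIDVector(frag, sim_vals)],
            flux_measurements={"v": (1.0, 0.1)}, fluxes={"v": 1.3},
        )
        manual = sum(((m - s) / sd) ** 2 for m, s, sd in
                     zip(meas_vals, sim_vals, sds)) + ((1.3 - 1.0) / 0.1) ** 2
        assert total == pytest.approx(manual)

    def test_fragment_mismatch_raises(self):
        from cocult.mfa import MIDVector

        frag_a = make_emu("Lac", (1, 2, 3))
        frag_b = make_emu("Ala", (1, 2, 3))
        meas = [MIDMeasurement(frag_a, np.full(4, 0.25), np.full(4, 0.01))]
        sim = [MIDVector(frag_b, np.full(4, 0.25))]
        with pytest.raises(ValueError, match="Lac"):
            ssr(meas, sim)


class TestFitting:
    def test_zero_noise_recovery(self):
        model, truth = toy_mfa_model(noise_sd=0.0, seed=11)
        est = fit_fluxes(model, n_restarts=10, seed=5)
        assert est.ssr <= 1e-8
        for rid, v in truth.items():
            assert est.fluxes[rid] == pytest.approx(v, rel=1e-4, abs=1e-6)

    def test_same_seed_identical_results(self):
        model, _ = toy_mfa_model(noise_sd=0.005, seed=3)
        a = fit_fluxes(model, n_restarts=5, seed=9)
        b = fit_fluxes(model, n_restarts=5, seed=9)
        assert a.ssr == b.ssr
        assert a.fluxes == b.fluxes
        assert a.best_restart_seed == b.best_restart_seed

    def test_noisy_fit_within_chi2_band(self):
        from scipy import stats

        model, _ = toy_mfa_model(noise_sd=0.005, seed=21)
        est = fit_fluxes(model, n_restarts=20, seed=2)
        assert est.ssr <= stats.chi2.ppf(0.95, est.dof)
        assert est.chi2_pass

    def test_underdetermined_rejected(self):
        net = parse_atom_network("external: A\nv1: A (ab) -> B (ab)\n")
        exp = Experiment(
            name="x", tracers=[Tracer("A", "U")],
            measurements=[MIDMeasurement(make_emu("B", (1,)),
                                         np.array([0.5, 0.5]),
                                         np.array([0.01, 0.01]))],
        )
        model = MFAModel(network=net, experiments=[exp])
        with pytest.raises(ValueError, match="under-determined"):
            # one free flux but only one independent measurement row would
            # leave dof < 1 after the MID sum constraint
            fit_fluxes(MFAModel(network=net, experiments=[
                Experiment(name="x", tracers=[Tracer("A", "U")],
                           measurements=[])
            ]), n_restarts=2, seed=0)


class TestMonteCarlo:
    def test_intervals_contain_point_estimate(self):
        model, _ = toy_mfa_model(noise_sd=0.005, seed=13)
        est = fit_fluxes(model, n_restarts=5, seed=1)
        est = monte_carlo_ci(model, est, n_samples=15, seed=2)
        for rid, (lo, hi) in est.intervals.items():
            assert lo - 1e-9 <= est.fluxes[rid] <= hi + 1e-9

    def test_interval_width_shrinks_with_noise(self):
        widths = {}
        for sd in (0.01, 0.001):
            model, _ = toy_mfa_model(noise_sd=sd, seed=17)
            est = fit_fluxes(model, n_restarts=5, seed=1)
            est = monte_carlo_ci(model, est, n_samples=15, seed=2)
            widths[sd] = np.mean([hi - lo for lo, hi in est.intervals.values()])
        assert widths[0.001] < widths[0.01]

    def test_truth_within_intervals_at_zero_noise(self):
        model, truth = toy_mfa_model(noise_sd=0.0, seed=19)
        est = fit_fluxes(model, n_restarts=5, seed=1)
        est = monte_carlo_ci(model, est, n_samples=15, seed=2)
        for rid, v in truth.items():
            lo, hi = est.intervals[rid]
            assert lo - 1e-6 <= v <= hi + 1e-6


class TestExport:
    def _estimated(self):
        model, truth = toy_mfa_model(noise_sd=0.0, seed=23)
        est = fit_fluxes(model, n_restarts=5, seed=1)
        return monte_carlo_ci(model, est, n_samples=10, seed=2), truth

    def test_empty_map_full_sidecar(self, tmp_path):
        est, _ = self._estimated()
        table, unmapped = export_intervals(est, {}, path=str(tmp_path / "iv.csv"))
        assert len(table) == 0
        assert set(unmapped) == set(est.intervals)

    def test_duplicate_target_rejected(self):
        est, _ = self._estimated()
        with pytest.raises(ValueError, match="duplicate"):
            export_intervals(est, {"v_glc": "GLCt", "v_gly": "GLCt"})

    def test_uptake_sign_convention(self):
        # an exchange written "met[e] ->" carries uptake as negative flux;
        # mapping with scale -1 flips and re-orders the interval
        est, _ = self._estimated()
        table, _ = export_intervals(est, {"v_glc": ("EX_glc", -1.0)})
        row = table.iloc[0]
        lo, hi = est.intervals["v_glc"]
        assert row.lo == pytest.approx(-hi)
        assert row.hi == pytest.approx(-lo)

    def test_round_trip_into_phenotype_tuning(self, stromal_constrained):
        from cocult.coculture import apply_flux_intervals
        from cocult.fba import fba_optimize

        est, truth = self._estimated()
        table, _ = export_intervals(
            est, {"v_glc": "GLCt", "v_gln": "GLNt", "v_lac_out": "LACt"}
        )
        intervals = {r.reaction_id: (r.lo, r.hi) for r in table.itertuples()}
        model, _ = stromal_constrained
        tuned = apply_flux_intervals(model, intervals)
        res = fba_optimize(tuned)
        assert res.optimal
        # the zero-noise fit pins transport fluxes near their true values
        assert res.fluxes["GLCt"] == pytest.approx(truth["v_glc"], abs=0.05)


class TestMidCsv:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        meas = [
            MIDMeasurement(make_emu("Lac", (1, 2, 3)), rng.dirichlet(np.ones(4)),
                           np.full(4, 0.005)),
            MIDMeasurement(make_emu("OAA", (1, 2, 3, 4)),
                           rng.dirichlet(np.ones(5)), np.full(5, 0.005)),
        ]
        path = str(tmp_path / "mids.csv")
        write_mid_csv(meas, path)
        back = read_mid_csv(path)
        by_frag = {m.fragment: m for m in back}
        for m in meas:
            assert np.allclose(by_frag[m.fragment].values, m.values)
            assert np.allclose(by_frag[m.fragment].sds, m.sds)
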