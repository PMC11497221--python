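"""Plan generation, end-to-end campaign execution, protocol freezing, IO."""

import numpy as np
import pytest

from autokinetics import (
    HANSCH_SIGMA,
    MonitorConfig,
    excess_screen,
    freeze_protocol,
    hammett_campaign,
    pseudo_first_order_series,
    replay_static,
    run_campaign,
)
from autokinetics import io, studies
from autokinetics.campaign import monitored_plan
from autokinetics.monitor import MonitorRecord, directory_stream
from autokinetics.processing import ConversionPoint


SUBS_8 = list(HANSCH_SIGMA)
CONCS_5 = list(studies.TOSYL_AMINE_MM)


class TestPlanGenerators:
    def test_hammett_campaign_is_8_by_5(self):
        plans = hammett_campaign(SUBS_8, CONCS_5, n_points=15)
        assert len(plans) == 40
        assert sum(p.schedule[1] for p in plans) == 600

    def test_substituent_major_ordering(self):
        plans = hammett_campaign(SUBS_8, CONCS_5)
        subs_seen = [p.meta["substituent"] for p in plans]
        # each substituent's runs are contiguous: one arylamine at a time
        blocks = [subs_seen[i : i + 5] for i in range(0, 40, 5)]
        assert all(len(set(b)) == 1 for b in blocks)

    def test_single_cell_campaign(self):
        assert len(hammett_campaign(["H"], [50.0])) == 1

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            hammett_campaign(["H", "H"], CONCS_5)
        with pytest.raises(ValueError, match="duplicate"):
            hammett_campaign(SUBS_8, [50.0, 50.0])

    def test_pseudo_first_order_series_shape(self):
        plans = pseudo_first_order_series(1.5, [100, 150, 200], 20, 82)
        assert len(plans) == 3
        assert all(p.schedule[1] == 20 for p in plans)
        assert [p.meta["excess_mM"] for p in plans] == [100.0, 150.0, 200.0]

    def test_empty_excess_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pseudo_first_order_series(1.5, [], 20, 82)

    def test_single_point_plan_allowed(self):
        plans = pseudo_first_order_series(1.5, [100.0], 1, 60)
        assert plans[0].schedule[1] == 1

    def test_excess_screen_counts(self):
        from autokinetics import Peak, Reaction, ReactionNetwork, SpectralSignature
        from autokinetics.processing import ProcessingRecipe

        assert len(excess_screen({"Fe": 1, "AQ": 2, "FP": 2}, 1.2)) == 4
        net = ReactionNetwork(
            species=["A", "P"],
            reactions=[Reaction(reactants={"A": 1}, products={"P": 1}, k=0.01)],
        )
        sig = SpectralSignature(modality="uvvis", peaks={"P": [Peak(500.0, 20.0, 1.0)]})
        recipe = ProcessingRecipe(
            mode="absorbance", wavelength=500.0, calibration=1.0, species="P"
        )
        one = excess_screen({"A": 1.0}, 1.2, network=net, signature=sig, recipe=recipe)
        assert len(one) == 2

    def test_excess_factor_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            excess_screen({"Fe": 1, "AQ": 2}, 1.0)

    def test_excess_plan_multiplies_one_reagent(self):
        plans = excess_screen({"Fe": 1, "AQ": 2, "FP": 2}, 1.2)
        std = plans[0].initial
        for plan in plans[1:]:
            varied = plan.meta["varied"]
            assert plan.initial[varied] == pytest.approx(1.2 * std[varied])
            others = {k: v for k, v in plan.initial.items() if k != varied}
            assert others == {k: v for k, v in std.items() if k != varied}


class TestRunCampaign:
    def test_full_campaign_json_is_deterministic(self):
        a = run_campaign(pseudo_first_order_series(relative_sigma=0.01, seed=5), "initial_rates_k2")
        b = run_campaign(pseudo_first_order_series(relative_sigma=0.01, seed=5), "initial_rates_k2")
        assert a.to_json() == b.to_json()

    def test_noiseless_hammett_recovers_truth_closely(self):
        plans = hammett_campaign(
            SUBS_8[:4], CONCS_5, rho_true=-0.98, rate_noise=0.0, relative_sigma=0.0, seed=0
        )
        result = run_campaign(plans, "hammett")
        assert result.inference.rho == pytest.approx(-0.98, abs=0.05)
        for fit in result.orders.values():
            assert fit.order == pytest.approx(0.7, abs=0.05)

    def test_incompatible_analysis_rejected(self):
        plans = pseudo_first_order_series()
        with pytest.raises(ValueError, match="conversion series"):
            run_campaign(plans, "hammett")
        with pytest.raises(ValueError, match="unknown analysis"):
            run_campaign(plans, "banana")

    def test_duplicate_plan_ids_rejected(self):
        plans = pseudo_first_order_series()
        with pytest.raises(ValueError, match="unique"):
            run_campaign([plans[0], plans[0]], "initial_rates_k2")

    def test_vtna_campaign_reads_first_order_for_all_reagents(self):
        plans = excess_screen({"Fe": 1, "AQ": 2, "FP": 2}, 1.2, seed=0)
        result = run_campaign(plans, "vtna")
        assert set(result.inference) == {"Fe", "AQ", "FP"}
        for vr in result.inference.values():
            assert vr.best_alpha == pytest.approx(1.0)


class TestFreezeProtocol:
    def _monitored(self, kobs=0.025, sigma=0.0, seed=0, threshold=0.01):
        config = MonitorConfig(window=5, threshold=threshold, max_measurements=40)
        amine0 = 100.0
        return monitored_plan(
            studies.tosylation_network(k=kobs / amine0, amine_order=1.0),
            {"TsCl": studies.TOSYL_TSCL0_MM, "ArNH2": amine0, "TsNHAr": 0.0},
            studies.tosylation_signature(),
            studies.tosylation_recipe(),
            config,
            relative_sigma=sigma,
            seed=seed,
        )

    def test_static_protocol_matches_stop_index(self):
        plan = self._monitored()
        record, protocol = run_campaign([plan], "monitor").inference
        assert protocol.n_measurements == record.stopped_at + 1
        assert protocol.duration_min == pytest.approx(record.conversions[-1].time)

    def test_flat_trace_freezes_to_window_measurements(self):
        plan = self._monitored(kobs=0.0)
        record, protocol = run_campaign([plan], "monitor").inference
        assert protocol.n_measurements == plan.monitor.window

    def test_max_reached_record_rejected(self):
        plan = self._monitored()
        record = MonitorRecord(
            conversions=[ConversionPoint(0.0, 0.1)], stopped_at=None, stop_reason="max_reached"
        )
        with pytest.raises(ValueError, match="cannot verify endpoint"):
            freeze_protocol(record, plan)

    def test_replay_reproduces_final_conversion_on_random_kinetics(self):
        rng = np.random.default_rng(42)
        for i in range(20):
            kobs = rng.uniform(0.015, 0.06)
            plan = self._monitored(kobs=kobs, sigma=0.002, seed=int(rng.integers(2**31)))
            record, protocol = run_campaign([plan], "monitor").inference
            assert record.stop_reason == "plateau"
            replayed = replay_static(protocol, plan, seed=int(rng.integers(2**31)))
            assert abs(replayed - protocol.final_conversion) <= plan.monitor.threshold


class TestIO:
    def test_spectrum_round_trip(self, tmp_path, single_peak_signature):
        from autokinetics import ConcentrationTrace, render_spectrum

        trace = ConcentrationTrace(
            times=np.array([3.0]), concentrations={"X": np.array([2.0])}
        )
        spec = render_spectrum(trace, 0, single_peak_signature(), np.arange(2, 3, 0.001))
        io.save_spectrum(spec, tmp_path / "s0.csv")
        back = io.load_spectrum(tmp_path / "s0.csv")
        assert np.allclose(back.x, spec.x) and np.allclose(back.y, spec.y)
        assert back.modality == "nmr" and back.timestamp == 3.0

    def test_network_yaml_round_trip(self, tmp_path):
        net = studies.tosylation_network(amine_order=0.46)
        io.network_to_yaml(net, tmp_path / "net.yaml")
        back = io.network_from_yaml(tmp_path / "net.yaml")
        assert back.species == net.species
        assert back.reactions[0].orders == {"ArNH2": 0.46}

    def test_signature_and_sigma_yaml_round_trips(self, tmp_path):
        sig = studies.tosylation_signature()
        io.signature_to_yaml(sig, tmp_path / "sig.yaml")
        back = io.signature_from_yaml(tmp_path / "sig.yaml")
        assert back.modality == "nmr"
        assert back.peaks["TsCl"][0].center == studies.TOSYL_CL_PEAK.center
        io.sigma_table_to_yaml(HANSCH_SIGMA, tmp_path / "sigma.yaml")
        assert io.sigma_table_from_yaml(tmp_path / "sigma.yaml") == HANSCH_SIGMA

    def test_directory_stream_feeds_monitor(self, tmp_path):
        from autokinetics import NoiseModel, render_spectrum, simulate_network

        net = studies.tosylation_network(k=2.5e-4, amine_order=1.0)
        times = np.arange(10) * 7.5
        trace = simulate_network(net, {"TsCl": 5.0, "ArNH2": 100.0, "TsNHAr": 0.0}, times)
        grid = studies.tosylation_grid()
        for i in range(10):
            spec = render_spectrum(trace, i, studies.tosylation_signature(), grid)
            io.save_spectrum(spec, tmp_path / f"spec_{i:03d}.csv")
        from autokinetics import run_monitor

        config = MonitorConfig(window=3, threshold=0.5, max_measurements=10)
        record = run_monitor(
            directory_stream(tmp_path), studies.tosylation_recipe(), config
        )
        assert record.stop_reason == "plateau"
        assert len(record.conversions) == 3
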