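from fractions import Fraction

import pytest

from catchn.bioenergetics import (
    EnergyConstants,
    PathwayDefinition,
    builtin_pathways,
    energy_budget,
    load_pathways,
    nadh_qh2_ratio,
    nitrogen_yield,
    table2_report,
)


@pytest.fixture(scope="module")
def pathways():
    return {p.name: p for p in builtin_pathways()}


class TestEnergyBudget:
    @pytest.mark.parametrize(
        "name,atp,h_influx,o2",
        [
            ("CATCH-N1", Fraction(14, 5), 56, -4),
            ("CATCH-N2", Fraction(8, 5), 52, -4),
            ("CATCH-N3", Fraction(-4, 5), 44, -3),
            ("CATCH-N4", Fraction(-2), 40, -3),
            ("TCA-malate", Fraction(-69, 25), Fraction(194, 5), Fraction(-14, 5)),
        ],
    )
    def test_reconciled_cycles_exact(self, pathways, name, atp, h_influx, o2):
        b = energy_budget(pathways[name])
        assert b.atp_net == atp
        assert b.h_influx_total == h_influx
        assert b.o2_consumed == o2

    def test_electron_conservation_succinate_cycles(self, pathways):
        # where the quinol column closes the balance, nitrogenase + oxidase
        # electrons account for every NADH electron pair plus quinol pairs
        for name in ("CATCH-N1", "CATCH-N2"):
            p = pathways[name]
            b = energy_budget(p)
            sourced = 2 * p.nadh_total + 2 * p.qh2_catabolic
            assert b.electrons_to_nitrogenase + b.electrons_to_oxidase == sourced

    def test_nitrogenase_only_cost(self):
        empty = PathwayDefinition(
            name="null", substrates={}, products={}, reaction_steps=0,
            nadh_total=Fraction(8), nadh_bifurcated=Fraction(8),
            qh2_catabolic=Fraction(0),
        )
        b = energy_budget(empty)
        # 8 bifurcated electrons reach the oxidase: 24 H+ -> 7.2 ATP - 16
        assert b.electrons_to_oxidase == 8
        assert b.atp_net == Fraction(-44, 5)

    def test_all_zero_pathway_is_pure_nitrogenase_cost(self):
        p = PathwayDefinition(
            name="zero", substrates={}, products={}, reaction_steps=0,
            nadh_total=Fraction(0), nadh_bifurcated=Fraction(0),
            qh2_catabolic=Fraction(0),
        )
        b = energy_budget(p)
        assert b.atp_net == -16
        assert not b.self_sufficient

    def test_sensitivity_directions(self, pathways):
        p = pathways["CATCH-N1"]
        base = energy_budget(p).atp_net
        import dataclasses

        more_h = dataclasses.replace(p, h_enzymatic=p.h_enzymatic + 1)
        more_slp = dataclasses.replace(
            p, substrate_level_atp=p.substrate_level_atp + 1
        )
        assert energy_budget(more_h).atp_net > base
        assert energy_budget(more_slp).atp_net > base
        pricier = EnergyConstants(
            atp_per_n2_nitrogenase=24, atp_per_fldhq=3
        )
        assert energy_budget(p, pricier).atp_net < base

    def test_constants_invariant_enforced(self):
        with pytest.raises(ValueError, match="nitrogenase"):
            EnergyConstants(atp_per_n2_nitrogenase=15)


class TestRatios:
    @pytest.mark.parametrize(
        "name,ratio",
        [
            ("CATCH-N1", Fraction(2)),
            ("CATCH-N2", Fraction(2)),
            ("TCA-malate", Fraction(5)),
            ("TCA-succinate", Fraction(5, 2)),
        ],
    )
    def test_nadh_qh2(self, pathways, name, ratio):
        assert nadh_qh2_ratio(pathways[name]) == ratio

    def test_no_quinol_raises(self):
        p = PathwayDefinition(
            name="x", substrates={}, products={}, reaction_steps=1,
            nadh_total=Fraction(8), nadh_bifurcated=Fraction(8),
            qh2_catabolic=Fraction(0),
        )
        with pytest.raises(ZeroDivisionError):
            nadh_qh2_ratio(p)


class TestNitrogenYield:
    def test_catchn1_two_alanine_three_ammonium(self, pathways):
        ny = nitrogen_yield(pathways["CATCH-N1"])
        assert ny.n_out_alanine == 2
        assert ny.n_out_ammonium == 3
        assert ny.n_yield_per_arginine == 5
        assert ny.pct_vs_classical == 25
        # conservation
        assert ny.n_in_organic + ny.n_fixed == ny.n_out_alanine + ny.n_out_ammonium

    def test_classical_reference_is_zero_gain(self, pathways):
        import dataclasses

        p = dataclasses.replace(
            pathways["CATCH-N1"], nadh_bifurcated=Fraction(0),
            nadh_total=Fraction(0), transaminations_per_arginine=0,
        )
        ny = nitrogen_yield(p)
        assert ny.n_yield_per_arginine == 4
        assert ny.pct_vs_classical == 0

    def test_scale_invariance(self, pathways):
        import dataclasses

        p = pathways["CATCH-N1"]
        doubled = dataclasses.replace(
            p,
            substrates={k: 2 * v for k, v in p.substrates.items()},
            products={k: 2 * v for k, v in p.products.items()},
            nadh_total=2 * p.nadh_total,
            nadh_bifurcated=2 * p.nadh_bifurcated,
            qh2_catabolic=2 * p.qh2_catabolic,
        )
        assert nitrogen_yield(doubled).pct_vs_classical == 25

    def test_pathway_without_arginine_rejected(self, pathways):
        with pytest.raises(ValueError, match="arginine"):
            nitrogen_yield(pathways["TCA-malate"])


class TestReport:
    def test_six_rows_with_printed_strings(self, pathways):
        table = table2_report(pathways.values())
        assert len(table) == 6
        row = table.set_index("pathway").loc["CATCH-N1"]
        assert row["atp_net_gain"] == "2.80"
        assert row["influx_h"] == "56 (48 + 8)"
        assert row["o2_per_n2"] == "-4"
        row4 = table.set_index("pathway").loc["CATCH-N4"]
        assert row4["atp_net_gain"] == "-2.00"
        tca = table.set_index("pathway").loc["TCA-malate"]
        assert tca["atp_net_gain"] == "-2.76"
        assert tca["influx_h"] == "38.8 (33.6 + 5.2)"

    def test_non_reconciled_flag_survives_yaml(self, pathways):
        assert pathways["TCA-succinate"].non_reconciled
        assert not pathways["CATCH-N1"].non_reconciled

    def test_empty_pathway_list_header_only(self):
        table = table2_report([])
        assert len(table) == 0
        assert "atp_net_gain" in table.columns

    def test_yaml_round_trip_via_custom_file(self, tmp_path):
        src = builtin_pathways()
        # re-serialise a subset and reload
        import yaml

        entries = [
            {
                "name": "copy",
                "substrates": {"arginine": 2, "succinate": 2},
                "products": {"alanine": 2},
                "reaction_steps": 9,
                "nadh_total": 8,
                "nadh_bifurcated": 8,
                "qh2_catabolic": 4,
                "h_enzymatic": 8,
                "substrate_level_atp": 2,
            }
        ]
        p = tmp_path / "pw.yaml"
        p.write_text(yaml.safe_dump(entries))
        loaded = load_pathways(p)[0]
        assert energy_budget(loaded).atp_net == energy_budget(src[0]).atp_net
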