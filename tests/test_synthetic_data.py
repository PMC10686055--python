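"""Synthetic fermentation generator: contracts the analysis relies on."""

import numpy as np
import pandas as pd
import pytest

import pepferm as pf
from pepferm.media import theoretical_co2_max
from pepferm.synthetic_data import (
    DEFAULT_SCHEDULE,
    STRAIN_TRANSPORTERS,
    GenotypeProfile,
    load_params,
)


def cfg_for(strain, medium, noise=0.0, seed=0):
    return pf.scenario(strain, medium, noise_sigma=noise, seed=seed)


class TestSchedule:
    def test_default_sampling_grid(self):
        assert DEFAULT_SCHEDULE[:9] == tuple(range(0, 49, 6))
        assert DEFAULT_SCHEDULE[9:13] == (60, 72, 84, 96)
        assert DEFAULT_SCHEDULE[13:] == (120, 144, 168, 240, 288)


class TestDeterminism:
    def test_identical_seed_bit_identical(self, media):
        a = pf.simulate_dataset(cfg_for("59A", media["P200"], noise=0.05, seed=42))
        b = pf.simulate_dataset(cfg_for("59A", media["P200"], noise=0.05, seed=42))
        for key in ("peptides", "od", "co2", "ct"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_different_seeds_differ(self, media):
        a = pf.simulate_dataset(cfg_for("59A", media["P200"], noise=0.05, seed=1))
        b = pf.simulate_dataset(cfg_for("59A", media["P200"], noise=0.05, seed=2))
        assert not np.allclose(a["od"].od600, b["od"].od600)


class TestPeptideSeries:
    def test_pepko_flat_at_100(self, media):
        series = pf.simulate_peptide_series(cfg_for("PepKO", media["P200"]))
        for s in series:
            if s.kind == "peptide":
                assert np.allclose(s.abundance, 100.0)

    def test_fot_only_depletes_short_lengths(self, media):
        series = pf.simulate_peptide_series(cfg_for("Fot1", media["P200"]))
        for s in series:
            if s.kind != "peptide" or s.analyte_id == "pep2_PP":
                continue
            level = pf.score_series(s).level
            assert level == (4 if s.length <= 4 else 0)

    def test_closed_form_depletion(self, media):
        profile = GenotypeProfile(
            strain="custom", transporters=frozenset({"FOT1"}),
            uptake={L: (0.1, 0.0) for L in range(2, 8)},
        )
        cfg = pf.ScenarioConfig(medium=media["P200"], genotype=profile,
                                noise_sigma=0.0, seed=0)
        s = next(x for x in pf.simulate_peptide_series(cfg)
                 if x.kind == "peptide" and x.analyte_id != "pep2_PP")
        at24 = s.abundance[list(s.times).index(24.0)]
        assert at24 == pytest.approx(100 * np.exp(-2.4), rel=1e-9)  # ~9.07

    def test_pp_control_inert_for_every_genotype(self, media):
        for strain in STRAIN_TRANSPORTERS:
            series = pf.simulate_peptide_series(cfg_for(strain, media["P200"]))
            pp = next(s for s in series if s.analyte_id == "pep2_PP")
            assert np.allclose(pp.abundance, 100.0)

    def test_panel_composition_matches_fixture(self, media):
        params = load_params()
        series = pf.simulate_peptide_series(cfg_for("59A", media["P200"]))
        counts = {}
        for s in series:
            key = 1 if s.kind == "free_amino_acid" else s.length
            counts[key] = counts.get(key, 0) + 1
        assert counts[1] == params["panel"]["n_faa"]
        assert counts[2] == params["panel"]["peptides"][2] == 19
        assert counts[3] == params["panel"]["peptides"][3] == 29

    def test_starts_at_100_even_with_noise(self, media):
        series = pf.simulate_peptide_series(cfg_for("59A", media["P200"],
                                                    noise=0.05, seed=5))
        assert all(s.abundance[0] == 100.0 for s in series)

    def test_opt2_delayed_by_preferred_nitrogen_with_other_transporters(self, media):
        alone = pf.scenario("Opt2", media["NAP200"]).genotype.uptake[5]
        with_others = pf.scenario("fot1fot2", media["NAP200"]).genotype.uptake[5]
        no_ammonium = pf.scenario("fot1fot2", media["P200"]).genotype.uptake[5]
        assert with_others[1] > alone[1]
        assert no_ammonium[1] == alone[1]


class TestGrowthAndCO2:
    def test_noiseless_co2_monotone_below_theoretical_max(self, media):
        _, co2 = pf.simulate_growth_and_co2(cfg_for("59A", media["P200"]))
        assert np.all(np.diff(co2.co2_g) >= 0)
        assert co2.co2_g[-1] <= theoretical_co2_max(media["P200"]) + 1e-9

    @pytest.mark.parametrize("strain", ["PepKO", "Opt1"])
    def test_no_peptide_access_never_attenuates_on_p200(self, media, strain):
        _, co2 = pf.simulate_growth_and_co2(cfg_for(strain, media["P200"]))
        assert pf.attenuation_time(co2, media["P200"]) is None

    def test_peptide_access_shortens_t80(self, media):
        _, co2_na = pf.simulate_growth_and_co2(cfg_for("59A", media["NA100"]))
        _, co2_nap = pf.simulate_growth_and_co2(cfg_for("59A", media["NAP200"]))
        t_na = pf.attenuation_time(co2_na, media["NA100"])
        t_nap = pf.attenuation_time(co2_nap, media["NAP200"])
        assert t_nap < t_na

    def test_non_consumer_k_similar_across_na100_nap200(self, media):
        ks = []
        for med in ("NA100", "NAP200"):
            growth, _ = pf.simulate_growth_and_co2(cfg_for("PepKO", media[med]))
            ks.append(max(growth.od))
        assert abs(ks[0] - ks[1]) / ks[0] < 0.05

    def test_accessible_nitrogen_monotone(self, media):
        for strain in ("59A", "Fot1", "Opt2", "PepKO"):
            g_na = pf.scenario(strain, media["NA100"]).genotype
            g_nap = pf.scenario(strain, media["NAP200"]).genotype
            assert g_nap.accessible_nitrogen(media["NAP200"]) >= \
                g_na.accessible_nitrogen(media["NA100"])


class TestCtTable:
    def test_expression_higher_at_48h(self, media):
        ct = pf.simulate_ct_table(cfg_for("59A", media["P200"], seed=9))
        expr = pf.normalize_to_act1(ct)
        for gene, sub in expr.groupby("gene"):
            by_time = sub.set_index("time_h").normalized_expression
            assert by_time[18] < by_time[48]
            assert by_time[18] < 0.7

    def test_opt1_induced_under_sulfate_limitation(self, media):
        def opt1_at_48(medium):
            ct = pf.simulate_ct_table(cfg_for("59A", medium, seed=9))
            expr = pf.normalize_to_act1(ct)
            return expr[(expr.gene == "OPT1") & (expr.time_h == 48)] \
                .normalized_expression.iloc[0]
        assert opt1_at_48(media["P200-SO4"]) > opt1_at_48(media["P200"])

    def test_act1_reference_is_unity(self, media):
        ct = pf.simulate_ct_table(cfg_for("59A", media["P200"]))
        # with zero noise ACT1-vs-ACT1 is exactly Ct 20, expression 1
        assert np.allclose(ct[ct.gene == "ACT1"].ct, 20.0)

    def test_only_genotype_genes_reported(self, media):
        ct = pf.simulate_ct_table(cfg_for("Fot1", media["P200"]))
        assert set(ct.gene) == {"ACT1", "FOT1"}
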