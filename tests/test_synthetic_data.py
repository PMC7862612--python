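"""Generator correctness: seeded determinism, factorial structure, moments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leukotox import (EffectParameters, ExperimentDesign, QpcrTruth,
                      ViabilityTruth, simulate_assay, simulate_qpcr,
                      simulate_viability)


class TestDesignValidation:
    def test_rejects_nonzero_first_concentration(self):
        with pytest.raises(ValueError, match="control"):
            ExperimentDesign(fish_ids=("F1",), concentrations=(1.0, 5.0))

    def test_rejects_unordered_concentrations(self):
        with pytest.raises(ValueError, match="increasing"):
            ExperimentDesign(fish_ids=("F1",), concentrations=(0.0, 5.0, 1.0))

    def test_rejects_empty_fish(self):
        with pytest.raises(ValueError, match="fish"):
            ExperimentDesign(fish_ids=(), concentrations=(0.0, 1.0))

    def test_rejects_nonzero_reference_fish_effect(self, design6):
        params = EffectParameters(fish_effects={"F1": 1.0})
        with pytest.raises(ValueError, match="reference fish"):
            simulate_assay(design6, params, seed=0)

    def test_rejects_concentration_key_outside_grid(self, design6):
        params = EffectParameters(conc_effects={7.0: 1.0})
        with pytest.raises(ValueError, match="7"):
            simulate_assay(design6, params, seed=0)


class TestAssayGenerator:
    def test_noise_free_wells_equal_linear_predictor(self, design6,
                                                     noise_free):
        df = simulate_assay(design6, noise_free, seed=3)
        expected = [noise_free.linear_predictor(r.fish_id, r.time, r.lps,
                                                r.concentration)
                    for r in df.itertuples()]
        np.testing.assert_array_equal(df["value"].to_numpy(),
                                      np.array(expected))

    def test_design_completeness_row_count(self, design6, rich_params):
        df = simulate_assay(design6, rich_params, seed=1)
        assert len(df) == 6 * 2 * 2 * 4 * 3 == design6.n_wells
        cells = df.groupby(["fish_id", "time", "lps", "concentration"]).size()
        assert (cells == design6.n_technical).all()

    def test_seeded_determinism(self, design6, rich_params):
        a = simulate_assay(design6, rich_params, seed=42)
        b = simulate_assay(design6, rich_params, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_assay(design6, rich_params, seed=43)
        assert not a["value"].equals(c["value"])

    def test_residual_sd_recovered_from_many_cells(self):
        # 10,000 wells at a single treatment via 10,000 fish, one well each:
        # each cell draws its own biological residual, so the sample SD
        # estimates residual_sd.
        n = 10_000
        design = ExperimentDesign(
            fish_ids=tuple(f"F{i}" for i in range(n)),
            concentrations=(0.0,), n_technical=1,
            time_points=("3h",), lps_levels=("no",))
        params = EffectParameters(intercept=5.0, residual_sd=1.0,
                                  technical_sd=0.0)
        df = simulate_assay(design, params, seed=11)
        sd = df["value"].std()
        mc_se = 1.0 / np.sqrt(2 * (n - 1))   # SE of a Gaussian sample SD
        assert abs(sd - 1.0) < 3 * mc_se

    def test_cell_means_converge_to_linear_predictor(self):
        # moment fidelity at n_technical = 1000: cell mean is predictor +
        # biological residual + technical mean, within 4 SEs of predictor
        design = ExperimentDesign(fish_ids=("F1", "F2"),
                                  concentrations=(0.0, 1.0, 5.0, 10.0),
                                  n_technical=1000)
        params = EffectParameters(
            intercept=2.0, fish_effects={"F2": 0.4}, time_effect=0.8,
            lps_effect=1.2, conc_effects={1.0: -0.1, 5.0: -0.5, 10.0: -1.0},
            time_lps_interaction=0.4,
            lps_conc_interactions={1.0: 0.05, 5.0: -0.2, 10.0: -0.45},
            residual_sd=1.0, technical_sd=0.5)
        df = simulate_assay(design, params, seed=5)
        se = np.sqrt(params.residual_sd ** 2
                     + params.technical_sd ** 2 / 1000)
        for (fish, time, lps, conc), grp in df.groupby(
                ["fish_id", "time", "lps", "concentration"]):
            mu = params.linear_predictor(fish, time, lps, conc)
            assert abs(grp["value"].mean() - mu) < 4 * se

    def test_blank_wells_appended_on_request(self, design6, noise_free):
        df = simulate_assay(design6, noise_free, seed=0, n_blank_wells=3,
                            blank_mean=2.0)
        blanks = df[df["role"] == "blank"]
        assert len(blanks) == 3
        assert (blanks["value"] == 2.0).all()


class TestViabilityGenerator:
    @pytest.mark.parametrize("conc,expected", [
        (0.0, 1.0),            # control sits at top
        (10.0, 0.5),           # half-maximal at ec50
        (40.0, 0.2),           # closed-form 1/(1 + 40/10)
    ])
    def test_hill_curve_values(self, conc, expected):
        truth = ViabilityTruth(ec50=10.0, hill=1.0, top=1.0, noise_sd=0.0)
        assert truth.viability(conc) == pytest.approx(expected)

    def test_noise_free_table_matches_hill(self, design6):
        truth = ViabilityTruth(ec50=5.0, hill=2.0, noise_sd=0.0)
        df = simulate_viability(design6, truth, seed=1)
        ratio = df["calcein"] / df["dapi"]
        viab = ratio / ratio[df["concentration"] == 0].iloc[0]
        expected = df["concentration"].map(truth.viability)
        np.testing.assert_allclose(viab, expected, rtol=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ViabilityTruth(ec50=10.0).viability(-1.0)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            ViabilityTruth(ec50=-1.0)
        with pytest.raises(ValueError):
            ViabilityTruth(ec50=1.0, hill=0.0)


class TestQpcrGenerator:
    def test_protocol_levels_only_by_default(self, design6):
        truth = QpcrTruth()
        df = simulate_qpcr(design6, truth, seed=2)
        assert set(df["concentration"]) == {0.0, 10.0}
        # two duplicates per sample x gene
        dups = df.groupby(["sample_id", "gene"]).size()
        assert (dups == 2).all()

    def test_ct_values_within_cycle_window(self, design6):
        df = simulate_qpcr(design6, QpcrTruth(), seed=2)
        assert ((df["ct"] > 0) & (df["ct"] <= 45)).all()

    def test_out_of_window_parameters_rejected(self, design6):
        with pytest.raises(ValueError, match="45"):
            simulate_qpcr(design6, QpcrTruth(ref_ct_mean=44.0), seed=0)

    def test_seeded_determinism(self, design6):
        truth = QpcrTruth(treatment_shift={"IL-1b": -2.0})
        a = simulate_qpcr(design6, truth, seed=9)
        b = simulate_qpcr(design6, truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_reference_gene_cannot_be_target(self):
        with pytest.raises(ValueError):
            QpcrTruth(delta_ct_control={"EF-1a": 0.0})


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_generators_are_deterministic_in_seed(seed):
    design = ExperimentDesign(fish_ids=("F1", "F2"),
                              concentrations=(0.0, 2.0), n_technical=2)
    params = EffectParameters(residual_sd=0.7, technical_sd=0.3)
    pd.testing.assert_frame_equal(simulate_assay(design, params, seed),
                                  simulate_assay(design, params, seed))
    truth = ViabilityTruth(ec50=3.0, noise_sd=0.1)
    pd.testing.assert_frame_equal(simulate_viability(design, truth, seed),
                                  simulate_viability(design, truth, seed))
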