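"""Generator ground truth: electron conservation, anchors, determinism."""

import numpy as np
import pytest

from ferracet import generate_culture, preset
from ferracet.kinetics import fe2_production_rate, final_accumulation
from ferracet.stoichiometry import acetate_deficit_electrons, diversion_efficiency
from ferracet.synthetic import (
    PRESETS,
    SyntheticCultureConfig,
    generate_proteome,
    write_proteome,
)


def test_presets_cover_species_and_conditions():
    names = set(PRESETS)
    for sp in ("gt1", "sphaeroides", "ovata", "woodii"):
        assert f"{sp}-organo" in names
        assert f"{sp}-litho" in names
    assert "gt1-dialysis" in names
    assert PRESETS["gt1-dialysis"].volume_mL == 120.0


def test_no_diversion_means_three_halves_acetate():
    cfg = preset("gt1-organo")
    cfg = SyntheticCultureConfig(**{**vars(cfg), "f_div": 0.0, "name": "nodiv"})
    sim = generate_culture(cfg)
    for s in sim.treatment:
        consumed = cfg.ethanol_mM - s.ethanol_mM
        np.testing.assert_allclose(s.acetate_mM, 1.5 * consumed, atol=1e-12)
        assert np.all(s.fe2_total_mM == 0.0)


def test_electron_conservation_noiseless():
    cfg = preset("gt1-organo")
    sim = generate_culture(cfg)
    treat, ctrl = sim.treatment[0], sim.control[0]
    consumed = cfg.ethanol_mM - treat.ethanol_mM
    electrons = 4.0 * consumed
    # 8 x acetate deficit equals the diverted electrons at every timepoint
    np.testing.assert_allclose(
        8.0 * (ctrl.acetate_mM - treat.acetate_mM), cfg.f_div * electrons, atol=1e-12
    )
    # Fe(II) electrons are exactly f_fe of the diverted electrons
    np.testing.assert_allclose(
        treat.fe2_total_mM, cfg.f_fe * cfg.f_div * electrons, atol=1e-12
    )


def test_gt1_organo_anchors():
    """The preset reproduces the measured electron budget of the GT1 culture."""
    sim = generate_culture(preset("gt1-organo"))
    truth = sim.truth
    assert truth.fe2_plateau_mM == pytest.approx(2.9, abs=1e-9)
    assert truth.acetate_deficit_umol == pytest.approx(31.0, abs=1e-9)
    assert truth.diverted_electrons_umol == pytest.approx(248.0, abs=1e-9)
    assert truth.fe2_electrons_umol == pytest.approx(58.0, abs=1e-9)
    # measured series agree with the declared truth
    treat, ctrl = sim.treatment[0], sim.control[0]
    deficit = acetate_deficit_electrons(
        ctrl.acetate_mM[-1] * 20.0, treat.acetate_mM[-1] * 20.0
    )
    assert deficit.electrons == pytest.approx(248.0, abs=1e-9)
    assert diversion_efficiency(58.0, deficit.electrons) == pytest.approx(
        58.0 / 248.0, abs=1e-12
    )


def test_pipeline_closure_all_presets():
    """Kinetics on noiseless output returns the configured rate and plateau."""
    for name, cfg in PRESETS.items():
        sim = generate_culture(cfg)
        s = sim.treatment[0]
        est = fe2_production_rate(s)
        assert est.slope_mM_per_day == pytest.approx(cfg.fe2_rate_mM_per_day, rel=1e-9), name
        assert final_accumulation(s) == pytest.approx(cfg.fe2_plateau_mM, rel=1e-9), name


def test_same_seed_identical_output():
    a = generate_culture(preset("gt1-organo", noise_sd_mM=0.1, cell_noise_cv=0.1, seed=42))
    b = generate_culture(preset("gt1-organo", noise_sd_mM=0.1, cell_noise_cv=0.1, seed=42))
    for sa, sb in zip(a.treatment + a.control, b.treatment + b.control):
        np.testing.assert_array_equal(sa.acetate_mM, sb.acetate_mM)
        np.testing.assert_array_equal(sa.fe2_total_mM, sb.fe2_total_mM)
        np.testing.assert_array_equal(sa.cell_density, sb.cell_density)


def test_different_seed_differs():
    a = generate_culture(preset("gt1-organo", noise_sd_mM=0.1, seed=1))
    b = generate_culture(preset("gt1-organo", noise_sd_mM=0.1, seed=2))
    assert not np.array_equal(a.treatment[0].fe2_total_mM, b.treatment[0].fe2_total_mM)


def test_fe_cap_warns():
    cfg = preset("gt1-organo")
    cfg = SyntheticCultureConfig(
        **{**vars(cfg), "f_div": 1.0, "f_fe": 1.0, "fe3_initial_mM": 9.0, "name": "cap"}
    )
    with pytest.warns(UserWarning, match="capping"):
        sim = generate_culture(cfg)
    assert np.max(sim.treatment[0].fe2_total_mM) == pytest.approx(9.0)


def test_diversion_fraction_bounds_enforced():
    cfg = preset("gt1-organo")
    with pytest.raises(ValueError):
        SyntheticCultureConfig(**{**vars(cfg), "f_div": 1.5})


def test_parameter_recovery_under_noise():
    """Noisy replicates: mean rate within 2%, diversion efficiency within 5%."""
    rates, efficiencies = [], []
    for i in range(200):
        sim = generate_culture(
            preset("gt1-organo", noise_sd_mM=0.1, seed=20_000 + i)
        )
        vol = sim.config.volume_mL
        for treat, ctrl in zip(sim.treatment, sim.control):
            rates.append(fe2_production_rate(treat).slope_mM_per_day)
            deficit = acetate_deficit_electrons(
                ctrl.acetate_mM[-1] * vol, treat.acetate_mM[-1] * vol
            )
            if deficit.electrons > 0:
                efficiencies.append(
                    diversion_efficiency(final_accumulation(treat) * vol, deficit.electrons)
                )
    assert np.mean(rates) == pytest.approx(0.47, rel=0.02)
    assert np.mean(efficiencies) == pytest.approx(58.0 / 248.0, rel=0.05)


class TestProteomeGenerator:
    def test_planted_counts_and_decoys(self):
        records, truth = generate_proteome(50, [("CxxCH", 2), ("CxxCH", 6)], seed=0)
        assert len(records) == 52
        assert set(truth["planted_count"]) == {0, 2, 6}

    def test_zero_everything_is_empty(self, tmp_path):
        records, truth = generate_proteome(0, [], seed=0)
        assert records == []
        path = tmp_path / "empty.faa"
        write_proteome(records, path)
        assert path.read_text() == ""

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.faa", tmp_path / "b.faa"
        for p in (p1, p2):
            records, _ = generate_proteome(30, [("CxxxCH", 3)], seed=123)
            write_proteome(records, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_infeasible_plant_errors(self):
        with pytest.raises(ValueError, match="cannot plant"):
            generate_proteome(0, [("CxxCH", 1000)], seed=0, max_protein_length=100)

    def test_ids_encode_nothing(self):
        records, truth = generate_proteome(10, [("CxxCH", 5)], seed=7)
        assert all(rid.startswith("prot_") for rid, _ in records)
        planted_id = truth.loc[truth["planted_count"] == 5, "protein_id"].iloc[0]
        # the planted protein is not systematically first or last
        ids = [rid for rid, _ in records]
        assert planted_id in ids
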