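import numpy as np
import pytest
from scipy import stats as sps

from sorgspec import (
    AnalyteStats,
    EffectModel,
    StudyConfig,
    default_band_library,
    default_grid,
    draw_concentrations,
    fit_pls,
    msc,
    r_squared,
    render_spectra,
    simulate_full_study,
    simulate_study,
    write_reference,
    write_spectra,
)
from sorgspec.io import ANALYTES
from sorgspec.synthesis import HULLED_STATS, POOLED_STATS


def test_draw_concentrations_matches_configured_moments():
    n = 10_000
    ref = draw_concentrations(n, POOLED_STATS, seed=42)
    for analyte in ANALYTES:
        s = POOLED_STATS[analyte]
        values = ref.column(analyte)
        # within 2% of the configured mean...
        assert abs(values.mean() - s.mean) / s.mean < 0.02
        # ...and within ~3 standard errors of the configured moments
        assert abs(values.mean() - s.mean) < 3 * s.sd / np.sqrt(n)
        assert abs(values.std(ddof=1) - s.sd) < 3 * s.sd / np.sqrt(2 * n)
        assert values.min() >= s.min and values.max() <= s.max


def test_draw_concentrations_degenerate_sd_and_reproducibility():
    stats = {a: AnalyteStats(s.mean, 1e-9, s.min, s.max) for a, s in POOLED_STATS.items()}
    ref = draw_concentrations(50, stats, seed=3)
    for analyte in ANALYTES:
        np.testing.assert_allclose(ref.column(analyte), POOLED_STATS[analyte].mean,
                                   rtol=1e-6)
    a = draw_concentrations(20, POOLED_STATS, seed=99)
    b = draw_concentrations(20, POOLED_STATS, seed=99)
    np.testing.assert_array_equal(a.analytes.to_numpy(), b.analytes.to_numpy())


def test_analyte_stats_validation():
    with pytest.raises(ValueError):
        AnalyteStats(mean=10, sd=1, min=20, max=5)
    with pytest.raises(ValueError):
        AnalyteStats(mean=10, sd=0, min=5, max=20)


def test_render_linearity_origin_and_homogeneity(toy_library):
    import pandas as pd

    from sorgspec.io import ReferenceChemistry

    zeros = ReferenceChemistry(
        ["Z1", "Z2"], pd.DataFrame(np.zeros((2, 8)), columns=list(ANALYTES))
    )
    quiet = EffectModel(scatter_spread=0, offset_sd=0, tilt_sd=0, noise_sd=0)
    out = render_spectra(zeros, toy_library, quiet, seed=0)
    np.testing.assert_array_equal(out.absorbance, 0.0)

    conc = draw_concentrations(3, POOLED_STATS, seed=5)
    single = render_spectra(conc, toy_library, quiet, seed=0)
    doubled_conc = ReferenceChemistry(conc.sample_ids, conc.analytes * 2.0)
    doubled = render_spectra(doubled_conc, toy_library, quiet, seed=0)
    np.testing.assert_allclose(doubled.absorbance, 2.0 * single.absorbance, rtol=1e-12)


def test_render_affine_construction(toy_library):
    conc = draw_concentrations(4, POOLED_STATS, seed=6)
    clean = toy_library.mixture(conc.analytes.to_numpy())
    quiet = EffectModel(scatter_spread=0, offset_sd=0, tilt_sd=0, noise_sd=0)
    base = render_spectra(conc, toy_library, quiet, seed=0).absorbance
    np.testing.assert_allclose(base, clean, rtol=1e-12)
    shifted = 2.0 * clean + 0.1  # b=2, a=0.1 exactly
    np.testing.assert_allclose(shifted, 2.0 * base + 0.1)


def test_simulate_study_default_shape_and_grading_partition():
    ds = simulate_study()
    assert ds.n_samples == 98
    assert ds.spectra.n_wavelengths == 1557
    assert ds.spectra.wavenumbers[0] == 4000.0 and ds.spectra.wavenumbers[-1] == 10000.0
    labels = ds.reference.grade
    assert labels is not None and len(labels) == 98
    assert set(labels) <= {"food", "feed", "fuel", "feed_fuel"}


def test_simulate_study_csv_reproducibility(tmp_path):
    cfg = StudyConfig(seed=21)
    for tag in ("a", "b"):
        ds = simulate_study(cfg)
        write_spectra(ds.spectra, tmp_path / f"{tag}_spec.csv")
        write_reference(ds.reference, tmp_path / f"{tag}_ref.csv")
    assert (tmp_path / "a_spec.csv").read_bytes() == (tmp_path / "b_spec.csv").read_bytes()
    assert (tmp_path / "a_ref.csv").read_bytes() == (tmp_path / "b_ref.csv").read_bytes()


def test_simulate_study_too_small_raises():
    with pytest.raises(ValueError):
        simulate_study(StudyConfig(n_hulled=4, n_hull_less=3))


def test_format_subsets_match_study_counts():
    datasets = simulate_full_study(StudyConfig(seed=2))
    assert datasets["whole_grain"].n_samples == 98
    assert datasets["whole_grain_flour"].n_samples == 98
    assert datasets["hulled_flour"].n_samples == 61
    assert datasets["hull_less_flour"].n_samples == 37


def test_noise_free_forward_model_is_exactly_low_rank():
    """With no noise and fixed scatter, 8 latent variables give R^2 = 1."""
    quiet = EffectModel(scatter_spread=0, offset_sd=0, tilt_sd=0, noise_sd=0)
    ds = simulate_study(StudyConfig(seed=4, effects=quiet, scan_format="whole_grain"))
    X = ds.spectra.absorbance
    y = ds.reference.column("protein")
    cal, val = np.arange(0, 70), np.arange(70, 98)
    model = fit_pls(X[cal], y[cal], n_lv=len(ANALYTES))
    assert r_squared(y[val], model.predict(X[val])) == pytest.approx(1.0, abs=1e-10)


def test_msc_restores_multiplicative_additive_perturbations():
    """Scatter/offset effects on one common mixture are removed by MSC."""
    import pandas as pd

    from sorgspec.io import ReferenceChemistry

    library = default_band_library()
    row = np.array([[POOLED_STATS[a].mean for a in ANALYTES]] * 30)
    conc = ReferenceChemistry(
        [f"R{i}" for i in range(30)], pd.DataFrame(row, columns=list(ANALYTES))
    )
    effects = EffectModel(scatter_spread=0.2, offset_sd=0.05, tilt_sd=0, noise_sd=0)
    spectra = render_spectra(conc, library, effects, seed=9).absorbance
    corrected = msc(spectra)
    spread = corrected.max(axis=0) - corrected.min(axis=0)
    assert spread.max() < 1e-8
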