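"""Ground-truth generators: exactness, determinism and error handling."""

import numpy as np
import pytest

from pelletcoat import doe, powder
from pelletcoat.synthetic import (
    ImageGroundTruth,
    SimulationSpec,
    gen_doe_response,
    gen_pellet_image,
    gen_pile_silhouette,
    gen_release_profile,
    gen_size_distribution,
)


# ------------------------------------------------------------ pellet images

def test_image_coated_budget_exact_to_one_pixel():
    for frac in (0.0, 0.37, 0.5, 1.0):
        img = gen_pellet_image(ImageGroundTruth(frac, n_pellets=10, seed=1))
        total = img.pellet_mask.sum()
        assert abs(img.coated_mask.sum() - frac * total) <= 1
        assert img.ground_truth == frac


def test_image_degenerate_fractions_have_pure_paint():
    from pelletcoat.imaging import classify_pixels, COATED

    none = gen_pellet_image(ImageGroundTruth(0.0, seed=2))
    assert not (classify_pixels(none.pixels) == COATED).any()
    full = gen_pellet_image(ImageGroundTruth(1.0, seed=2))
    labels = classify_pixels(full.pixels)
    assert ((labels == COATED) == full.pellet_mask).all()


def test_image_generator_deterministic_under_seed():
    a = gen_pellet_image(ImageGroundTruth(0.5, noise_sd=0.03, seed=42))
    b = gen_pellet_image(ImageGroundTruth(0.5, noise_sd=0.03, seed=42))
    assert np.array_equal(a.pixels, b.pixels)
    c = gen_pellet_image(ImageGroundTruth(0.5, noise_sd=0.03, seed=43))
    assert not np.array_equal(a.pixels, c.pixels)


def test_image_infeasible_packing_raises():
    with pytest.raises(ValueError, match="overlap"):
        gen_pellet_image(
            ImageGroundTruth(0.5, n_pellets=60, pellet_radius_px=20,
                             image_size=(128, 128), seed=0)
        )


def test_image_ground_truth_validation():
    with pytest.raises(ValueError):
        ImageGroundTruth(coated_fraction=1.2)
    with pytest.raises(ValueError):
        ImageGroundTruth(coated_fraction=0.5, n_pellets=0)
    with pytest.raises(ValueError):
        ImageGroundTruth(coated_fraction=0.5, noise_sd=-0.1)


# ----------------------------------------------------------- design tables

def test_doe_response_noise_free_equals_model_evaluation(
    design_table, reference_coefficients
):
    spec = SimulationSpec(reference_coefficients, noise_sd=0.0)
    table = gen_doe_response(design_table.drop(columns="coated_surface_pct"), spec)
    run7 = table.loc[table["run_id"] == 7, "coated_surface_pct"].item()
    assert run7 == pytest.approx(19.96, abs=1e-9)
    # every run equals the term-by-term model evaluation
    model = doe.CodedModel.from_coefficients(reference_coefficients)
    for row in table.itertuples():
        expected = doe.predict(
            model, (row.polymer, row.concentration_pct, row.ratio))
        assert row.coated_surface_pct == pytest.approx(expected, abs=1e-9)


def test_doe_response_zero_coefficients_constant_zero(design_table):
    table = gen_doe_response(
        design_table.drop(columns="coated_surface_pct"),
        SimulationSpec({}, noise_sd=0.0),
    )
    assert (table["coated_surface_pct"] == 0.0).all()


def test_doe_response_rejects_unknown_terms():
    with pytest.raises(ValueError, match="unknown model terms"):
        SimulationSpec({"D1": 1.0})


def test_doe_response_clamped_and_seeded(design_table, reference_coefficients):
    base = design_table.drop(columns="coated_surface_pct")
    spec = SimulationSpec(reference_coefficients, noise_sd=30.0, seed=5)
    a = gen_doe_response(base, spec)
    b = gen_doe_response(base, spec)
    assert a["coated_surface_pct"].tolist() == b["coated_surface_pct"].tolist()
    assert a["coated_surface_pct"].between(0, 100).all()


def test_doe_intercept_recovery_over_replicates(
    design_table, reference_coefficients
):
    """Monte-Carlo: mean fitted intercept near the generating value."""
    base = design_table.drop(columns="coated_surface_pct")
    intercepts = []
    for seed in range(200):
        spec = SimulationSpec(reference_coefficients, noise_sd=5.0, seed=seed)
        fit = doe.fit_model(gen_doe_response(base, spec))
        intercepts.append(fit.coefficients["intercept"])
    # sampling error of the mean ~ 5/sqrt(200) ~ 0.35 before design effects
    assert np.mean(intercepts) == pytest.approx(
        reference_coefficients["intercept"], abs=0.5)


# --------------------------------------------------------- release profiles

def test_release_profile_flat_zero_and_burst_limit():
    t = np.array([0.0, 10.0, 20.0])
    flat = gen_release_profile(t, f_burst=0, k_per_min=0, plateau=0)
    assert np.array_equal(flat.cumulative_pct, np.zeros(3))
    fast = gen_release_profile(t, f_burst=20, k_per_min=1e6, plateau=60)
    assert fast.cumulative_pct[0] == pytest.approx(20.0)
    assert fast.cumulative_pct[1:] == pytest.approx([80.0, 80.0])


def test_release_profile_monotone_after_noise():
    t = np.linspace(1, 120, 24)
    prof = gen_release_profile(t, 10, 0.05, 70, noise_sd=5.0, seed=3)
    assert (np.diff(prof.cumulative_pct) >= 0).all()


def test_release_profile_validation():
    with pytest.raises(ValueError, match="increasing"):
        gen_release_profile([1.0, 1.0], 0, 0.1, 50)
    with pytest.raises(ValueError, match="rate"):
        gen_release_profile([1.0, 2.0], 0, -0.1, 50)
    with pytest.raises(ValueError, match="100"):
        gen_release_profile([1.0, 2.0], 60, 0.1, 60)


# ------------------------------------------------------- size distributions

def test_size_distribution_normalized_and_ordered():
    dist = gen_size_distribution(4.59, gsd=1.5)
    assert dist.volume_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(dist.bin_centers_um) > 0).all()


def test_size_distribution_monodisperse_limit():
    dist = gen_size_distribution(4.59, gsd=1.0001, n_bins=201)
    assert powder.d43(dist) == pytest.approx(4.59, rel=1e-3)
    assert powder.d32(dist) == pytest.approx(4.59, rel=1e-3)


def test_size_distribution_moment_inequality():
    dist = gen_size_distribution(4.0, gsd=1.5)
    assert powder.d43(dist) >= powder.d32(dist)


def test_size_distribution_validation():
    with pytest.raises(ValueError):
        gen_size_distribution(4.0, gsd=0.9)
    with pytest.raises(ValueError):
        gen_size_distribution(4.0, gsd=1.5, range_um=(5.0, 2.0))


# --------------------------------------------------------- pile silhouettes

@pytest.mark.parametrize("angle, base, height", [(45.0, 200, 100), (30.0, 200, 58)])
def test_pile_geometry(angle, base, height):
    mask, truth = gen_pile_silhouette(angle, base_width_px=base)
    assert truth["height_px"] == height
    rows = np.flatnonzero(mask.any(axis=1))
    assert rows[-1] - rows[0] == height


def test_pile_recovered_angle_within_one_degree():
    for angle in (14.5, 20.9, 37.8, 48.4):
        mask, _ = gen_pile_silhouette(angle, base_width_px=300, noise_px=1.0,
                                      seed=8)
        assert powder.angle_of_repose(mask) == pytest.approx(angle, abs=1.0)


def test_pile_validation():
    with pytest.raises(ValueError):
        gen_pile_silhouette(0.0)
    with pytest.raises(ValueError):
        gen_pile_silhouette(95.0)
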