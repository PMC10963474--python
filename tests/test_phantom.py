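"""Phantom generator: determinism, class-conditional geometry, label
rasterization against independent oracles, cohort apportionment."""

import numpy as np
import pytest
from scipy import ndimage

from catseg.phantom import (CLASS_GEOMETRY, PATHOLOGIES, class_counts,
                            generate_cohort, make_phantom_spec, render_phase)


def test_spec_deterministic_under_seed():
    assert make_phantom_spec("NOR", seed=7) == make_phantom_spec("NOR", seed=7)


def test_unknown_pathology_rejected_with_value():
    with pytest.raises(ValueError, match="'LVH'"):
        make_phantom_spec("LVH", seed=0)


@pytest.mark.parametrize("seed", range(8))
def test_hcm_wall_thicker_than_normal_midpoint(seed):
    """HCM thickens the annulus beyond the NOR class midpoint wall."""
    spec = make_phantom_spec("HCM", seed=seed)
    nor_mid = sum(CLASS_GEOMETRY["NOR"]["wall_ED"]) / 2
    assert spec.r_epi_ED - spec.r_endo_ED > nor_mid


@pytest.mark.parametrize("seed", range(8))
def test_dcm_cavity_larger_than_normal_maximum(seed):
    spec = make_phantom_spec("DCM", seed=seed)
    assert spec.r_endo_ED > CLASS_GEOMETRY["NOR"]["r_endo_ED"][1]


@pytest.mark.parametrize("seed", range(4))
def test_arv_crescent_larger_than_normal(seed):
    spec = make_phantom_spec("ARV", seed=seed)
    assert spec.rv_params["radius_ED"] > CLASS_GEOMETRY["NOR"]["rv_radius"][1]


def test_diastole_not_smaller_than_systole():
    for p in PATHOLOGIES:
        spec = make_phantom_spec(p, seed=1)
        assert spec.r_endo_ED >= spec.r_endo_ES


def test_noise_free_render_gives_exact_tissue_means():
    spec = make_phantom_spec("NOR", seed=2)
    clean = type(spec)(**{**spec.__dict__, "blur_sigma": 0.0, "noise_sd": 0.0,
                          "n_distractors": 0,
                          "tissue_sds": {k: 0.0 for k in spec.tissue_sds}})
    vol, lab = render_phase(clean, "ED")
    myo = lab.data == 2
    assert myo.any()
    assert np.all(vol.data[myo] == np.float32(clean.tissue_means["myo"]))


@pytest.mark.parametrize("pathology", PATHOLOGIES)
def test_annulus_voxel_count_matches_rasterization_oracle(pathology):
    """Label-2 volume within 15% of slices * pi*(r_epi^2 - r_endo^2), and the
    per-slice count equals an independent brute-force rasterization."""
    spec = make_phantom_spec(pathology, seed=3)
    _, lab = render_phase(spec, "ED")
    n_myo = int((lab.data == 2).sum())
    slices = spec.grid_shape[2]
    analytic = slices * np.pi * (spec.r_epi_ED ** 2 - spec.r_endo_ED ** 2)
    if spec.infarct_sector is None:
        assert abs(n_myo - analytic) / analytic < 0.15
    # brute-force oracle on one slice (direct per-pixel distance test)
    rows, cols, _ = spec.grid_shape
    cr, cc = spec.center
    count = 0
    for r in range(rows):
        for c in range(cols):
            d = np.hypot(r - cr, c - cc)
            if spec.r_endo_ED < d <= spec.r_epi_ED:
                count += 1
    if spec.infarct_sector is None:
        assert count == int((lab.data[:, :, 0] == 2).sum())
    else:  # the thinned sector only removes annulus voxels
        assert int((lab.data[:, :, 0] == 2).sum()) <= count


def test_labels_invariant_to_noise_level():
    spec = make_phantom_spec("NOR", seed=4)
    noisy = type(spec)(**{**spec.__dict__, "noise_sd": 25.0})
    _, lab_a = render_phase(spec, "ED")
    _, lab_b = render_phase(noisy, "ED")
    np.testing.assert_array_equal(lab_a.data, lab_b.data)


def test_label_values_and_disjointness(nor_patient):
    for tag in ("ED", "ES"):
        _, lab = nor_patient.phase(tag)
        assert set(np.unique(lab.data)) <= {0, 1, 2, 3}


def test_myocardium_is_annulus_enclosing_cavity(nor_patient):
    """On each slice with both labels, background cannot reach the LV
    cavity without crossing the myocardium ring."""
    _, lab = nor_patient.phase("ED")
    for z in range(lab.data.shape[2]):
        sl = lab.data[:, :, z]
        if not ((sl == 2).any() and (sl == 3).any()):
            continue
        # fill from the border through non-myocardium: must not reach LV
        outside = sl != 2
        filled, _ = ndimage.label(outside)
        border_labels = set(filled[0, :]) | set(filled[-1, :]) \
            | set(filled[:, 0]) | set(filled[:, -1])
        lv_labels = set(np.unique(filled[sl == 3]))
        assert not (lv_labels & border_labels)


def test_regeneration_is_bit_identical():
    spec = make_phantom_spec("MINF", seed=9)
    v1, l1 = render_phase(spec, "ES")
    v2, l2 = render_phase(spec, "ES")
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(l1.data, l2.data)


def test_phases_share_grid_and_spacing(nor_patient):
    assert nor_patient.ED[0].shape == nor_patient.ES[0].shape
    assert nor_patient.ED[0].spacing == nor_patient.ES[0].spacing


def test_cohort_of_150_balanced_gives_30_per_class():
    counts = class_counts(150, [0.2] * 5)
    assert all(c == 30 for c in counts.values())


def test_cohort_of_10_uniform_gives_2_per_class():
    counts = class_counts(10, [0.2] * 5)
    assert all(c == 2 for c in counts.values())


def test_cohort_rounding_largest_remainder():
    counts = class_counts(7, [0.2] * 5)
    assert sorted(counts.values()) == [1, 1, 1, 2, 2]
    assert sum(counts.values()) == 7


def test_negative_proportions_rejected():
    with pytest.raises(ValueError, match="negative"):
        class_counts(10, [0.5, 0.7, -0.2, 0.0, 0.0])


def test_single_patient_cohort_byte_identical():
    a = generate_cohort(1, [1, 0, 0, 0, 0], seed=3, grid_shape=(32, 32, 8))
    b = generate_cohort(1, [1, 0, 0, 0, 0], seed=3, grid_shape=(32, 32, 8))
    np.testing.assert_array_equal(a[0].ED[0].data, b[0].ED[0].data)
    np.testing.assert_array_equal(a[0].ES[1].data, b[0].ES[1].data)
    assert a[0].pathology == "NOR"


def test_distractors_change_intensity_not_labels():
    spec = make_phantom_spec("NOR", seed=6)
    plain = type(spec)(**{**spec.__dict__, "n_distractors": 0})
    v_d, l_d = render_phase(spec, "ED")
    v_p, l_p = render_phase(plain, "ED")
    np.testing.assert_array_equal(l_d.data, l_p.data)
    assert not np.array_equal(v_d.data, v_p.data)
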