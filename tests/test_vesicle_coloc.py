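import numpy as np
import pytest

from mitoquant.core import VoxelGrid
from mitoquant.preprocess import DenoiseSpec, PreprocessConfig
from mitoquant.synth.vesicles import VesicleScenario, simulate_vesicle_stack
from mitoquant.vesicle_coloc import (
    ColocRule,
    classify,
    detect_puncta,
    mito_morphometrics,
)

MIXED = {"AP": 5, "LYS": 3, "AL": 7, "MITO_only": 4, "AM": 2, "ML": 4, "AML": 6}


def _detect_all(channels, config=None):
    kwargs = {} if config is None else {"config": config}
    return (
        detect_puncta(channels[0], "LC3", **kwargs),
        detect_puncta(channels[1], "LYSO", **kwargs),
        detect_puncta(channels[2], "MITO", **kwargs),
    )


def test_all_background_channel_gives_empty_set():
    grid = VoxelGrid(np.zeros((4, 8, 8)), 0.35, 0.1)
    out = detect_puncta(grid, "LC3")
    assert out.n_puncta == 0


def test_small_puncta_removed_by_size_filter():
    img = np.zeros((6, 16, 16))
    img[2, 3:5, 3:5] = 100.0  # 4-voxel punctum
    grid = VoxelGrid(img, 0.35, 0.1)
    cfg = PreprocessConfig(denoise=DenoiseSpec(method="none"), min_voxels=8)
    assert detect_puncta(grid, "LC3", cfg).n_puncta == 0
    cfg0 = PreprocessConfig(denoise=DenoiseSpec(method="none"), min_voxels=0)
    assert detect_puncta(grid, "LC3", cfg0).n_puncta == 1


def test_unknown_role_rejected():
    with pytest.raises(ValueError, match="unknown channel role"):
        detect_puncta(VoxelGrid(np.ones((2, 4, 4)), 0.35, 0.1), "DAPI")


def test_full_overlap_aml_scenario(vesicle_geometry, noise_free):
    scenario = VesicleScenario(counts={"AML": 4}, overlap_fraction=1.0, noise=noise_free)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=4)
    table = classify(*_detect_all(channels))
    assert table.counts == {"AP": 0, "LYS": 0, "AL": 0, "MITO": 0, "AM": 0, "ML": 0, "AML": 4}


def test_isolated_lc3_classified_ap(vesicle_geometry, noise_free):
    scenario = VesicleScenario(counts={"AP": 3}, noise=noise_free)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=6)
    table = classify(*_detect_all(channels))
    assert table.counts["AP"] == 3
    assert sum(table.counts.values()) == 3


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mixed_scenario_recovers_all_class_counts(vesicle_geometry, seed):
    scenario = VesicleScenario(counts=MIXED)
    channels, truth = simulate_vesicle_stack(vesicle_geometry, scenario, seed=seed)
    table = classify(*_detect_all(channels))
    expected = truth.class_counts()
    expected["MITO"] = expected.pop("MITO_only")
    assert table.counts == expected


def test_partition_property(vesicle_geometry):
    scenario = VesicleScenario(counts=MIXED)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=9)
    lc3, lyso, mito = _detect_all(channels)
    table = classify(lc3, lyso, mito)
    assert (
        table.counts["AP"] + table.counts["AL"] + table.counts["AM"] + table.counts["AML"]
        == lc3.n_puncta
    )


def test_raising_min_shared_voxels_never_increases_coloc_counts(vesicle_geometry):
    scenario = VesicleScenario(counts=MIXED)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=13)
    lc3, lyso, mito = _detect_all(channels)
    prev = None
    for m in (1, 5, 20, 100):
        table = classify(lc3, lyso, mito, ColocRule(min_shared_voxels=m))
        coloc = {c: table.counts[c] for c in ("AL", "AM", "ML", "AML")}
        if prev is not None:
            assert all(coloc[c] <= prev[c] for c in coloc)
        prev = coloc


def test_inclusive_mode_counts_pairs_regardless_of_third_channel(vesicle_geometry, noise_free):
    scenario = VesicleScenario(counts={"AML": 5}, noise=noise_free)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=15)
    lc3, lyso, mito = _detect_all(channels)
    incl = classify(lc3, lyso, mito, ColocRule(classes_exclusive=False))
    assert incl.counts["AML"] == 5
    assert incl.counts["AM"] == 5  # LC3∧Mito irrespective of Lyso
    assert incl.counts["AL"] == 5
    excl = classify(lc3, lyso, mito, ColocRule(classes_exclusive=True))
    assert excl.counts["AM"] == excl.counts["AL"] == 0


def test_geometry_mismatch_raises(vesicle_geometry, noise_free):
    scenario = VesicleScenario(counts={"AP": 1}, noise=noise_free)
    channels, _ = simulate_vesicle_stack(vesicle_geometry, scenario, seed=0)
    lc3, lyso, _mito = _detect_all(channels)
    small = VoxelGrid(np.zeros((4, 8, 8)), 0.35, 0.1)
    other = detect_puncta(small, "MITO")
    with pytest.raises(ValueError, match="geometries differ"):
        classify(lc3, lyso, other)


class TestMitoMorphometrics:
    def test_empty_channel(self):
        grid = VoxelGrid(np.zeros((4, 8, 8)), 0.35, 0.1)
        count, vol = mito_morphometrics(detect_puncta(grid, "MITO"))
        assert (count, vol) == (0, 0.0)

    def test_two_cubes_arithmetic(self):
        img = np.zeros((8, 20, 20))
        img[1:4, 2:5, 2:5] = 100.0
        img[4:7, 12:15, 12:15] = 100.0
        grid = VoxelGrid(img, 0.35, 0.1)
        cfg = PreprocessConfig(denoise=DenoiseSpec(method="none"), min_voxels=0)
        count, vol = mito_morphometrics(detect_puncta(grid, "MITO", cfg))
        assert count == 2
        assert vol == pytest.approx(27 * 0.1 * 0.1 * 0.35)
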