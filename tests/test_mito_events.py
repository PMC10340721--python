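import numpy as np
import pytest
from _oracles import flood_fill_components

from mitoquant.core import BinaryVolume
from mitoquant.mito_events import detect_events, label_structures, summarise_series
from mitoquant.preprocess import DenoiseSpec, PreprocessConfig, binarize
from mitoquant.synth.mito import MitoScenario, ScriptedEvent, simulate_mito_timelapse

NOISE_FREE_CFG = PreprocessConfig(denoise=DenoiseSpec(method="none"))


def _vol(mask, vz=0.25, vxy=0.1):
    return BinaryVolume(np.asarray(mask, dtype=bool), vz, vxy)


class TestLabelStructures:
    def test_empty_mask(self):
        _, stats = label_structures(_vol(np.zeros((3, 4, 4))))
        assert stats.structure_count == 0
        assert stats.mean_volume_um3 == 0.0
        assert stats.empty

    def test_two_cubes_volume_arithmetic(self):
        mask = np.zeros((5, 12, 12), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[1:4, 7:10, 7:10] = True
        _, stats = label_structures(_vol(mask))
        assert stats.structure_count == 2
        assert stats.mean_volume_um3 == pytest.approx(27 * 0.1 * 0.1 * 0.25)

    def test_matches_flood_fill_oracle_on_random_spheres(self, rng):
        mask = np.zeros((10, 60, 60), dtype=bool)
        placed = []
        while len(placed) < 20:
            c = rng.integers([2, 5, 5], [8, 55, 55])
            if all(np.abs(c - p).max() > 6 for p in placed):
                placed.append(c)
                z, y, x = np.ogrid[:10, :60, :60]
                mask |= (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= 4
        _, stats = label_structures(_vol(mask))
        comps = flood_fill_components(mask)
        assert stats.structure_count == len(comps) == 20
        assert sorted(stats.volumes_um3) == pytest.approx(
            sorted(len(c) * 0.25 * 0.01 for c in comps)
        )

    def test_mean_volume_times_count_equals_total(self, rng):
        mask = rng.random((8, 32, 32)) > 0.85
        vol = _vol(mask)
        _, stats = label_structures(vol)
        assert stats.mean_volume_um3 * stats.structure_count == pytest.approx(
            vol.volume_um3(), rel=1e-12
        )


class TestDetectEvents:
    def test_identical_frames_give_no_events(self, rng):
        mask = rng.random((6, 24, 24)) > 0.9
        res = detect_events(_vol(mask), _vol(mask))
        assert res.events == []
        assert res.appeared == [] and res.disappeared == []

    def test_rod_with_gap_is_one_fission_at_the_gap(self):
        rod = np.zeros((3, 5, 14), dtype=bool)
        rod[1, 2, 2:12] = True
        broken = rod.copy()
        broken[1, 2, 7] = False
        res = detect_events(_vol(rod), _vol(broken))
        assert len(res.events) == 1
        (event,) = res.events
        assert event.event_type == "fission"
        z, y, x = event.location
        assert (z, y) == (1, 2) and 5 <= x <= 9

    def test_time_reversal_swaps_fission_and_fusion(self, rng):
        a = rng.random((6, 24, 24)) > 0.88
        b = rng.random((6, 24, 24)) > 0.88
        fwd = detect_events(_vol(a), _vol(b))
        rev = detect_events(_vol(b), _vol(a))
        flip = {"fission": "fusion", "fusion": "fission"}
        fwd_set = sorted((e.event_type, e.location) for e in fwd.events)
        rev_set = sorted((flip[e.event_type], e.location) for e in rev.events)
        assert fwd_set == rev_set

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            detect_events(_vol(np.zeros((2, 3, 3))), _vol(np.zeros((2, 4, 4))))

    def test_count_bookkeeping_on_scripted_transitions(self, mito_geometry, noise_free):
        scenario = MitoScenario(
            n_tubules=5,
            noise=noise_free,
            scripted_events=(
                ScriptedEvent(2, "fission"),
                ScriptedEvent(4, "fusion"),
                ScriptedEvent(6, "fission"),
                ScriptedEvent(6, "fusion"),
            ),
        )
        frames, _truth = simulate_mito_timelapse(mito_geometry, scenario, seed=17)
        masks = [binarize(f, NOISE_FREE_CFG) for f in frames]
        for t in range(len(masks) - 1):
            res = detect_events(masks[t], masks[t + 1])
            e = sum(1 for ev in res.events if ev.event_type == "fission")
            f = sum(1 for ev in res.events if ev.event_type == "fusion")
            _, st0 = label_structures(masks[t])
            _, st1 = label_structures(masks[t + 1])
            assert st1.structure_count - st0.structure_count == e - f

    def test_event_location_inside_participating_footprint(self, mito_geometry, noise_free):
        scenario = MitoScenario(
            n_tubules=3, noise=noise_free,
            scripted_events=(ScriptedEvent(3, "fission"), ScriptedEvent(6, "fusion")),
        )
        frames, _ = simulate_mito_timelapse(mito_geometry, scenario, seed=23)
        masks = [binarize(f, NOISE_FREE_CFG) for f in frames]
        found = 0
        for t in range(len(masks) - 1):
            lab_t, _ = label_structures(masks[t])
            lab_t1, _ = label_structures(masks[t + 1])
            for e in detect_events(masks[t], masks[t + 1]).events:
                found += 1
                at_t = lab_t.labels[e.location]
                at_t1 = lab_t1.labels[e.location]
                if e.event_type == "fission":
                    assert at_t in e.parent_labels or at_t1 in e.child_labels
                else:
                    assert at_t in e.parent_labels or at_t1 in e.child_labels
        assert found == 2


class TestSummariseSeries:
    def test_identity_series(self, rng):
        mask = rng.random((5, 20, 20)) > 0.88
        frames = [_vol(mask) for _ in range(9)]
        summary, stats = summarise_series(frames)
        assert summary.mean_fission == 0.0
        assert summary.mean_fusion == 0.0
        n = stats[0].structure_count
        assert summary.mean_structure_count == n

    def test_requires_two_frames(self, rng):
        with pytest.raises(ValueError, match=">= 2 frames"):
            summarise_series([_vol(rng.random((3, 8, 8)) > 0.5)])

    def test_matches_per_pair_brute_force(self, mito_geometry, noise_free):
        scenario = MitoScenario(
            n_tubules=4, noise=noise_free,
            scripted_events=(ScriptedEvent(2, "fission"), ScriptedEvent(5, "fission")),
        )
        frames, _ = simulate_mito_timelapse(mito_geometry, scenario, seed=31)
        masks = [binarize(f, NOISE_FREE_CFG) for f in frames]
        summary, _stats = summarise_series(masks)
        fis = [
            sum(1 for e in detect_events(masks[i], masks[i + 1]).events
                if e.event_type == "fission")
            for i in range(len(masks) - 1)
        ]
        assert summary.fission_per_pair == fis
        assert summary.mean_fission == pytest.approx(np.mean(fis))
        counts = [label_structures(m)[1].structure_count for m in masks]
        assert summary.mean_structure_count == pytest.approx(np.mean(counts))
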