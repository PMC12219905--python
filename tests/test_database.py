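"""(T1, T2) grid enumeration, database building, noise augmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from molli_ptnn import (
    GridSpec,
    NoiseConfig,
    SignalVector,
    augment_with_noise,
    build_database,
    enumerate_grid,
    normalize_database,
    normalize_signal,
)
from molli_ptnn.io import load_database, save_database

TINY_GRID = GridSpec(t1_min=800, t1_max=1200, t1_step=200,
                     t2_min=50, t2_max=150, t2_step=100)  # 2 x 2 entries


class TestEnumerateGrid:
    def test_t1_major_ordering_and_exclusions(self):
        spec = GridSpec(t1_min=100, t1_max=300, t1_step=100,
                        t2_min=20, t2_max=220, t2_step=100)
        pairs = enumerate_grid(spec)
        # T2 values {20,120,220}; T1 {100,200}: (100,120),(100,220),(200,220) excluded
        expected = [(100, 20), (200, 20), (200, 120)]
        assert [tuple(p) for p in pairs] == expected

    def test_t2_floor_exclusion(self):
        spec = GridSpec(t1_min=600, t1_max=700, t1_step=100,
                        t2_min=10, t2_max=30, t2_step=10)
        pairs = enumerate_grid(spec)
        assert pairs[:, 1].min() == 20.0

    def test_default_range_convention(self):
        # T1 half-open above, T2 closed: both documented endpoints
        spec = GridSpec(t1_step=100.0, t2_step=5.0)
        pairs = enumerate_grid(spec)
        assert pairs[:, 0].max() == 1900.0
        assert pairs[:, 1].max() == 400.0
        assert pairs[:, 0].min() == 600.0
        assert pairs[:, 1].min() == 20.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(GridSpec(t1_min=50, t1_max=60, t1_step=5,
                                    t2_min=100, t2_max=400, t2_step=5))


class TestBuildDatabase:
    def test_entries_match_standalone_simulation(self, schedule_533, params):
        from molli_ptnn import simulate_molli_signal

        db = build_database(schedule_533, params, TINY_GRID)
        assert len(db) == 4
        i = int(np.flatnonzero((db.t1 == 1000) & (db.t2 == 50))[0])
        single = simulate_molli_signal(schedule_533, params, 1000.0, 50.0)
        assert np.allclose(db.signals[i], single.magnitudes, atol=1e-12)
        assert np.array_equal(db.tis, schedule_533.effective_tis)

    def test_deterministic(self, schedule_533, params):
        a = build_database(schedule_533, params, TINY_GRID)
        b = build_database(schedule_533, params, TINY_GRID)
        assert np.array_equal(a.signals, b.signals)
        assert a.schedule_fingerprint == b.schedule_fingerprint

    def test_chunking_invariant(self, schedule_533, ideal_params):
        spec = GridSpec(t1_step=200.0, t2_step=50.0)
        whole = build_database(schedule_533, ideal_params, spec)
        chunked = build_database(schedule_533, ideal_params, spec, chunk_size=7)
        assert np.array_equal(whole.signals, chunked.signals)


class TestAugmentation:
    @pytest.fixture()
    def small_db(self, schedule_533, ideal_params):
        return build_database(schedule_533, ideal_params,
                              GridSpec(t1_step=200.0, t2_step=100.0))

    def test_count_multiplies_and_labels_repeat(self, small_db):
        out = augment_with_noise(small_db, NoiseConfig(snr=40, n_instances=10,
                                                       seed=3))
        assert len(out) == 10 * len(small_db)
        assert np.array_equal(out.t1, np.repeat(small_db.t1, 10))
        assert np.array_equal(out.t2, np.repeat(small_db.t2, 10))
        assert np.all(out.signals >= 0)

    def test_seeded_reproducibility(self, small_db):
        a = augment_with_noise(small_db, NoiseConfig(seed=3))
        b = augment_with_noise(small_db, NoiseConfig(seed=3))
        c = augment_with_noise(small_db, NoiseConfig(seed=4))
        assert np.array_equal(a.signals, b.signals)
        assert not np.array_equal(a.signals, c.signals)
        assert np.array_equal(a.t1, c.t1)

    def test_degenerate_noise_is_identity(self, small_db):
        out = augment_with_noise(small_db, NoiseConfig(snr=np.inf, n_instances=1,
                                                       seed=0))
        assert np.array_equal(out.signals, small_db.signals)

    def test_double_augmentation_rejected(self, small_db):
        once = augment_with_noise(small_db, NoiseConfig(seed=0))
        with pytest.raises(ValueError, match="already"):
            augment_with_noise(once, NoiseConfig(seed=0))

    def test_noise_mean_converges_to_clean_signal(self, small_db):
        # one entry, many instances: sample mean within ~SE of the noiseless
        # value (zero-clipping bias is negligible at SNR 40)
        one = small_db.subset(np.array([0]))
        n = 2000
        out = augment_with_noise(one, NoiseConfig(snr=40, n_instances=n, seed=9))
        sigma = one.signals.max() / 40.0
        err = np.abs(out.signals.mean(axis=0) - one.signals[0])
        assert np.all(err < 3.0 * sigma / np.sqrt(n) + 1e-3 * sigma)


class TestNormalization:
    def test_flat_vector(self):
        v = SignalVector(magnitudes=np.ones(8), effective_tis=np.arange(1, 9.0))
        out = normalize_signal(v)
        assert np.allclose(out.magnitudes, 1 / np.sqrt(8))
        assert out.normalized

    @given(st.lists(st.floats(min_value=0.001, max_value=1e4),
                    min_size=8, max_size=8),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_unit_norm_and_scale_invariance(self, mags, gain):
        v = SignalVector(magnitudes=np.array(mags), effective_tis=np.arange(1, 9.0))
        scaled = SignalVector(magnitudes=gain * np.array(mags),
                              effective_tis=np.arange(1, 9.0))
        a, b = normalize_signal(v), normalize_signal(scaled)
        assert np.linalg.norm(a.magnitudes) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(a.magnitudes, b.magnitudes, atol=1e-9)

    def test_all_zero_rejected(self):
        v = SignalVector(magnitudes=np.zeros(8), effective_tis=np.arange(1, 9.0))
        with pytest.raises(ValueError):
            normalize_signal(v)

    def test_database_normalization(self, schedule_533, ideal_params):
        db = build_database(schedule_533, ideal_params,
                            GridSpec(t1_step=200.0, t2_step=100.0))
        dbn = normalize_database(db)
        assert np.allclose(np.linalg.norm(dbn.signals, axis=1), 1.0)
        assert dbn.normalized and not db.normalized


def test_hdf5_round_trip(schedule_533, ideal_params, tmp_path):
    db = build_database(schedule_533, ideal_params,
                        GridSpec(t1_step=200.0, t2_step=100.0))
    db = normalize_database(augment_with_noise(db, NoiseConfig(seed=5)))
    path = tmp_path / "db.h5"
    save_database(db, path)
    back = load_database(path)
    assert np.array_equal(back.signals, db.signals)
    assert np.array_equal(back.t1, db.t1)
    assert back.schedule_fingerprint == db.schedule_fingerprint
    assert back.normalized
    assert back.noise_config.snr == 40.0
    assert back.grid_spec.t1_step == 200.0
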