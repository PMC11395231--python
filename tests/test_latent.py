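"""Representation learning: crop geometry, normalization invariance, the
KL-weight ramp, autoencoder training contracts and separation reporting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridscope.errors import ConfigError, DataError
from hybridscope.latent import (
    BetaSchedule,
    Crop,
    VAEConfig,
    beta_at,
    crop_and_pad,
    embed_umap,
    encode,
    feature_table,
    normalize_crops,
    phenotype_report,
    train_vae,
)
from hybridscope.latent.vae import BetaVAE, EmbeddingSet
from hybridscope.segment import CellRecord, ImageField, segment_field
from hybridscope.simgen import FieldConfig, generate_crop_set, generate_field

TINY = VAEConfig(
    encoder_filters=(8, 16), latent_dim=8, batch_size=8,
    max_epochs=3, validation_fraction=0.2, seed=0,
)


def _uniform_field(h=128, w=128, value=3.0):
    pixels = np.full((h, w, 3), value, dtype=np.float32)
    return ImageField(pixels, np.zeros((h, w), dtype=bool), provenance="u")


def _record(cell_id, row, col):
    return CellRecord(
        cell_id=cell_id, centroid=(row, col), bbox=(0, 0, 10, 10), area_px=50,
        mean_intensity={"CK": 1.0, "CD45": 1.0, "DAPI": 1.0},
    )


class TestCropAndPad:
    def test_corner_cell_zero_padded(self):
        field = _uniform_field()
        crop = crop_and_pad(field, _record(1, 0.0, 0.0))
        assert crop.tensor.shape == (64, 64, 3)
        assert (crop.tensor[:32, :32] == 0).all()  # out-of-field quadrant
        assert (crop.tensor[32:, 32:] == 3.0).all()

    def test_interior_window_identity(self):
        field = _uniform_field()
        crop = crop_and_pad(field, _record(1, 64.0, 64.0))
        np.testing.assert_array_equal(crop.tensor, field.pixels[32:96, 32:96])

    def test_centroid_outside_field_rejected(self):
        with pytest.raises(DataError):
            crop_and_pad(_uniform_field(), _record(1, 500.0, 10.0))

    def test_planted_cell_centered_on_nucleus(self):
        cfg = FieldConfig(height_px=256, width_px=256, n_leukocytes=5,
                          n_chc=1, n_control_cells=0, seed=13)
        field, _ = generate_field(cfg)
        _, records = segment_field(field)
        rec = max(records, key=lambda r: r.mean_intensity["DAPI"])
        crop = crop_and_pad(field, rec)
        peak = np.unravel_index(crop.tensor[..., 2].argmax(), (64, 64))
        assert abs(peak[0] - 32) <= 1 and abs(peak[1] - 32) <= 1


class TestNormalizeCrops:
    def _crop(self, value, sample="s"):
        return Crop(np.full((64, 64, 3), value, dtype=np.float32), (sample, 0))

    def test_division_by_sample_median(self):
        records = [_record(i, 5, 5) for i in range(3)]
        for r in records:
            r.mean_intensity = {"CK": 10.0, "CD45": 5.0, "DAPI": 2.0}
        (out,) = normalize_crops([self._crop(20.0)], {"s": records})
        assert out.tensor[0, 0, 0] == pytest.approx(2.0)
        assert out.tensor[0, 0, 1] == pytest.approx(4.0)
        assert out.tensor[0, 0, 2] == pytest.approx(10.0)

    def test_self_normalization_unit_mean(self):
        crops = [self._crop(7.0) for _ in range(4)]
        out = normalize_crops(crops)
        for c in out:
            assert c.tensor.mean(axis=(0, 1)) == pytest.approx([1.0, 1.0, 1.0])

    def test_illumination_invariance(self):
        """A 2x-brighter replicate of a sample normalizes to the same crops."""
        base = generate_crop_set(6, 6, 0.0, seed=4)
        bright = [
            Crop(2.0 * c.tensor, c.provenance, c.phase, c.punctate) for c in base
        ]
        na = normalize_crops(base)
        nb = normalize_crops(bright)
        for a, b in zip(na, nb):
            np.testing.assert_allclose(a.tensor, b.tensor, rtol=1e-5, atol=1e-6)

    def test_missing_records_rejected(self):
        with pytest.raises(DataError):
            normalize_crops([self._crop(1.0)], {"other": [_record(0, 1, 1)]})


class TestBetaSchedule:
    def test_start_value(self):
        assert beta_at(0) == pytest.approx(0.001)

    def test_first_batch_at_ceiling(self):
        assert beta_at(1999) == pytest.approx(2.0)
        assert beta_at(1998) < 2.0

    def test_plateau_persists(self):
        assert beta_at(10**6) == 2.0

    def test_negative_index_rejected(self):
        with pytest.raises(ConfigError):
            beta_at(-1)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigError):
            BetaSchedule(beta_step=0.0)
        with pytest.raises(ConfigError):
            BetaSchedule(beta_start=3.0, beta_max=2.0)

    @settings(deadline=None, derandomize=True)
    @given(k=st.integers(0, 10_000))
    def test_monotone_and_clamped(self, k):
        s = BetaSchedule()
        assert beta_at(k, s) <= beta_at(k + 1, s) <= s.beta_max


class TestVAE:
    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            VAEConfig(latent_dim=0)
        with pytest.raises(ConfigError):
            VAEConfig(validation_fraction=0.9)

    def test_encoder_output_is_latent_dim(self):
        model = BetaVAE(VAEConfig(seed=0))
        x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
        mu, logvar = model.encode_params(x)
        assert mu.shape == (1, 64) and logvar.shape == (1, 64)

    def test_decoder_output_shape(self):
        model = BetaVAE(TINY)
        xhat = model.decode(np.zeros((2, TINY.latent_dim), dtype=np.float32))
        assert xhat.shape == (2, 64, 64, 3)

    def test_too_few_crops_rejected(self):
        crops = generate_crop_set(4, 4, 0.0, seed=0)
        with pytest.raises(DataError):
            train_vae(crops, TINY)

    def test_training_reduces_validation_reconstruction(self, two_class_training):
        history = two_class_training["history"]
        assert history[-1]["val_recon"] < history[0]["val_recon"]

    def test_history_beta_follows_schedule(self, two_class_training):
        betas = [h["beta"] for h in two_class_training["history"]]
        assert betas == sorted(betas)
        assert betas[0] < betas[-1] <= 2.0

    def test_training_determinism(self):
        crops = normalize_crops(generate_crop_set(12, 12, 0.0, seed=2))
        _, h1 = train_vae(crops, TINY)
        _, h2 = train_vae(crops, TINY)
        assert h1 == h2

    def test_duplicate_crop_identical_embedding(self, two_class_training):
        model = two_class_training["model"]
        crop = two_class_training["crops"][0]
        eset = encode(model, [crop, crop])
        np.testing.assert_array_equal(eset.matrix[0], eset.matrix[1])

    def test_embedding_rows_align_with_crops(self, two_class_training):
        eset = two_class_training["embeddings"]
        crops = two_class_training["crops"]
        assert eset.matrix.shape == (len(crops), 64)
        assert eset.labels == [c.phase for c in crops]


class TestUMAP:
    def test_shape_and_determinism(self, rng):
        matrix = rng.normal(size=(40, 8))
        a = embed_umap(matrix, n_neighbors=5, seed=42)
        b = embed_umap(matrix, n_neighbors=5, seed=42)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(DataError):
            embed_umap(rng.normal(size=(10, 4)), n_neighbors=15)

    def test_separated_blobs_stay_separable(self, rng):
        blob_a = rng.normal(0, 0.3, size=(30, 6))
        blob_b = rng.normal(5, 0.3, size=(30, 6))
        coords = embed_umap(np.vstack([blob_a, blob_b]), n_neighbors=5, seed=42)
        labels = np.array([0] * 30 + [1] * 30)
        from sklearn.neighbors import KNeighborsClassifier

        knn = KNeighborsClassifier(n_neighbors=1)
        acc = knn.fit(coords, labels).score(coords, labels)
        assert acc >= 0.95


class TestPhenotypeReport:
    def _eset(self, matrix, labels):
        return EmbeddingSet(
            matrix=matrix, labels=labels,
            provenance=[("s", i) for i in range(len(labels))],
        )

    def test_identical_embeddings_degenerate(self):
        eset = self._eset(np.ones((12, 4)), ["responsive"] * 6 + ["resistant"] * 6)
        report = phenotype_report(eset)
        assert report.degenerate and report.silhouette == 0.0

    def test_single_class_rejected(self):
        eset = self._eset(np.random.default_rng(0).normal(size=(10, 4)),
                          ["responsive"] * 10)
        with pytest.raises(DataError):
            phenotype_report(eset)

    def test_feature_directions_on_fixture(self, two_class_training):
        report = phenotype_report(two_class_training["embeddings"])
        assert report.directions["ck_higher_in_resistant"]
        assert report.directions["cd45_higher_in_responsive"]

    def test_feature_table_columns(self):
        crops = generate_crop_set(3, 3, 0.0, seed=5)
        table = feature_table(crops)
        assert list(table.columns) == [
            "sample_id", "cell_id", "phase",
            "mean_ck", "mean_cd45", "mean_dapi", "area_px",
        ]
        assert (table["area_px"] > 0).all()
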