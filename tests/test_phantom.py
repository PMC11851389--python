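"""Phantom simulator: projector/FBP consistency and artifact phenomenology."""

import numpy as np
import pytest

from scdiff.errors import ConfigurationError
from scdiff.metrics import psnr
from scdiff.phantom import (
    ArtifactSpec,
    Ellipse,
    PhantomSpec,
    ProjectionGeometry,
    build_unpaired_dataset,
    default_geometry,
    fbp_reconstruct,
    fov_mask,
    hu_to_mu,
    lung_artifact_spec,
    lung_phantom_spec,
    make_cbct_from_pct,
    make_phantom,
    radon_project,
)


def masked_rmse(a, b, size):
    m = fov_mask(size)
    return float(np.sqrt(np.mean((a - b)[m] ** 2)))


class TestPhantomConstruction:
    def test_single_ellipse_center_value(self):
        spec = PhantomSpec(ellipses=(Ellipse((0, 0), (0.5, 0.5), 0.0, 1000.0),),
                           background=-1000.0)
        img = make_phantom(spec, 64)
        assert img.data[32, 32] == pytest.approx(0.0)  # -1000 + 1000

    def test_empty_spec_gives_uniform_background(self):
        img = make_phantom(PhantomSpec(ellipses=(), background=-500.0), 64)
        assert np.all(img.data == -500.0)

    def test_two_disjoint_ellipses_three_levels(self):
        spec = PhantomSpec(
            ellipses=(Ellipse((-0.5, 0), (0.2, 0.2), 0.0, 500.0),
                      Ellipse((0.5, 0), (0.2, 0.2), 0.0, 900.0)),
            background=-1000.0)
        img = make_phantom(spec, 64, supersample=1)
        assert len(np.unique(img.data)) == 3

    def test_out_of_fov_ellipse_rejected(self):
        with pytest.raises(ConfigurationError):
            Ellipse((0.8, 0.0), (0.5, 0.2), 0.0, 100.0)

    def test_determinism_given_seed(self):
        spec = lung_phantom_spec()
        a = make_phantom(spec, 64, np.random.default_rng(5))
        b = make_phantom(spec, 64, np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)


class TestProjector:
    def test_zero_attenuation_image_gives_zero_sinogram(self):
        img = make_phantom(PhantomSpec(ellipses=(), background=-1000.0), 64)
        sino = radon_project(img, ProjectionGeometry(n_angles=16))
        assert np.allclose(sino, 0.0, atol=1e-9)

    def test_uniform_disk_central_chord(self):
        # disk of radius 0.5 FOV units (16 px at size 64) and 0 HU inside
        spec = PhantomSpec(ellipses=(Ellipse((0, 0), (0.5, 0.5), 0.0, 1000.0),),
                           background=-1000.0)
        img = make_phantom(spec, 64)
        sino = radon_project(img, ProjectionGeometry(n_angles=8))
        nd = sino.shape[1]
        chord_px = 2 * 0.5 * 32  # 2r in pixels
        expected = hu_to_mu(0.0) * chord_px
        assert sino[0, nd // 2] == pytest.approx(expected, rel=0.02)

    def test_rotationally_symmetric_phantom_has_equal_angle_rows(self):
        spec = PhantomSpec(ellipses=(Ellipse((0, 0), (0.6, 0.6), 0.0, 800.0),),
                           background=-1000.0)
        sino = radon_project(make_phantom(spec, 64), ProjectionGeometry(n_angles=12))
        ref = sino[0]
        scale = np.sqrt(np.mean(ref**2))
        for row in sino[1:]:
            assert np.sqrt(np.mean((row - ref) ** 2)) < 0.01 * scale


class TestFBP:
    def test_full_view_self_reconstruction(self, fixture_phantom_128, full_view_geometry):
        sino = radon_project(fixture_phantom_128, full_view_geometry)
        rec = fbp_reconstruct(sino, full_view_geometry, 128)
        assert masked_rmse(rec.data, fixture_phantom_128.data, 128) < 40.0

    def test_sparse_view_reconstruction_is_worse(self, fixture_phantom_128,
                                                 full_view_geometry):
        full_sino = radon_project(fixture_phantom_128, full_view_geometry)
        full_rmse = masked_rmse(
            fbp_reconstruct(full_sino, full_view_geometry, 128).data,
            fixture_phantom_128.data, 128)
        g30 = ProjectionGeometry(n_angles=30)
        sparse_rmse = masked_rmse(
            fbp_reconstruct(radon_project(fixture_phantom_128, g30), g30, 128).data,
            fixture_phantom_128.data, 128)
        assert sparse_rmse > full_rmse

    def test_error_decreases_with_view_count(self, fixture_phantom_128):
        errs = []
        for n in (30, 90, 360):
            g = ProjectionGeometry(n_angles=n)
            rec = fbp_reconstruct(radon_project(fixture_phantom_128, g), g, 128)
            errs.append(masked_rmse(rec.data, fixture_phantom_128.data, 128))
        assert errs[0] > errs[1] > errs[2]

    def test_zero_sinogram_reconstructs_to_air(self):
        g = ProjectionGeometry(n_angles=16)
        nd = radon_project(
            make_phantom(PhantomSpec(ellipses=(), background=-1000.0), 64), g
        ).shape[1]
        rec = fbp_reconstruct(np.zeros((16, nd)), g, 64)
        assert np.allclose(rec.data, -1000.0, atol=1e-6)


class TestArtifacts:
    def test_degenerate_spec_approximates_self_reconstruction(self, fixture_phantom_128):
        art = ArtifactSpec(sparse_views=360, shading_amplitude=0.0,
                           hu_offset=0.0, noise_sigma=0.0)
        cb = make_cbct_from_pct(fixture_phantom_128, art, default_geometry(128))
        assert masked_rmse(cb.data, fixture_phantom_128.data, 128) < 40.0

    def test_pure_offset_shifts_mean_by_50(self, fixture_phantom_64):
        art = ArtifactSpec(sparse_views=360, shading_amplitude=0.0,
                           hu_offset=50.0, noise_sigma=0.0)
        cb = make_cbct_from_pct(fixture_phantom_64, art, default_geometry(64))
        shift = float(np.mean(cb.data - fixture_phantom_64.data))
        assert shift == pytest.approx(50.0, abs=1.0)

    def test_default_preset_degrades_psnr(self, fixture_phantom_64):
        geom = default_geometry(64)
        clean_rec = make_cbct_from_pct(
            fixture_phantom_64,
            ArtifactSpec(sparse_views=360, shading_amplitude=0.0,
                         hu_offset=0.0, noise_sigma=0.0), geom)
        cbct = make_cbct_from_pct(fixture_phantom_64, lung_artifact_spec(), geom)
        assert psnr(cbct, fixture_phantom_64) < psnr(clean_rec, fixture_phantom_64)

    def test_any_nonzero_artifact_changes_image(self, fixture_phantom_64):
        geom = default_geometry(64)
        for art in (ArtifactSpec(sparse_views=30, shading_amplitude=0, hu_offset=0,
                                 noise_sigma=0),
                    ArtifactSpec(sparse_views=360, shading_amplitude=50, hu_offset=0,
                                 noise_sigma=0),
                    ArtifactSpec(sparse_views=360, shading_amplitude=0, hu_offset=10,
                                 noise_sigma=0)):
            cb = make_cbct_from_pct(fixture_phantom_64, art, geom)
            assert np.mean(np.abs(cb.data - fixture_phantom_64.data)) > 0

    def test_determinism_given_seed(self, fixture_phantom_64):
        geom = default_geometry(64)
        art = ArtifactSpec(seed=3)
        a = make_cbct_from_pct(fixture_phantom_64, art, geom)
        b = make_cbct_from_pct(fixture_phantom_64, art, geom)
        assert np.array_equal(a.data, b.data)


class TestUnpairedDataset:
    def test_split_contract(self):
        ds = build_unpaired_dataset(4, 5, size=32, seed=0, n_test_subjects=0)
        # 4 train subjects: 2 contribute pCT, 2 contribute CBCT
        assert len(ds.train_pct) == 10
        assert len(ds.train_cbct) == 10
        assert set(ds.manifest["pct_subjects"]).isdisjoint(ds.manifest["cbct_subjects"])

    def test_test_split_is_paired(self):
        ds = build_unpaired_dataset(3, 4, size=32, seed=1)
        assert len(ds.test_pct) == len(ds.test_cbct) == 4
        art = ArtifactSpec(**ds.manifest["artifact"])
        # CBCT test slices must derive from their own pCT: same anatomy, so
        # the difference is bounded by the artifact model, not the jitter
        for pct, cbct in zip(ds.test_pct, ds.test_cbct):
            diff = np.mean(np.abs(cbct.data - pct.data))
            assert 0 < diff < 4 * (art.shading_amplitude + abs(art.hu_offset)
                                   + art.noise_sigma + 40)

    def test_byte_identical_datasets_from_same_seed(self, tmp_path):
        a = build_unpaired_dataset(3, 2, size=32, seed=7)
        b = build_unpaired_dataset(3, 2, size=32, seed=7)
        for va, vb in zip(a.train_pct + a.train_cbct + a.test_pct + a.test_cbct,
                          b.train_pct + b.train_cbct + b.test_pct + b.test_cbct):
            assert np.array_equal(va.data, vb.data)

    def test_save_load_round_trip(self, tmp_path):
        ds = build_unpaired_dataset(3, 2, size=32, seed=2)
        ds.save(tmp_path / "ds")
        from scdiff.phantom import UnpairedDataset

        back = UnpairedDataset.load(tmp_path / "ds")
        assert len(back.train_pct) == len(ds.train_pct)
        assert np.allclose(back.test_cbct[0].data, ds.test_cbct[0].data, atol=1e-3)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            build_unpaired_dataset(1, 4)
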