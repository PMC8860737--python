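"""Optical density, Macenko stain vectors, projection, zonated profiles."""

import numpy as np
import pandas as pd
import pytest

import hepazone as hz
import hepazone.stains as st
from hepazone.zonation import PortalityField, ZonationMaps

from conftest import EOSIN, HEMATOXYLIN, unit


class TestOpticalDensity:
    def test_white_maps_to_zero(self):
        od = st.rgb_to_od(np.full((1, 1, 3), 255, dtype=np.uint8))
        np.testing.assert_array_equal(od, 0.0)

    def test_one_decade_attenuation(self):
        od = st.rgb_to_od(np.full((1, 1, 3), 25.5), i0=255, eps=0.0)
        np.testing.assert_allclose(od, 1.0)

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(1)
        od = rng.uniform(0, 1.0, (20, 20, 3))
        back = st.rgb_to_od(st.od_to_rgb(od))
        # one 8-bit step at I ~ 25..255 is < 0.02 OD
        np.testing.assert_allclose(back, od, atol=0.02)


class TestMacenko:
    def _mixture(self, rng, n=20000, noise=0.0):
        conc = rng.uniform(0, 1.2, (n, 2))
        conc[: n // 10, 1] = 0.0       # near-pure hematoxylin pixels
        conc[n // 10: n // 5, 0] = 0.0  # near-pure eosin pixels
        od = conc @ np.array([HEMATOXYLIN, EOSIN])
        if noise:
            od = np.clip(od + rng.normal(0, noise, od.shape), 0, None)
        return od.reshape(-1, 1, 3)

    def test_exact_recovery_of_known_vectors(self):
        od = self._mixture(np.random.default_rng(2))
        est = st.macenko_stain_vectors(od)
        for got, want in ((est.v1, HEMATOXYLIN), (est.v2, EOSIN)):
            ang = np.arccos(np.clip(np.dot(got, want), -1, 1))
            assert ang < 1e-3

    def test_noisy_recovery_within_two_degrees(self):
        od = self._mixture(np.random.default_rng(3), noise=0.01)
        est = st.macenko_stain_vectors(od)
        for got, want in ((est.v1, HEMATOXYLIN), (est.v2, EOSIN)):
            ang = np.degrees(np.arccos(np.clip(np.dot(got, want), -1, 1)))
            assert ang < 2.0

    def test_hematoxylin_like_vector_first(self):
        od = self._mixture(np.random.default_rng(4))
        est = st.macenko_stain_vectors(od)
        assert est.v1[2] > est.v2[2]  # larger blue OD component
        assert est.source == "macenko"

    def test_single_stain_degenerate(self):
        rng = np.random.default_rng(5)
        od = (rng.uniform(0.2, 1.0, (500, 1)) * np.array(HEMATOXYLIN)).reshape(-1, 1, 3)
        with pytest.raises(ValueError, match="degenerate"):
            st.macenko_stain_vectors(od)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            st.macenko_stain_vectors(np.zeros((4, 4, 3)))


class TestProjection:
    def test_pure_first_stain(self, he_vectors):
        od = 0.7 * np.array(he_vectors.v1).reshape(1, 1, 3)
        c1, c2 = st.project_onto_stains(od, he_vectors)
        assert c1[0, 0] == pytest.approx(0.7, abs=1e-12)
        assert c2[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_two_stain_algebra(self, he_vectors):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 2, (10, 10))
        b = rng.uniform(0, 2, (10, 10))
        m = he_vectors.matrix
        od = a[..., None] * m[:, 0] + b[..., None] * m[:, 1]
        c1, c2 = st.project_onto_stains(od, he_vectors)
        np.testing.assert_allclose(c1, a, atol=1e-9)
        np.testing.assert_allclose(c2, b, atol=1e-9)

    def test_zero_od(self, he_vectors):
        c1, c2 = st.project_onto_stains(np.zeros((3, 3, 3)), he_vectors)
        assert not c1.any() and not c2.any()

    def test_reconstruction_on_noisy_mixture(self, he_vectors):
        rng = np.random.default_rng(7)
        m = he_vectors.matrix
        a = rng.uniform(0, 1, (30, 30))
        b = rng.uniform(0, 1, (30, 30))
        noise = 0.01
        od = a[..., None] * m[:, 0] + b[..., None] * m[:, 1]
        od_noisy = od + rng.normal(0, noise, od.shape)
        c1, c2 = st.project_onto_stains(np.clip(od_noisy, 0, None), he_vectors)
        recon = c1[..., None] * m[:, 0] + c2[..., None] * m[:, 1]
        rms = np.sqrt(np.mean((recon - od) ** 2))
        assert rms < 3 * noise

    def test_collinear_vectors_rejected(self):
        v = unit((0.5, 0.6, 0.62))
        with pytest.raises(ValueError, match="collinear"):
            hz.StainVectors(v, v)


def toy_maps(lob, zon, n_zones=12, resolution=4000.0):
    fld = PortalityField(np.zeros(lob.shape), resolution, np.empty((0, 2)), np.empty((0, 2)))
    return ZonationMaps(lob.astype(np.int32), zon.astype(np.int32), n_zones, fld)


class TestZonatedQuantification:
    def test_constant_intensity(self):
        lob = np.array([[1, 1], [2, 2]])
        zon = np.array([[1, 2], [1, 2]])
        prof = st.zonated_quantification(np.full((2, 2), 3.5), toy_maps(lob, zon))
        assert (prof["mean_intensity"] == 3.5).all()
        assert prof["n_pixels"].sum() == 4

    def test_portality_intensity_recovers_zone_centers(self, small_zonation):
        maps, _ = small_zonation
        prof = st.zonated_quantification(maps.portality.values, maps)
        summary = hz.zone_profile_summary(prof)
        for _, row in summary.iterrows():
            center = (row["zone"] - 0.5) / 12
            assert abs(row["mean"] - center) < 0.5 / 12

    def test_brute_force_groupby_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            shape = (12, 15)
            lob = rng.integers(0, 4, shape)
            zon = np.where(lob > 0, rng.integers(1, 5, shape), 0)
            vals = rng.normal(0, 1, shape)
            prof = st.zonated_quantification(vals, toy_maps(lob, zon, n_zones=4))
            df = pd.DataFrame({"lobulus": lob.ravel(), "zone": zon.ravel(),
                               "v": vals.ravel()})
            df = df[df["lobulus"] > 0]
            expect = df.groupby(["lobulus", "zone"])["v"].agg(["mean", "size"]).reset_index()
            got = prof.sort_values(["lobulus", "zone"]).reset_index(drop=True)
            expect = expect.sort_values(["lobulus", "zone"]).reset_index(drop=True)
            assert len(got) == len(expect)
            np.testing.assert_allclose(got["mean_intensity"], expect["mean"], rtol=1e-12)
            np.testing.assert_array_equal(got["n_pixels"], expect["size"])

    def test_pixel_counts_partition_mask(self, small_zonation):
        maps, mask = small_zonation
        prof = st.zonated_quantification(np.zeros(maps.lobuli.shape), maps)
        assert prof["n_pixels"].sum() == mask.mask.sum()

    def test_extent_mismatch(self, small_zonation):
        maps, _ = small_zonation
        with pytest.raises(ValueError):
            st.zonated_quantification(np.zeros((5, 5)), maps)


class TestZoneProfileSummary:
    def test_single_lobulus_identity(self):
        prof = pd.DataFrame({"lobulus": [1, 1, 1], "zone": [1, 2, 3],
                             "mean_intensity": [0.5, 0.6, 0.7], "n_pixels": [9, 9, 9]})
        summ = hz.zone_profile_summary(prof)
        np.testing.assert_allclose(summ["mean"], [0.5, 0.6, 0.7])
        np.testing.assert_allclose(summ["median"], summ["mean"])

    def test_two_lobuli_mean(self):
        prof = pd.DataFrame({"lobulus": [1, 2], "zone": [1, 1],
                             "mean_intensity": [0.2, 0.4], "n_pixels": [5, 5]})
        summ = hz.zone_profile_summary(prof)
        assert summ.loc[0, "mean"] == pytest.approx(0.3)
        assert summ.loc[0, "n_lobuli"] == 2

    def test_aggregation_oracle_random(self):
        rng = np.random.default_rng(9)
        prof = pd.DataFrame({
            "lobulus": rng.integers(1, 20, 300),
            "zone": rng.integers(1, 13, 300),
            "mean_intensity": rng.uniform(0, 1, 300),
            "n_pixels": rng.integers(1, 50, 300)})
        summ = hz.zone_profile_summary(prof).set_index("zone")
        for z, grp in prof.groupby("zone"):
            assert summ.loc[z, "mean"] == pytest.approx(grp["mean_intensity"].mean())
            assert summ.loc[z, "median"] == pytest.approx(grp["mean_intensity"].median())

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            hz.zone_profile_summary(pd.DataFrame(columns=["zone", "mean_intensity"]))
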