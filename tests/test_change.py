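import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floracast._utils import lonlat_to_unit_vectors, unit_vector_to_lonlat
from floracast.change import (
    CONTRACTION,
    EXPANSION,
    NORTHWARD,
    SOUTHWARD,
    STABLE,
    STABLE_LATITUDE,
    centroid,
    classify_change,
    migration_vector,
    sector_mean_migration,
    summarize_change,
)
from floracast.errors import NoCentroidError, UndefinedBaselineError
from floracast.projection import make_range_map

from conftest import tiny_grid


def _map(occ_cells, shape=(10, 10), lat0=55.5, lon0=0.5, species="sp",
         period="current", scenario="none"):
    """Range map with given occupied (row, col) cells on a 1-degree grid."""
    suit = np.zeros(shape)
    for r, c in occ_cells:
        suit[r, c] = 1.0
    grid = tiny_grid({"a": np.zeros(shape)}, lon0=lon0, lat0=lat0,
                     period=period, scenario=scenario)
    return make_range_map(species, grid, suit, 0.5)


class TestClassifyChange:
    def test_within_band_stable(self):
        assert classify_change(100, 104) == STABLE

    def test_zero_change_stable(self):
        assert classify_change(100, 100) == STABLE

    def test_contraction_and_expansion(self):
        assert classify_change(100, 40) == CONTRACTION
        assert classify_change(100, 250) == EXPANSION
        assert (250 - 100) / 100 == pytest.approx(1.5)  # fold change

    def test_band_edge_symmetric(self):
        assert classify_change(100, 105.0) == STABLE
        assert classify_change(100, 95.0) == STABLE
        assert classify_change(100, 105.0000001 + 1e-4) == EXPANSION
        assert classify_change(100, 94.9999 - 1e-4) == CONTRACTION

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedBaselineError):
            classify_change(0, 10)


class TestCentroid:
    def test_single_cell(self):
        m = _map([(3, 4)])
        lon, lat = centroid(m)
        assert lon == pytest.approx(4.5, abs=1e-9)
        assert lat == pytest.approx(58.5, abs=1e-9)

    def test_two_cells_spherical_mean(self):
        # oracle: average the two unit vectors numerically
        m = _map([(0, 0), (0, 9)], lat0=60.5, lon0=-9.5)  # cells at lon -9.5, +(-0.5)
        lon, lat = centroid(m)
        v = lonlat_to_unit_vectors([-9.5, -0.5], [60.5, 60.5]).mean(axis=0)
        lon_o, lat_o = unit_vector_to_lonlat(v)
        assert lon == pytest.approx(lon_o, abs=1e-9)
        assert lat == pytest.approx(lat_o, abs=1e-9)
        assert lat > 60.5  # spherical mean of an east-west pair is poleward

    def test_symmetric_pair_at_60N(self):
        grid = tiny_grid({"a": np.zeros((1, 21))}, lon0=-10.0, lat0=60.0)
        suit = np.zeros((1, 21))
        suit[0, 0] = suit[0, 20] = 1.0  # cells at -10 and +10 longitude
        m = make_range_map("sp", grid, suit, 0.5)
        lon, lat = centroid(m)
        assert lon == pytest.approx(0.0, abs=1e-9)
        assert lat > 60.0

    def test_translation_property(self):
        cells = [(r, c) for r in range(2, 5) for c in range(3, 7)]
        m_now = _map(cells)
        shifted = [(r + 5, c) for r, c in cells]
        m_fut = _map(shifted)
        _, lat_now = centroid(m_now)
        _, lat_fut = centroid(m_fut)
        assert lat_fut - lat_now == pytest.approx(5.0, abs=0.1)

    def test_cell_order_invariance(self):
        cells = [(1, 1), (4, 7), (2, 3)]
        a = centroid(_map(cells))
        b = centroid(_map(cells[::-1]))
        assert a == pytest.approx(b)

    def test_planar_agreement_small_patch(self):
        cells = [(r, c) for r in range(3, 6) for c in range(2, 8)]
        m = _map(cells, lat0=55.5)
        lon, lat = centroid(m)
        rows, cols = np.nonzero(m.occupancy)
        w = m.cell_areas()[rows, cols]
        lon_planar = np.average(m.lon_centers[cols], weights=w)
        lat_planar = np.average(m.lat_centers[rows], weights=w)
        assert lon == pytest.approx(lon_planar, abs=0.05)
        assert lat == pytest.approx(lat_planar, abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(NoCentroidError):
            centroid(_map([]))


class TestMigrationVector:
    def test_identical_centroids(self):
        dlat, dlon, shift, direction = migration_vector((10.0, 70.0), (10.0, 70.0))
        assert (dlat, dlon, shift) == (0.0, 0.0, 0.0)
        assert direction == STABLE_LATITUDE

    def test_one_degree_north(self):
        dlat, dlon, shift, direction = migration_vector((0.0, 70.0), (0.0, 71.0))
        assert dlat == 1.0 and dlon == 0.0
        assert shift == pytest.approx(111.195, abs=0.01)  # R * pi / 180
        assert direction == NORTHWARD

    def test_antimeridian_wrap(self):
        dlat, dlon, _, _ = migration_vector((179.0, 70.0), (-179.0, 70.0))
        assert dlon == pytest.approx(2.0)

    def test_southward(self):
        *_, direction = migration_vector((0.0, 70.0), (0.0, 69.0))
        assert direction == SOUTHWARD

    @given(
        st.floats(-180, 180), st.floats(-85, 85),
        st.floats(-180, 180), st.floats(-85, 85),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_symmetry(self, lon1, lat1, lon2, lat2):
        _, _, s_ab, _ = migration_vector((lon1, lat1), (lon2, lat2))
        _, _, s_ba, _ = migration_vector((lon2, lat2), (lon1, lat1))
        assert s_ab == pytest.approx(s_ba, abs=1e-6)
        assert s_ab >= 0


class TestSummarizeChange:
    def test_expansion_row(self):
        now = _map([(2, 2)])
        fut = _map([(2, 2), (3, 2), (4, 2)], period="2090s", scenario="SSP5-8.5")
        s = summarize_change(now, fut)
        assert s.change_class == EXPANSION
        assert not s.extinct_flag
        assert s.dlat > 0 and s.direction_class == NORTHWARD
        assert s.delta_km2 == pytest.approx(fut.aoh_km2 - now.aoh_km2)

    def test_extinction_row(self):
        now = _map([(2, 2)])
        fut = _map([], period="2090s", scenario="SSP5-8.5")
        s = summarize_change(now, fut)
        assert s.extinct_flag
        assert s.change_class == CONTRACTION  # extinct implies contraction
        assert s.centroid_future is None and s.dlat is None

    def test_species_mismatch_rejected(self):
        now = _map([(2, 2)], species="a")
        fut = _map([(2, 2)], species="b", period="2090s", scenario="SSP5-8.5")
        with pytest.raises(ValueError):
            summarize_change(now, fut)


def _summary(dlat, lon=0.0, lat=60.0, extinct=False, species="s"):
    from floracast.change import ChangeSummary

    return ChangeSummary(
        species_id=species, period="2090s", scenario="SSP5-8.5",
        aoh_now_km2=100.0, aoh_future_km2=0.0 if extinct else 120.0,
        delta_km2=0.0, fold_change=0.2, change_class=EXPANSION,
        extinct_flag=extinct, centroid_now=(lon, lat),
        centroid_future=None if extinct else (lon, lat + dlat),
        dlat=None if extinct else dlat, dlon=None if extinct else 0.0,
        shift_km=None if extinct else abs(dlat) * 111.0,
        direction_class=None if extinct else (NORTHWARD if dlat > 0 else SOUTHWARD),
    )


class TestSectorMeanMigration:
    sector_of = staticmethod(lambda lon, lat: "A" if lon < 10 else "B")

    def test_uniform_shift(self):
        summaries = [_summary(2.0, species=f"s{i}") for i in range(5)]
        m = sector_mean_migration(summaries, "A", self.sector_of)
        assert m.mean_dlat == pytest.approx(2.0)
        assert m.pct_northward == 100.0

    def test_mixed_shifts(self):
        summaries = [_summary(3.0), _summary(-1.0, species="t")]
        m = sector_mean_migration(summaries, "A", self.sector_of)
        assert m.mean_dlat == pytest.approx(1.0)
        assert m.pct_northward == 50.0

    def test_extinct_excluded_from_means_counted_in_tally(self):
        summaries = [_summary(2.0), _summary(0.0, extinct=True, species="x")]
        m = sector_mean_migration(summaries, "A", self.sector_of)
        assert m.mean_dlat == pytest.approx(2.0)
        assert m.n_extinct == 1
        assert m.n_species == 2

    def test_empty_sector_warns(self):
        with pytest.warns(UserWarning):
            out = sector_mean_migration([_summary(1.0)], "B", self.sector_of)
        assert out is None
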