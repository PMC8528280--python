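"""Census loading, normalization, temperature partitioning and windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import oifnet as o
from oifnet.abundance import default_species_meta


def _write_census(tmp_path, df):
    p = tmp_path / "census.csv"
    df.to_csv(p, index=False)
    return p


class TestLoadCensus:
    def test_roundtrip(self, toy_census, tmp_path):
        p = _write_census(tmp_path, toy_census.to_frame())
        tab = o.load_census(p)
        assert tab.n == 3 and tab.L == 6
        np.testing.assert_allclose(tab.counts, toy_census.counts)
        np.testing.assert_allclose(tab.mean_temp, toy_census.mean_temp)

    def test_all_zero_counts_is_valid(self, tmp_path):
        df = pd.DataFrame({
            "date": pd.date_range("2002-01-01", periods=3, freq="15D"),
            "surface.t": [10.0, 11.0, 12.0], "bottom.t": [9.0, 10.0, 11.0],
            "a": [0.0, 0.0, 0.0], "b": [0.0, 0.0, 0.0]})
        tab = o.load_census(_write_census(tmp_path, df))
        assert tab.n == 2 and np.all(tab.counts == 0)

    def test_metadata_count_mismatch_names_both(self, toy_census, tmp_path):
        p = _write_census(tmp_path, toy_census.to_frame())
        with pytest.raises(ValueError, match="3.*2|2.*3"):
            o.load_census(p, meta=default_species_meta(2))

    def test_missing_temperature_is_hard_error(self, toy_census, tmp_path):
        df = toy_census.to_frame().drop(columns=["bottom.t"])
        with pytest.raises(ValueError, match="surface.t"):
            o.load_census(_write_census(tmp_path, df))

    def test_nonmonotone_dates_name_offenders(self, toy_census, tmp_path):
        df = toy_census.to_frame()
        df.loc[3, "date"] = df.loc[1, "date"]
        with pytest.raises(ValueError, match="increasing"):
            o.load_census(_write_census(tmp_path, df))

    def test_negative_abundance_is_hard_error(self, toy_census, tmp_path):
        df = toy_census.to_frame()
        df.loc[2, "sp1"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            o.load_census(_write_census(tmp_path, df))


class TestNormalize:
    def test_symmetric_column_gives_unit_zscores(self, toy_census):
        toy_census.counts[0] = [0, 2, 4, 0, 2, 4]
        na = o.normalize(toy_census)
        # the sample sd (denominator L-1) of a balanced 0/2/4 column maps the
        # values onto +-sqrt(5/6)... use the forced 3-point case instead
        dates = pd.date_range("2002-01-01", periods=3, freq="15D")
        tab = o.CensusTable(
            timestamps=pd.DatetimeIndex(dates),
            counts=np.array([[0.0, 2.0, 4.0]]),
            surface_temp=np.array([10.0, 11.0, 12.0]),
            bottom_temp=np.array([14.0, 13.0, 12.0]),
            species_meta=default_species_meta(1))
        na = o.normalize(tab)
        np.testing.assert_allclose(na.x[0], [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(na.mean_temp, [12.0, 12.0, 12.0])

    def test_zscores_have_zero_mean_unit_sd(self, default_community):
        tab, _ = default_community
        na = o.normalize(tab)
        np.testing.assert_allclose(na.x.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(na.x.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_idempotent(self, toy_census):
        na = o.normalize(toy_census)
        renorm = (na.x - na.x.mean(axis=1, keepdims=True)) / na.x.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(renorm, na.x, atol=1e-9)

    def test_constant_species_errors_with_name(self, toy_census):
        toy_census.counts[1] = 5.0
        with pytest.raises(ValueError, match="sp2"):
            o.normalize(toy_census)


class TestPartition:
    def test_boundary_goes_up(self, toy_census):
        # the 15.0 degC census point must land in the 15-20 bin
        na = o.normalize(toy_census)
        part = o.partition_by_TR(na)
        k = list(part.membership)
        assert toy_census.mean_temp[5] == 15.0
        assert part.bins[k[5]] == "15-20"
        # brute-force membership check for every point
        for t, T in enumerate(na.mean_temp):
            lab = part.bins[k[t]]
            if lab.startswith("<="):
                assert T <= 10
            elif lab.startswith(">="):
                assert T >= 25
            else:
                lo, hi = map(float, lab.split("-"))
                assert lo <= T < hi

    def test_single_bin_when_uniform(self, toy_census):
        toy_census.surface_temp[:] = 12.0
        toy_census.bottom_temp[:] = 12.0
        na = o.normalize(toy_census)
        part = o.partition_by_TR(na)
        assert part.sizes == (0, 6, 0, 0, 0)

    @given(temps=st.lists(st.floats(-2, 35, allow_nan=False), min_size=1, max_size=60))
    def test_partition_conserves_points(self, temps):
        L = len(temps)
        x = np.tile(np.linspace(-1, 1, L), (2, 1)) + 1e-3 * np.arange(2)[:, None]
        na = o.NormalizedAbundance(
            x=x, timestamps=pd.DatetimeIndex(
                pd.date_range("2002-01-01", periods=L, freq="15D")),
            mean_temp=np.array(temps))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = o.partition_by_TR(na)
        assert sum(part.sizes) == L
        assert np.bincount(part.membership, minlength=5).tolist() == list(part.sizes)


class TestWindows:
    @pytest.mark.parametrize("axis,L,l,step,G", [
        ("time", 285, 24, 2, 131),
        ("temperature", 31, 10, 1, 22),
        ("time", 24, 24, 2, 1),
    ])
    def test_window_counts(self, axis, L, l, step, G):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = o.make_windows(axis, L, l, step)
        assert spec.G == G
        assert len(spec.starts()) == G

    def test_temperature_windows_are_5deg_halfopen(self):
        spec = o.make_windows("temperature", 31, 10, 1)
        ivals = spec.temperature_intervals()
        assert ivals[0] == (5.0, 10.0)
        assert ivals[-1] == (26.0, 31.0)
        assert all(b - a == 5.0 for a, b in ivals)

    @given(L=st.integers(2, 400), l=st.integers(1, 100), step=st.integers(1, 20))
    def test_G_matches_bruteforce_start_enumeration(self, L, l, step):
        import warnings
        if L <= l:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = o.make_windows("time", L, l, step)
        starts = [s for s in range(0, L, step) if s + l <= L]
        assert spec.G == len(starts)

    def test_nonpositive_step_errors(self):
        with pytest.raises(ValueError):
            o.make_windows("time", 100, 10, 0)


class TestDiversity:
    def test_counts_strictly_positive_presences(self, toy_census):
        d = o.alpha_diversity(toy_census)
        assert d.alpha_t.tolist() == [1, 2, 3, 1, 3, 3]

    def test_alpha_bounds_and_rescale_invariance(self, default_community):
        tab, _ = default_community
        d1 = o.alpha_diversity(tab)
        assert np.all(d1.alpha_t <= tab.n) and np.all(d1.alpha_t >= 0)
        tab2 = o.CensusTable(
            timestamps=tab.timestamps, counts=tab.counts * np.pi,
            surface_temp=tab.surface_temp, bottom_temp=tab.bottom_temp,
            species_meta=tab.species_meta)
        assert np.array_equal(o.alpha_diversity(tab2).alpha_t, d1.alpha_t)

    def test_all_zero_time_point(self, toy_census):
        toy_census.counts[:, 3] = 0.0
        assert o.alpha_diversity(toy_census).alpha_t[3] == 0


class TestGroupAbundance:
    def test_ep_is_native_plus_invasive(self, default_community):
        tab, _ = default_community
        na = o.normalize(tab)
        ep = o.group_abundance(tab, "EP", na)
        nat = o.group_abundance(tab, "native", na)
        inv = o.group_abundance(tab, "invasive", na)
        np.testing.assert_allclose(ep, nat + inv, atol=1e-9)

    def test_single_species_group_equals_its_series(self, toy_census):
        na = o.normalize(toy_census)
        inv = o.group_abundance(toy_census, "invasive", na)  # only sp2
        np.testing.assert_allclose(inv, na.x[1])

    def test_totals_match_bruteforce_sums(self, default_community):
        tab, _ = default_community
        na = o.normalize(tab)
        fs = o.group_abundance(tab, "FS", na)
        mask = [m.is_fish_stock for m in tab.species_meta]
        expect = sum(na.x[i] for i in range(tab.n) if mask[i])
        np.testing.assert_allclose(fs, expect, atol=1e-9)

    def test_unknown_group_lists_valid_labels(self, toy_census):
        with pytest.raises(ValueError, match="EP"):
            o.group_abundance(toy_census, "plankton")
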