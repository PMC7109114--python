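import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsascan.association_scan import (
    AssociationTrack,
    call_regions,
    delta_snp_index,
    dsnp_for_variant,
    ed_association_value,
    ed_value,
    fit_windows,
    pool_frequencies,
    snp_index,
    threshold_median_3sd,
    threshold_null_simulation,
    threshold_quantile,
)
from bsascan.variant_io import GeneModel, ValidationError

from conftest import make_variant


def test_pool_frequencies_from_depth_table(roles, table_row_variant):
    freqs, reason = pool_frequencies(table_row_variant, roles)
    assert reason is None
    assert freqs.axes == ("ref", "alt")  # InDel axes
    np.testing.assert_allclose(freqs.green, [1.0, 0.0])
    np.testing.assert_allclose(freqs.red, [24 / 33, 9 / 33])


def test_pool_frequencies_snp_on_nucleotide_axes(roles):
    v = make_variant(
        "Chr04", 9_115_802, "T", ["A"],
        {"red_parent": (3, 4), "original": (8, 0), "green_parent": (7, 0),
         "green_pool": (11, 0), "red_pool": (7, 6)},
    )
    freqs, _ = pool_frequencies(v, roles)
    assert freqs.axes == ("A", "C", "G", "T")
    np.testing.assert_allclose(freqs.red, [6 / 13, 0, 0, 7 / 13])
    np.testing.assert_allclose(freqs.green, [0, 0, 0, 1.0])


def test_pool_frequencies_zero_depth_excluded(roles):
    v = make_variant(
        "Chr04", 10, "T", ["A"],
        {"red_parent": (3, 4), "original": (8, 0), "green_parent": (7, 0),
         "green_pool": (0, 0), "red_pool": (7, 6)},
    )
    freqs, reason = pool_frequencies(v, roles)
    assert freqs is None and reason == "zero_pool_depth"


def test_ed_examples():
    assert ed_value(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0
    assert ed_value(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(math.sqrt(2))
    # from the candidate-row depths: green (1,0) vs red (24/33, 9/33)
    ed = ed_value(np.array([24 / 33, 9 / 33]), np.array([1.0, 0.0]))
    assert ed == pytest.approx(0.38569, abs=1e-5)
    assert ed_association_value(ed) == pytest.approx(0.00853, abs=1e-5)


def test_ed_axis_mismatch():
    with pytest.raises(ValidationError):
        ed_value(np.zeros(4), np.zeros(2))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    f_red=st.floats(0, 1),
    f_green=st.floats(0, 1),
)
def test_ed_biallelic_identity(f_red, f_green):
    """For a biallelic site on the 4-nucleotide axes, ED = sqrt(2)*|df|."""
    red = np.array([1 - f_red, 0, 0, f_red])
    green = np.array([1 - f_green, 0, 0, f_green])
    assert ed_value(red, green) == pytest.approx(
        math.sqrt(2) * abs(f_red - f_green), abs=1e-12
    )
    assert 0 <= ed_value(red, green) <= math.sqrt(2) + 1e-12


@pytest.mark.parametrize(
    "m,p,expected",
    [(39, 0, 1.0), (24, 9, 24 / 33), (7, 7, 0.5)],
)
def test_snp_index(m, p, expected):
    assert snp_index(m, p) == pytest.approx(expected)


def test_snp_index_zero_depth_undefined():
    assert snp_index(0, 0) is None


def test_delta_snp_index():
    assert delta_snp_index(1.0, 24 / 33) == pytest.approx(9 / 33)
    assert delta_snp_index(0.4, 0.4) == 0.0
    assert delta_snp_index(1.0, 0.0) == 1.0


def test_dsnp_for_variant_candidate_row(roles, table_row_variant):
    """Green parent hom ref (female) vs red parent het: M = ref allele.
    Green pool 39,0 -> index 1.0; red pool 24,9 -> 24/33."""
    val, reason = dsnp_for_variant(table_row_variant, roles)
    assert reason is None
    assert val == pytest.approx(1.0 - 24 / 33)


def test_dsnp_uninformative_when_parents_match(roles):
    v = make_variant(
        "Chr04", 11, "A", ["G"],
        {"red_parent": (10, 9), "original": (8, 9), "green_parent": (12, 13),
         "green_pool": (20, 21), "red_pool": (19, 18)},
    )
    val, reason = dsnp_for_variant(v, roles)
    assert val is None and reason == "uninformative_parents"


# ---------------------------------------------------------------------------
# Windows


def brute_force_windows(positions, values, chrom_length, window, step, min_n):
    starts = list(range(0, max(chrom_length - window, 0) + 1, step))
    fitted = []
    for s in starts:
        inside = [v for p, v in zip(positions, values) if s <= p - 1 < s + window]
        fitted.append(sum(inside) / len(inside) if len(inside) >= min_n else float("nan"))
    return starts, fitted


def test_fit_windows_single_variant_constant():
    t = fit_windows([5000], [0.7], chrom_length=100_000, window=10_000, step=2_000)
    covering = (t.window_start <= 4999) & (4999 < t.window_start + 10_000)
    assert np.all(t.fitted[covering] == 0.7)
    assert np.all(np.isnan(t.fitted[~covering]))


def test_fit_windows_mean_of_two():
    t = fit_windows([100, 200], [0.2, 0.4], chrom_length=1_000, window=1_000, step=1_000)
    assert t.fitted[0] == pytest.approx(0.3)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_fit_windows_matches_brute_force(data):
    n = data.draw(st.integers(0, 40))
    chrom_length = data.draw(st.integers(1_000, 100_000))
    step = data.draw(st.sampled_from([500, 1_000, 2_500]))
    window = step * data.draw(st.integers(1, 8))
    min_n = data.draw(st.integers(1, 3))
    positions = data.draw(
        st.lists(st.integers(1, chrom_length), min_size=n, max_size=n)
    )
    values = data.draw(
        st.lists(st.floats(-1, 1, allow_nan=False), min_size=n, max_size=n)
    )
    t = fit_windows(positions, values, chrom_length, window=window, step=step,
                    min_variants_per_window=min_n)
    starts, expected = brute_force_windows(positions, values, chrom_length, window, step, min_n)
    assert list(t.window_start) == starts
    np.testing.assert_allclose(t.fitted, expected, rtol=1e-12, atol=1e-12, equal_nan=True)


# ---------------------------------------------------------------------------
# Thresholds


def _track_from_fitted(fitted, window=10_000, step=10_000, chrom="c", kind="ED5",
                       chrom_length=None):
    fitted = np.asarray(fitted, float)
    starts = np.arange(len(fitted)) * step
    return AssociationTrack(
        chrom=chrom, kind=kind, positions=np.array([]), raw=np.array([]),
        window=window, step=step,
        chrom_length=chrom_length or int(starts[-1] + window),
        window_start=starts, fitted=fitted,
        n_variants=np.where(np.isnan(fitted), 0, 1),
    )


def test_threshold_median_3sd_hand_example():
    t = _track_from_fitted([0, 0, 0, 1])
    thr = threshold_median_3sd(t)
    assert thr.value == pytest.approx(1.5)  # median 0 + 3*0.5


def test_threshold_median_3sd_constant_track():
    thr = threshold_median_3sd(_track_from_fitted([0.3, 0.3, 0.3]))
    assert thr.value == pytest.approx(0.3)


def test_threshold_quantile_interpolation_and_median():
    t = _track_from_fitted(np.arange(1.0, 101.0))
    assert threshold_quantile(t, 0.99).value == pytest.approx(99.01)
    assert threshold_quantile(t, 0.5).value == pytest.approx(np.median(np.arange(1.0, 101.0)))
    with pytest.raises(ValidationError):
        threshold_quantile(t, 1.5)


def test_threshold_null_simulation_monotone_in_depth():
    thr = threshold_null_simulation([10, 40, 100, 1000], level=0.90, n_sims=20_000, seed=5)
    b = thr.params["per_depth"]
    assert b[10] > b[100] > b[1000]
    # Monte-Carlo self-consistency at depth 40 between two seeds
    thr2 = threshold_null_simulation([40], level=0.90, n_sims=100_000, seed=6)
    thr3 = threshold_null_simulation([40], level=0.90, n_sims=100_000, seed=7)
    assert abs(thr2.params["per_depth"][40] - thr3.params["per_depth"][40]) < 0.02


# ---------------------------------------------------------------------------
# Regions


def test_call_regions_windows_are_exactly_above_threshold_set():
    rng = np.random.default_rng(11)
    fitted = rng.random(300)
    fitted[rng.random(300) < 0.1] = np.nan
    t = _track_from_fitted(fitted, window=30_000, step=10_000)
    thr = 0.8
    regions = call_regions(t, thr)
    # oracle: the union of the regions' window starts equals the set of
    # defined windows with fitted >= threshold
    above = {int(s) for s, f in zip(t.window_start, fitted) if not np.isnan(f) and f >= thr}
    covered = {
        int(s)
        for r in regions
        for s in t.window_start
        if r.start <= s <= r.end
    }
    assert covered == above


def test_call_regions_not_merged_across_gaps():
    fitted = [1, 1, 0, 1, np.nan, 1]
    t = _track_from_fitted(fitted, window=10_000, step=10_000)
    regions = call_regions(t, 0.5)
    assert len(regions) == 3
    assert [(r.start, r.end) for r in regions] == [
        (0, 10_000), (30_000, 30_000), (50_000, 50_000)
    ]


def test_call_region_size_arithmetic_and_gene_count():
    # run of above-threshold 2 Mb windows with starts 8,840,000 .. 22,590,000
    n = 2_700
    fitted = np.zeros(n)
    lo, hi = 884, 2259
    fitted[lo : hi + 1] = 1.0
    t = _track_from_fitted(fitted, window=2_000_000, step=10_000,
                           chrom="Chr04", chrom_length=30_000_000)
    genes = [
        GeneModel("inside", "Chr04", "+", ((9_000_000, 9_001_000),), ((9_000_000, 9_001_000),)),
        GeneModel("outside", "Chr04", "+", ((25_000_000, 25_001_000),), ((25_000_000, 25_001_000),)),
        GeneModel("other", "Chr05", "+", ((9_000_000, 9_001_000),), ((9_000_000, 9_001_000),)),
    ]
    (region,) = call_regions(t, 0.5, gene_models=genes)
    assert (region.start, region.end) == (8_840_000, 22_590_000)
    assert region.size_mb == pytest.approx(13.75)
    assert region.gene_count == 1


def test_call_regions_zero_size_region():
    """A single above-threshold window yields a start == end (0 Mb) region."""
    fitted = np.zeros(100)
    fitted[50] = 1.0
    t = _track_from_fitted(fitted, window=2_000_000, step=10_000)
    (region,) = call_regions(t, 0.5)
    assert region.start == region.end == 500_000
    assert region.size_mb == 0.0
    assert call_regions(t, 2.0) == []
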