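import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disomap import disorder
from disomap.datatypes import RegionSet

from conftest import make_track


# ----------------------------------------------------------------------- MDP

def test_mdp_two_point_mean_and_sd():
    mdp, sd = disorder.compute_mdp([make_track([0.2]), make_track([0.4])])
    assert mdp.values[0] == pytest.approx(0.3)
    assert sd.values[0] == pytest.approx(np.sqrt(0.02), abs=1e-12)


def test_mdp_single_track_is_identity_with_zero_band():
    track = make_track([0.1, 0.5, 0.9])
    mdp, sd = disorder.compute_mdp([track])
    assert np.allclose(mdp.values, track.values)
    assert np.allclose(sd.values, 0.0)


def test_mdp_matches_summation_oracle(rng):
    tracks = [make_track(rng.uniform(0, 1, 50)) for _ in range(6)]
    for t in tracks:  # plant some missing values
        t.values[rng.integers(0, 50, 4)] = np.nan
    mdp, sd = disorder.compute_mdp(tracks)
    for i in range(50):
        vals = [t.values[i] for t in tracks if not np.isnan(t.values[i])]
        assert mdp.values[i] == pytest.approx(sum(vals) / len(vals))
        lo = min(t.values[i] for t in tracks if not np.isnan(t.values[i]))
        hi = max(t.values[i] for t in tracks if not np.isnan(t.values[i]))
        assert lo - 1e-12 <= mdp.values[i] <= hi + 1e-12


def test_mdp_rejects_residue_missing_everywhere():
    bad = [make_track([0.1, np.nan]), make_track([0.2, np.nan])]
    with pytest.raises(ValueError, match="residue 2"):
        disorder.compute_mdp(bad)
    with pytest.raises(ValueError, match="length"):
        disorder.compute_mdp([make_track([0.1]), make_track([0.1, 0.2])])


# ---------------------------------------------------------------------- PPDR

def test_ppdr_examples():
    assert disorder.ppdr(make_track([0.6, 0.4, 0.5, 0.2])) == pytest.approx(50.0)
    assert disorder.ppdr(make_track([0.0] * 7)) == 0.0


def test_ppdr_matches_counting_oracle(rng):
    values = rng.uniform(0, 1, 1000)
    values[rng.integers(0, 1000, 30)] = np.nan
    track = make_track(values)
    present = values[~np.isnan(values)]
    expected = 100.0 * sum(1 for v in present if v >= 0.5) / len(present)
    assert disorder.ppdr(track) == pytest.approx(expected)


def test_ppdr_monotone_in_threshold_and_permutation_invariant(rng):
    values = rng.uniform(0, 1, 200)
    track = make_track(values)
    thresholds = np.linspace(0, 1, 11)
    ppdrs = [disorder.ppdr(track, t) for t in thresholds]
    assert all(a >= b for a, b in zip(ppdrs, ppdrs[1:]))
    shuffled = make_track(rng.permutation(values))
    assert disorder.ppdr(shuffled) == pytest.approx(disorder.ppdr(track))


def test_ppdr_empty_rejected():
    with pytest.raises(ValueError):
        disorder.ppdr(make_track([np.nan, np.nan]))


# ------------------------------------------------------------- classification

@pytest.mark.parametrize("value,expected", [
    (8.47, disorder.HIGHLY_ORDERED),
    (15.65, disorder.MODERATELY_DISORDERED),
    (10.0, disorder.MODERATELY_DISORDERED),
    (30.0, disorder.HIGHLY_DISORDERED),
    (0.0, disorder.HIGHLY_ORDERED),
    (100.0, disorder.HIGHLY_DISORDERED),
])
def test_disorder_category_boundaries(value, expected):
    assert disorder.classify_disorder(value) == expected


@settings(derandomize=True, max_examples=300)
@given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
def test_disorder_categories_partition_domain(value):
    label = disorder.classify_disorder(value)
    assert label in (disorder.HIGHLY_ORDERED, disorder.MODERATELY_DISORDERED,
                     disorder.HIGHLY_DISORDERED)
    if label == disorder.HIGHLY_ORDERED:
        assert value < 10
    elif label == disorder.MODERATELY_DISORDERED:
        assert 10 <= value < 30
    else:
        assert value >= 30


def test_disorder_category_out_of_range():
    for bad in (-0.1, 100.1):
        with pytest.raises(ValueError):
            disorder.classify_disorder(bad)


# ------------------------------------------------------------------- regions

def regions_oracle(values, threshold, min_length):
    """Brute force: test every interval for above-threshold and maximality."""
    n = len(values)
    ok = [not np.isnan(v) and v >= threshold for v in values]
    out = []
    for s in range(n):
        for e in range(s, n):
            if all(ok[s:e + 1]) and (s == 0 or not ok[s - 1]) \
                    and (e == n - 1 or not ok[e + 1]) \
                    and e - s + 1 >= min_length:
                out.append((s + 1, e + 1))
    return out


def test_extract_regions_examples():
    regions = disorder.extract_regions(make_track([0.7, 0.7, 0.3, 0.9]), 0.5)
    assert [(r.start, r.end) for r in regions] == [(1, 2), (4, 4)]
    empty = disorder.extract_regions(make_track([0.1, 0.2]), 0.5)
    assert len(empty) == 0


def test_extract_regions_missing_breaks_runs():
    regions = disorder.extract_regions(make_track([0.9, np.nan, 0.9]), 0.5)
    assert [(r.start, r.end) for r in regions] == [(1, 1), (3, 3)]


def test_extract_regions_matches_bruteforce(rng):
    for _ in range(30):
        values = rng.uniform(0, 1, 200)
        values[rng.uniform(size=200) < 0.05] = np.nan
        track = make_track(values)
        got = [(r.start, r.end)
               for r in disorder.extract_regions(track, 0.6, min_length=3)]
        assert got == regions_oracle(values, 0.6, 3)


def test_extract_regions_sorted_disjoint_maximal(rng):
    values = rng.uniform(0, 1, 300)
    regions = disorder.extract_regions(make_track(values), 0.5)
    spans = [(r.start, r.end) for r in regions]
    assert spans == sorted(spans)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        assert s2 > e1 + 1  # disjoint and not mergeable (maximality)
    for s, e in spans:
        assert all(values[s - 1:e] >= 0.5)
        if s > 1:
            assert values[s - 2] < 0.5
        if e < len(values):
            assert values[e] < 0.5


def test_regionset_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        RegionSet("P1", [(1, 5, "IDPR"), (4, 8, "IDPR")])
    # different kinds may overlap
    RegionSet("P1", [(1, 5, "IDPR"), (4, 8, "DPR")])


def test_summarize_disorder_consistency(rng):
    tracks = [make_track(rng.uniform(0, 1, 80), name=f"p{i}") for i in range(4)]
    summary = disorder.summarize_disorder(tracks)
    assert set(summary.ppdr_by_predictor) == {f"p{i}" for i in range(4)}
    for name, value in summary.ppdr_by_predictor.items():
        assert summary.category_by_predictor[name] == \
            disorder.classify_disorder(value)
    assert 0 <= summary.ppdr_mdp <= 100
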