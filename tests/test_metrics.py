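"""Derived statistics: ratios, normalisation, window partition, reporting
filters, GUIDE-seq retention and specificity, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editquant import (
    BaseEditProfile,
    ReadSimConfig,
    align_semiglobal,
    apply_reporting_filters,
    base_edit_profile,
    guideseq_specificity,
    mismatch_filter,
    normalize_activity,
    off_on_ratio,
    select_on_target_adenine,
    simulate_edited_reads,
    simulate_guideseq_readset,
    summarize,
    window_vs_bystander,
)
from editquant.simulate import SubEditFreq

from .conftest import random_dna


def make_profile(fracs: dict[int, float], ref_bases=None, variant="v") -> BaseEditProfile:
    bases = ref_bases or {p: ("A" if p in fracs else "C") for p in range(1, 21)}
    full = {p: fracs.get(p, float("nan")) for p in range(1, 21)}
    return BaseEditProfile(variant=variant, target_base="A", ref_bases=bases,
                           edited_fraction=full, n_reads=100)


@pytest.mark.parametrize("off,on,expected", [(0.05, 0.50, 0.10), (0.0, 0.4, 0.0), (0.3, 0.3, 1.0)])
def test_off_on_ratio(off, on, expected):
    assert off_on_ratio(off, on) == pytest.approx(expected)


def test_off_on_ratio_undefined_when_on_zero():
    assert math.isnan(off_on_ratio(0.1, 0.0))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(off=st.floats(0, 1), on=st.floats(0.01, 1), c=st.floats(0.01, 100))
def test_off_on_ratio_scale_invariant(off, on, c):
    assert off_on_ratio(off * c, on * c) == pytest.approx(off_on_ratio(off, on), rel=1e-9)


def test_normalize_activity():
    assert normalize_activity(0.8, 0.8) == 1.0
    assert normalize_activity(0.12, 0.80) == pytest.approx(0.15)
    assert math.isnan(normalize_activity(0.1, 0.0))


def test_normalization_is_per_pair_not_aggregate():
    # cohort where median of per-pair ratios differs from ratio of medians
    variant = [0.1, 0.4, 0.9]
    reference = [0.8, 0.5, 1.0]
    per_pair = [normalize_activity(v, r) for v, r in zip(variant, reference)]
    assert np.median(per_pair) != pytest.approx(np.median(variant) / np.median(reference))
    assert per_pair == pytest.approx([0.125, 0.8, 0.9])


def test_window_vs_bystander_partition():
    prof = make_profile({5: 0.6, 12: 0.1})
    win, by = window_vs_bystander(prof)
    assert win["positions"] == [5]
    assert by["positions"] == [12]
    assert win["summary"].median == pytest.approx(0.6)


def test_window_partition_covers_all_target_positions():
    prof = make_profile({p: 0.0 for p in (2, 4, 6, 8, 10, 19)})
    win, by = window_vs_bystander(prof)
    assert sorted(win["positions"] + by["positions"]) == [2, 4, 6, 8, 10, 19]
    assert set(win["positions"]).isdisjoint(by["positions"])
    assert win["summary"].median == 0.0 and by["summary"].median == 0.0


def test_window_empty_flagged():
    prof = make_profile({12: 0.3})
    win, _ = window_vs_bystander(prof)
    assert win["empty"] and win["summary"] is None


def test_profile_recovery_from_simulated_reads(tref):
    n = 1500
    subs = [SubEditFreq(4, "A", "G", 0.6), SubEditFreq(8, "A", "G", 0.6),
            SubEditFreq(12, "A", "G", 0.1, intended=False),
            SubEditFreq(15, "A", "G", 0.1, intended=False)]
    cfg = ReadSimConfig(amplicon=tref, n_reads=n, sub_edits=subs, seed=31)
    reads, _ = simulate_edited_reads(cfg)
    aligned = [align_semiglobal(str(r.seq), tref, r.id) for r in reads]
    prof = base_edit_profile(aligned, tref, target_base="A", variant="sim")
    for pos, p in [(4, 0.6), (8, 0.6), (12, 0.1), (15, 0.1)]:
        se = np.sqrt(p * (1 - p) / n)
        assert abs(prof.edited_fraction[pos] - p) <= 3 * se, pos
    assert prof.edited_fraction[18] == 0.0  # untouched adenine


def test_select_on_target_adenine_max_and_tie():
    profs = {"ref": make_profile({4: 0.2, 6: 0.7, 12: 0.5})}
    assert select_on_target_adenine(profs, "ref") == 6
    tie = {"ref": make_profile({5: 0.4, 6: 0.4})}
    assert select_on_target_adenine(tie, "ref") == 5  # smallest position wins


def test_select_on_target_adenine_brute_force_agreement(rng):
    for _ in range(20):
        pos = sorted(rng.choice(range(1, 21), size=5, replace=False))
        vals = rng.random(5)
        profs = {"ref": make_profile(dict(zip(map(int, pos), vals)))}
        brute = int(pos[int(np.argmax(vals))])
        assert select_on_target_adenine(profs, "ref") == brute


def test_select_on_target_adenine_errors():
    with pytest.raises(ValueError, match="missing"):
        select_on_target_adenine({}, "ref")
    no_a = make_profile({})
    with pytest.raises(ValueError, match="no target-base"):
        select_on_target_adenine({"ref": no_a}, "ref")


def test_reporting_filter_boundaries():
    df = pd.DataFrame({"on_target": [0.70, 0.71, 0.90, 0.30],
                       "editing": [0.2, 0.049, 0.5, 0.1]})
    retained, excluded = apply_reporting_filters(df)
    # strictly-exceeds rule: 0.70 itself is excluded
    assert list(retained.on_target) == [0.71, 0.90]
    assert list(excluded.on_target) == [0.70, 0.30]
    assert list(retained.low_editing) == [True, False]
    assert (excluded.rule == "on_target_not_exceeding_threshold").all()
    # partition property
    assert len(retained) + len(excluded) == len(df)


@pytest.mark.parametrize("mm,retain", [(0, True), (7, True), (8, False)])
def test_mismatch_filter_boundary(mm, retain):
    target = "GACGTACGTACGTACGTACG"
    cand = list(target)
    for i in range(mm):
        cand[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cand[i]]
    ok, count = mismatch_filter("".join(cand), target)
    assert count == mm and ok == retain


def test_mismatch_filter_matches_positionwise_count(rng):
    for _ in range(50):
        a, b = random_dna(rng, 20), random_dna(rng, 20)
        _, count = mismatch_filter(a, b)
        assert count == sum(x != y for x, y in zip(a, b))


def test_mismatch_filter_length_check():
    with pytest.raises(ValueError, match="length"):
        mismatch_filter("ACGT", "ACGTA")


def test_guideseq_specificity_values():
    only_on = simulate_guideseq_readset("A" * 20, [("A" * 20, 500, True)])
    pct, n_off = guideseq_specificity(only_on)
    assert pct == 100.0 and n_off == 0

    table = simulate_guideseq_readset(
        "A" * 20, [("A" * 20, 900, True), ("C" * 20, 100, False)]
    )
    pct, n_off = guideseq_specificity(table)
    assert pct == pytest.approx(90.0) and n_off == 1


def test_guideseq_specificity_summation(rng):
    counts = rng.integers(1, 500, size=5)
    sites = [(random_dna(rng, 20), int(c), i == 0) for i, c in enumerate(counts)]
    df = simulate_guideseq_readset(sites[0][0], sites)
    pct, n_off = guideseq_specificity(df)
    assert pct == pytest.approx(100 * counts[0] / counts.sum())
    assert 0 <= pct <= 100 and n_off == 4
    assert (pct == 100.0) == (counts[1:].sum() == 0)


def test_summarize():
    s = summarize([1, 2, 3])
    assert s.median == 2 and s.n == 3
    single = summarize([0.4])
    assert single.median == 0.4 and single.iqr == 0.0
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_quantiles_uniform(rng):
    draws = rng.random(1000)
    s = summarize(draws)
    assert abs(s.median - 0.5) <= 0.05
    assert abs(s.q1 - 0.25) <= 0.05
    assert abs(s.q3 - 0.75) <= 0.05
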