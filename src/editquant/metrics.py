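"""Derived activity/specificity statistics and reporting filters.

Covers the per-target summaries built on top of the outcome tables: editing
window vs bystander partitions for base editors, off-target/on-target
activity ratios, normalisation to a reference variant, desk-scale GUIDE-seq
specificity (percentage of on-target reads among all site reads after the
mismatch-retention rule), and the reporting filters used when presenting
mismatch screens (on-target activity must *exceed* 70%; editing below 5% is
flagged low).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedRead
from .amplicon import AmpliconReference
from .calling import EditSpec, call_base_edit

TARGET_CONVERSION = {"A": "G", "C": "T"}  # ABE: A->G, CBE: C->T


@dataclass
class Summary:
    """Median and interquartile range, linear-interpolation quantiles."""

    median: float
    q1: float
    q3: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summarize(values) -> Summary:
    """Median and [Q1, Q3] of a value list (linear interpolation)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return Summary(median=float(med), q1=float(q1), q3=float(q3), n=v.size)


@dataclass
class BaseEditProfile:
    """Per-protospacer-position substitution frequencies for one editor.

    ``edited_fraction[pos]`` is the fraction of non-indel passing reads whose
    base at protospacer position ``pos`` (1-20) was converted from the
    editor's target base (A->G or C->T).  Positions whose reference base is
    not the target base hold NaN.
    """

    variant: str
    target_base: str
    ref_bases: dict[int, str]
    edited_fraction: dict[int, float]
    n_reads: int
    window: tuple[int, int] = (4, 8)

    def target_positions(self) -> list[int]:
        return [p for p in range(1, 21) if self.ref_bases[p] == self.target_base]

    def window_positions(self) -> list[int]:
        lo, hi = self.window
        return [p for p in self.target_positions() if lo <= p <= hi]

    def bystander_positions(self) -> list[int]:
        lo, hi = self.window
        return [p for p in self.target_positions() if not lo <= p <= hi]


def base_edit_profile(
    aligned_reads: list[AlignedRead],
    ref: AmpliconReference,
    target_base: str = "A",
    window: tuple[int, int] = (4, 8),
    variant: str = "variant",
    include_indel_reads: bool = False,
) -> BaseEditProfile:
    """Build a per-position editing profile from aligned, filter-passing
    reads.  Indel-bearing reads are excluded from the denominator by default
    (consistent with counting substitutions "without indels")."""
    if target_base not in TARGET_CONVERSION:
        raise ValueError("target_base must be 'A' or 'C'")
    to_base = TARGET_CONVERSION[target_base]
    ref_bases = {p: ref.base_at(p) for p in range(1, 21)}
    counts = {p: 0 for p in range(1, 21)}
    n = 0
    spec = EditSpec()
    for a in aligned_reads:
        if not include_indel_reads and a.has_indel():
            continue
        bases, _ = call_base_edit(a, ref, spec)
        n += 1
        for p in range(1, 21):
            if ref_bases[p] == target_base and bases[p] == to_base:
                counts[p] += 1
    frac = {
        p: (counts[p] / n if n and ref_bases[p] == target_base else float("nan"))
        for p in range(1, 21)
    }
    return BaseEditProfile(
        variant=variant, target_base=target_base, ref_bases=ref_bases,
        edited_fraction=frac, n_reads=n, window=window,
    )


def window_vs_bystander(profile: BaseEditProfile) -> tuple[dict, dict]:
    """Partition the profile's target-base positions into the editing window
    (positions 4-8 by default) and bystanders, returning the raw per-position
    value lists plus median/IQR summaries."""
    win_pos = profile.window_positions()
    by_pos = profile.bystander_positions()
    win_vals = [profile.edited_fraction[p] for p in win_pos]
    by_vals = [profile.edited_fraction[p] for p in by_pos]
    win = {"positions": win_pos, "values": win_vals,
           "summary": summarize(win_vals) if win_vals else None,
           "empty": not win_vals}
    by = {"positions": by_pos, "values": by_vals,
          "summary": summarize(by_vals) if by_vals else None,
          "empty": not by_vals}
    return win, by


def select_on_target_adenine(
    profiles: dict[str, BaseEditProfile], reference_variant: str
) -> int:
    """Protospacer position of the target base edited at the highest level
    by the designated reference variant; ties break to the smallest
    position."""
    if reference_variant not in profiles:
        raise ValueError(f"reference variant {reference_variant!r} missing")
    prof = profiles[reference_variant]
    positions = prof.target_positions()
    if not positions:
        raise ValueError(f"profile {reference_variant!r} has no target-base positions")
    best_pos, best_val = None, -1.0
    for p in positions:
        v = prof.edited_fraction[p]
        if v > best_val:
            best_pos, best_val = p, v
    return best_pos


@dataclass(frozen=True)
class SpecificityRecord:
    on_target: float
    off_target: float

    @property
    def ratio(self) -> float:
        return off_on_ratio(self.off_target, self.on_target)


def off_on_ratio(off: float, on: float) -> float:
    """Relative activity off/on; undefined (NaN) when on-target is zero."""
    if on == 0:
        return float("nan")
    return off / on


def normalize_activity(variant: float, reference: float) -> float:
    """Per-pair normalisation variant/reference; may exceed 1.  NaN when the
    reference activity is zero."""
    if reference == 0:
        return float("nan")
    return variant / reference


def apply_reporting_filters(
    records: pd.DataFrame,
    on_target_threshold: float = 0.70,
    min_edit: float = 0.05,
    on_target_col: str = "on_target",
    edit_col: str = "editing",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presentation filters for mismatch screens.

    Retains rows whose on-target activity strictly exceeds the threshold
    ("exceeded 70%"); rows with editing below ``min_edit`` are additionally
    flagged low.  Returns (retained, exclusion log); retained and excluded
    rows partition the input.
    """
    if on_target_col not in records.columns:
        raise ValueError(f"records lack an {on_target_col!r} column")
    keep = records[on_target_col] > on_target_threshold
    retained = records[keep].copy()
    excluded = records[~keep].copy()
    excluded["rule"] = "on_target_not_exceeding_threshold"
    if edit_col in records.columns:
        retained["low_editing"] = retained[edit_col] < min_edit
    return retained, excluded


def mismatch_filter(candidate: str, target: str, max_mm: int = 7) -> tuple[bool, int]:
    """GUIDE-seq off-target retention: Hamming distance between a candidate
    site and the 20-mer target; retain iff at most ``max_mm`` mismatches."""
    if len(candidate) != len(target):
        raise ValueError(
            f"length mismatch: candidate {len(candidate)} vs target {len(target)}"
        )
    mm = sum(1 for a, b in zip(candidate.upper(), target.upper()) if a != b)
    return mm <= max_mm, mm


def guideseq_specificity(site_counts: pd.DataFrame) -> tuple[float, int]:
    """On-target cleavage specificity as the percentage of on-target reads
    among all site reads, plus the number of retained off-target sites."""
    on = site_counts[site_counts["on_target"]]
    if len(on) != 1:
        raise ValueError(f"expected exactly one on-target site, got {len(on)}")
    total = int(site_counts["reads"].sum())
    if total == 0:
        raise ValueError("zero total reads")
    pct = 100.0 * float(on["reads"].iloc[0]) / total
    return pct, len(site_counts) - 1
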