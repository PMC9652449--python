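"""Outcome-classification rules: window exactness, intended-edit logic,
tag detection, precedence and sample-level bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from editquant import (
    EditSpec,
    IntendedEdit,
    ReadSimConfig,
    SubEdit,
    align_semiglobal,
    call_base_edit,
    call_indel,
    call_prime_edit,
    detect_dsodn_tag,
    quantify_sample,
    simulate_edited_reads,
)
from editquant.calling import DSODN_CENTER, DSODN_CENTER_RC, classify_read
from editquant.simulate import IndelProfile, SubEditFreq


def delete_at(seq: str, pos: int, length: int = 1) -> str:
    return seq[:pos] + seq[pos + length :]


def insert_at(seq: str, pos: int, ins: str) -> str:
    return seq[:pos] + ins + seq[pos:]


@pytest.mark.parametrize("offset,called", [(-3, False), (-2, True), (-1, True),
                                           (0, True), (1, True), (2, True), (3, False)])
def test_indel_window_exactness_deletions(tref, offset, called):
    cut = tref.cut_site
    read = delete_at(tref.sequence, cut + offset)[:100]
    a = align_semiglobal(read, tref)
    assert (call_indel(a, tref) is not None) == called


@pytest.mark.parametrize("offset,called", [(-3, False), (-2, True), (2, True), (3, False)])
def test_indel_window_exactness_insertions(tref, offset, called):
    cut = tref.cut_site
    # 3-bp insertion chosen not to left-shift (first char != preceding base)
    prev = tref.sequence[cut + offset - 1]
    ins = "TAG" if prev != "T" else "CAG"
    read = insert_at(tref.sequence, cut + offset, ins)[:100]
    a = align_semiglobal(read, tref)
    assert (call_indel(a, tref) is not None) == called


def test_substitution_only_read_is_not_indel(tref):
    pos = tref.position_to_ref(5)
    seq = list(tref.sequence)
    seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    a = align_semiglobal("".join(seq)[:100], tref)
    assert call_indel(a, tref) is None


def test_span_counts_flag(tref):
    cut = tref.cut_site
    # 10-bp deletion starting at cut-5: starts left of the window but spans
    # the cut; strict rule ignores it, span_counts counts it
    read = delete_at(tref.sequence, cut - 5, 10)[:90]
    a = align_semiglobal(read, tref)
    assert call_indel(a, tref) is None
    assert call_indel(a, tref, span_counts=True) is not None


def test_strict_indel_read_flag(tref):
    cut = tref.cut_site
    seq = delete_at(tref.sequence, cut)
    seq = list(seq)
    seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
    a = align_semiglobal("".join(seq)[:95], tref)
    assert call_indel(a, tref) is not None  # distal mismatch does not veto
    assert call_indel(a, tref, strict_indel_read=True) is None


def test_base_edit_intended_and_indel_veto(tref):
    spec = EditSpec(substitutions=[SubEdit(4, "A", "G")])
    pos = tref.position_to_ref(4)
    edited = tref.sequence[:pos] + "G" + tref.sequence[pos + 1 :]
    a = align_semiglobal(edited[:100], tref)
    bases, intended = call_base_edit(a, tref, spec)
    assert intended and bases[4] == "G"

    with_ins = insert_at(edited, tref.cut_site, "T")
    a2 = align_semiglobal(with_ins[:100], tref)
    _, intended2 = call_base_edit(a2, tref, spec)
    assert not intended2  # indel-bearing reads never count as intended

    a3 = align_semiglobal(tref.sequence[:100], tref)
    bases3, intended3 = call_base_edit(a3, tref, spec)
    assert not intended3
    assert bases3[4] == "A"


def test_prime_edit_exact_vs_background(tref):
    cut = tref.cut_site
    spec = EditSpec(intended_indel=IntendedEdit("insertion", cut, "T"))
    exact = insert_at(tref.sequence, cut, "T")[:100]
    assert call_prime_edit(align_semiglobal(exact, tref), tref, spec) == "intended_pe"

    other = delete_at(tref.sequence, cut, 2)[:100]
    assert call_prime_edit(align_semiglobal(other, tref), tref, spec) == "background_indel"

    # intended insertion plus an extra distal deletion is not "only the
    # intended edit"
    extra = delete_at(insert_at(tref.sequence, cut, "T"), cut + 20, 1)[:100]
    assert call_prime_edit(align_semiglobal(extra, tref), tref, spec) == "background_indel"

    unedited = tref.sequence[:100]
    assert call_prime_edit(align_semiglobal(unedited, tref), tref, spec) is None


def test_prime_edit_requires_spec(tref):
    a = align_semiglobal(tref.sequence[:100], tref)
    with pytest.raises(ValueError, match="intended_indel"):
        call_prime_edit(a, tref, EditSpec())


def test_dsodn_tag_detection(tref):
    cut = tref.cut_site
    assert detect_dsodn_tag(insert_at(tref.sequence, cut, DSODN_CENTER))
    assert detect_dsodn_tag(insert_at(tref.sequence, cut, DSODN_CENTER_RC))
    assert not detect_dsodn_tag(tref.sequence)
    decoy = DSODN_CENTER[:7] + "C" + DSODN_CENTER[8:]
    assert decoy != DSODN_CENTER
    assert not detect_dsodn_tag(insert_at(tref.sequence, cut, decoy))


def test_tag_precedence_is_mode_scoped(tref):
    cut = tref.cut_site
    from editquant.calling import DSODN

    read = insert_at(tref.sequence, cut, DSODN)[:120]
    a = align_semiglobal(read, tref)
    assert classify_read(a, tref, EditSpec(), "tag").klass == "tag"
    assert classify_read(a, tref, EditSpec(), "nuclease").klass == "indel"


def test_quantify_arithmetic(tref):
    cut = tref.cut_site
    edited = delete_at(tref.sequence, cut)[:99]
    reads = [(f"r{i}", tref.sequence[:100]) for i in range(180)]
    reads += [(f"e{i}", edited) for i in range(20)]
    table, calls = quantify_sample(reads, tref, mode="nuclease")
    assert table.total_reads == 200
    assert table.counts["indel"] == 20
    assert table.indel_freq == pytest.approx(0.10)
    assert sum(table.counts.values()) == table.total_reads


def test_quantify_all_discarded_warns(tref):
    junk = "TGCA" * 25  # unrelated sequence, fails the prefix filter
    with pytest.warns(UserWarning, match="no reads passed"):
        table, _ = quantify_sample([("r1", junk), ("r2", junk)], tref, mode="nuclease")
    assert table.warning == "no_passing_reads"
    assert table.indel_freq == 0.0


def test_quantify_denominator_options(tref):
    cut = tref.cut_site
    good = tref.sequence[:100]
    bad = "TGCA" * 25
    edited = delete_at(tref.sequence, cut)[:99]
    reads = [("a", good), ("b", bad), ("c", edited), ("d", edited)]
    t_default, _ = quantify_sample(reads, tref, mode="nuclease")
    assert t_default.denominator == 3
    assert t_default.indel_freq == pytest.approx(2 / 3)
    t_raw, _ = quantify_sample(reads, tref, mode="nuclease", count_discarded=True)
    assert t_raw.denominator == 4
    assert t_raw.indel_freq == pytest.approx(0.5)


def test_classification_partition_and_oracle_equivalence(tref):
    """Error-free simulated reads must be classified identically to the
    truth table (a strict partition, no discordance)."""
    pe = IntendedEdit("insertion", tref.cut_site, "CTT")
    spec = EditSpec(substitutions=[SubEdit(4, "A", "G")], intended_indel=pe)
    cfg = ReadSimConfig(
        amplicon=tref, n_reads=600, prime_edit=pe, prime_edit_freq=0.15,
        background_indel_freq=0.15, tag_freq=0.1,
        sub_edits=[SubEditFreq(4, "A", "G", 0.3)], seed=21,
    )
    reads, truth = simulate_edited_reads(cfg)
    table, calls = quantify_sample(reads, tref, spec=spec, mode="combined")
    called = pd.DataFrame({"read_id": [c.read_id for c in calls],
                           "called": [c.klass for c in calls]})
    df = called.merge(truth, on="read_id")
    assert (df.called == df.true_class).all()
    assert sum(table.counts.values()) == table.total_reads


def test_called_indel_count_monotone_in_true_freq(tref):
    counts = []
    for f in (0.1, 0.3, 0.5):
        cfg = ReadSimConfig(amplicon=tref, n_reads=300, indel_freq=f, seed=77)
        reads, _ = simulate_edited_reads(cfg)
        table, _ = quantify_sample(reads, tref, mode="nuclease")
        counts.append(table.counts["indel"])
    assert counts == sorted(counts)


def test_frequency_recovery_with_sequencing_error(tref):
    n = 2000
    cfg = ReadSimConfig(amplicon=tref, n_reads=n, indel_freq=0.30,
                        sub_edits=[SubEditFreq(4, "A", "G", 0.2)],
                        seq_error_rate=0.001, seed=13)
    reads, truth = simulate_edited_reads(cfg)
    spec = EditSpec(substitutions=[SubEdit(4, "A", "G")])
    table, _ = quantify_sample(reads, tref, spec=spec, mode="base_editor")
    se_i = np.sqrt(0.3 * 0.7 / n)
    assert abs(table.indel_freq - 0.30) <= 3 * se_i
    p_sub = ((truth.true_class == "intended_sub").mean())
    se_s = np.sqrt(max(p_sub * (1 - p_sub), 1e-9) / n)
    assert abs(table.sub_freq - p_sub) <= 3 * se_s + 0.01
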