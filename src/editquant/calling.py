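"""Per-read editing-outcome classification and per-sample quantification.

Reads that survive the prefix-identity filter are classified into outcome
categories (indel, intended substitution, intended prime edit, background
indel, dsODN tag, unedited); per-sample frequencies are the class counts
divided by the read total.  The rules mirror standard amplicon-sequencing
practice for nuclease, base-editor, prime-editor and tag-integration
samples:

* an *indel* call requires an insertion or deletion whose left-aligned
  reference start lies within +/-2 bp of the cut site;
* an *intended substitution* (base edit) call requires every specified
  substitution to be present and the read to carry no indel at all;
* an *intended prime edit* call requires the read's indel content to equal
  exactly the specified edit; any other indel makes the read *background*;
* a *tag* call requires an exact match to the 15-bp center fragment of the
  GUIDE-seq dsODN in either orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .align import AlignedRead, InvalidReadError, Segment, align_semiglobal, prefix_identity
from .amplicon import AmpliconReference, revcomp

DSODN_CENTER = "GTTGTCATATGTTAA"
DSODN_CENTER_RC = revcomp(DSODN_CENTER)  # TTAACATATGACAAC

#: The 34-bp GUIDE-seq double-stranded oligodeoxynucleotide whose center
#: fragment is counted to detect tag integration.
DSODN = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"

CLASSES = (
    "discarded",
    "unedited",
    "indel",
    "intended_sub",
    "intended_pe",
    "background_indel",
    "tag",
)

MODES = ("nuclease", "base_editor", "prime_editor", "tag", "combined")


@dataclass(frozen=True)
class SubEdit:
    """One intended substitution at a protospacer position (1-20), bases in
    protospacer (non-targeted strand) orientation."""

    position: int
    from_base: str
    to_base: str

    def validate(self, ref: AmpliconReference) -> None:
        if not 1 <= self.position <= 20:
            raise ValueError(f"substitution position {self.position} outside 1-20")
        have = ref.base_at(self.position)
        if have != self.from_base:
            raise ValueError(
                f"position {self.position}: reference has {have}, spec says "
                f"{self.from_base}"
            )


@dataclass(frozen=True)
class IntendedEdit:
    """An intended prime edit.

    ``kind`` is 'insertion' (``seq`` inserted at inter-base reference
    coordinate ``ref_pos``), 'deletion' (``length`` bases removed starting at
    ``ref_pos``) or 'substitution_block' (``seq`` replaces the reference
    block starting at ``ref_pos``).
    """

    kind: str
    ref_pos: int
    seq: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution_block"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "insertion" and not self.seq:
            raise ValueError("insertion requires a sequence")
        if self.kind == "deletion" and self.length <= 0:
            raise ValueError("deletion requires a positive length")
        if self.kind == "substitution_block" and not self.seq:
            raise ValueError("substitution block requires a sequence")

    def canonical(self, ref_seq: str) -> "IntendedEdit":
        """Left-aligned equivalent placement (insertions/deletions only)."""
        if self.kind == "insertion":
            s, ins = canonical_insertion(ref_seq, self.ref_pos, self.seq)
            return IntendedEdit("insertion", s, ins)
        if self.kind == "deletion":
            s = canonical_deletion(ref_seq, self.ref_pos, self.length)
            return IntendedEdit("deletion", s, length=self.length)
        return self


def canonical_deletion(ref_seq: str, start: int, length: int) -> int:
    """Leftmost sequence-equivalent start of deleting ref[start:start+length]."""
    s = start
    while s > 0 and ref_seq[s - 1] == ref_seq[s + length - 1]:
        s -= 1
    return s


def canonical_insertion(ref_seq: str, start: int, ins: str) -> tuple[int, str]:
    """Leftmost sequence-equivalent placement of inserting ``ins`` at the
    inter-base coordinate ``start``; the inserted string rotates as it
    shifts."""
    s, cur = start, ins
    while s > 0 and cur[-1] == ref_seq[s - 1]:
        cur = ref_seq[s - 1] + cur[:-1]
        s -= 1
    return s, cur


@dataclass
class EditSpec:
    """What the sample was meant to install."""

    substitutions: list[SubEdit] = field(default_factory=list)
    intended_indel: IntendedEdit | None = None
    window: tuple[int, int] = (4, 8)

    def validate(self, ref: AmpliconReference) -> None:
        for sub in self.substitutions:
            sub.validate(ref)
        if not 1 <= self.window[0] <= self.window[1] <= 20:
            raise ValueError(f"editing window {self.window} outside 1-20")


@dataclass(frozen=True)
class EditCall:
    read_id: str
    klass: str
    indel_len: int = 0  # signed: + insertion, - deletion
    indel_start: int = -1  # left-aligned reference coordinate
    substitutions: tuple[str, ...] = ()  # e.g. ("5:A>G",)
    reason: str = ""  # reason code for discarded reads


@dataclass
class OutcomeTable:
    """Per-sample counts and frequencies over the outcome classes."""

    sample_id: str
    total_reads: int
    counts: dict[str, int]
    denominator: int
    warning: str = ""

    def frequency(self, klass: str) -> float:
        if self.denominator == 0:
            return 0.0
        return self.counts.get(klass, 0) / self.denominator

    @property
    def indel_freq(self) -> float:
        return self.frequency("indel")

    @property
    def sub_freq(self) -> float:
        return self.frequency("intended_sub")

    @property
    def pe_freq(self) -> float:
        return self.frequency("intended_pe")

    @property
    def background_freq(self) -> float:
        return self.frequency("background_indel")

    @property
    def tag_freq(self) -> float:
        return self.frequency("tag")

    def as_row(self) -> dict:
        row: dict = {"sample_id": self.sample_id, "total_reads": self.total_reads,
                     "denominator": self.denominator}
        for k in CLASSES:
            row[f"n_{k}"] = self.counts.get(k, 0)
        row.update(
            indel_freq=self.indel_freq,
            sub_freq=self.sub_freq,
            pe_freq=self.pe_freq,
            background_freq=self.background_freq,
            tag_freq=self.tag_freq,
        )
        if self.warning:
            row["warning"] = self.warning
        return row


# -- per-read calls ----------------------------------------------------------


def call_indel(
    a: AlignedRead,
    ref: AmpliconReference,
    window_bp: int = 2,
    strict_indel_read: bool = False,
    span_counts: bool = False,
) -> Segment | None:
    """Return the first indel segment whose left-aligned reference start lies
    within ``window_bp`` of the cut site, else None.

    By default distal mismatches do not veto the call ("without mismatches"
    read as: the indel event itself is a pure insertion/deletion operation);
    ``strict_indel_read=True`` applies the stricter reading and vetoes any
    read carrying a mismatch anywhere.  ``span_counts=True`` additionally
    counts deletions that start left of the window but span the cut site.
    """
    if strict_indel_read and any(s.op == "X" for s in a.segments):
        return None
    cut = ref.cut_site
    for s in a.indel_segments():
        if cut - window_bp <= s.ref_start <= cut + window_bp:
            return s
        if (
            span_counts
            and s.op == "D"
            and s.ref_start < cut - window_bp
            and s.ref_start + s.length > cut
        ):
            return s
    return None


def call_base_edit(
    a: AlignedRead, ref: AmpliconReference, spec: EditSpec
) -> tuple[dict[int, str], bool]:
    """Report the read base at every protospacer position (protospacer
    orientation) and whether the read carries the intended modification.

    Intended is true iff every specified substitution is present and the
    alignment contains no indel segment anywhere in the read.
    """
    bases: dict[int, str] = {}
    for pos in range(1, 21):
        b = a.read_base_at_ref(ref.position_to_ref(pos))
        if b is not None and ref.strand == "-":
            b = revcomp(b)
        bases[pos] = b if b is not None else "-"
    if not spec.substitutions:
        return bases, False
    intended = not a.has_indel() and all(
        bases[s.position] == s.to_base for s in spec.substitutions
    )
    return bases, intended


def _read_indels(a: AlignedRead) -> list[tuple[str, int, str | int]]:
    """Indel content of an alignment as comparable tuples.

    Insertions -> ('insertion', ref_pos, inserted_seq); deletions ->
    ('deletion', ref_pos, length).  Segments are already left-aligned by the
    aligner.
    """
    out: list[tuple[str, int, str | int]] = []
    for s in a.indel_segments():
        if s.op == "I":
            out.append(
                ("insertion", s.ref_start, a.read_seq[s.read_start : s.read_start + s.length])
            )
        else:
            out.append(("deletion", s.ref_start, s.length))
    return out


def call_prime_edit(
    a: AlignedRead, ref: AmpliconReference, spec: EditSpec
) -> str | None:
    """'intended_pe' iff the read's indel content equals exactly the intended
    edit; 'background_indel' iff it carries any other indel; None otherwise.
    """
    if spec.intended_indel is None:
        raise ValueError("prime-edit calling requires spec.intended_indel")
    edit = spec.intended_indel.canonical(ref.sequence)
    indels = _read_indels(a)
    if edit.kind == "substitution_block":
        if indels:
            return "background_indel"
        block = edit.seq
        got = "".join(
            (a.read_base_at_ref(edit.ref_pos + k) or "-") for k in range(len(block))
        )
        return "intended_pe" if got == block else None
    if edit.kind == "insertion":
        want = [("insertion", edit.ref_pos, edit.seq)]
    else:
        want = [("deletion", edit.ref_pos, edit.length)]
    if indels == want:
        return "intended_pe"
    if indels:
        return "background_indel"
    return None


def detect_dsodn_tag(read_seq: str) -> bool:
    """Exact-substring detection of the dsODN 15-bp center fragment in either
    orientation (case-insensitive)."""
    s = read_seq.upper()
    return DSODN_CENTER in s or DSODN_CENTER_RC in s


# -- sample-level quantification --------------------------------------------


def classify_read(
    a: AlignedRead,
    ref: AmpliconReference,
    spec: EditSpec,
    mode: str,
    window_bp: int = 2,
    strict_indel_read: bool = False,
    span_counts: bool = False,
) -> EditCall:
    """Classify one passing read under the given mode's precedence
    (tag > indel-class > substitution).

    'combined' mode applies every rule the spec enables, in that precedence
    order, for samples mixing tag, prime-edit and substitution outcomes.
    """
    if mode in ("tag", "combined") and detect_dsodn_tag(a.read_seq):
        return EditCall(a.read_id, "tag")
    if mode == "combined" and spec.intended_indel is not None:
        pe = call_prime_edit(a, ref, spec)
        if pe is not None:
            return EditCall(a.read_id, pe)
        if spec.substitutions:
            _, intended = call_base_edit(a, ref, spec)
            if intended:
                subs = tuple(
                    f"{s.position}:{s.from_base}>{s.to_base}" for s in spec.substitutions
                )
                return EditCall(a.read_id, "intended_sub", substitutions=subs)
        return EditCall(a.read_id, "unedited")
    if mode == "prime_editor":
        pe = call_prime_edit(a, ref, spec)
        if pe is not None:
            e = spec.intended_indel.canonical(ref.sequence)  # type: ignore[union-attr]
            if pe == "intended_pe" and e.kind != "substitution_block":
                length = len(e.seq) if e.kind == "insertion" else -e.length
                return EditCall(a.read_id, pe, indel_len=length, indel_start=e.ref_pos)
            return EditCall(a.read_id, pe)
        return EditCall(a.read_id, "unedited")
    seg = call_indel(
        a, ref, window_bp=window_bp,
        strict_indel_read=strict_indel_read, span_counts=span_counts,
    )
    if seg is not None:
        length = seg.length if seg.op == "I" else -seg.length
        return EditCall(a.read_id, "indel", indel_len=length, indel_start=seg.ref_start)
    if mode in ("base_editor", "combined") and spec.substitutions:
        bases, intended = call_base_edit(a, ref, spec)
        if intended:
            subs = tuple(
                f"{s.position}:{s.from_base}>{s.to_base}" for s in spec.substitutions
            )
            return EditCall(a.read_id, "intended_sub", substitutions=subs)
    return EditCall(a.read_id, "unedited")


def quantify_sample(
    reads,
    ref: AmpliconReference,
    spec: EditSpec | None = None,
    mode: str = "nuclease",
    sample_id: str = "sample",
    window_bp: int = 2,
    prefix_len: int = 20,
    min_frac: float = 0.75,
    count_discarded: bool = False,
    orientation: str = "forward",
    strict_indel_read: bool = False,
    span_counts: bool = False,
) -> tuple[OutcomeTable, list[EditCall]]:
    """Align, filter and classify a read set; return the outcome table and
    the per-read calls.

    ``reads`` is an iterable of (read_id, sequence) pairs or Bio.SeqRecord
    objects.  The frequency denominator is the number of reads passing the
    prefix-identity filter; ``count_discarded=True`` switches to the raw read
    total.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    spec = spec or EditSpec()
    spec.validate(ref)
    counts = {k: 0 for k in CLASSES}
    calls: list[EditCall] = []
    total = 0
    for rec in reads:
        read_id, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        total += 1
        try:
            a = align_semiglobal(seq, ref, read_id=read_id, orientation=orientation)
        except InvalidReadError as exc:
            calls.append(EditCall(read_id, "discarded", reason=exc.code))
            counts["discarded"] += 1
            continue
        if not prefix_identity(a, ref, prefix_len=prefix_len, min_frac=min_frac):
            calls.append(EditCall(read_id, "discarded", reason="prefix_identity"))
            counts["discarded"] += 1
            continue
        call = classify_read(
            a, ref, spec, mode, window_bp=window_bp,
            strict_indel_read=strict_indel_read, span_counts=span_counts,
        )
        calls.append(call)
        counts[call.klass] += 1
    if total == 0:
        raise ValueError("quantify_sample requires at least one read")
    denominator = total if count_discarded else total - counts["discarded"]
    warning = ""
    if total - counts["discarded"] == 0:
        warning = "no_passing_reads"
        warnings.warn(f"sample {sample_id}: no reads passed the prefix filter")
        denominator = total
    table = OutcomeTable(
        sample_id=sample_id,
        total_reads=total,
        counts=counts,
        denominator=denominator,
        warning=warning,
    )
    return table, calls
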