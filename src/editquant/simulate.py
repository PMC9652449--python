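"""Synthetic amplicon reads and in vitro observations with known truth.

The read simulator draws one outcome class per read from a categorical
distribution (indel, intended prime edit, background indel, dsODN tag, or
the unedited remainder), applies the class's mutation to the reference
amplicon, optionally applies intended substitutions (base edits)
independently per position to reads in the unedited slot, then adds i.i.d.
per-base substitution sequencing error and truncates to the read length.
Reads are single-end and span the amplicon 5' end, so the downstream
prefix-identity filter applies directly.

Indels are recorded in the truth table at their *left-aligned* placement,
and a draw whose canonical placement would drift outside the configured
start-offset range is resampled, so the truth table agrees with the
coordinate convention of the window rule by construction.

The kinetics simulators produce noisy one-phase exponential curves:
cleaved(t) = P * (1 - exp(-t/tau)) for time courses, and
intact(r) = exp(-a * r) for active-fraction titrations (single-turnover
Poisson partitioning of enzyme over plasmid molecules), both clipped to
[0, 1] after Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconReference, revcomp
from .calling import DSODN, IntendedEdit, SubEdit, canonical_deletion, canonical_insertion

TRUE_CLASSES = ("unedited", "indel", "intended_sub", "intended_pe", "background_indel", "tag")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IndelProfile:
    """Distribution over simulated indel events.

    ``lengths`` are signed (negative = deletion, positive = insertion,
    within [-20, 20] excluding 0); ``start_offsets`` are drawn relative to
    the cut site (inter-base for insertions, leftmost removed base for
    deletions).  Uniform over both sets by default.
    """

    lengths: tuple[int, ...] = tuple(range(-10, 0)) + tuple(range(1, 11))
    start_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)

    def __post_init__(self) -> None:
        if not self.lengths or any(l == 0 or abs(l) > 20 for l in self.lengths):
            raise ValueError("indel lengths must be non-zero and within [-20, 20]")
        if not self.start_offsets:
            raise ValueError("start_offsets must be non-empty")


@dataclass(frozen=True)
class SubEditFreq:
    """An intended substitution applied with a per-read frequency."""

    position: int
    from_base: str
    to_base: str
    freq: float
    intended: bool = True

    def as_sub_edit(self) -> SubEdit:
        return SubEdit(self.position, self.from_base, self.to_base)


@dataclass
class ReadSimConfig:
    amplicon: AmpliconReference
    n_reads: int
    indel_freq: float = 0.0
    indel_profile: IndelProfile = field(default_factory=IndelProfile)
    sub_edits: list[SubEditFreq] = field(default_factory=list)
    prime_edit: IntendedEdit | None = None
    prime_edit_freq: float = 0.0
    background_indel_freq: float = 0.0
    tag_freq: float = 0.0
    seq_error_rate: float = 0.0
    read_len: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.read_len < 25:
            raise ValueError("read_len must be >= 25 (must span prefix filter and cut)")
        for f, name in (
            (self.indel_freq, "indel_freq"),
            (self.prime_edit_freq, "prime_edit_freq"),
            (self.background_indel_freq, "background_indel_freq"),
            (self.tag_freq, "tag_freq"),
            (self.seq_error_rate, "seq_error_rate"),
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {f}")
        s = self.indel_freq + self.prime_edit_freq + self.background_indel_freq + self.tag_freq
        if s > 1.0 + 1e-12:
            raise ValueError(f"outcome-class frequencies sum to {s} > 1")
        if self.prime_edit_freq > 0 and self.prime_edit is None:
            raise ValueError("prime_edit_freq > 0 requires a prime_edit specification")
        if self.background_indel_freq > 0 and self.prime_edit is None:
            # background indels are defined relative to an intended edit in
            # prime-editing samples; still allow standalone use
            pass
        for sub in self.sub_edits:
            if not 0.0 <= sub.freq <= 1.0:
                raise ValueError(f"sub_edits frequency {sub.freq} outside [0, 1]")
            sub.as_sub_edit().validate(self.amplicon)


def _apply_indel(seq: str, is_ins: bool, start: int, length: int, ins_seq: str) -> str:
    if is_ins:
        return seq[:start] + ins_seq + seq[start:]
    return seq[:start] + seq[start + length :]


def _draw_indel(
    rng: np.random.Generator,
    ref_seq: str,
    cut: int,
    profile: IndelProfile,
    forbid: tuple | None = None,
    max_tries: int = 1000,
):
    """Draw an indel whose canonical (left-aligned) placement stays inside
    the configured offset range; optionally forbid one exact event."""
    offsets = np.asarray(profile.start_offsets)
    lo, hi = offsets.min(), offsets.max()
    for _ in range(max_tries):
        length = int(profile.lengths[rng.integers(len(profile.lengths))])
        start = cut + int(offsets[rng.integers(len(offsets))])
        if length > 0:
            ins_seq = "".join(_BASES[rng.integers(4, size=length)])
            cstart, cseq = canonical_insertion(ref_seq, start, ins_seq)
            event = ("insertion", cstart, cseq)
        else:
            if start < 0 or start - length > len(ref_seq):
                continue
            cstart = canonical_deletion(ref_seq, start, -length)
            event = ("deletion", cstart, -length)
            cseq = ""
        if not (cut + lo <= cstart <= cut + hi):
            continue
        if forbid is not None and event == forbid:
            continue
        return length, cstart, cseq, event
    raise RuntimeError("could not draw an indel satisfying the placement constraints")


def simulate_edited_reads(config: ReadSimConfig) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate a read set and its truth table.

    Returns (reads, truth) where reads are FASTQ-ready SeqRecords (constant
    Phred quality 40) and truth is one row per read with the true class and
    mutation details.  Deterministic for a fixed config and seed.
    """
    config.validate()
    ref = config.amplicon
    rng = np.random.default_rng(config.seed)
    cut = ref.cut_site
    thresholds = np.cumsum(
        [config.indel_freq, config.prime_edit_freq, config.background_indel_freq, config.tag_freq]
    )
    pe_event = None
    if config.prime_edit is not None:
        e = config.prime_edit.canonical(ref.sequence)
        pe_event = (
            (e.kind, e.ref_pos, e.seq) if e.kind != "deletion" else (e.kind, e.ref_pos, e.length)
        )
    reads: list[SeqRecord] = []
    truth_rows: list[dict] = []
    n_digits = max(5, len(str(config.n_reads)))
    for i in range(config.n_reads):
        read_id = f"read{i:0{n_digits}d}"
        u = rng.random()
        seq = ref.sequence
        klass = "unedited"
        indel_len = 0
        indel_start = -1
        subs: list[str] = []
        if u < thresholds[0]:
            klass = "indel"
            length, cstart, cseq, _ = _draw_indel(rng, seq, cut, config.indel_profile)
            seq = _apply_indel(seq, length > 0, cstart, abs(length), cseq)
            indel_len, indel_start = length, cstart
        elif u < thresholds[1]:
            klass = "intended_pe"
            e = config.prime_edit.canonical(ref.sequence)  # type: ignore[union-attr]
            if e.kind == "insertion":
                seq = _apply_indel(seq, True, e.ref_pos, 0, e.seq)
                indel_len, indel_start = len(e.seq), e.ref_pos
            elif e.kind == "deletion":
                seq = _apply_indel(seq, False, e.ref_pos, e.length, "")
                indel_len, indel_start = -e.length, e.ref_pos
            else:
                seq = seq[: e.ref_pos] + e.seq + seq[e.ref_pos + len(e.seq) :]
        elif u < thresholds[2]:
            klass = "background_indel"
            length, cstart, cseq, _ = _draw_indel(
                rng, seq, cut, config.indel_profile, forbid=pe_event
            )
            seq = _apply_indel(seq, length > 0, cstart, abs(length), cseq)
            indel_len, indel_start = length, cstart
        elif u < thresholds[3]:
            klass = "tag"
            odn = DSODN if rng.random() < 0.5 else revcomp(DSODN)
            seq = seq[:cut] + odn + seq[cut:]
            indel_len, indel_start = len(odn), cut
        else:
            intended_all = bool(config.sub_edits) and any(s.intended for s in config.sub_edits)
            for sub in config.sub_edits:
                if rng.random() < sub.freq:
                    pos = ref.position_to_ref(sub.position)
                    b = sub.to_base if ref.strand == "+" else revcomp(sub.to_base)
                    seq = seq[:pos] + b + seq[pos + 1 :]
                    subs.append(f"{sub.position}:{sub.from_base}>{sub.to_base}")
                elif sub.intended:
                    intended_all = False
            if intended_all:
                klass = "intended_sub"
        read = seq[: config.read_len]
        if config.seq_error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(len(read)) < config.seq_error_rate)[0]
            for h in hits:
                cur = arr[h].decode()
                choices = [b for b in "ACGT" if b != cur]
                arr[h] = choices[rng.integers(3)]
            read = arr.tobytes().decode()
        rec = SeqRecord(Seq(read), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(read)
        reads.append(rec)
        truth_rows.append(
            {
                "read_id": read_id,
                "true_class": klass,
                "indel_len": indel_len,
                "indel_start": indel_start,
                "substitutions": ";".join(subs),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_class", "indel_len", "indel_start", "substitutions"])
    return reads, truth


# -- kinetics observations ---------------------------------------------------


@dataclass
class KinSimConfig:
    tau: float = 30.0
    plateau: float = 1.0
    times: tuple[float, ...] = ()
    noise_sd: float = 0.0
    active_fraction: float = 1.0
    ratios: tuple[float, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.plateau <= 1.0:
            raise ValueError("plateau must be within (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.times:
            t = np.asarray(self.times, dtype=float)
            # t = 0 is allowed in simulation (the curve passes through the
            # origin); fitting requires strictly positive times
            if not (np.all(t >= 0) and np.all(np.diff(t) > 0)):
                raise ValueError("times must be non-negative and strictly increasing")
        if not 0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be within [0, 1]")
        for r in self.ratios:
            if not 0 < r <= 20:
                raise ValueError(f"ratio {r} outside (0, 20]")


def simulate_timecourse(config: KinSimConfig) -> pd.DataFrame:
    """Noisy cleaved-fraction time course: P*(1-exp(-t/tau)) + N(0, sd),
    clipped to [0, 1].  Noiseless calls return the exact curve."""
    config.validate()
    if not config.times:
        raise ValueError("simulate_timecourse requires a time grid")
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    clean = config.plateau * (1.0 - np.exp(-t / config.tau))
    if config.noise_sd > 0:
        clean = clean + rng.normal(0.0, config.noise_sd, size=t.shape)
    frac = np.clip(clean, 0.0, 1.0)
    return pd.DataFrame({"time_s": t, "cleaved_fraction": frac})


def simulate_titration(config: KinSimConfig) -> pd.DataFrame:
    """Intact-plasmid fraction versus nominal protein:plasmid ratio under
    single turnover: intact(r) = exp(-a*r) + N(0, sd), clipped to [0, 1]."""
    config.validate()
    if not config.ratios:
        raise ValueError("simulate_titration requires a ratio grid")
    rng = np.random.default_rng(config.seed)
    r = np.asarray(config.ratios, dtype=float)
    clean = np.exp(-config.active_fraction * r)
    if config.noise_sd > 0:
        clean = clean + rng.normal(0.0, config.noise_sd, size=r.shape)
    frac = np.clip(clean, 0.0, 1.0)
    return pd.DataFrame({"ratio": r, "intact_fraction": frac})


def simulate_guideseq_readset(
    target: str, sites: list[tuple[str, int, bool]]
) -> pd.DataFrame:
    """Desk-scale GUIDE-seq site table: (site sequence, read count,
    on-target flag) rows with derived totals in ``attrs``."""
    if len(target) != 20:
        raise ValueError("target must be a 20-mer")
    n_on = sum(1 for _, _, on in sites if on)
    if n_on != 1:
        raise ValueError(f"exactly one site must be flagged on-target, got {n_on}")
    df = pd.DataFrame(sites, columns=["site", "reads", "on_target"])
    total = int(df["reads"].sum())
    if total == 0:
        raise ValueError("zero total reads")
    df.attrs["target"] = target
    df.attrs["total_reads"] = total
    return df
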