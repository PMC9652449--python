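"""Reference amplicon definitions.

An amplicon is a short PCR product containing one protospacer.  Protospacer
positions are numbered 1-20 in the 5'->3' direction of the non-targeted
strand (the strand whose sequence equals the spacer), the convention used
throughout base-editing literature.  SpCas9 cuts bluntly 3 bp 5' of the PAM,
i.e. between protospacer positions 17 and 18; the cut site is therefore a
derived quantity, never user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string (case-insensitive, returns upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """A reference amplicon with its protospacer annotation.

    Parameters
    ----------
    name
        Amplicon identifier.
    sequence
        Uppercase DNA (ACGTN) of the amplicon, 5'->3' on the sequenced strand.
    protospacer_start
        0-based reference index of protospacer position 1.
    strand
        '+' if the protospacer reads 5'->3' on ``sequence``, '-' if on its
        reverse complement.
    pam
        The 3-mer PAM immediately 3' of the protospacer (NGG for SpCas9).
    """

    name: str
    sequence: str
    protospacer_start: int
    strand: str = "+"
    pam: str = "NGG"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"amplicon {self.name!r}: non-ACGTN characters {bad}")
        if self.strand not in "+-":
            raise ValueError(f"amplicon {self.name!r}: strand must be '+' or '-'")
        if len(self.pam) != 3:
            raise ValueError(f"amplicon {self.name!r}: PAM must be a 3-mer")
        ps = self.protospacer_start
        if self.strand == "+":
            if not (0 <= ps and ps + 20 <= len(seq)):
                raise ValueError(
                    f"amplicon {self.name!r}: protospacer [{ps}, {ps + 20}) "
                    f"outside sequence of length {len(seq)}"
                )
        else:
            if not (19 <= ps < len(seq)):
                raise ValueError(
                    f"amplicon {self.name!r}: minus-strand protospacer starting "
                    f"at {ps} does not fit in sequence of length {len(seq)}"
                )

    # -- derived coordinates -------------------------------------------------

    @property
    def cut_site(self) -> int:
        """0-based inter-base cut coordinate (bond between positions 17/18).

        An inter-base coordinate ``c`` denotes the bond between reference
        bases ``c-1`` and ``c``.
        """
        if self.strand == "+":
            return self.protospacer_start + 17
        return self.protospacer_start - 16

    @property
    def protospacer(self) -> str:
        """Protospacer 5'->3' on the non-targeted strand (positions 1-20)."""
        if self.strand == "+":
            return self.sequence[self.protospacer_start : self.protospacer_start + 20]
        s = self.sequence[self.protospacer_start - 19 : self.protospacer_start + 1]
        return revcomp(s)

    def position_to_ref(self, pos: int) -> int:
        """Map a 1-based protospacer position to a 0-based reference index."""
        if not 1 <= pos <= 20:
            raise ValueError(f"protospacer position {pos} outside 1-20")
        if self.strand == "+":
            return self.protospacer_start + pos - 1
        return self.protospacer_start - (pos - 1)

    def base_at(self, pos: int) -> str:
        """Reference base at a protospacer position, protospacer orientation."""
        b = self.sequence[self.position_to_ref(pos)]
        return b if self.strand == "+" else revcomp(b)
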