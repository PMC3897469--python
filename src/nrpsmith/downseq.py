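"""Up-Seq / Down-Seq delimitation of condensation-superfamily domains.

Condensation (C) and epimerization (E) domains share a conserved ~300
residue core (the Pfam PF00668 / InterPro IPR001242 region, here called
the Up-Seq) carrying the HHxxxDG active-site motif, followed by a
~150–171 residue C-terminal region (the Down-Seq) whose sequence is
specific to the catalytic subtype.  The Down-Seq runs from the end of the
core hit to the start of the following domain (A or C), or to the protein
end for a terminal domain.  A spacer of 165±10 residues is typical; the
delimitation never fails on atypical lengths, it only raises warning
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")

ACTIVE_SITE_MOTIF = "HHxxxDG"


class DelimitError(ValueError):
    """Raised for overlapping annotations or invalid sequences."""


@dataclass(frozen=True)
class SpacerExpectation:
    """Expected Down-Seq length between a C-core hit and the next domain.

    ``expected_len`` ± ``tolerance`` marks the typical band; lengths outside
    ``hard_band`` additionally raise the SPACER_EXTREME flag.
    """

    expected_len: int = 165
    tolerance: int = 10
    hard_band: tuple[int, int] = (130, 210)

    def __post_init__(self) -> None:
        if self.expected_len - self.tolerance <= 0:
            raise ValueError("tolerance must leave a positive expected length")


@dataclass
class RegionSplit:
    """Delimited Up-Seq / Down-Seq intervals (0-based half-open)."""

    upseq: tuple[int, int]
    downseq: tuple[int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def spacer_len(self) -> int:
        return self.downseq[1] - self.downseq[0]


def delimit_regions(
    core_hit: tuple[int, int],
    next_domain_start: int | None,
    protein_len: int,
    expectation: SpacerExpectation = SpacerExpectation(),
) -> RegionSplit:
    """Split a C/E domain around its core hit.

    The Up-Seq is the core hit itself; the Down-Seq extends from the core
    end to ``next_domain_start``, or to the protein end when the domain is
    terminal (fungal Ct, final E).  Atypical spacer lengths raise the
    SPACER_ATYPICAL / SPACER_EXTREME warning flags, never an error;
    overlapping annotations (next domain starting inside the core) are an
    error.
    """
    start, end = core_hit
    if not (0 <= start < end <= protein_len):
        raise DelimitError(
            f"core hit [{start}, {end}) outside protein of length {protein_len}"
        )
    right = protein_len if next_domain_start is None else next_domain_start
    if right < end:
        raise DelimitError(
            f"next domain start {right} lies inside core hit [{start}, {end})"
        )
    if right > protein_len:
        raise DelimitError(
            f"next domain start {right} beyond protein length {protein_len}"
        )
    split = RegionSplit(upseq=(start, end), downseq=(end, right))
    spacer = split.spacer_len
    lo = expectation.expected_len - expectation.tolerance
    hi = expectation.expected_len + expectation.tolerance
    if not (lo <= spacer <= hi):
        split.flags.append("SPACER_ATYPICAL")
    if not (expectation.hard_band[0] <= spacer <= expectation.hard_band[1]):
        split.flags.append("SPACER_EXTREME")
    return split


def find_active_site(upseq_sequence: str) -> tuple[int, str] | None:
    """Locate the HHxxxDG active-site motif in an Up-Seq region.

    Returns the leftmost exact window ``H-H-x-x-x-D-G``.  If none exists,
    the leftmost window with at most one mismatch among the flanking fixed
    positions (H1, G7) is returned, while the catalytic H2 and D6 residues
    are always required exactly.  Absence returns ``None`` rather than an
    error; characters outside the 20-letter alphabet plus X are an error.
    """
    seq = upseq_sequence.upper()
    bad = set(seq) - _VALID_AA
    if bad:
        raise DelimitError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    n = len(seq)
    fallback: tuple[int, str] | None = None
    for i in range(n - 6):
        w = seq[i : i + 7]
        if w[1] != "H" or w[5] != "D":
            continue
        mism = (w[0] != "H") + (w[6] != "G")
        if mism == 0:
            return i, w
        if mism <= 1 and fallback is None:
            fallback = (i, w)
    return fallback
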