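"""IUPAC motif matching shared by ITS annotation and promoter scanning.

Consensus patterns use standard IUPAC classes (Y = C/T, W = A/T, ...).
Query bases must be unambiguous to match: an N or ambiguity code in the
*query* matches nothing, a deliberately conservative counting rule.
"""

from __future__ import annotations

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def base_matches(base: str, pattern_char: str) -> bool:
    """True when an unambiguous query base satisfies the pattern class."""
    cls = IUPAC_CLASSES.get(pattern_char)
    if cls is None:
        raise ValueError(f"invalid IUPAC pattern character {pattern_char!r}")
    return base in "ACGT" and base in cls


def match_count(window: str, motif: str) -> int:
    """Number of positions where the window satisfies the motif."""
    if len(window) != len(motif):
        raise ValueError(
            f"window length {len(window)} != motif length {len(motif)}"
        )
    return sum(base_matches(b, m) for b, m in zip(window.upper(), motif.upper()))


def matches_fully(window: str, motif: str) -> bool:
    return match_count(window, motif) == len(motif)


def find_motif(seq: str, motif: str, start: int = 1, end: int | None = None) -> int | None:
    """1-based start of the first full motif match at or after ``start``
    (and starting at or before ``end``), or None."""
    L = len(motif)
    last = (end if end is not None else len(seq) - L + 1)
    for s in range(start, last + 1):
        if s + L - 1 > len(seq):
            break
        if matches_fully(seq[s - 1 : s + L - 1], motif):
            return s
    return None
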