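"""Sigma-70-style promoter scanning of operon upstream regions.

Upstream regions are expected to end at the transcript start. The
scanner locates the -10 (Pribnow box, consensus TATAAT) hexamer, then
the -35 (TTGACA) hexamer at an allowed spacing upstream of it, and
finally an optional -52 element (consensus AWWWWWTTTTT). A promoter is
called likely functional when both the -35 and the -10 windows match
the consensus at 3 to 6 of their 6 positions; the -52 element is
reported but never contributes to the call, since it may or may not be
functional. Elements whose window would run off the 5' end are
reported as absent rather than partially scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .motif import match_count
from .seq_io import SequenceRecord

FUNCTIONAL_MIN_MATCHES = 3


@dataclass(frozen=True)
class PromoterConsensus:
    minus10: str = "TATAAT"
    minus35: str = "TTGACA"
    minus52: str = "AWWWWWTTTTT"
    #: allowed nt between the -35 end and the -10 start
    spacer_35_10: tuple[int, int] = (16, 19)
    #: allowed nt between the -52 end and the -35 start
    spacer_52_35: tuple[int, int] = (7, 9)
    #: allowed nt between the -10 end and the transcript start (3' end)
    discriminator: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        if len(self.minus10) != 6 or len(self.minus35) != 6 or len(self.minus52) != 11:
            raise ValueError("consensus motif lengths must be 6, 6 and 11")


@dataclass(frozen=True)
class ElementHit:
    window: tuple[int, int]  # 1-based closed interval in the upstream sequence
    sequence: str
    matches: int


@dataclass
class PromoterAnnotation:
    seq_id: str
    minus10: ElementHit
    minus35: ElementHit
    minus52: ElementHit | None
    functional: bool
    transcript_start_context: str

    def to_row(self) -> dict:
        return {
            "id": self.seq_id,
            "minus52": self.minus52.sequence if self.minus52 else "",
            "minus52_matches": self.minus52.matches if self.minus52 else "",
            "minus35": self.minus35.sequence,
            "minus35_matches": self.minus35.matches,
            "minus10": self.minus10.sequence,
            "minus10_matches": self.minus10.matches,
            "transcript_begin_context": self.transcript_start_context,
            "functional": self.functional,
        }


def promoter_table(annotations: list[PromoterAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.to_row() for a in annotations])


def scan_promoter(
    upstream: SequenceRecord | str,
    consensus: PromoterConsensus | None = None,
) -> PromoterAnnotation:
    """Locate -10 / -35 / -52 elements in an upstream region.

    Greedy, 3'-anchored search: the -10 window maximizing the consensus
    match count over the allowed discriminator range is fixed first
    (ties to the window closest to the 3' end), then the best -35 at an
    allowed spacing, then the best -52. Raises when the sequence cannot
    hold the -35/-10 composite at any allowed spacing.
    """
    consensus = consensus or PromoterConsensus()
    if isinstance(upstream, SequenceRecord):
        seq_id, s = upstream.id, upstream.residues
    else:
        seq_id, s = "upstream", upstream.upper().replace("U", "T")
    L = len(s)
    min_span = (
        6 + consensus.spacer_35_10[0] + 6 + consensus.discriminator[0]
    )
    if L < min_span:
        raise ValueError(
            f"{seq_id}: upstream length {L} shorter than the minimal "
            f"-35/-10 span {min_span}"
        )

    def best(
        candidates: list[tuple[int, int]], motif: str
    ) -> ElementHit | None:
        # candidates: (start, end) 1-based closed, already length-checked;
        # ties go to the window closest to the 3' end (largest start)
        hit = None
        for start, end in candidates:
            window = s[start - 1 : end]
            m = match_count(window, motif)
            if hit is None or m > hit.matches or (m == hit.matches and start > hit.window[0]):
                hit = ElementHit(window=(start, end), sequence=window, matches=m)
        return hit

    d_lo, d_hi = consensus.discriminator
    cands10 = [
        (L - d - 6 + 1, L - d)
        for d in range(d_lo, d_hi + 1)
        if L - d - 6 + 1 >= 1
    ]
    hit10 = best(cands10, consensus.minus10)
    if hit10 is None:
        raise ValueError(f"{seq_id}: no room for a -10 window")

    s_lo, s_hi = consensus.spacer_35_10
    cands35 = [
        (hit10.window[0] - sp - 6, hit10.window[0] - sp - 1)
        for sp in range(s_lo, s_hi + 1)
        if hit10.window[0] - sp - 6 >= 1
    ]
    hit35 = best(cands35, consensus.minus35)
    if hit35 is None:
        raise ValueError(
            f"{seq_id}: no room for a -35 window at spacing "
            f"{s_lo}-{s_hi} upstream of the -10"
        )

    p_lo, p_hi = consensus.spacer_52_35
    cands52 = [
        (hit35.window[0] - sp - 11, hit35.window[0] - sp - 1)
        for sp in range(p_lo, p_hi + 1)
        if hit35.window[0] - sp - 11 >= 1
    ]
    hit52 = best(cands52, consensus.minus52)

    functional = (
        hit35.matches >= FUNCTIONAL_MIN_MATCHES
        and hit10.matches >= FUNCTIONAL_MIN_MATCHES
    )
    return PromoterAnnotation(
        seq_id=seq_id,
        minus10=hit10,
        minus35=hit35,
        minus52=hit52,
        functional=functional,
        transcript_start_context=s[hit10.window[1] :],
    )
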