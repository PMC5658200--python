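"""Diagnostic signature positions, sequence typing, reversions, primers.

The signature of two operon types is the set of alignment columns at
which each type has its own consensus base (consensus requiring at
least ``saturation_threshold`` agreement among non-missing residues,
85% by default) and the two consensus bases differ — the "consistently
variable" positions. Sequences are typed by the share of signature
positions matching each type's consensus; reversions (a sequence of one
type carrying the other type's consensus base, the fingerprint of gene
conversion) are counted per position; and type-specific primer windows
are proposed from runs of columns fully conserved within one type but
divergent from the other.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .seq_io import UNAMBIGUOUS, MultiAlignment

TYPE1 = "Type1"
TYPE2 = "Type2"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SignaturePosition:
    position: int  # 1-based alignment column
    consensus_type1: str
    consensus_type2: str
    saturation_type1: float
    saturation_type2: float
    helix: str | None = None


@dataclass
class SignatureTable:
    """Consistently variable positions between the two operon types."""

    positions: list[SignaturePosition]
    alignment_width: int
    saturation_threshold: float = 0.85

    def __post_init__(self) -> None:
        cols = [p.position for p in self.positions]
        if cols != sorted(set(cols)):
            raise ValueError("signature positions must be strictly increasing")
        for p in self.positions:
            if p.consensus_type1 == p.consensus_type2:
                raise ValueError(f"position {p.position}: consensus bases equal")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def columns(self) -> list[int]:
        return [p.position for p in self.positions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": p.position,
                    "base_type1": p.consensus_type1,
                    "base_type2": p.consensus_type2,
                    "saturation_type1": p.saturation_type1,
                    "saturation_type2": p.saturation_type2,
                    "helix": p.helix if p.helix is not None else "",
                }
                for p in self.positions
            ]
        )


def _consensus(column: Sequence[str], threshold: float) -> tuple[str, float] | None:
    """Modal base and its saturation among non-missing residues.

    Returns None when there are no scorable residues or the modal base
    falls below the saturation threshold. Modal ties are broken
    alphabetically (a tie can never reach thresholds above 0.5 anyway).
    """
    counts = Counter(b for b in column if b in UNAMBIGUOUS)
    total = sum(counts.values())
    if total == 0:
        return None
    top = max(counts.values())
    base = min(b for b, c in counts.items() if c == top)
    saturation = top / total
    if saturation < threshold:
        return None
    return base, saturation


def _split_rows(
    aln: MultiAlignment, labels: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    rows1 = [r.residues for r in aln if labels.get(r.id) == TYPE1]
    rows2 = [r.residues for r in aln if labels.get(r.id) == TYPE2]
    if not rows1 or not rows2:
        empty = TYPE1 if not rows1 else TYPE2
        raise ValueError(f"no sequences labeled {empty}")
    return rows1, rows2


def find_signature(
    aln: MultiAlignment,
    labels: Mapping[str, str],
    saturation_threshold: float = 0.85,
    helix_of: Mapping[int, str] | None = None,
) -> SignatureTable:
    """Columns where the two types hold different, saturated consensuses.

    Missing residues (gaps, N, ambiguity codes) are excluded from the
    saturation denominator. ``helix_of`` optionally labels positions
    with the helix containing them (see ``rrna_structure``).
    """
    rows1, rows2 = _split_rows(aln, labels)
    positions = []
    for col in range(1, aln.width + 1):
        c1 = _consensus([r[col - 1] for r in rows1], saturation_threshold)
        c2 = _consensus([r[col - 1] for r in rows2], saturation_threshold)
        if c1 is None or c2 is None or c1[0] == c2[0]:
            continue
        positions.append(
            SignaturePosition(
                position=col,
                consensus_type1=c1[0],
                consensus_type2=c2[0],
                saturation_type1=c1[1],
                saturation_type2=c2[1],
                helix=helix_of.get(col) if helix_of else None,
            )
        )
    return SignatureTable(
        positions=positions,
        alignment_width=aln.width,
        saturation_threshold=saturation_threshold,
    )


@dataclass(frozen=True)
class TypingScore:
    """Share of signature positions matching each type's consensus."""

    seq_id: str
    frac_type1: int
    frac_type2: int
    frac_other: int
    n_scored: int

    @property
    def call(self) -> str:
        if self.frac_type1 > self.frac_type2:
            return TYPE1
        if self.frac_type2 > self.frac_type1:
            return TYPE2
        return "unknown"


def _largest_remainder(raw: Sequence[float]) -> list[int]:
    """Round percentages to integers summing to 100."""
    floors = [int(x) for x in raw]
    deficit = 100 - sum(floors)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - floors[i], -i), reverse=True
    )
    out = list(floors)
    for i in order[:deficit]:
        out[i] += 1
    return out


def classify_sequence(
    seq: str, sig: SignatureTable, seq_id: str = "query", rounding: str = "largest-remainder"
) -> TypingScore:
    """Type a sequence against the signature.

    Only signature positions where the sequence carries an unambiguous
    base are scored. Percentages are rounded to integers by the
    largest-remainder method (default) so the triple always sums to
    100; ``rounding="nearest"`` rounds each independently and may sum
    to 99 or 101.
    """
    if len(seq) != sig.alignment_width:
        raise ValueError(
            f"sequence length {len(seq)} != alignment width {sig.alignment_width}"
        )
    n1 = n2 = nother = 0
    for p in sig.positions:
        base = seq[p.position - 1]
        if base not in UNAMBIGUOUS:
            continue
        if base == p.consensus_type1:
            n1 += 1
        elif base == p.consensus_type2:
            n2 += 1
        else:
            nother += 1
    scored = n1 + n2 + nother
    if scored == 0:
        raise ValueError(f"{seq_id}: all signature positions missing")
    raw = [100.0 * n1 / scored, 100.0 * n2 / scored, 100.0 * nother / scored]
    if rounding == "largest-remainder":
        f1, f2, fo = _largest_remainder(raw)
    elif rounding == "nearest":
        f1, f2, fo = (int(round(x)) for x in raw)
    else:
        raise ValueError(f"unknown rounding policy {rounding!r}")
    return TypingScore(
        seq_id=seq_id, frac_type1=f1, frac_type2=f2, frac_other=fo, n_scored=scored
    )


@dataclass(frozen=True)
class Reversion:
    """Signature-position hits of the opposite type's consensus base."""

    position: int
    from_type: str  # the labeled type of the sequences carrying the base
    seq_ids: tuple[str, ...]
    observed_base: str


def detect_reversions(
    aln: MultiAlignment, labels: Mapping[str, str], sig: SignatureTable
) -> list[Reversion]:
    """Find sequences carrying the *other* type's consensus base.

    Such sites are the expected signature of partial gene conversion
    between operon copies. Returns one entry per (position, type);
    ``{r.position for r in result}`` gives the flagged-position count.
    """
    hits: dict[tuple[int, str], list[str]] = defaultdict(list)
    base_at: dict[tuple[int, str], str] = {}
    for rec in aln:
        lab = labels.get(rec.id)
        if lab not in (TYPE1, TYPE2):
            continue
        for p in sig.positions:
            other_base = p.consensus_type2 if lab == TYPE1 else p.consensus_type1
            base = rec.residues[p.position - 1]
            if base in UNAMBIGUOUS and base == other_base:
                hits[(p.position, lab)].append(rec.id)
                base_at[(p.position, lab)] = base
    return [
        Reversion(
            position=pos,
            from_type=lab,
            seq_ids=tuple(ids),
            observed_base=base_at[(pos, lab)],
        )
        for (pos, lab), ids in sorted(hits.items())
    ]


@dataclass(frozen=True)
class PrimerWindow:
    """A candidate type-specific primer site."""

    start: int  # 1-based alignment columns, closed interval
    end: int
    target_type: str
    primer: str  # 5'->3' reverse primer (reverse complement of the window)
    cross_mismatches: int
    three_prime_mismatch: bool


def design_type_primers(
    aln: MultiAlignment,
    labels: Mapping[str, str],
    length_range: tuple[int, int] = (20, 30),
    min_cross_mismatches: int = 3,
) -> list[PrimerWindow]:
    """Windows fully conserved within one type but divergent from the other.

    A window qualifies for a target type when every sequence of that
    type carries the identical, gap/ambiguity-free residues across it,
    and the other type's consensus differs at ``min_cross_mismatches``
    or more columns. Reverse primers (reverse complements) are emitted,
    as used to recover operon copies that cloning misses through PCR
    bias. Windows are reported leftmost-first, then shorter-first; the
    ``three_prime_mismatch`` flag (a cross mismatch at the primer's 3'
    end, i.e. the window's leftmost column) supports ranking.
    """
    rows1, rows2 = _split_rows(aln, labels)
    by_type = {TYPE1: rows1, TYPE2: rows2}
    lo, hi = length_range

    # per-column precomputation: the fully conserved base of each type
    # (None when any residue is missing or disagrees) and each type's
    # majority consensus base
    conserved: dict[str, list[str | None]] = {}
    majority: dict[str, list[str | None]] = {}
    for lab, rows in by_type.items():
        cons_col: list[str | None] = []
        maj_col: list[str | None] = []
        for col in range(aln.width):
            bases = [r[col] for r in rows]
            first = bases[0]
            cons_col.append(
                first
                if first in UNAMBIGUOUS and all(b == first for b in bases)
                else None
            )
            c = _consensus(bases, 0.0)
            maj_col.append(c[0] if c else None)
        conserved[lab] = cons_col
        majority[lab] = maj_col

    out: list[PrimerWindow] = []
    for start in range(1, aln.width + 1):
        for length in range(lo, hi + 1):
            end = start + length - 1
            if end > aln.width:
                break
            for target in (TYPE1, TYPE2):
                other = TYPE2 if target == TYPE1 else TYPE1
                own_cols = conserved[target][start - 1 : end]
                other_cols = majority[other][start - 1 : end]
                if any(b is None for b in own_cols) or any(
                    b is None for b in other_cols
                ):
                    continue
                mismatch_cols = [
                    i for i, (x, y) in enumerate(zip(own_cols, other_cols)) if x != y
                ]
                if len(mismatch_cols) < min_cross_mismatches:
                    continue
                window = "".join(own_cols)  # type: ignore[arg-type]
                out.append(
                    PrimerWindow(
                        start=start,
                        end=end,
                        target_type=target,
                        primer=reverse_complement(window),
                        cross_mismatches=len(mismatch_cols),
                        three_prime_mismatch=0 in mismatch_cols,
                    )
                )
    out.sort(key=lambda w: (w.start, w.end - w.start, w.target_type))
    return out


def best_primer(
    windows: Sequence[PrimerWindow], target_type: str
) -> PrimerWindow | None:
    """Top-ranked window for a type: most cross mismatches, 3'-end
    mismatch preferred, then leftmost, then shortest."""
    candidates = [w for w in windows if w.target_type == target_type]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda w: (
            -w.cross_mismatches,
            not w.three_prime_mismatch,
            w.start,
            w.end - w.start,
        ),
    )
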