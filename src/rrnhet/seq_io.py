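"""Sequence and alignment containers plus FASTA input/output.

All coordinates in this package are 1-based with closed intervals, the
convention used in rRNA secondary-structure models and supplementary
alignment tables. RNA input is accepted and normalized to the DNA
alphabet (U -> T) so that gene-level and transcript-level views of an
operon can be mixed freely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

REGIONS = {"16S", "ITS", "23S", "5S", "upstream", "operon", "other"}
OPERON_TYPES = {"Type1", "Type2", "unknown"}

#: Unambiguous bases; everything else (gaps, N, IUPAC ambiguity) is
#: treated as missing data by the analysis stages.
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

_HEADER_TOKEN = re.compile(r"(\w+)=(\S+)")


class DuplicateIdError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with optional strain/region/type metadata.

    ``operon_type`` carries the two-operon-type labels ("Type1" for the
    divergent operon, "Type2" for the majority operons) used throughout
    the analysis; "unknown" for unlabeled input.
    """

    id: str
    residues: str
    strain: str | None = None
    region: str = "other"
    operon_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        norm = self.residues.upper().replace("U", "T")
        bad = set(norm) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if not norm:
            raise ValueError(f"record {self.id!r}: empty residues")
        object.__setattr__(self, "residues", norm)
        if self.region not in REGIONS:
            raise ValueError(f"record {self.id!r}: unknown region {self.region!r}")
        if self.operon_type not in OPERON_TYPES:
            raise ValueError(
                f"record {self.id!r}: unknown operon_type {self.operon_type!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def base(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


@dataclass
class MultiAlignment:
    """An alignment of equal-length records with 1-based columns."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        widths = {len(r) for r in self.records}
        if len(widths) != 1:
            offenders = sorted({r.id for r in self.records})
            raise ValueError(
                f"unequal sequence lengths in alignment (ids: {', '.join(offenders)})"
            )
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DuplicateIdError(f"duplicate ids in alignment: {sorted(dupes)}")

    @property
    def width(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, position: int) -> list[str]:
        """Residues of a 1-based alignment column, in record order."""
        if not 1 <= position <= self.width:
            raise IndexError(f"column {position} outside 1..{self.width}")
        return [r.residues[position - 1] for r in self.records]

    def to_matrix(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])

    def subset(self, ids: Iterable[str]) -> "MultiAlignment":
        wanted = list(ids)
        return MultiAlignment([self[i] for i in wanted])


def _parse_header(header: str) -> SequenceRecord:
    parts = header.split(None, 1)
    seq_id = parts[0]
    strain = None
    region = "other"
    operon_type = "unknown"
    if len(parts) == 2:
        for key, value in _HEADER_TOKEN.findall(parts[1]):
            if key == "strain":
                strain = value
            elif key == "region":
                region = value
            elif key == "type":
                operon_type = value
    return SequenceRecord(
        id=seq_id, residues="N", strain=strain, region=region, operon_type=operon_type
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Header tokens ``strain=`` ``region=`` ``type=`` after the id are
    parsed into metadata fields; anything else is ignored.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(entry.description)
        if meta.id in seen:
            raise DuplicateIdError(f"duplicate id {meta.id!r} in {path}")
        seen.add(meta.id)
        records.append(replace(meta, residues=str(entry.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            tokens = []
            if rec.strain is not None:
                tokens.append(f"strain={rec.strain}")
            if rec.region != "other":
                tokens.append(f"region={rec.region}")
            if rec.operon_type != "unknown":
                tokens.append(f"type={rec.operon_type}")
            suffix = (" " + " ".join(tokens)) if tokens else ""
            fh.write(f">{rec.id}{suffix}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def read_alignment(path: str | Path) -> MultiAlignment:
    """Read an aligned FASTA file; all sequences must have equal length."""
    return MultiAlignment(read_fasta(path))


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of a global pairwise alignment: the alignment plus its score."""

    alignment: MultiAlignment
    score: float


def align_pair_global(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment under linear gap scores.

    Traceback ties are broken deterministically: diagonal
    (match/mismatch) over up (gap in ``b``) over left (gap in ``a``).
    """
    sa, sb = a.ungapped, b.ungapped
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    n, m = len(sa), len(sb)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    arr_a = np.frombuffer(sa.encode(), dtype="S1")
    arr_b = np.frombuffer(sb.encode(), dtype="S1")
    sub = np.where(arr_a[:, None] == arr_b[None, :], match, mismatch)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        row = score[i, :]
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + gap)
            row[j] = prev
    # traceback, diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = score[i, j]
        if i > 0 and j > 0 and here == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and here == score[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    rec_a = replace(a, residues="".join(reversed(out_a)))
    rec_b = replace(b, residues="".join(reversed(out_b)))
    return PairwiseAlignment(
        alignment=MultiAlignment([rec_a, rec_b]), score=float(score[n, m])
    )
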