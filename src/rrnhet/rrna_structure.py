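"""Reference helix maps, helix folding, and helix-localized variability.

rRNA secondary structure is described by a helix map in the coordinates
of a reference ("model") sequence: each helix pairs a 5' strand
interval against a 3' strand interval, antiparallel. Folding is purely
canonical (Watson-Crick plus, by default, G.U wobble); no free-energy
minimization is attempted. Positions that are mismatched in the
reference model may be "closed" — drawn paired — when the target bases
do pair canonically, provided at most ``max_closable`` such closures
occur in the helix; this reproduces the drawing convention used when
transferring a reference structure onto a related sequence.

Comparing the two operon types' consensus sequences helix by helix
quantifies how strongly the between-type heterogeneity is localized in
particular helices, and flags helices whose pairing pattern actually
changes between the types.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seq_io import UNAMBIGUOUS, MultiAlignment
from .operon_typing import SignatureTable

CANONICAL_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def pairs_canonically(x: str, y: str, wobble: bool = True) -> bool:
    if (x, y) in CANONICAL_PAIRS:
        return True
    return wobble and (x, y) in WOBBLE_PAIRS


@dataclass(frozen=True)
class Helix:
    name: str
    strand5: tuple[int, int]  # 1-based closed interval in model coordinates
    strand3: tuple[int, int]

    def __post_init__(self) -> None:
        s5, s3 = self.strand5, self.strand3
        if not (s5[0] <= s5[1] < s3[0] <= s3[1]):
            raise ValueError(f"helix {self.name}: strand5 must precede strand3")
        if s5[1] - s5[0] != s3[1] - s3[0]:
            raise ValueError(f"helix {self.name}: strand lengths differ")

    @property
    def length(self) -> int:
        return self.strand5[1] - self.strand5[0] + 1

    def contains(self, model_pos: int) -> bool:
        return (
            self.strand5[0] <= model_pos <= self.strand5[1]
            or self.strand3[0] <= model_pos <= self.strand3[1]
        )


@dataclass
class HelixMap:
    """Helix coordinates of a reference secondary-structure model."""

    molecule: str  # 16S, 23S or 5S
    length: int  # model sequence length
    helices: list[Helix] = field(default_factory=list)
    domain_boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [h.name for h in self.helices]
        if len(names) != len(set(names)):
            raise ValueError("helix names must be unique")
        occupied: set[int] = set()
        for h in self.helices:
            for lo, hi in (h.strand5, h.strand3):
                span = set(range(lo, hi + 1))
                if span & occupied:
                    raise ValueError(f"helix {h.name} overlaps another helix")
                occupied |= span
                if hi > self.length:
                    raise ValueError(f"helix {h.name} exceeds model length")

    def helix_of(self, model_pos: int) -> str | None:
        for h in self.helices:
            if h.contains(model_pos):
                return h.name
        return None

    @classmethod
    def from_tsv(cls, path: str | Path, molecule: str | None = None) -> "HelixMap":
        """Load a map from a TSV with columns: molecule, helix,
        strand5_start, strand5_end, strand3_start, strand3_end.
        An optional row with helix == "_length" carries the model length
        in strand5_start; otherwise the maximum coordinate is used."""
        helices = []
        mol = molecule
        length = 0
        with Path(path).open() as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if mol is None:
                    mol = row["molecule"]
                if row["molecule"] != mol:
                    continue
                if row["helix"] == "_length":
                    length = int(row["strand5_start"])
                    continue
                helices.append(
                    Helix(
                        name=row["helix"],
                        strand5=(int(row["strand5_start"]), int(row["strand5_end"])),
                        strand3=(int(row["strand3_start"]), int(row["strand3_end"])),
                    )
                )
        if not length:
            length = max(h.strand3[1] for h in helices)
        return cls(molecule=mol or "16S", length=length, helices=helices)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(
                "molecule\thelix\tstrand5_start\tstrand5_end\tstrand3_start\tstrand3_end\n"
            )
            fh.write(f"{self.molecule}\t_length\t{self.length}\t0\t0\t0\n")
            for h in self.helices:
                fh.write(
                    f"{self.molecule}\t{h.name}\t{h.strand5[0]}\t{h.strand5[1]}"
                    f"\t{h.strand3[0]}\t{h.strand3[1]}\n"
                )


def default_16s_helix_map() -> HelixMap:
    """The packaged default 16S helix map (a synthetic stand-in layout;
    supply your own map for real molecules)."""
    path = Path(__file__).parent / "data" / "helix_map_16s_synthetic.tsv"
    return HelixMap.from_tsv(path)


def fold_helix(
    strand5: str,
    strand3: str,
    reference_mismatch_positions: Iterable[int] = (),
    max_closable: int = 2,
    wobble: bool = True,
) -> list[bool]:
    """Pairing mask of a helix: strand5 position i (1-based) against
    strand3 position L+1-i.

    Reference-model mismatch positions are closed (marked paired) only
    when the target bases pair canonically there and the total number
    of such closures does not exceed ``max_closable``; all other
    positions are paired iff canonical. With ``max_closable=0`` the
    result is the plain canonical mask.
    """
    if not strand5 or not strand3:
        raise ValueError("helix strands must be non-empty")
    strand5 = strand5.upper().replace("U", "T")
    strand3 = strand3.upper().replace("U", "T")
    if len(strand5) != len(strand3):
        raise ValueError(
            f"strand length mismatch: {len(strand5)} vs {len(strand3)}"
        )
    L = len(strand5)
    ref = set(reference_mismatch_positions)
    bad = {p for p in ref if not 1 <= p <= L}
    if bad:
        raise ValueError(f"reference mismatch positions outside helix: {sorted(bad)}")
    canonical = [
        pairs_canonically(strand5[i - 1], strand3[L - i], wobble) for i in range(1, L + 1)
    ]
    closable = [p for p in sorted(ref) if canonical[p - 1]]
    close = set(closable) if len(closable) <= max_closable else set()
    mask = []
    for i in range(1, L + 1):
        if i in ref:
            mask.append(i in close)
        else:
            mask.append(canonical[i - 1])
    return mask


def dot_bracket(strand5: str, strand3: str, mask: list[bool]) -> str:
    """Dot-bracket string for the two strands joined by an ellipsis."""
    left = "".join("(" if m else "." for m in mask)
    right = "".join(")" if m else "." for m in reversed(mask))
    return f"{left}...{right}"


@dataclass(frozen=True)
class ColumnMapping:
    """Alignment column -> model coordinate mapping.

    ``model_position[col]`` is the 1-based model position for columns
    where the model row has a residue; for columns opposite a model gap
    it is None and ``insertion_after[col]`` gives the model position
    the insertion follows (0 = before the first model residue).
    """

    model_position: dict[int, int]
    insertion_after: dict[int, int]

    def position_or_anchor(self, col: int) -> int:
        if col in self.model_position:
            return self.model_position[col]
        return self.insertion_after[col]


def map_columns_to_model(
    aln: MultiAlignment, model_row_id: str, hmap: HelixMap
) -> ColumnMapping:
    """Map alignment columns onto model coordinates by counting the
    model row's non-gap residues."""
    row = aln[model_row_id].residues
    ungapped = sum(1 for b in row if b != "-")
    if ungapped != hmap.length:
        raise ValueError(
            f"model row {model_row_id!r} has {ungapped} residues; "
            f"helix map expects {hmap.length}"
        )
    model_position: dict[int, int] = {}
    insertion_after: dict[int, int] = {}
    pos = 0
    for col, base in enumerate(row, start=1):
        if base == "-":
            insertion_after[col] = pos
        else:
            pos += 1
            model_position[col] = pos
    return ColumnMapping(model_position=model_position, insertion_after=insertion_after)


@dataclass
class HelixComparison:
    helix: str
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    structure_altering: bool = False
    detail: str = ""


@dataclass
class StructureComparison:
    """Per-helix between-type variability plus unpaired-region counts."""

    per_helix: dict[str, HelixComparison]
    unpaired_region_changes: int

    @property
    def total_assigned(self) -> int:
        return self.unpaired_region_changes + sum(
            h.substitutions + h.insertions + h.deletions
            for h in self.per_helix.values()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "helix": h.helix,
                    "substitutions": h.substitutions,
                    "insertions": h.insertions,
                    "deletions": h.deletions,
                    "structure_altering": h.structure_altering,
                    "detail": h.detail,
                }
                for h in self.per_helix.values()
            ]
        )


def _type_consensus_rows(
    aln: MultiAlignment, labels: Mapping[str, str]
) -> dict[str, str]:
    """Strict-majority consensus row per type, gaps allowed as states."""
    from collections import Counter

    rows_by_type: dict[str, list[str]] = {"Type1": [], "Type2": []}
    for rec in aln:
        lab = labels.get(rec.id)
        if lab in rows_by_type:
            rows_by_type[lab].append(rec.residues)
    out = {}
    for lab, rows in rows_by_type.items():
        if not rows:
            raise ValueError(f"no sequences labeled {lab}")
        cons = []
        for col in range(len(rows[0])):
            counts = Counter(r[col] for r in rows)
            top = max(counts.values())
            cons.append(min(b for b, c in counts.items() if c == top))
        out[lab] = "".join(cons)
    return out


def helix_variability(
    aln: MultiAlignment,
    labels: Mapping[str, str],
    sig: SignatureTable,
    hmap: HelixMap,
    colmap: ColumnMapping,
    max_closable: int = 2,
    wobble: bool = True,
) -> StructureComparison:
    """Assign between-type variability to helices and unpaired regions.

    Signature positions count as substitutions in the helix containing
    their model position (insertion columns are attributed to the helix
    of the model position they follow). Columns where the two type
    consensuses differ by a gap count as insertions (Type1 consensus
    has the base opposite a Type2/model gap) or deletions (Type1
    consensus gapped). A helix is structure-altering when folding the
    two type-consensus helix sequences yields different pairing masks
    or different strand lengths.
    """
    cons = _type_consensus_rows(aln, labels)
    t1, t2 = cons["Type1"], cons["Type2"]
    comparisons = {h.name: HelixComparison(helix=h.name) for h in hmap.helices}
    unpaired = 0

    def bucket(col: int) -> HelixComparison | None:
        anchor = colmap.position_or_anchor(col)
        if anchor == 0:
            return None
        name = hmap.helix_of(anchor)
        return comparisons.get(name) if name else None

    for p in sig.positions:
        target = bucket(p.position)
        if target is None:
            unpaired += 1
        else:
            target.substitutions += 1

    sig_cols = set(sig.columns)
    for col in range(1, aln.width + 1):
        if col in sig_cols:
            continue
        b1, b2 = t1[col - 1], t2[col - 1]
        if b1 == b2 or "-" not in (b1, b2):
            continue
        target = bucket(col)
        if target is None:
            unpaired += 1
        elif b1 == "-":
            target.deletions += 1
        else:
            target.insertions += 1

    # fold each helix from each type consensus and compare masks
    model_to_col = {v: k for k, v in colmap.model_position.items()}
    for h in hmap.helices:
        comp = comparisons[h.name]

        def strand(cons_row: str, interval: tuple[int, int]) -> str:
            cols = []
            for mp in range(interval[0], interval[1] + 1):
                if mp in model_to_col:
                    cols.append(model_to_col[mp])
            # include insertion columns anchored inside the strand
            ins = [
                c
                for c, after in colmap.insertion_after.items()
                if interval[0] <= after < interval[1]
            ]
            cols = sorted(cols + ins)
            return "".join(
                cons_row[c - 1] for c in cols if cons_row[c - 1] != "-"
            )

        masks = []
        for cons_row in (t1, t2):
            s5 = strand(cons_row, h.strand5)
            s3 = strand(cons_row, h.strand3)
            if len(s5) != len(s3) or not s5:
                masks.append(("unfoldable", len(s5), len(s3)))
            else:
                masks.append(
                    tuple(fold_helix(s5, s3, max_closable=max_closable, wobble=wobble))
                )
        if masks[0] != masks[1]:
            comp.structure_altering = True
            comp.detail = "pairing mask differs between type consensuses"
    return StructureComparison(per_helix=comparisons, unpaired_region_changes=unpaired)
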