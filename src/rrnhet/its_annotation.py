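"""16S-23S internal transcribed spacer (ITS) domain annotation.

The ITS between the 16S and 23S rRNA genes carries an ordered series of
conserved domains — leader, D1-D1' helix, D2, a D2-D3 spacer, D3,
optional tRNA-Ile and tRNA-Ala genes, the V2 and Box-B helices, Box-A,
D4, the V3 helix and D5 — whose architecture differs systematically
between divergent operon types. Domains are located by an ordered
template search: motif domains by their first full IUPAC match after
the running cursor, helix domains by the first foldable hairpin
(canonical stem, short loop) in their search window, and spacers as the
residue between their neighbours. Since the full domain motifs vary by
lineage, the templates are data (editable TSVs), not constants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .motif import find_motif
from .rrna_structure import pairs_canonically
from .seq_io import SequenceRecord

DOMAIN_ORDER = [
    "leader",
    "D1-D1'",
    "D2",
    "spacer_D2_D3",
    "D3",
    "tRNA-Ile",
    "V2",
    "tRNA-Ala",
    "BoxB",
    "BoxA",
    "D4",
    "V3",
    "D5",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainTemplate:
    name: str
    kind: str  # motif | helix | spacer
    pattern: str  # IUPAC string for motifs; "stem=a..b;loop=c..d;window=w" for helices
    required: bool = True

    def helix_params(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for part in self.pattern.split(";"):
            key, _, val = part.partition("=")
            if ".." in val:
                lo, hi = val.split("..")
                out[key] = (int(lo), int(hi))
            else:
                out[key] = (int(val), int(val))
        return out


@dataclass
class DomainTemplateSet:
    """Ordered domain templates for one ITS architecture."""

    templates: list[DomainTemplate]

    def __post_init__(self) -> None:
        names = [t.name for t in self.templates]
        if len(names) != len(set(names)):
            raise ValueError("duplicate domain templates")
        order = {n: i for i, n in enumerate(DOMAIN_ORDER)}
        if sorted(names, key=order.__getitem__) != names:
            raise ValueError("templates must follow canonical domain order")

    def __getitem__(self, name: str) -> DomainTemplate:
        for t in self.templates:
            if t.name == name:
                return t
        raise KeyError(name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainTemplateSet":
        templates = []
        with Path(path).open() as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                templates.append(
                    DomainTemplate(
                        name=row["domain"],
                        kind=row["kind"],
                        pattern=row["pattern"],
                        required=row["required"].lower() in ("yes", "true", "1"),
                    )
                )
        return cls(templates)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("domain\tkind\tpattern\trequired\n")
            for t in self.templates:
                fh.write(
                    f"{t.name}\t{t.kind}\t{t.pattern}\t{'yes' if t.required else 'no'}\n"
                )


def default_templates(operon_type: str) -> DomainTemplateSet:
    """Packaged default templates (synthetic realizations of the two
    architectures; edit or replace for real lineages)."""
    suffix = {"Type1": "type1", "Type2": "type2"}[operon_type]
    path = Path(__file__).parent / "data" / f"its_templates_{suffix}_synthetic.tsv"
    return DomainTemplateSet.from_tsv(path)


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    interval: tuple[int, int] | None  # 1-based closed; None when absent
    sequence: str
    present: bool


@dataclass
class ITSAnnotation:
    """Ordered ITS domains with 1-based closed intervals."""

    seq_id: str
    domains: list[DomainAnnotation]
    first3: str

    def __getitem__(self, name: str) -> DomainAnnotation:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def present_intervals(self) -> list[tuple[str, tuple[int, int]]]:
        return [(d.name, d.interval) for d in self.domains if d.present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seqid": self.seq_id,
                    "domain": d.name,
                    "start": d.interval[0] if d.present else "",
                    "end": d.interval[1] if d.present else "",
                    "sequence": d.sequence,
                }
                for d in self.domains
            ]
        )


def find_hairpin(
    seq: str,
    search_start: int,
    search_end: int,
    stem_range: tuple[int, int],
    loop_range: tuple[int, int],
    wobble: bool = True,
) -> tuple[int, int, int] | None:
    """First canonical hairpin in a window.

    Scans start positions left to right; at each start prefers the
    longest stem, then the smallest loop. Returns (start, stem, loop)
    with ``start`` 1-based, or None.
    """
    n = len(seq)
    for start in range(search_start, search_end + 1):
        for stem in range(stem_range[1], stem_range[0] - 1, -1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = start + 2 * stem + loop - 1
                if end > n:
                    continue
                s5 = seq[start - 1 : start - 1 + stem]
                s3 = seq[start - 1 + stem + loop : end]
                if all(
                    pairs_canonically(s5[i], s3[stem - 1 - i], wobble)
                    for i in range(stem)
                ):
                    return start, stem, loop
    return None


def annotate_its(
    seq: SequenceRecord | str, templates: DomainTemplateSet, wobble: bool = True
) -> ITSAnnotation:
    """Dissect an ITS sequence into domains by ordered template search."""
    if isinstance(seq, SequenceRecord):
        seq_id, s = seq.id, seq.residues
        if seq.region not in ("ITS", "other"):
            raise AnnotationError(f"{seq_id}: region is {seq.region}, expected ITS")
    else:
        seq_id, s = "its", seq.upper().replace("U", "T")
    if len(s) < 50:
        raise AnnotationError(f"{seq_id}: ITS too short ({len(s)} nt)")

    annotations: list[DomainAnnotation] = []
    cursor = 1  # next unconsumed 1-based position
    pending_spacer: DomainTemplate | None = None

    def emit(name: str, interval: tuple[int, int] | None) -> None:
        if interval is None:
            annotations.append(DomainAnnotation(name, None, "", False))
        else:
            lo, hi = interval
            annotations.append(
                DomainAnnotation(name, (lo, hi), s[lo - 1 : hi], True)
            )

    for tpl in templates.templates:
        if tpl.kind == "spacer":
            pending_spacer = tpl
            continue
        if tpl.name == "leader":
            continue  # resolved once D1-D1' is placed
        if tpl.kind == "helix":
            params = tpl.helix_params()
            window = params.get("window", (40, 40))[1]
            if tpl.name == "D1-D1'":
                lo_search, hi_search = 1, window
            else:
                lo_search, hi_search = cursor, min(cursor + window - 1, len(s))
            hit = find_hairpin(
                s, lo_search, hi_search, params["stem"], params["loop"], wobble
            )
            if hit is None:
                if tpl.name == "D1-D1'":
                    raise AnnotationError(
                        f"{seq_id}: no D1-D1' helix foldable within the "
                        f"first {window} nt"
                    )
                if tpl.required:
                    raise AnnotationError(f"{seq_id}: required helix {tpl.name} not found")
                emit(tpl.name, None)
                continue
            start, stem, loop = hit
            end = start + 2 * stem + loop - 1
            if tpl.name == "D1-D1'":
                emit("leader", (1, start - 1) if start > 1 else None)
            elif start < cursor:
                raise AnnotationError(
                    f"{seq_id}: helix {tpl.name} overlaps the previous domain"
                )
            if pending_spacer is not None:
                _flush_spacer(emit, pending_spacer, cursor, start - 1)
                pending_spacer = None
            emit(tpl.name, (start, end))
            cursor = end + 1
        elif tpl.kind == "motif":
            pos = find_motif(s, tpl.pattern, start=cursor)
            if pos is None:
                if tpl.required:
                    raise AnnotationError(
                        f"{seq_id}: required motif {tpl.name} "
                        f"({tpl.pattern}) not found after position {cursor}"
                    )
                emit(tpl.name, None)
                continue
            if pos < cursor:
                raise AnnotationError(
                    f"{seq_id}: motif {tpl.name} overlaps the previous domain"
                )
            if pending_spacer is not None:
                _flush_spacer(emit, pending_spacer, cursor, pos - 1)
                pending_spacer = None
            end = pos + len(tpl.pattern) - 1
            emit(tpl.name, (pos, end))
            cursor = end + 1
        else:
            raise ValueError(f"unknown template kind {tpl.kind!r}")

    ordered = sorted(
        annotations, key=lambda d: d.interval[0] if d.present else 0
    )
    # restore canonical domain order for reporting
    order = {n: i for i, n in enumerate(DOMAIN_ORDER)}
    annotations.sort(key=lambda d: order[d.name])
    _check_tiling(seq_id, ordered)
    return ITSAnnotation(seq_id=seq_id, domains=annotations, first3=s[:3])


def _flush_spacer(emit, tpl: DomainTemplate, lo: int, hi: int) -> None:
    emit(tpl.name, (lo, hi) if hi >= lo else None)


def _check_tiling(seq_id: str, ordered: list[DomainAnnotation]) -> None:
    prev_end = 0
    prev_name = None
    for d in ordered:
        if not d.present:
            continue
        if d.interval[0] <= prev_end:
            raise AnnotationError(
                f"{seq_id}: domains {prev_name} and {d.name} overlap"
            )
        prev_end = d.interval[1]
        prev_name = d.name


def its_feature_table(
    annotations: list[ITSAnnotation], labels: dict[str, str]
) -> pd.DataFrame:
    """Comparative per-type ITS feature table.

    For each operon-type label: the observed ITS-start 3-mers, the
    D2-D3 spacer length range, the D3 motif set, the D4 and D5 length
    ranges, and the tRNA presence patterns.
    """
    if not annotations:
        raise ValueError("no annotations")
    rows = []
    by_label: dict[str, list[ITSAnnotation]] = {}
    for ann in annotations:
        lab = labels[ann.seq_id]
        by_label.setdefault(lab, []).append(ann)

    def length_range(anns: list[ITSAnnotation], name: str) -> str:
        lens = sorted(
            {
                a[name].interval[1] - a[name].interval[0] + 1
                for a in anns
                if a[name].present
            }
        )
        if not lens:
            return "absent"
        return str(lens[0]) if lens[0] == lens[-1] else f"{lens[0]}-{lens[-1]}"

    for lab, anns in sorted(by_label.items()):
        trna_patterns = sorted(
            {
                ("Ile+" if a["tRNA-Ile"].present else "Ile-")
                + ("Ala+" if a["tRNA-Ala"].present else "Ala-")
                for a in anns
            }
        )
        rows.append(
            {
                "operon_type": lab,
                "n": len(anns),
                "first3": ",".join(sorted({a.first3 for a in anns})),
                "spacer_D2_D3_length": length_range(anns, "spacer_D2_D3"),
                "D3_motifs": ",".join(
                    sorted({a["D3"].sequence for a in anns if a["D3"].present})
                ),
                "D4_length": length_range(anns, "D4"),
                "D5_length": length_range(anns, "D5"),
                "tRNAs": ";".join(trna_patterns),
            }
        )
    return pd.DataFrame(rows)
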