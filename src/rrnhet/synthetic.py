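"""Synthetic multi-strain rRNA operon datasets with known ground truth.

The generator emulates the study design that motivates the package: a
species cluster in which every strain carries several ribosomal
operons, most of them nearly identical ("Type 2") plus one divergent
copy ("Type 1") whose differences are concentrated at planted
signature positions localized in designated helices. Each operon gets
a type-specific ITS architecture (Type 1: ITS starting AAC, D2-D3
spacer of 10-11 nt, D3 = GGTAY, short 6-nt D5; Type 2: TTT start,
4-6 nt spacer, D3 = GGTTC, long D5) and a type-specific sigma-70-style
promoter. Strains drift within species by a small per-site noise rate,
species drift apart by a larger background rate that never touches the
signature, and optional "reversions" overwrite signature sites with
the other type's base, imitating partial gene conversion.

All randomness flows from one numpy Generator seeded by ``cfg.seed``,
so a fixed configuration reruns byte-identically. The emitted
alignments are gapless by construction (no indel evolution); clone
libraries are drawn with replacement under per-operon weights to mimic
PCR amplification bias.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .its_annotation import DomainTemplateSet, annotate_its, default_templates
from .motif import IUPAC_CLASSES
from .promoter import PromoterConsensus, scan_promoter
from .rrna_structure import HelixMap, default_16s_helix_map
from .seq_io import MultiAlignment, SequenceRecord, write_fasta

BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: promoter element realizations per operon type (motifs as printed for
#: the two operon types' upstream regions: a perfect/near-consensus
#: sigma-70 promoter for Type 2, a weaker but still functional one for
#: Type 1)
DEFAULT_PROMOTER_ELEMENTS = {
    "Type1": {"minus52": "AAAAGTACGGT", "minus35": "CACACA", "minus10": "TACAAT"},
    "Type2": {"minus52": "AAAAATTTTGA", "minus35": "TTGACA", "minus10": "TATATT"},
}

DEFAULT_SIGNATURE_HELICES = ("H6", "H9", "H10", "H18", "H21", "H27", "H28", "H33")


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    n_species: int = 3
    strains_per_species: int = 3
    operons_per_strain: int = 5
    n_type1: int = 1
    gene_length_16s: int = 1500
    gene_length_23s: int = 2800
    include_23s: bool = True
    #: number of planted between-type differences in the 16S; when None,
    #: derived as round(between_type_divergence * gene_length_16s)
    signature_positions: int | None = 123
    between_type_divergence: float = 0.08
    between_type_divergence_23s: float = 0.068
    within_type_site_noise: float = 0.002
    between_species_divergence: float = 0.02
    reversion_rate: float = 0.0
    signature_helices: tuple[str, ...] = DEFAULT_SIGNATURE_HELICES
    clone_n_clones: int = 12
    clone_type1_bias_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.between_type_divergence,
            self.between_type_divergence_23s,
            self.within_type_site_noise,
            self.between_species_divergence,
            self.reversion_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if not 0 < self.n_type1 < self.operons_per_strain:
            raise ValueError("n_type1 must be in 1..operons_per_strain-1")
        if self.n_signature_16s > self.gene_length_16s:
            raise ValueError("signature positions exceed 16S gene length")

    @property
    def n_signature_16s(self) -> int:
        if self.signature_positions is not None:
            return self.signature_positions
        return round(self.between_type_divergence * self.gene_length_16s)

    @property
    def n_signature_23s(self) -> int:
        return round(self.between_type_divergence_23s * self.gene_length_23s)


@dataclass
class SyntheticTruth:
    operon_type: dict[str, str]
    signature_16s: list[dict]  # position, base_type1, base_type2, helix
    signature_23s: list[int]
    genospecies: dict[str, str]  # strain -> species label
    its_boundaries: dict[str, list[tuple[str, int, int]]]
    promoter_windows: dict[str, dict[str, tuple[int, int]]]

    def to_json(self) -> str:
        payload = {
            "operon_type": self.operon_type,
            "signature_16s": self.signature_16s,
            "signature_23s": self.signature_23s,
            "genospecies": self.genospecies,
            "its_boundaries": self.its_boundaries,
            "promoter_windows": self.promoter_windows,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    records: list[SequenceRecord]
    alignment_16s: MultiAlignment
    alignment_23s: MultiAlignment | None
    metadata: pd.DataFrame
    truth: SyntheticTruth
    tree_newick: str
    helix_map: HelixMap

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.truth.operon_type)

    @property
    def strain_of(self) -> dict[str, str]:
        return dict(zip(self.metadata["seq_id"], self.metadata["strain"]))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "sequences.fasta")
        write_fasta(self.alignment_16s.records, out / "alignment_16s.fasta")
        if self.alignment_23s is not None:
            write_fasta(self.alignment_23s.records, out / "alignment_23s.fasta")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(self.truth.to_json())
        (out / "tree.nwk").write_text(self.tree_newick + "\n")
        self.helix_map.to_tsv(out / "helix_map.tsv")
        (out / "config.yaml").write_text(
            yaml.safe_dump(asdict(self.config), sort_keys=True)
        )


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


def _mutate(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each listed position with a different random base."""
    out = seq.copy()
    shifts = rng.integers(1, 4, size=len(positions))
    out[positions] = (out[positions] + shifts) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


def realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Draw a concrete sequence satisfying an IUPAC pattern."""
    out = []
    for ch in pattern:
        options = sorted(IUPAC_CLASSES[ch])
        out.append(options[rng.integers(0, len(options))])
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _build_its(
    operon_type: str,
    templates: DomainTemplateSet,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Assemble an ITS from templates; rejection-sample until the
    annotator recovers exactly the planted boundaries."""
    start3 = "AAC" if operon_type == "Type1" else "TTT"
    spacer_range = (10, 11) if operon_type == "Type1" else (4, 6)
    helix_plant = {"D1-D1'": (8, 4), "V2": (6, 4), "BoxB": (7, 5), "V3": (6, 4)}

    for _ in range(max_tries):
        parts: list[tuple[str, str]] = []
        leader = start3 + _random_seq(rng, int(rng.integers(5, 10)), "AC")
        parts.append(("leader", leader))
        for tpl in templates.templates:
            if tpl.kind == "helix":
                stem_len, loop_len = helix_plant[tpl.name]
                stem = _random_seq(rng, stem_len)
                loop = _random_seq(rng, loop_len, "AC")
                parts.append((tpl.name, stem + loop + _revcomp(stem)))
            elif tpl.kind == "spacer":
                n = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
                parts.append((tpl.name, _random_seq(rng, n, "AC")))
            else:
                parts.append((tpl.name, realize_pattern(tpl.pattern, rng)))
        seq = "".join(s for _, s in parts)
        boundaries: list[tuple[str, int, int]] = []
        pos = 1
        for name, s in parts:
            boundaries.append((name, pos, pos + len(s) - 1))
            pos += len(s)
        try:
            ann = annotate_its(seq, templates)
        except Exception:
            continue
        recovered = [(n, iv[0], iv[1]) for n, iv in ann.present_intervals()]
        if recovered == boundaries:
            return seq, boundaries
    raise GenerationError(
        f"could not build a round-trip-clean {operon_type} ITS in {max_tries} tries"
    )


def _build_upstream(
    operon_type: str,
    elements: dict[str, str],
    consensus: PromoterConsensus,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Assemble an upstream region ending at the transcript start;
    rejection-sample until the scanner recovers the planted windows."""
    for _ in range(max_tries):
        prefix = _random_seq(rng, int(rng.integers(8, 15)))
        lo52, hi52 = consensus.spacer_52_35
        sp52 = _random_seq(rng, int(rng.integers(lo52, hi52 + 1)))
        sp35 = _random_seq(rng, 17)
        disc = _random_seq(rng, 4)
        seq = (
            prefix
            + elements["minus52"]
            + sp52
            + elements["minus35"]
            + sp35
            + elements["minus10"]
            + disc
        )
        if len(seq) < 60:  # left-pad to the minimum input length
            pad = 60 - len(seq)
            seq = _random_seq(rng, pad) + seq
            prefix = seq[: len(prefix) + pad]
        p52 = len(prefix) + 1
        p35 = p52 + 11 + len(sp52)
        p10 = p35 + 6 + len(sp35)
        windows = {
            "minus52": (p52, p52 + 10),
            "minus35": (p35, p35 + 5),
            "minus10": (p10, p10 + 5),
        }
        try:
            ann = scan_promoter(seq, consensus)
        except ValueError:
            continue
        got = {
            "minus35": ann.minus35.window,
            "minus10": ann.minus10.window,
        }
        if ann.minus52 is not None:
            got["minus52"] = ann.minus52.window
        if got == windows:
            return seq, windows
    raise GenerationError(
        f"could not build a round-trip-clean {operon_type} upstream in {max_tries} tries"
    )


def generate_dataset(
    cfg: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full multi-strain dataset plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    hmap = default_16s_helix_map()
    if cfg.gene_length_16s < hmap.length:
        raise ValueError(
            f"gene_length_16s must be >= helix map length {hmap.length}"
        )

    # --- 16S type ancestors -------------------------------------------------
    L16 = cfg.gene_length_16s
    anc2_16s = rng.integers(0, 4, size=L16)
    helix_cols: list[tuple[int, str]] = []
    for name in cfg.signature_helices:
        helix = next(h for h in hmap.helices if h.name == name)
        for lo, hi in (helix.strand5, helix.strand3):
            helix_cols.extend((p, name) for p in range(lo, hi + 1))
    n_sig = cfg.n_signature_16s
    if n_sig > len(helix_cols):
        # overflow positions go to unpaired regions
        paired = {p for p, _ in helix_cols}
        free = [p for p in range(1, L16 + 1) if p not in paired]
        extra = rng.choice(len(free), size=n_sig - len(helix_cols), replace=False)
        chosen = helix_cols + [(free[i], "unpaired") for i in sorted(extra)]
    else:
        idx = rng.choice(len(helix_cols), size=n_sig, replace=False)
        chosen = [helix_cols[i] for i in sorted(idx)]
    chosen.sort()
    sig_positions = np.array([p for p, _ in chosen]) - 1
    anc1_16s = _mutate(anc2_16s, sig_positions, rng)
    signature_truth = [
        {
            "position": int(p + 1),
            "base_type1": str(BASES[anc1_16s[p]]),
            "base_type2": str(BASES[anc2_16s[p]]),
            "helix": helix,
        }
        for (p, helix) in zip(sig_positions, [h for _, h in chosen])
    ]

    # --- 23S type ancestors -------------------------------------------------
    if cfg.include_23s:
        L23 = cfg.gene_length_23s
        anc2_23s = rng.integers(0, 4, size=L23)
        sig23 = np.sort(rng.choice(L23, size=cfg.n_signature_23s, replace=False))
        anc1_23s = _mutate(anc2_23s, sig23, rng)
        sig23_truth = [int(p + 1) for p in sig23]
    else:
        sig23_truth = []

    # --- per-species backgrounds (never touching signature sites) ----------
    non_sig_16s = np.setdiff1d(np.arange(L16), sig_positions)
    species_anc: list[dict] = []
    for sp in range(cfg.n_species):
        k = rng.binomial(len(non_sig_16s), cfg.between_species_divergence)
        pos = rng.choice(non_sig_16s, size=k, replace=False)
        shifts = rng.integers(1, 4, size=k)
        a2 = anc2_16s.copy()
        a2[pos] = (a2[pos] + shifts) % 4
        a1 = anc1_16s.copy()
        a1[pos] = (a1[pos] + shifts) % 4  # same background change in both types
        entry = {"16s": {"Type1": a1, "Type2": a2}}
        if cfg.include_23s:
            non_sig_23s = np.setdiff1d(np.arange(L23), sig23)
            k23 = rng.binomial(len(non_sig_23s), cfg.between_species_divergence)
            pos23 = rng.choice(non_sig_23s, size=k23, replace=False)
            shifts23 = rng.integers(1, 4, size=k23)
            b2 = anc2_23s.copy()
            b2[pos23] = (b2[pos23] + shifts23) % 4
            b1 = anc1_23s.copy()
            b1[pos23] = (b1[pos23] + shifts23) % 4
            entry["23s"] = {"Type1": b1, "Type2": b2}
        species_anc.append(entry)

    # --- per-operon ITS and upstream templates ------------------------------
    templates = {t: default_templates(t) for t in ("Type1", "Type2")}
    consensus = PromoterConsensus()
    its_by_operon: dict[int, tuple[str, list]] = {}
    upstream_by_operon: dict[int, tuple[str, dict]] = {}
    for op in range(1, cfg.operons_per_strain + 1):
        op_type = "Type1" if op <= cfg.n_type1 else "Type2"
        its_by_operon[op] = _build_its(op_type, templates[op_type], rng)
        upstream_by_operon[op] = _build_upstream(
            op_type, DEFAULT_PROMOTER_ELEMENTS[op_type], consensus, rng
        )

    # --- strains ------------------------------------------------------------
    records: list[SequenceRecord] = []
    aln16_rows: list[SequenceRecord] = []
    aln23_rows: list[SequenceRecord] = []
    meta_rows: list[dict] = []
    truth_types: dict[str, str] = {}
    its_boundaries: dict[str, list] = {}
    promoter_windows: dict[str, dict] = {}
    genospecies: dict[str, str] = {}
    strain_names_by_species: list[list[str]] = []

    for sp in range(cfg.n_species):
        species_label = f"Species_{sp + 1}"
        strain_names: list[str] = []
        for st in range(cfg.strains_per_species):
            strain = f"S{sp + 1}-{chr(ord('a') + st)}"
            strain_names.append(strain)
            genospecies[strain] = species_label
            for op in range(1, cfg.operons_per_strain + 1):
                op_type = "Type1" if op <= cfg.n_type1 else "Type2"
                base_id = f"{strain}_op{op}"
                truth_types[base_id] = op_type

                seq16 = species_anc[sp]["16s"][op_type]
                noise_mask = rng.random(L16) < cfg.within_type_site_noise
                seq16 = _mutate(seq16, np.flatnonzero(noise_mask), rng)
                if cfg.reversion_rate > 0:
                    rev_mask = rng.random(len(sig_positions)) < cfg.reversion_rate
                    rev_pos = sig_positions[rev_mask]
                    other = anc1_16s if op_type == "Type2" else anc2_16s
                    seq16 = seq16.copy()
                    seq16[rev_pos] = other[rev_pos]
                rec16 = SequenceRecord(
                    id=base_id,
                    residues=_to_str(seq16),
                    strain=strain,
                    region="16S",
                    operon_type=op_type,
                )
                aln16_rows.append(rec16)
                records.append(rec16)

                if cfg.include_23s:
                    seq23 = species_anc[sp]["23s"][op_type]
                    noise23 = rng.random(L23) < cfg.within_type_site_noise
                    seq23 = _mutate(seq23, np.flatnonzero(noise23), rng)
                    rec23 = SequenceRecord(
                        id=f"{base_id}_23S",
                        residues=_to_str(seq23),
                        strain=strain,
                        region="23S",
                        operon_type=op_type,
                    )
                    aln23_rows.append(rec23)
                    records.append(rec23)

                its_seq, bounds = its_by_operon[op]
                its_id = f"{base_id}_ITS"
                records.append(
                    SequenceRecord(
                        id=its_id,
                        residues=its_seq,
                        strain=strain,
                        region="ITS",
                        operon_type=op_type,
                    )
                )
                its_boundaries[its_id] = [list(b) for b in bounds]

                up_seq, windows = upstream_by_operon[op]
                up_id = f"{base_id}_upstream"
                records.append(
                    SequenceRecord(
                        id=up_id,
                        residues=up_seq,
                        strain=strain,
                        region="upstream",
                        operon_type=op_type,
                    )
                )
                promoter_windows[up_id] = {k: list(v) for k, v in windows.items()}

                meta_rows.append(
                    {
                        "seq_id": base_id,
                        "strain": strain,
                        "morphospecies": species_label,
                        "operon_index": op,
                        "operon_type": op_type,
                    }
                )
        strain_names_by_species.append(strain_names)

    tree = (
        "("
        + ",".join(
            "(" + ",".join(f"{s}:1" for s in strains) + f"){label}:1"
            for strains, label in zip(
                strain_names_by_species,
                (f"Species_{i + 1}" for i in range(cfg.n_species)),
            )
        )
        + ")root;"
    )

    dataset = SyntheticDataset(
        config=cfg,
        records=records,
        alignment_16s=MultiAlignment(aln16_rows),
        alignment_23s=MultiAlignment(aln23_rows) if cfg.include_23s else None,
        metadata=pd.DataFrame(meta_rows),
        truth=SyntheticTruth(
            operon_type=truth_types,
            signature_16s=signature_truth,
            signature_23s=sig23_truth,
            genospecies=genospecies,
            its_boundaries=its_boundaries,
            promoter_windows=promoter_windows,
        ),
        tree_newick=tree,
        helix_map=hmap,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def simulate_clone_library(
    operons: list[SequenceRecord],
    n_clones: int,
    weights: list[float] | np.ndarray,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Draw a clone library with replacement under per-operon weights.

    Weights model PCR amplification bias; a zero weight reproduces an
    operon type that cloning misses entirely (the situation that
    motivates type-specific primers).
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(operons):
        raise ValueError("one weight per operon required")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(operons), size=n_clones, replace=True, p=w / w.sum())
    clones = []
    for i, k in enumerate(picks, start=1):
        src = operons[k]
        clones.append(
            SequenceRecord(
                id=f"clone_{i:03d}_{src.id}",
                residues=src.residues,
                strain=src.strain,
                region=src.region,
                operon_type=src.operon_type,
            )
        )
    return clones
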