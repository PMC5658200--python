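"""End-to-end orchestration: typing, distances, ITS, promoters,
structure and genospecies, with a machine-readable report bundle.

The pipeline consumes a dataset directory (as written by the synthetic
generator, or assembled by hand from real data in the same layout:
``alignment_16s.fasta``, optional ``alignment_23s.fasta``,
``sequences.fasta`` with region-tagged headers, ``metadata.tsv``,
optional ``tree.nwk`` and ``helix_map.tsv``) and writes one JSON
summary plus per-stage TSVs. Every threshold used is recorded in the
summary, and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .divergence import identity_matrix, range_summary
from .genospecies import StrainProfile, clades_from_tree, delimit
from .its_annotation import annotate_its, default_templates, its_feature_table
from .operon_typing import (
    best_primer,
    classify_sequence,
    design_type_primers,
    detect_reversions,
    find_signature,
)
from .promoter import PromoterConsensus, promoter_table, scan_promoter
from .rrna_structure import (
    HelixMap,
    default_16s_helix_map,
    helix_variability,
    map_columns_to_model,
)
from .seq_io import MultiAlignment, read_alignment, read_fasta


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    saturation_threshold: float = 0.85
    identity_threshold: float = 98.7
    max_closable: int = 2
    primer_length_range: tuple[int, int] = (20, 30)
    primer_min_cross_mismatches: int = 3
    promoter: PromoterConsensus = field(default_factory=PromoterConsensus)
    use_tree: bool = True
    use_morphology: bool = True
    wobble: bool = True
    seed: int = 0

    def thresholds(self) -> dict:
        return {
            "saturation_threshold": self.saturation_threshold,
            "identity_threshold": self.identity_threshold,
            "max_closable": self.max_closable,
            "primer_length_range": list(self.primer_length_range),
            "primer_min_cross_mismatches": self.primer_min_cross_mismatches,
            "promoter_functional_min_matches": 3,
            "promoter_spacer_35_10": list(self.promoter.spacer_35_10),
            "promoter_spacer_52_35": list(self.promoter.spacer_52_35),
            "gu_wobble_canonical": self.wobble,
        }


@dataclass
class DatasetInputs:
    alignment_16s: MultiAlignment
    alignment_23s: MultiAlignment | None
    its_records: list
    upstream_records: list
    metadata: pd.DataFrame
    tree_newick: str | None
    helix_map: HelixMap


def load_dataset_dir(path: str | Path) -> DatasetInputs:
    path = Path(path)
    aln16 = read_alignment(path / "alignment_16s.fasta")
    aln23 = (
        read_alignment(path / "alignment_23s.fasta")
        if (path / "alignment_23s.fasta").exists()
        else None
    )
    seqs = read_fasta(path / "sequences.fasta")
    meta = pd.read_csv(path / "metadata.tsv", sep="\t")
    tree = None
    if (path / "tree.nwk").exists():
        tree = (path / "tree.nwk").read_text().strip()
    hmap = (
        HelixMap.from_tsv(path / "helix_map.tsv")
        if (path / "helix_map.tsv").exists()
        else default_16s_helix_map()
    )
    return DatasetInputs(
        alignment_16s=aln16,
        alignment_23s=aln23,
        its_records=[r for r in seqs if r.region == "ITS"],
        upstream_records=[r for r in seqs if r.region == "upstream"],
        metadata=meta,
        tree_newick=tree,
        helix_map=hmap,
    )


def _safe_range(dm, groups, pair, **kw):
    try:
        rs = range_summary(dm, groups, pair, **kw)
    except ValueError:
        return None
    return {
        "min_identity": round(rs.min_identity, 1),
        "max_identity": round(rs.max_identity, 1),
        "min_divergence": round(rs.min_divergence, 1),
        "max_divergence": round(rs.max_divergence, 1),
        "n_pairs": rs.n_pairs,
    }


def run_pipeline(
    inputs: DatasetInputs,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = inputs.metadata
    labels = dict(zip(meta["seq_id"], meta["operon_type"]))
    strain_of = dict(zip(meta["seq_id"], meta["strain"]))
    morph_of = dict(zip(meta["strain"], meta["morphospecies"]))
    aln16 = inputs.alignment_16s
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "n_sequences_16s": len(aln16),
        "n_strains": meta["strain"].nunique(),
    }

    # --- operon typing ------------------------------------------------------
    try:
        sig = find_signature(aln16, labels, cfg.saturation_threshold)
        sig.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
        typing_rows = []
        correct = 0
        for rec in aln16:
            score = classify_sequence(rec.residues, sig, seq_id=rec.id)
            typing_rows.append(
                {
                    "seq_id": rec.id,
                    "frac_type1": score.frac_type1,
                    "frac_type2": score.frac_type2,
                    "frac_other": score.frac_other,
                    "n_scored": score.n_scored,
                    "call": score.call,
                    "label": labels.get(rec.id, "unknown"),
                }
            )
            if score.call == labels.get(rec.id):
                correct += 1
        pd.DataFrame(typing_rows).to_csv(out / "typing.tsv", sep="\t", index=False)
        reversions = detect_reversions(aln16, labels, sig)
        pd.DataFrame(
            [
                {
                    "position": r.position,
                    "from_type": r.from_type,
                    "observed_base": r.observed_base,
                    "seq_ids": ",".join(r.seq_ids),
                }
                for r in reversions
            ]
        ).to_csv(out / "reversions.tsv", sep="\t", index=False)
        primers = design_type_primers(
            aln16,
            labels,
            length_range=cfg.primer_length_range,
            min_cross_mismatches=cfg.primer_min_cross_mismatches,
        )
        best = [
            b
            for t in ("Type1", "Type2")
            if (b := best_primer(primers, t)) is not None
        ]
        pd.DataFrame(
            [
                {
                    "target_type": w.target_type,
                    "start": w.start,
                    "end": w.end,
                    "primer_5to3": w.primer,
                    "cross_mismatches": w.cross_mismatches,
                    "three_prime_mismatch": w.three_prime_mismatch,
                }
                for w in best
            ]
        ).to_csv(out / "primers.tsv", sep="\t", index=False)
        summary["typing"] = {
            "n_signature_positions": len(sig),
            "typing_accuracy_percent": round(100.0 * correct / len(aln16), 1),
            "n_reversion_positions": len({r.position for r in reversions}),
            "n_primer_candidates": len(primers),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("typing", str(exc)) from exc

    # --- divergence ranges --------------------------------------------------
    try:
        dm16 = identity_matrix(aln16)
        dm16.to_frame().to_csv(out / "distances_16s.tsv", sep="\t", index=False)
        ranges = {
            "16S_type1_vs_type2_within_strain": _safe_range(
                dm16,
                labels,
                ("Type1", "Type2"),
                within_strain_only=True,
                strain_of=strain_of,
            ),
            "16S_type1_vs_type2_all": _safe_range(dm16, labels, ("Type1", "Type2")),
            "16S_within_type1": _safe_range(dm16, labels, ("Type1", "Type1")),
            "16S_within_type2": _safe_range(dm16, labels, ("Type2", "Type2")),
        }
        if inputs.alignment_23s is not None:
            aln23 = inputs.alignment_23s
            labels23 = {r.id: labels.get(r.id.removesuffix("_23S"), "unknown") for r in aln23}
            strain23 = {r.id: strain_of.get(r.id.removesuffix("_23S")) for r in aln23}
            dm23 = identity_matrix(aln23)
            dm23.to_frame().to_csv(out / "distances_23s.tsv", sep="\t", index=False)
            ranges.update(
                {
                    "23S_type1_vs_type2": _safe_range(
                        dm23, labels23, ("Type1", "Type2")
                    ),
                    "23S_within_type1": _safe_range(dm23, labels23, ("Type1", "Type1")),
                    "23S_within_type2": _safe_range(dm23, labels23, ("Type2", "Type2")),
                }
            )
        summary["divergence_ranges"] = ranges
    except Exception as exc:  # noqa: BLE001
        raise StageError("divergence", str(exc)) from exc

    # --- ITS feature table --------------------------------------------------
    try:
        annotations = []
        for rec in inputs.its_records:
            base = rec.id.removesuffix("_ITS")
            lab = labels.get(base, rec.operon_type)
            annotations.append(annotate_its(rec, default_templates(lab)))
        if annotations:
            its_labels = {
                a.seq_id: labels.get(a.seq_id.removesuffix("_ITS"), "unknown")
                for a in annotations
            }
            table = its_feature_table(annotations, its_labels)
            table.to_csv(out / "its_features.tsv", sep="\t", index=False)
            pd.concat([a.to_frame() for a in annotations]).to_csv(
                out / "its_annotations.tsv", sep="\t", index=False
            )
            summary["its"] = {
                "n_annotated": len(annotations),
                "per_type": table.to_dict(orient="records"),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("its", str(exc)) from exc

    # --- promoters ----------------------------------------------------------
    try:
        pann = [scan_promoter(r, cfg.promoter) for r in inputs.upstream_records]
        if pann:
            promoter_table(pann).to_csv(out / "promoters.tsv", sep="\t", index=False)
            summary["promoters"] = {
                "n_scanned": len(pann),
                "n_functional": sum(a.functional for a in pann),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("promoter", str(exc)) from exc

    # --- helix-localized variability ---------------------------------------
    try:
        model_row = next(
            r.id for r in aln16 if labels.get(r.id) == "Type2" and "-" not in r.residues
        )
        colmap = map_columns_to_model(aln16, model_row, inputs.helix_map)
        comparison = helix_variability(
            aln16,
            labels,
            sig,
            inputs.helix_map,
            colmap,
            max_closable=cfg.max_closable,
            wobble=cfg.wobble,
        )
        comparison.to_frame().to_csv(out / "helix_variability.tsv", sep="\t", index=False)
        loaded = {
            h.helix: h.substitutions
            for h in comparison.per_helix.values()
            if h.substitutions > 0
        }
        summary["structure"] = {
            "model_row": model_row,
            "helices_with_substitutions": loaded,
            "unpaired_region_changes": comparison.unpaired_region_changes,
            "structure_altering_helices": sorted(
                h.helix for h in comparison.per_helix.values() if h.structure_altering
            ),
        }
    except StopIteration:
        summary["structure"] = {"skipped": "no gapless Type2 model row"}
    except Exception as exc:  # noqa: BLE001
        raise StageError("structure", str(exc)) from exc

    # --- genospecies --------------------------------------------------------
    try:
        strains = sorted(meta["strain"].unique())
        clades = (
            clades_from_tree(newick=inputs.tree_newick)
            if (cfg.use_tree and inputs.tree_newick)
            else {}
        )
        profiles = []
        for s in strains:
            identities: dict[str, dict[str, float]] = {}
            for t in ("Type1", "Type2"):
                table: dict[str, float] = {}
                for other in strains:
                    if other == s:
                        continue
                    pairs = [
                        dm16.identity(a, b)
                        for a in dm16.ids
                        for b in dm16.ids
                        if strain_of.get(a) == s
                        and strain_of.get(b) == other
                        and labels.get(a) == t
                        and labels.get(b) == t
                    ]
                    if pairs:
                        table[other] = max(pairs)
                if table:
                    identities[t] = table
            profiles.append(
                StrainProfile(
                    strain=s,
                    identities=identities,
                    morphospecies=morph_of.get(s) if cfg.use_morphology else None,
                    tree_clade=clades.get(s),
                )
            )
        partition = delimit(profiles, threshold=cfg.identity_threshold)
        (out / "genospecies.json").write_text(
            json.dumps(partition.to_dict(), indent=1, sort_keys=True)
        )
        summary["genospecies"] = {
            "count": len(partition),
            "clusters": [sorted(c) for c in partition.clusters],
            "criteria_used": sorted({p.criterion for p in partition.provenance})
            or ["identity"],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("genospecies", str(exc)) from exc

    summary["config_hash"] = hashlib.sha256(
        json.dumps(cfg.thresholds(), sort_keys=True).encode()
    ).hexdigest()[:12]
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary
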