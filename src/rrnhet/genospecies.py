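"""Genospecies delimitation from identity, phylogeny and morphology.

Strains are partitioned by three criteria applied in order:

1. Identity — two strains belong to the same candidate genospecies
   only when their 16S rRNA identity exceeds the species threshold
   (98.7% by default) in *every* operon type for which a comparison is
   available; an identity at or below the threshold in either operon
   separates them. Candidate clusters are the connected components of
   the resulting link graph (single linkage, the minimal-assumption
   reading).
2. Phylogeny — clusters whose members occupy different labeled tree
   clades are split.
3. Morphology — clusters containing different named morphospecies are
   split, honouring phenotype-based species even when molecular
   separation is weak.

Criteria only ever split, never merge, so adding information refines
the partition monotonically. Missing clade or morphospecies labels are
non-informative (they never cause a split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import networkx as nx

DEFAULT_THRESHOLD = 98.7


@dataclass
class StrainProfile:
    """Per-strain identity records against the other strains.

    ``identities`` maps operon type -> {other strain -> percent
    identity}; only types present in the mapping are "available" for
    the pair.
    """

    strain: str
    identities: dict[str, dict[str, float]] = field(default_factory=dict)
    morphospecies: str | None = None
    tree_clade: str | None = None

    def identity_with(self, other: str) -> dict[str, float]:
        out = {}
        for operon_type, table in self.identities.items():
            if other in table:
                out[operon_type] = table[other]
        return out


@dataclass(frozen=True)
class SplitRecord:
    criterion: str  # identity | phylogeny | morphology
    detail: str
    parent: frozenset[str]
    children: tuple[frozenset[str], ...]


@dataclass
class GenospeciesPartition:
    clusters: list[frozenset[str]]
    provenance: list[SplitRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if c & seen:
                raise ValueError("clusters must be disjoint")
            seen |= c

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, strain: str) -> frozenset[str]:
        for c in self.clusters:
            if strain in c:
                return c
        raise KeyError(strain)

    def to_dict(self) -> dict:
        return {
            "n_genospecies": len(self.clusters),
            "clusters": [sorted(c) for c in self.clusters],
            "provenance": [
                {
                    "criterion": p.criterion,
                    "detail": p.detail,
                    "parent": sorted(p.parent),
                    "children": [sorted(ch) for ch in p.children],
                }
                for p in self.provenance
            ],
        }


def _pair_identities(
    a: StrainProfile, b: StrainProfile
) -> dict[str, float]:
    out = a.identity_with(b.strain)
    for operon_type, value in b.identity_with(a.strain).items():
        out.setdefault(operon_type, value)
    return out


def _split_by_label(
    clusters: list[frozenset[str]],
    label_of: dict[str, str | None],
    criterion: str,
    provenance: list[SplitRecord],
) -> list[frozenset[str]]:
    out: list[frozenset[str]] = []
    for cluster in clusters:
        groups: dict[str, set[str]] = {}
        unlabeled: set[str] = set()
        for strain in cluster:
            lab = label_of.get(strain)
            if lab is None:
                unlabeled.add(strain)
            else:
                groups.setdefault(lab, set()).add(strain)
        if len(groups) <= 1:
            out.append(cluster)
            continue
        # unlabeled strains stay with the largest labeled group
        # (non-informative labels never cause a split)
        target = max(sorted(groups), key=lambda k: len(groups[k]))
        groups[target] |= unlabeled
        children = tuple(
            frozenset(groups[k]) for k in sorted(groups)
        )
        provenance.append(
            SplitRecord(
                criterion=criterion,
                detail=f"labels {sorted(groups)}",
                parent=cluster,
                children=children,
            )
        )
        out.extend(children)
    return out


def delimit(
    profiles: list[StrainProfile], threshold: float = DEFAULT_THRESHOLD
) -> GenospeciesPartition:
    """Partition strains into genospecies by the three criteria."""
    strains = [p.strain for p in profiles]
    if len(strains) != len(set(strains)):
        raise ValueError("duplicate strain ids")
    by_name = {p.strain: p for p in profiles}

    graph = nx.Graph()
    graph.add_nodes_from(strains)
    provenance: list[SplitRecord] = []
    below: list[str] = []
    for a, b in combinations(strains, 2):
        ids = _pair_identities(by_name[a], by_name[b])
        if not ids:
            raise ValueError(f"missing pairwise identity for strains {a!r}/{b!r}")
        if all(v > threshold for v in ids.values()):
            graph.add_edge(a, b)
        else:
            low = {t: v for t, v in ids.items() if v <= threshold}
            below.append(f"{a}/{b}: " + ", ".join(f"{t}={v:.1f}" for t, v in sorted(low.items())))

    clusters = [frozenset(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: sorted(c)[0])
    if len(clusters) > 1:
        provenance.append(
            SplitRecord(
                criterion="identity",
                detail=(
                    f"identity <= {threshold} in at least one operon type for: "
                    + "; ".join(below)
                ),
                parent=frozenset(strains),
                children=tuple(clusters),
            )
        )
    clusters = _split_by_label(
        clusters,
        {p.strain: p.tree_clade for p in profiles},
        "phylogeny",
        provenance,
    )
    clusters = _split_by_label(
        clusters,
        {p.strain: p.morphospecies for p in profiles},
        "morphology",
        provenance,
    )
    clusters.sort(key=lambda c: sorted(c)[0])
    return GenospeciesPartition(clusters=clusters, provenance=provenance)


def clades_from_tree(
    tree_path: str | Path | None = None, newick: str | None = None
) -> dict[str, str | None]:
    """Leaf -> clade labels from a newick tree with labeled internal nodes.

    A leaf's clade is the label of its nearest labeled ancestor; leaves
    with no labeled ancestor map to None. The package never infers
    trees — the tree and its clade labels are user inputs.
    """
    if (tree_path is None) == (newick is None):
        raise ValueError("provide exactly one of tree_path or newick")
    if tree_path is not None:
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    else:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    out: dict[str, str | None] = {}
    for leaf in tree.leaf_node_iter():
        label = None
        node = leaf.parent_node
        while node is not None:
            if node.label:
                label = node.label
                break
            node = node.parent_node
        out[leaf.taxon.label] = label
    return out
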