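"""Genospecies delimitation by identity, phylogeny and morphology."""

import itertools

import numpy as np
import pytest

from rrnhet import StrainProfile, clades_from_tree, delimit


def profiles_from_identity(
    ident: dict[tuple[str, str], dict[str, float]],
    morph: dict[str, str] | None = None,
    clade: dict[str, str] | None = None,
):
    strains = sorted({s for pair in ident for s in pair})
    profiles = []
    for s in strains:
        identities: dict[str, dict[str, float]] = {}
        for (a, b), by_type in ident.items():
            if s not in (a, b):
                continue
            other = b if s == a else a
            for t, v in by_type.items():
                identities.setdefault(t, {})[other] = v
        profiles.append(
            StrainProfile(
                strain=s,
                identities=identities,
                morphospecies=(morph or {}).get(s),
                tree_clade=(clade or {}).get(s),
            )
        )
    return profiles


def brute_force_delimit(strains, ident, threshold, morph, clade):
    """Independent re-derivation: iterate merging, then label splits."""
    clusters = [{s} for s in strains]
    changed = True
    while changed:
        changed = False
        for ca, cb in itertools.combinations(list(clusters), 2):
            if any(
                all(v > threshold for v in ident[tuple(sorted((a, b)))].values())
                for a in ca
                for b in cb
            ):
                clusters.remove(ca)
                clusters.remove(cb)
                clusters.append(ca | cb)
                changed = True
                break
    for label_of in (clade, morph):
        new = []
        for c in clusters:
            labs = {label_of[s] for s in c if label_of.get(s) is not None}
            if len(labs) <= 1:
                new.append(c)
                continue
            groups: dict[str, set] = {}
            none_group = {s for s in c if label_of.get(s) is None}
            for s in c - none_group:
                groups.setdefault(label_of[s], set()).add(s)
            target = max(sorted(groups), key=lambda k: len(groups[k]))
            groups[target] |= none_group
            new.extend(groups.values())
        clusters = new
    return sorted((frozenset(c) for c in clusters), key=lambda c: sorted(c)[0])


class TestDelimit:
    def test_similar_strains_cluster_together(self):
        profiles = profiles_from_identity(
            {("A", "B"): {"Type1": 99.5, "Type2": 99.2}},
            morph={"A": "hyalinum", "B": "hyalinum"},
            clade={"A": "c1", "B": "c1"},
        )
        part = delimit(profiles)
        assert [sorted(c) for c in part.clusters] == [["A", "B"]]
        assert part.provenance == []

    def test_low_identity_in_one_operon_separates(self):
        # C falls below threshold against A and B in one operon type
        profiles = profiles_from_identity(
            {
                ("A", "B"): {"Type1": 99.5, "Type2": 99.5},
                ("A", "C"): {"Type1": 98.0, "Type2": 99.5},
                ("B", "C"): {"Type1": 98.0, "Type2": 99.5},
            }
        )
        part = delimit(profiles)
        assert [sorted(c) for c in part.clusters] == [["A", "B"], ["C"]]
        assert part.provenance[0].criterion == "identity"

    def test_boundary_identity_separates(self):
        # identity exactly at the threshold counts as separation
        profiles = profiles_from_identity({("A", "B"): {"Type2": 98.7}})
        assert len(delimit(profiles)) == 2

    def test_morphospecies_overrides_weak_molecular_signal(self):
        profiles = profiles_from_identity(
            {("A", "B"): {"Type2": 99.9}},
            morph={"A": "arcangeli", "B": "hyalinum"},
        )
        part = delimit(profiles)
        assert len(part) == 2
        assert part.provenance[0].criterion == "morphology"

    def test_tree_clades_split_components(self):
        profiles = profiles_from_identity(
            {
                ("A", "B"): {"Type2": 99.9},
                ("A", "C"): {"Type2": 99.9},
                ("B", "C"): {"Type2": 99.9},
            },
            clade={"A": "c1", "B": "c1", "C": "c2"},
        )
        part = delimit(profiles)
        assert [sorted(c) for c in part.clusters] == [["A", "B"], ["C"]]
        assert part.provenance[0].criterion == "phylogeny"

    def test_missing_pairwise_identity_errors(self):
        profiles = [
            StrainProfile(strain="A", identities={"Type2": {"B": 99.0}}),
            StrainProfile(strain="B", identities={"Type2": {"A": 99.0}}),
            StrainProfile(strain="C", identities={}),
        ]
        with pytest.raises(ValueError, match="'A'/'C'|'C'/'A'"):
            delimit(profiles)

    def test_threshold_extremes(self):
        ident = {
            ("A", "B"): {"Type2": 99.9},
            ("A", "C"): {"Type2": 99.5},
            ("B", "C"): {"Type2": 99.5},
        }
        profiles = profiles_from_identity(ident)
        assert len(delimit(profiles, threshold=100.0)) == 3
        assert len(delimit(profiles, threshold=0.0)) == 1

    def test_adding_criteria_never_merges(self):
        ident = {
            ("A", "B"): {"Type2": 99.9},
            ("A", "C"): {"Type2": 98.0},
            ("B", "C"): {"Type2": 99.9},
        }
        base = delimit(profiles_from_identity(ident))
        refined = delimit(
            profiles_from_identity(ident, morph={"A": "x", "B": "y", "C": "y"})
        )
        # every refined cluster is contained in some base cluster
        for c in refined.clusters:
            assert any(c <= b for b in base.clusters)
        assert len(refined) >= len(base)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            strains = [f"S{i}" for i in range(n)]
            ident = {}
            for a, b in itertools.combinations(strains, 2):
                ident[(a, b)] = {
                    "Type1": float(rng.choice([97.0, 99.0, 99.9])),
                    "Type2": float(rng.choice([97.0, 99.0, 99.9])),
                }
            morph = {
                s: str(rng.choice(["m1", "m2", "none"])) for s in strains
            }
            morph = {s: (None if v == "none" else v) for s, v in morph.items()}
            part = delimit(profiles_from_identity(ident, morph=morph))
            expected = brute_force_delimit(
                strains,
                {tuple(sorted(k)): v for k, v in ident.items()},
                98.7,
                morph,
                {},
            )
            assert sorted(part.clusters, key=lambda c: sorted(c)[0]) == expected


class TestClades:
    def test_nearest_labeled_ancestor(self):
        newick = "((A:1,B:1)cladeX:1,(C:1,(D:1,E:1):1)cladeY:1)root;"
        clades = clades_from_tree(newick=newick)
        assert clades["A"] == clades["B"] == "cladeX"
        assert clades["C"] == clades["D"] == clades["E"] == "cladeY"

    def test_unlabeled_leaves_map_to_none(self):
        clades = clades_from_tree(newick="((A:1,B:1):1,C:1);")
        assert set(clades.values()) <= {None}
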