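"""Pairwise p-distance, percent identity and group-wise range summaries.

Identity is reported as ``100 * (1 - p)`` where ``p`` is the proportion
of differing sites among compared sites; divergence is ``100 * p``, so
identity + divergence = 100 for every pair by construction. The default
missing-data policy is pairwise deletion: columns where either residue
is a gap, N, or any other IUPAC ambiguity contribute nothing, matching
the common distance-matrix default in phylogenetic software. Note that
under pairwise deletion p-distance need not satisfy the triangle
inequality, since each pair may be compared over a different site set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .seq_io import UNAMBIGUOUS, MultiAlignment

POLICIES = ("pairwise-deletion", "gaps-as-difference")


class NoComparableSitesError(ValueError):
    pass


def p_distance(
    row_a: str, row_b: str, policy: str = "pairwise-deletion"
) -> dict[str, float]:
    """p-distance between two aligned rows.

    Returns ``{"distance": p, "sites": n}``. Under the default policy a
    site is compared only when both residues are unambiguous bases;
    under ``gaps-as-difference`` a gap opposite a base counts as a
    difference (ambiguity codes remain excluded either way).
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    a = row_a.upper()
    b = row_b.upper()
    sites = 0
    mismatches = 0
    for x, y in zip(a, b):
        x_ok = x in UNAMBIGUOUS
        y_ok = y in UNAMBIGUOUS
        if x_ok and y_ok:
            sites += 1
            if x != y:
                mismatches += 1
        elif policy == "gaps-as-difference" and (
            (x_ok and y == "-") or (y_ok and x == "-")
        ):
            sites += 1
            mismatches += 1
    if sites == 0:
        raise NoComparableSitesError("no comparable sites")
    return {"distance": mismatches / sites, "sites": sites}


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair compared-site counts."""

    ids: list[str]
    values: np.ndarray
    sites_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n) and self.sites_used.shape == (n, n)

    def _index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def distance(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index(id_a), self._index(id_b)])

    def identity(self, id_a: str, id_b: str) -> float:
        """Percent identity, 100 * (1 - p)."""
        return 100.0 * (1.0 - self.distance(id_a, id_b))

    def divergence(self, id_a: str, id_b: str) -> float:
        """Percent divergence, 100 * p."""
        return 100.0 * self.distance(id_a, id_b)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: id_a, id_b, sites, p_distance, identity_percent."""
        rows = []
        for i, j in combinations(range(len(self.ids)), 2):
            rows.append(
                {
                    "id_a": self.ids[i],
                    "id_b": self.ids[j],
                    "sites": int(self.sites_used[i, j]),
                    "p_distance": float(self.values[i, j]),
                    "identity_percent": 100.0 * (1.0 - float(self.values[i, j])),
                }
            )
        return pd.DataFrame(rows)


def identity_matrix(
    aln: MultiAlignment, policy: str = "pairwise-deletion"
) -> DistanceMatrix:
    """All-pairs p-distance over an alignment."""
    n = len(aln)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    rows = [r.residues for r in aln]
    if policy == "pairwise-deletion":
        # vectorized fast path, equivalent to p_distance per pair
        mat = aln.to_matrix()
        valid = np.isin(mat, sorted(UNAMBIGUOUS))
        for i, j in combinations(range(n), 2):
            mask = valid[i] & valid[j]
            s = int(mask.sum())
            if s == 0:
                raise NoComparableSitesError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            mism = int(((mat[i] != mat[j]) & mask).sum())
            values[i, j] = values[j, i] = mism / s
            sites[i, j] = sites[j, i] = s
        np.fill_diagonal(sites, 0)
        return DistanceMatrix(ids=list(aln.ids), values=values, sites_used=sites)
    for i, j in combinations(range(n), 2):
        try:
            res = p_distance(rows[i], rows[j], policy=policy)
        except NoComparableSitesError as exc:
            raise NoComparableSitesError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            ) from exc
        values[i, j] = values[j, i] = res["distance"]
        sites[i, j] = sites[j, i] = res["sites"]
    np.fill_diagonal(sites, 0)
    return DistanceMatrix(ids=list(aln.ids), values=values, sites_used=sites)


@dataclass(frozen=True)
class RangeSummary:
    """Min/max percent identity over a set of qualifying pairs."""

    group_a: str
    group_b: str
    min_identity: float
    max_identity: float
    n_pairs: int

    @property
    def min_divergence(self) -> float:
        return 100.0 - self.max_identity

    @property
    def max_divergence(self) -> float:
        return 100.0 - self.min_identity

    def format(self) -> str:
        """Identity range rounded to one decimal, study-report style."""
        return f"{self.min_identity:.1f}-{self.max_identity:.1f}%"


def range_summary(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    pair_spec: tuple[str, str],
    within_strain_only: bool = False,
    strain_of: Mapping[str, str] | Callable[[str], str | None] | None = None,
) -> RangeSummary:
    """Identity range over all pairs whose group labels match ``pair_spec``.

    With ``within_strain_only`` the comparison is restricted to pairs
    sharing strain metadata (supplied via ``strain_of``), reproducing
    within-strain operon-type comparisons.
    """
    missing = [i for i in dm.ids if i not in groups]
    if missing:
        raise ValueError(f"unlabeled ids: {missing}")
    if within_strain_only and strain_of is None:
        raise ValueError("within_strain_only requires strain_of")
    label_a, label_b = pair_spec
    get_strain = (
        strain_of.get if isinstance(strain_of, Mapping) else strain_of
    )
    identities = []
    for x, y in combinations(dm.ids, 2):
        lab = {groups[x], groups[y]}
        if lab != {label_a, label_b}:
            continue
        if label_a == label_b and (groups[x] != label_a or groups[y] != label_a):
            continue
        if within_strain_only:
            sx, sy = get_strain(x), get_strain(y)
            if sx is None or sx != sy:
                continue
        identities.append(dm.identity(x, y))
    if not identities:
        raise ValueError(
            f"no qualifying pairs for groups {label_a!r}/{label_b!r}"
            + (" within strains" if within_strain_only else "")
        )
    return RangeSummary(
        group_a=label_a,
        group_b=label_b,
        min_identity=min(identities),
        max_identity=max(identities),
        n_pairs=len(identities),
    )
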