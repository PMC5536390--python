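"""Tree data model, Newick/table I/O, time-sliced clade extraction and
sampling-fraction machinery.

The central object is :class:`Phylogeny`, a thin wrapper around a rooted,
ultrametric :class:`dendropy.Tree` that caches node ages (Myr before present),
tip labels and genus assignments.  Tip labels follow the ``Genus_species``
convention of published timetrees; the genus is the substring before the
first separator (``_`` by default).

Clades are extracted with a series of half-open time slices measured backward
from the present: a clade is recorded for a slice ``(lo, hi]`` when its crown
age falls inside the slice and its parent's age lies strictly above ``hi``
("most inclusive" rule), which guarantees that clades within one slice are
pairwise disjoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "CladeRecord",
    "TraitTable",
    "GenusRichnessTable",
    "parse_newick",
    "slice_clades",
    "clade_sampling_fraction",
    "crown_capture_probability",
    "read_trait_table",
    "read_richness_table",
]

#: default relative tolerance for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a valid tree."""


class Phylogeny:
    """A rooted, ultrametric, time-calibrated phylogeny.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths in Myr.
    genus_separator:
        Character separating genus from species epithet in tip labels.
    strict:
        If True (default), reject non-ultrametric trees.
    rtol:
        Relative tolerance (fraction of tree depth) for the ultrametricity
        check.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        genus_separator: str = "_",
        strict: bool = True,
        rtol: float = ULTRAMETRIC_RTOL,
    ) -> None:
        self._tree = tree
        self.genus_separator = genus_separator
        self._index_nodes(strict=strict, rtol=rtol)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        text: str,
        genus_separator: str = "_",
        strict: bool = True,
        rtol: float = ULTRAMETRIC_RTOL,
    ) -> "Phylogeny":
        """Parse a Newick string into a :class:`Phylogeny`.

        Every edge except the root edge must carry a branch length and tip
        labels must be unique.
        """
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick string: {exc}") from exc
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                who = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"missing branch length on edge above {who!r}")
            if node.parent_node is not None and node.edge.length < 0:
                who = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"negative branch length above {who!r}")
        return cls(tree, genus_separator=genus_separator, strict=strict, rtol=rtol)

    def _index_nodes(self, strict: bool, rtol: float) -> None:
        root = self._tree.seed_node
        # distance from root, computed along edges
        for node in self._tree.preorder_node_iter():
            if node is root:
                node._root_dist = 0.0
            else:
                node._root_dist = node.parent_node._root_dist + (node.edge.length or 0.0)
        tip_dists = [leaf._root_dist for leaf in self._tree.leaf_node_iter()]
        if not tip_dists:
            raise NewickParseError("tree has no tips")
        self.depth = max(tip_dists)
        if strict and self.depth > 0:
            spread = self.depth - min(tip_dists)
            if spread > rtol * self.depth:
                raise NewickParseError(
                    f"tree is not ultrametric: root-to-tip spread {spread:g} "
                    f"exceeds {rtol:g} of depth {self.depth:g}"
                )
        for node in self._tree.preorder_node_iter():
            node.age = self.depth - node._root_dist
        self._tips = list(self._tree.leaf_node_iter())
        self.tip_labels = [t.taxon.label for t in self._tips]

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def crown_age(self) -> float:
        return self.root.age

    def genus_of(self, label: str) -> str:
        return label.split(self.genus_separator)[0]

    @property
    def tip_genera(self) -> list[str]:
        return [self.genus_of(x) for x in self.tip_labels]

    def genus_counts(self) -> dict[str, int]:
        """Number of sampled tips per genus over the whole tree."""
        out: dict[str, int] = {}
        for g in self.tip_genera:
            out[g] = out.get(g, 0) + 1
        return out

    def internal_nodes(self) -> list[dendropy.Node]:
        return [n for n in self._tree.preorder_node_iter() if not n.is_leaf()]

    def branching_times(self) -> np.ndarray:
        """Ages of internal nodes (crown age included), sorted descending."""
        ages = [n.age for n in self.internal_nodes()]
        return np.sort(np.asarray(ages, dtype=float))[::-1]

    # ------------------------------------------------------------------
    # serialisation / subsetting
    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 12) -> str:
        return _newick_from_node(self._tree.seed_node, precision) + ";"

    def extract_clade(self, node: dendropy.Node) -> "Phylogeny":
        """Return the subtree rooted at ``node`` as a new Phylogeny."""
        text = _newick_from_node(node, 12) + ";"
        return Phylogeny.from_newick(text, genus_separator=self.genus_separator, strict=False)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Prune to the given tip labels (unifurcations suppressed)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        tree = dendropy.Tree(self._tree)  # deep clone with its own namespace
        taxa = [t for t in tree.taxon_namespace if t.label in keep]
        tree.retain_taxa(taxa)
        tree.seed_node.edge.length = None
        return Phylogeny(tree, genus_separator=self.genus_separator, strict=False)

    def vcv(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Brownian-motion phylogenetic covariance matrix.

        Entry (i, j) is the shared root-to-MRCA path length of tips i and j;
        diagonal entries are the root-to-tip distances.
        """
        labels = list(order) if order is not None else self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))

        def recurse(node: dendropy.Node) -> list[int]:
            if node.is_leaf():
                i = idx.get(node.taxon.label)
                if i is None:
                    return []
                C[i, i] = node._root_dist
                return [i]
            groups = [recurse(ch) for ch in node.child_nodes()]
            shared = node._root_dist
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = shared
            return [i for g in groups for i in g]

        recurse(self._tree.seed_node)
        return C


def _newick_from_node(node: dendropy.Node, precision: int) -> str:
    if node.is_leaf():
        body = node.taxon.label
    else:
        body = "(" + ",".join(
            _newick_from_node(ch, precision) for ch in node.child_nodes()
        ) + ")"
    if node.parent_node is not None and node.edge.length is not None:
        body += f":{node.edge.length:.{precision}g}"
    return body


def parse_newick(text: str, **kwargs) -> Phylogeny:
    """Module-level convenience wrapper for :meth:`Phylogeny.from_newick`."""
    return Phylogeny.from_newick(text, **kwargs)


# ----------------------------------------------------------------------
# trait and richness tables
# ----------------------------------------------------------------------
@dataclass
class TraitTable:
    """Species -> positive trait value (e.g. seed mass in grams)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [s for s, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"nonpositive trait values for: {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, species: str) -> float:
        return self.values[species]

    def __contains__(self, species: str) -> bool:
        return species in self.values

    def log_values(self, base: float = 10.0) -> dict[str, float]:
        lb = math.log(base)
        return {s: math.log(v) / lb for s, v in self.values.items()}

    def subset(self, species: Iterable[str]) -> "TraitTable":
        return TraitTable({s: self.values[s] for s in species if s in self.values})


@dataclass
class GenusRichnessTable:
    """Genus -> number of described species."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        bad = [g for g, c in self.counts.items() if int(c) < 1 or int(c) != c]
        if bad:
            raise ValueError(f"richness counts must be positive integers: {sorted(bad)[:5]}")
        self.counts = {g: int(c) for g, c in self.counts.items()}

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, genus: str) -> int:
        return self.counts[genus]

    def __contains__(self, genus: str) -> bool:
        return genus in self.counts


def read_trait_table(path) -> TraitTable:
    """Read a two-column TSV ``species<TAB>value`` with a header row."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns, got {df.shape[1]}")
    species = df.iloc[:, 0].astype(str)
    dupes = species[species.duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated species rows: {sorted(set(dupes))}")
    vals = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(float)
    nonpos = species[~(vals > 0)].tolist()
    if nonpos:
        raise ValueError(f"{path}: nonpositive trait values for: {nonpos}")
    return TraitTable(dict(zip(species, vals)))


def read_richness_table(path) -> GenusRichnessTable:
    """Read a two-column TSV ``genus<TAB>n_described`` with a header row."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns, got {df.shape[1]}")
    genera = df.iloc[:, 0].astype(str)
    dupes = genera[genera.duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated genus rows: {sorted(set(dupes))}")
    counts = pd.to_numeric(df.iloc[:, 1], errors="raise")
    return GenusRichnessTable(dict(zip(genera, counts)))


# ----------------------------------------------------------------------
# clade extraction
# ----------------------------------------------------------------------
@dataclass
class CladeRecord:
    """One clade extracted for a time slice.

    ``f``, ``n`` and ``p_crown`` are filled in by
    :func:`clade_sampling_fraction` / :func:`crown_capture_probability`
    (``annotate_clades`` does both).
    """

    clade_id: str
    tips: tuple[str, ...]
    crown_node: object
    crown_age: float
    slice_index: int
    k: int
    f: float | None = None
    n: int | None = None
    p_crown: float | None = None

    def __post_init__(self) -> None:
        if self.k != len(self.tips):
            raise ValueError("tip count does not match member tip set")


def slice_clades(
    tree: Phylogeny,
    slice_width: float = 2.0,
    max_age: float = 20.0,
    min_tips: int = 4,
) -> list[CladeRecord]:
    """Extract the most inclusive clades whose crown ages fall in each slice.

    Slices are half-open intervals ``(lo, lo + slice_width]`` from the present
    back to ``max_age``.  A node qualifies for a slice when its crown age lies
    in the slice, its parent's age is strictly above the slice's upper bound
    (the root counts as having an infinitely old parent) and it subtends at
    least ``min_tips`` tips.  Within a slice the selected clades are pairwise
    disjoint by construction.
    """
    n_slices = int(round(max_age / slice_width))
    records: list[CladeRecord] = []
    for node in tree.internal_nodes():
        k = sum(1 for _ in node.leaf_iter())
        if k < min_tips:
            continue
        age = node.age
        if not (0.0 < age <= max_age):
            continue
        s = min(int(math.ceil(age / slice_width)) - 1, n_slices - 1)
        lo, hi = s * slice_width, (s + 1) * slice_width
        if not (lo < age <= hi):  # guard against float edge cases
            continue
        parent_age = node.parent_node.age if node.parent_node is not None else math.inf
        if parent_age <= hi:
            continue
        tips = tuple(leaf.taxon.label for leaf in node.leaf_iter())
        records.append(
            CladeRecord(
                clade_id=f"s{s}_{tips[0]}",
                tips=tips,
                crown_node=node,
                crown_age=age,
                slice_index=s,
                k=k,
            )
        )
    records.sort(key=lambda r: (r.slice_index, -r.k, r.clade_id))
    return records


def clade_sampling_fraction(
    clade: CladeRecord,
    tree: Phylogeny,
    richness: GenusRichnessTable,
) -> tuple[float, int]:
    """Weighted sampling fraction and estimated total richness of a clade.

    The genus-level sampling fraction ``f_g`` is the number of congeners
    sampled anywhere in the tree divided by the number of described species
    of the genus; the clade's fraction is the mean of the ``f_g`` weighted by
    how many members of each genus the clade contains.  Total clade richness
    is estimated as ``round(k / f)``.
    """
    sampled = tree.genus_counts()
    genus_in_clade: dict[str, int] = {}
    for label in clade.tips:
        g = tree.genus_of(label)
        genus_in_clade[g] = genus_in_clade.get(g, 0) + 1
    missing = sorted(g for g in genus_in_clade if g not in richness)
    if missing:
        raise KeyError(f"genera missing from richness table: {missing}")
    k = clade.k
    f = 0.0
    for g, kg in genus_in_clade.items():
        fg = sampled[g] / richness[g]
        if fg > 1.0:
            logger.warning(
                "genus %s: sampled %d exceeds described %d; clipping f_g to 1",
                g, sampled[g], richness[g],
            )
            fg = 1.0
        f += (kg / k) * fg
    f = min(f, 1.0)
    n = max(k, int(round(k / f)))
    clade.f = f
    clade.n = n
    return f, n


def crown_capture_probability(n: int, k: int, exact: bool = False):
    """Probability that the MRCA of ``k`` uniformly sampled species is the
    true crown node of an ``n``-species clade.

    Assumes the two basal subclades split the richness as ``(a, n - a)`` with
    ``a`` uniform on ``1..n-1``; the MRCA of the sample is the crown node
    exactly when the sample hits both sides.  Averaging the hit probability
    over ``a`` gives the closed form ``1 - 2(n-k) / ((n-1)(k+1))``.

    With ``exact=True`` the value is returned as a :class:`fractions.Fraction`.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..n, got k={k}, n={n}")
    if exact:
        return 1 - Fraction(2 * (n - k), (n - 1) * (k + 1))
    return 1.0 - 2.0 * (n - k) / ((n - 1) * (k + 1))


def annotate_clades(
    tree: Phylogeny,
    clades: list[CladeRecord],
    richness: GenusRichnessTable,
) -> list[CladeRecord]:
    """Fill in sampling fraction, richness and crown-capture probability."""
    for rec in clades:
        f, n = clade_sampling_fraction(rec, tree, richness)
        rec.p_crown = float(crown_capture_probability(n, rec.k)) if n >= 2 else 1.0
    return clades


def filter_clades(
    clades: list[CladeRecord],
    min_f: float = 0.3,
    min_p_crown: float = 0.7,
) -> list[CladeRecord]:
    """Apply the sampling-fraction and crown-capture inclusion filters."""
    out = []
    for rec in clades:
        if rec.f is None or rec.p_crown is None:
            raise ValueError(f"clade {rec.clade_id} not annotated")
        if rec.f >= min_f and rec.p_crown >= min_p_crown:
            out.append(rec)
    return out
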