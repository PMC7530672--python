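"""Genetic distances between multilocus genotypes and trees/networks.

Bruvo's distance models stepwise microsatellite mutation: two alleles x
and y (in repeat units) are at distance ``1 - 2**(-|x - y|)``, so a
single-step difference scores 0.5 and large differences saturate at 1.
For a diploid locus the distance is the minimum over the two perfect
matchings of the allele pairs of the mean per-pair distance.  Loci with
missing data in either genotype are excluded from the cross-locus
average (the organism is diploid throughout, so the genome
addition/loss models for ploidy changes do not apply).

Allele sharing is the multiset-intersection proportion used for
commercial-starter attribution: per locus the two allele pairs share 0,
1 or 2 alleles; the proportion is total shared over ``2 * L_compared``.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import networkx as nx
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .io import MISSING, LocusPanel, MultilocusGenotype, StratifiedCollection

__all__ = [
    "bruvo_allele",
    "bruvo_locus",
    "bruvo_pair",
    "bruvo_matrix",
    "allele_sharing",
    "nj_tree",
    "nj_bootstrap_support",
    "spanning_network",
    "geographic_distance_matrix",
]


def bruvo_allele(x: int, y: int) -> float:
    """Per-allele Bruvo distance ``1 - 2**(-|x-y|)`` (repeat units)."""
    return 1.0 - 2.0 ** (-abs(int(x) - int(y)))


def bruvo_locus(a, b) -> float:
    """Bruvo distance between two diploid allele pairs in repeat units.

    Minimum over the two perfect matchings of the mean per-allele
    distance.  Either pair containing MISSING is the caller's problem:
    use :func:`bruvo_pair` for genotype-level missing handling.
    """
    a1, a2 = a
    b1, b2 = b
    m1 = (bruvo_allele(a1, b1) + bruvo_allele(a2, b2)) / 2.0
    m2 = (bruvo_allele(a1, b2) + bruvo_allele(a2, b1)) / 2.0
    return min(m1, m2)


def bruvo_pair(ra: np.ndarray, rb: np.ndarray) -> float:
    """Bruvo distance between two genotypes given ``(L, 2)`` repeat-unit
    arrays; loci missing in either genotype are excluded from the mean.

    Raises ``ValueError`` when no locus is comparable.
    """
    ok = (ra[:, 0] != MISSING) & (rb[:, 0] != MISSING)
    if not ok.any():
        raise ValueError("no comparable loci: distance undefined")
    vals = [bruvo_locus(ra[j], rb[j]) for j in np.flatnonzero(ok)]
    return float(np.mean(vals))


def _bruvo_matrix_values(rep: np.ndarray) -> np.ndarray:
    """Vectorised pairwise Bruvo over an ``(n, L, 2)`` repeat array."""
    n, L, _ = rep.shape
    present = rep[:, :, 0] != MISSING  # (n, L)
    # per-allele distances for the two matchings, all pairs at once
    a = rep[:, None, :, :].astype(float)  # (n, 1, L, 2)
    b = rep[None, :, :, :].astype(float)  # (1, n, L, 2)
    d = lambda x, y: 1.0 - 2.0 ** (-np.abs(x - y))
    m1 = (d(a[..., 0], b[..., 0]) + d(a[..., 1], b[..., 1])) / 2.0
    m2 = (d(a[..., 0], b[..., 1]) + d(a[..., 1], b[..., 0])) / 2.0
    per_locus = np.minimum(m1, m2)  # (n, n, L)
    ok = present[:, None, :] & present[None, :, :]
    cnt = ok.sum(axis=2)
    if (cnt == 0).any():
        bad = np.argwhere(cnt == 0)
        bad = bad[bad[:, 0] != bad[:, 1]]
        if len(bad):
            raise ValueError("genotype pair with no comparable loci")
    per_locus = np.where(ok, per_locus, 0.0)
    with np.errstate(invalid="ignore"):
        vals = per_locus.sum(axis=2) / np.maximum(cnt, 1)
    np.fill_diagonal(vals, 0.0)
    return (vals + vals.T) / 2.0  # enforce exact symmetry


def bruvo_matrix(coll: StratifiedCollection) -> DistanceMatrix:
    """Pairwise Bruvo distance matrix over a collection (repeat units)."""
    if len(coll) < 2:
        raise ValueError("need at least 2 genotypes")
    return DistanceMatrix(_bruvo_matrix_values(coll.repeat_array()), ids=coll.ids)


def allele_sharing(a: MultilocusGenotype, b: MultilocusGenotype) -> tuple[float, int]:
    """Proportion of shared alleles between two genotypes.

    Per locus, shared = multiset intersection size of the two allele
    pairs (0, 1 or 2); proportion = total shared / (2 * L_compared).
    Loci missing in either genotype are excluded from numerator and
    denominator.  Returns ``(proportion, n_excluded_loci)``.
    """
    shared = 0
    compared = 0
    excluded = 0
    for j in range(a.n_loci):
        pa, pb = a.alleles[j], b.alleles[j]
        if pa[0] == MISSING or pb[0] == MISSING:
            excluded += 1
            continue
        compared += 1
        ca: dict[int, int] = {}
        for x in pa:
            ca[x] = ca.get(x, 0) + 1
        for x in set(pb):
            shared += min(ca.get(x, 0), list(pb).count(x))
    if compared == 0:
        return float("nan"), excluded
    return shared / (2.0 * compared), excluded


def n_diff_loci(a: MultilocusGenotype, b: MultilocusGenotype) -> int:
    """Number of loci at which the allele multisets differ (loci missing
    in either genotype are not counted as differing)."""
    diffs = 0
    for j in range(a.n_loci):
        pa, pb = a.alleles[j], b.alleles[j]
        if pa[0] == MISSING or pb[0] == MISSING:
            continue
        if sorted(pa) != sorted(pb):
            diffs += 1
    return diffs


# ---------------------------------------------------------------------------
# trees


def nj_tree(dm: DistanceMatrix, midpoint: bool = True) -> TreeNode:
    """Neighbor-joining tree, midpoint-rooted by default.

    Negative branch lengths (an NJ artefact) are clamped to zero.
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 labels for neighbor joining")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = _skbio_nj(dm)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        if midpoint:
            tree = tree.root_at_midpoint()
    return tree


def _bipartitions(tree: TreeNode, labels: frozenset) -> set[frozenset]:
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            parts.add(min(side, labels - side, key=sorted))
    return parts


def nj_bootstrap_support(
    coll: StratifiedCollection, n_boot: int = 100, seed: int = 0, min_support: int = 25
) -> tuple[TreeNode, dict[frozenset, int]]:
    """Locus-resampling bootstrap support for the Bruvo NJ tree.

    Loci are resampled with replacement ``n_boot`` times; each replicate
    tree's bipartitions are counted.  Returns the midpoint-rooted tree
    built from all loci and the bipartition -> support-percentage map
    (entries below ``min_support`` are dropped, mirroring the common
    practice of hiding weakly supported nodes).
    """
    rep = coll.repeat_array()
    labels = frozenset(coll.ids)
    base = nj_tree(DistanceMatrix(_bruvo_matrix_values(rep), ids=coll.ids))
    counts: dict[frozenset, int] = {p: 0 for p in _bipartitions(base, labels)}
    rng = np.random.default_rng(seed)
    L = rep.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        try:
            vals = _bruvo_matrix_values(rep[:, idx, :])
        except ValueError:  # resample left a pair with no comparable loci
            continue
        t = nj_tree(DistanceMatrix(vals, ids=coll.ids))
        for p in _bipartitions(t, labels):
            if p in counts:
                counts[p] += 1
    support = {p: round(100 * c / n_boot) for p, c in counts.items()}
    return base, {p: s for p, s in support.items() if s >= min_support}


# ---------------------------------------------------------------------------
# spanning networks


def spanning_network(dm: DistanceMatrix, multiplicity: dict[str, int] | None = None) -> nx.Graph:
    """Minimum spanning tree over a complete distance matrix.

    Kruskal's algorithm with ties broken by lexicographic label-pair
    order for determinism.  Node attribute ``multiplicity`` carries the
    clone-class size when a partition is supplied.
    """
    ids = list(dm.ids)
    g = nx.Graph()
    for i in ids:
        g.add_node(i, multiplicity=(multiplicity or {}).get(i, 1))
    edges = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = sorted((ids[i], ids[j]))
        edges.append((float(dm[ids[i], ids[j]]), a, b))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    uf = {i: i for i in ids}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            uf[ra] = rb
            g.add_edge(a, b, distance=w)
    return g


def geographic_distance_matrix(coords) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from a coordinates
    DataFrame indexed by id with latitude/longitude in decimal degrees."""
    ids = list(coords.index.astype(str))
    lat = np.radians(coords["latitude"].to_numpy(float))
    lon = np.radians(coords["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * 6371.0088 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=ids)
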