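"""Multilocus-genotype (clone) identification and clone correction.

Fermenting must samples are dominated by a few clonally expanded
genotypes, so raw isolate counts overweight clones.  Clone correction
keeps one representative per identical multilocus genotype (MLG) within
a stratum group (here typically the wine estate); identical MLGs found
in *different* groups are all retained, since recovering the same
genotype at two estates is signal, not pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, MultilocusGenotype, StratifiedCollection
from .distance import n_diff_loci

__all__ = ["MLGPartition", "find_mlgs", "clone_correct", "clonal_variants"]


@dataclass
class MLGPartition:
    """Partition of individuals into multilocus-genotype classes.

    ``classes`` maps a genotype key to the sorted member ids; the class
    representative is the lexicographically smallest id (deterministic).
    """

    classes: dict[tuple, list[str]]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def representatives(self) -> list[str]:
        return sorted(members[0] for members in self.classes.values())

    def class_of(self, individual_id: str) -> tuple:
        for key, members in self.classes.items():
            if individual_id in members:
                return key
        raise KeyError(individual_id)


def _same_mlg(a: MultilocusGenotype, b: MultilocusGenotype, policy: str) -> bool:
    if policy == "strict":
        return a.key() == b.key()
    if policy == "ignore_missing":
        ok = (~a.missing_mask) & (~b.missing_mask)
        if not ok.any():
            return False
        sa = np.sort(a.alleles[ok], axis=1)
        sb = np.sort(b.alleles[ok], axis=1)
        return bool(np.array_equal(sa, sb))
    raise ValueError(f"unknown missing policy: {policy}")


def find_mlgs(coll: StratifiedCollection, missing_policy: str = "strict") -> MLGPartition:
    """Group individuals into MLG classes.

    ``strict``: classes are exact-profile matches (individuals with
    missing loci only join a class when byte-identical) — conservative,
    never collapses distinct strains through missing data.
    ``ignore_missing``: loci missing in either individual are skipped in
    the comparison; uses single-linkage over pairwise matches.
    """
    if len(coll) == 0:
        raise ValueError("empty collection")
    if missing_policy == "strict":
        classes: dict[tuple, list[str]] = {}
        for g in coll:
            classes.setdefault(g.key(), []).append(g.individual_id)
        for members in classes.values():
            members.sort()
        return MLGPartition(dict(sorted(classes.items())))
    # permissive: single-linkage union-find over pairwise matches
    n = len(coll)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _same_mlg(coll[i], coll[j], missing_policy):
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(coll[i].individual_id)
    classes = {}
    for members in groups.values():
        members.sort()
        rep = coll.genotypes[coll.ids.index(members[0])]
        classes[rep.key()] = members
    return MLGPartition(dict(sorted(classes.items())))


def clone_correct(
    coll: StratifiedCollection, within_stratum: str, missing_policy: str = "strict"
) -> StratifiedCollection:
    """Keep one representative per MLG class within each group of a
    stratum (lowest individual_id).  Identical MLGs in different groups
    are all retained.  Idempotent."""
    keep: list[int] = []
    for label, idx in coll.groups(within_stratum).items():
        part = find_mlgs(coll.subset(idx), missing_policy)
        reps = set(part.representatives)
        keep.extend(i for i in idx if coll[i].individual_id in reps)
    keep.sort()
    out = coll.subset(keep)
    out.rejected = [
        (coll[i].individual_id, f"clone within {within_stratum}")
        for i in range(len(coll))
        if i not in set(keep)
    ]
    return out


def clonal_variants(
    focal: MultilocusGenotype, coll: StratifiedCollection, max_diff_loci: int
) -> list[tuple[str, int]]:
    """Individuals differing from ``focal`` at <= max_diff_loci loci.

    A locus differs when the allele multisets differ; sorted by
    (n_diff_loci, individual_id).  The focal profile must be complete.
    """
    if focal.missing_mask.any():
        raise ValueError("focal genotype has missing loci")
    out = []
    for g in coll:
        d = n_diff_loci(focal, g)
        if d <= max_diff_loci:
            out.append((g.individual_id, d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
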