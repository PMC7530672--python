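"""Attribution of isolates to commercial yeast starters.

Isolates sharing at least 75% of their alleles over the typed loci
with a commercial starter (and carrying no missing values) are
classified as starter-related; those at 0 locus differences are
identical, at 1-2 differences clonal variants (single mutations during
clonal expansion).  Removing related isolates before population
structure analyses prevents starter use in cellars from inflating the
apparent similarity between regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .clonal import find_mlgs
from .distance import allele_sharing, bruvo_matrix, n_diff_loci, spanning_network
from .io import MultilocusGenotype, StratifiedCollection

__all__ = ["StarterPanel", "attribute", "remove_related", "starter_network"]

RELATED_CATEGORIES = ("identical", "clonal_variant", "related")


@dataclass
class StarterPanel:
    """Named reference starter genotypes; profiles must be complete.

    Several profiles may share a name (e.g. clonal variants recovered
    from different industrial batches of the same starter); attribution
    to a name takes the best match over its profiles.
    """

    profiles: list[MultilocusGenotype]

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("empty starter panel")
        for p in self.profiles:
            if p.missing_mask.any():
                raise ValueError(f"starter {p.individual_id} has missing loci")

    @property
    def names(self) -> list[str]:
        seen = []
        for p in self.profiles:
            name = p.meta.get("starter_name", p.individual_id)
            if name not in seen:
                seen.append(name)
        return seen

    def profiles_of(self, name: str) -> list[MultilocusGenotype]:
        return [
            p for p in self.profiles if p.meta.get("starter_name", p.individual_id) == name
        ]


def attribute(
    coll: StratifiedCollection, panel: StarterPanel, threshold: float = 0.75
) -> pd.DataFrame:
    """Attribute each isolate to its best-matching starter.

    Returns a DataFrame indexed by individual_id with columns
    best_starter, sharing, n_diff_loci, tied_starters, eligible,
    category.  Isolates with any missing locus are ineligible (the
    attribution rule requires complete profiles) and categorised
    ``unrelated``.  Categories: ``identical`` (0 differing loci),
    ``clonal_variant`` (1-2), ``related`` (sharing >= threshold at >= 3
    differing loci), else ``unrelated``.  Ties go to all tied starter
    names, the alphabetically first reported as best.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rows = []
    for g in coll:
        eligible = not g.missing_mask.any()
        per_name = {}
        for name in panel.names:
            best = None
            for p in panel.profiles_of(name):
                share, _ = allele_sharing(g, p)
                diffs = n_diff_loci(g, p)
                if best is None or share > best[0] or (share == best[0] and diffs < best[1]):
                    best = (share, diffs)
            per_name[name] = best
        top = max(v[0] for v in per_name.values())
        tied = sorted(n for n, v in per_name.items() if v[0] == top)
        best_name = tied[0]
        diffs = per_name[best_name][1]
        if not eligible:
            cat = "unrelated"
        elif top >= threshold:
            cat = "identical" if diffs == 0 else ("clonal_variant" if diffs <= 2 else "related")
        else:
            cat = "unrelated"
        rows.append(
            {
                "individual_id": g.individual_id,
                "best_starter": best_name,
                "sharing": top,
                "n_diff_loci": diffs,
                "tied_starters": ";".join(tied),
                "eligible": eligible,
                "category": cat,
            }
        )
    return pd.DataFrame(rows).set_index("individual_id")


def remove_related(
    coll: StratifiedCollection, report: pd.DataFrame
) -> StratifiedCollection:
    """Drop starter-related isolates (identical / clonal variant /
    related); the removal is recorded on ``result.rejected``."""
    related = set(report.index[report["category"].isin(RELATED_CATEGORIES)])
    keep = [i for i, g in enumerate(coll) if g.individual_id not in related]
    out = coll.subset(keep)
    out.rejected = [(i, "starter-related") for i in sorted(related)]
    return out


def starter_network(
    coll: StratifiedCollection,
    panel: StarterPanel,
    starter_name: str,
    threshold: float = 0.75,
) -> tuple[nx.Graph, float]:
    """Minimum spanning network around one starter and its related
    isolates, plus a star-likeness score.

    Related isolates are those sharing >= threshold alleles with any
    profile of the named starter (complete profiles only).  Nodes are
    MLG-class representatives with class multiplicity; the starter node
    is named after the starter.  Star-likeness = fraction of related
    classes whose network path to the starter has <= 2 edges: a
    recently expanded clone set is star-shaped (single mutations off
    the starter), an old local cluster is not.

    Returns (graph, star_likeness); an empty graph (the starter alone)
    with score NaN when no isolate is related.
    """
    if starter_name not in panel.names:
        raise KeyError(f"unknown starter: {starter_name}")
    profs = panel.profiles_of(starter_name)
    related_idx = []
    for i, g in enumerate(coll):
        if g.missing_mask.any():
            continue
        if max(allele_sharing(g, p)[0] for p in profs) >= threshold:
            related_idx.append(i)
    starter = profs[0].copy()
    starter.individual_id = starter_name
    starter.meta = {"estate": "starter", "appellation": "starter"}
    if not related_idx:
        g = nx.Graph()
        g.add_node(starter_name, multiplicity=1)
        return g, float("nan")
    members = StratifiedCollection(
        [starter] + [coll[i].copy() for i in related_idx], coll.panel
    )
    part = find_mlgs(members, "strict")
    mult = {m[0]: len(m) for m in part.classes.values()}
    reps = sorted(mult)
    rep_coll = members.subset([members.ids.index(r) for r in reps])
    if len(rep_coll) == 1:  # everything identical to the starter
        g = nx.Graph()
        g.add_node(reps[0], multiplicity=mult[reps[0]])
        return g, 1.0
    dm = bruvo_matrix(rep_coll)
    net = spanning_network(dm, mult)
    # locate the class containing the starter
    starter_rep = next(m[0] for m in part.classes.values() if starter_name in m)
    paths = nx.single_source_shortest_path_length(net, starter_rep)
    others = [r for r in net.nodes if r != starter_rep]
    close = sum(1 for r in others if paths.get(r, 99) <= 2)
    return net, close / len(others)
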