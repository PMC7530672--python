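"""Hierarchical AMOVA, pairwise Fst, Mantel tests and per-population
heterozygosity summaries.

The AMOVA follows the Excoffier-style decomposition of genetic variance
over a nested hierarchy.  For codominant diploid data the units are the
2N gene copies, one-hot encoded per locus and scaled so that the
squared Euclidean distance between two copies equals their allele
mismatch count; the deepest grouping level is the individual, which
yields a within-individual variance component and hence a
"Phi for individuals" (an Fis analogue, large under selfing).
Components are estimated per locus with unbalanced nested expected-
mean-square coefficients (k_{l,m} = sum_j n_j^2 / n_ancestor_l(j)) and
summed over loci; loci missing in an individual are excluded at that
locus only.

Pairwise Fst uses the two-population AMOVA on inter-individual allele
distances (PhiPT, the GenAlEx flavour); Weir-Cockerham theta is
available as an alternative estimator.  Significance is assessed by
permutation with the +1 correction, so p is floored at 1/(n_perm+1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .io import MISSING, StratifiedCollection

__all__ = [
    "AMOVAResult",
    "amova",
    "pairwise_fst",
    "phi_pt",
    "weir_cockerham_theta",
    "mantel",
    "pop_summary",
    "balanced_fst",
]

_SQ = math.sqrt(0.5)  # one-hot scale: d^2(copy, copy) = mismatch count


# ---------------------------------------------------------------------------
# nested variance-component engine


def _ssd_features(X: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared deviations from group centroids."""
    sums = np.zeros((n_groups, X.shape[1]))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    return float((X * X).sum() - ((sums * sums).sum(axis=1) / counts).sum())


def _ssd_dist(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Within-group SSD from squared distances: sum_g (1/n_g) sum_{i<j} d2."""
    total = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            total += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _recode(arr: np.ndarray) -> tuple[np.ndarray, int]:
    _, inv = np.unique(arr, return_inverse=True)
    return inv, int(inv.max()) + 1


def _nested_decomposition(levels: list[np.ndarray], ssd_fn) -> tuple[list[float], list[int], list[float]]:
    """Generic unbalanced nested ANOVA.

    ``levels``: group-code arrays over units, top stratum first, deepest
    grouping last.  ``ssd_fn(codes, n_groups)`` returns the within-group
    SSD for a partition.  Returns (SS, df, variance components), each of
    length ``len(levels) + 1`` (among each level, then within deepest).
    """
    n = len(levels[0])
    k = len(levels)
    codes = []
    ngs = []
    for lab in levels:
        c, g = _recode(lab)
        codes.append(c)
        ngs.append(g)
    ssd = [ssd_fn(np.zeros(n, dtype=int), 1)]  # total
    for c, g in zip(codes, ngs):
        ssd.append(ssd_fn(c, g))
    ss = [ssd[l - 1] - ssd[l] for l in range(1, k + 1)] + [ssd[k]]
    gcounts = [1] + ngs
    df = [gcounts[l] - gcounts[l - 1] for l in range(1, k + 1)] + [n - ngs[-1]]

    # k_{l,m} = sum over level-m groups j of n_j^2 / n_{ancestor_l(j)}
    sizes = [np.bincount(c, minlength=g).astype(float) for c, g in zip(codes, ngs)]
    first = [np.zeros(g, dtype=int) for g in ngs]
    for m in range(k):
        # index of first unit in each level-m group
        seen = {}
        for u, c in enumerate(codes[m]):
            if c not in seen:
                seen[c] = u
        for c, u in seen.items():
            first[m][c] = u

    def kcoef(l: int, m: int) -> float:
        nj = sizes[m]
        if l == 0:
            return float((nj * nj).sum() / n)
        anc = codes[l - 1][first[m]]
        return float((nj * nj / sizes[l - 1][anc]).sum())

    comps = [0.0] * (k + 1)
    comps[k] = ss[k] / df[k] if df[k] > 0 else 0.0
    for l in range(k, 0, -1):
        coef = kcoef_pair(kcoef, l, l)
        rhs = ss[l - 1] - df[l - 1] * comps[k]
        for m in range(l + 1, k + 1):
            rhs -= kcoef_pair(kcoef, l, m) * comps[m - 1]
        comps[l - 1] = rhs / coef if (coef > 1e-12 and df[l - 1] > 0) else 0.0
    return ss, df, comps


def kcoef_pair(kcoef, l: int, m: int) -> float:
    """Coefficient of sigma^2_m in E[SS among level l] (1-based levels)."""
    return kcoef(l, m - 1) - kcoef(l - 1, m - 1)


# ---------------------------------------------------------------------------
# per-locus data preparation


def _locus_copies(arr: np.ndarray):
    """Per-locus one-hot copy features.

    ``arr``: (n, L, 2) allele sizes.  Yields (X, ind_idx) per locus:
    X (2*n_present, n_alleles) scaled features, ind_idx the individual
    index of each copy.
    """
    n, L, _ = arr.shape
    out = []
    for j in range(L):
        present = np.flatnonzero(arr[:, j, 0] != MISSING)
        vals = arr[present, j, :].reshape(-1)
        classes, inv = np.unique(vals, return_inverse=True)
        X = np.zeros((len(vals), len(classes)))
        X[np.arange(len(vals)), inv] = _SQ
        out.append((X, np.repeat(present, 2)))
    return out


def _locus_counts(arr: np.ndarray):
    """Per-locus allele-count features over individuals (PhiPT units)."""
    n, L, _ = arr.shape
    out = []
    for j in range(L):
        present = np.flatnonzero(arr[:, j, 0] != MISSING)
        vals = arr[present, j, :]
        classes, inv = np.unique(vals.reshape(-1), return_inverse=True)
        X = np.zeros((len(present), len(classes)))
        np.add.at(X, (np.repeat(np.arange(len(present)), 2), inv), _SQ)
        out.append((X, present))
    return out


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AMOVAResult:
    """Variance decomposition over an ordered stratum hierarchy.

    ``levels`` holds one record per tested level, top first, each with
    name, df, variance component (sigma2), Phi and permutation p-value;
    ``within_individual`` is (df, sigma2) when gene copies were the
    units, else None.  Components may be negative (retained raw; a
    ``negative_components`` flag is set).
    """

    model: list[str]
    levels: list[dict]
    within_individual: tuple[int, float] | None
    n_perm: int
    distance: str
    negative_components: bool = False

    @property
    def total_variance(self) -> float:
        tot = sum(l["sigma2"] for l in self.levels)
        if self.within_individual is not None:
            tot += self.within_individual[1]
        return tot


def _phis(comps: list[float]) -> list[float]:
    """Phi per level: top = sigma_1/total; nested level l =
    sigma_l / sum_{m>=l} sigma_m."""
    total = sum(comps)
    out = []
    for l in range(len(comps) - 1):
        denom = total if l == 0 else sum(comps[l:])
        out.append(comps[l] / denom if denom != 0 else 0.0)
    return out


def _amova_components(locus_data, level_labels: list[np.ndarray]) -> list[float]:
    """Sum per-locus nested components; levels given at individual scope,
    the deepest entry being the individual index itself (copies mode) or
    absent (individual-units mode)."""
    k = len(level_labels)
    tot = np.zeros(k + 1)
    for X, ind_idx in locus_data:
        if len(X) == 0 or X.shape[1] < 2:
            continue
        lv = [lab[ind_idx] for lab in level_labels]
        _, _, comps = _nested_decomposition(lv, lambda c, g: _ssd_features(X, c, g))
        tot += comps
    return list(tot)


def amova(
    coll: StratifiedCollection,
    model: list[str],
    n_perm: int = 999,
    distance: str = "squared_euclidean_allele",
    seed: int = 0,
) -> AMOVAResult:
    """Hierarchical AMOVA with permutation tests.

    ``model`` is the ordered stratum list, top first (e.g.
    ``["appellation", "estate"]``).  With the default allele distance
    the gene copies are the units and a within-individual component is
    estimated; with ``distance="bruvo"`` the individuals are the units
    and the Bruvo matrix supplies the squared distances.

    Permutation schemes: the deepest model stratum permutes individuals
    among its groups within their parent groups; higher strata permute
    subgroups among groups; the individual level permutes gene copies
    among individuals within the deepest stratum groups.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    labels = [coll.labels(s) for s in model]
    n = len(coll)
    enc = [_recode(lab)[0] for lab in labels]
    for l, lab in enumerate(labels):
        if len(set(lab)) < 2 and l == 0:
            raise ValueError(f"stratum '{model[l]}' has a single group: nothing to test")
    # strict nesting check
    for l in range(1, len(model)):
        pairs = {}
        for i in range(n):
            g = enc[l][i]
            if g in pairs and pairs[g] != enc[l - 1][i]:
                raise ValueError(
                    f"stratum '{model[l]}' is not nested within '{model[l-1]}'"
                )
            pairs[g] = enc[l - 1][i]

    rng = np.random.default_rng(seed)
    arr = coll.allele_array()
    copies_mode = distance == "squared_euclidean_allele"
    if copies_mode:
        locus_data = _locus_copies(arr)
        ind_level = np.arange(n)

        def components(levs):
            return _amova_components(locus_data, levs + [ind_level])
    elif distance == "bruvo":
        from .distance import bruvo_matrix

        D2 = bruvo_matrix(coll).data

        def components(levs):
            _, _, comps = _nested_decomposition(
                [lv for lv in levs], lambda c, g: _ssd_dist(D2, c, g)
            )
            return comps
    else:
        raise ValueError(f"unknown distance: {distance}")

    obs = components(enc)
    phis = _phis(obs)

    k = len(model)
    pvals: list[float | None] = [None] * len(phis)
    parent = enc[k - 2] if k >= 2 else np.zeros(n, dtype=int)

    def perm_within(codes: np.ndarray, within: np.ndarray) -> np.ndarray:
        out = codes.copy()
        for g in np.unique(within):
            idx = np.flatnonzero(within == g)
            out[idx] = out[rng.permutation(idx)]
        return out

    if n_perm:
        # deepest model stratum: individuals among groups (within parents)
        cnt = 0
        for _ in range(n_perm):
            p_enc = list(enc)
            p_enc[k - 1] = perm_within(enc[k - 1], parent)
            c = components(p_enc)
            if _phis(c)[k - 1] >= phis[k - 1] - 1e-12:
                cnt += 1
        pvals[k - 1] = (cnt + 1) / (n_perm + 1)
        # higher strata: permute subgroups among parent groups
        for l in range(k - 1):
            sub = enc[l + 1]
            sub_ids = np.unique(sub)
            sub_parent = np.array([enc[l][np.flatnonzero(sub == s)[0]] for s in sub_ids])
            cnt = 0
            for _ in range(n_perm):
                shuffled = sub_parent[rng.permutation(len(sub_parent))]
                p_top = shuffled[np.searchsorted(sub_ids, sub)]
                p_enc = list(enc)
                p_enc[l] = p_top
                c = components(p_enc)
                if _phis(c)[l] >= phis[l] - 1e-12:
                    cnt += 1
            pvals[l] = (cnt + 1) / (n_perm + 1)
        # within-individual level: permute copies among individuals in pops
        if copies_mode:
            pop = enc[k - 1]
            cnt = 0
            for _ in range(n_perm):
                c = np.zeros(len(obs))
                for X, ind_idx in locus_data:
                    if len(X) == 0 or X.shape[1] < 2:
                        continue
                    perm_ind = perm_within(ind_idx, pop[ind_idx])
                    lv = [lab[ind_idx] for lab in enc] + [perm_ind]
                    _, _, comps = _nested_decomposition(
                        lv, lambda cc, g: _ssd_features(X, cc, g)
                    )
                    c += comps
                if _phis(list(c))[k] >= phis[k] - 1e-12:
                    cnt += 1
            pvals[k] = (cnt + 1) / (n_perm + 1)

    # dfs from the full design
    levels_full = enc + ([np.arange(n)] if copies_mode else [])
    gcounts = [1] + [_recode(l)[1] for l in levels_full]
    units = 2 * n if copies_mode else n
    dfs = [gcounts[i + 1] - gcounts[i] for i in range(len(levels_full))]
    df_within = units - gcounts[-1]

    level_names = list(model) + (["individual"] if copies_mode else [])
    recs = []
    for i, name in enumerate(level_names):
        recs.append(
            {
                "name": name,
                "df": dfs[i],
                "sigma2": obs[i],
                "phi": phis[i],
                "p_value": pvals[i] if i < len(pvals) else None,
            }
        )
    if not copies_mode:
        recs.append(
            {"name": "within", "df": df_within, "sigma2": obs[-1], "phi": None, "p_value": None}
        )
    return AMOVAResult(
        model=list(model),
        levels=recs,
        within_individual=(df_within, obs[-1]) if copies_mode else None,
        n_perm=n_perm,
        distance=distance,
        negative_components=any(c < 0 for c in obs),
    )


# ---------------------------------------------------------------------------
# pairwise Fst


def _phipt_from_locus_counts(locus_data, codes: np.ndarray) -> float:
    """One-level PhiPT over individuals from per-locus count features."""
    sa = 0.0
    sw = 0.0
    for X, present in locus_data:
        if len(X) == 0 or X.shape[1] < 2:
            continue
        c = codes[present]
        if len(np.unique(c)) < 2:
            continue
        _, _, comps = _nested_decomposition([c], lambda cc, g: _ssd_features(X, cc, g))
        sa += comps[0]
        sw += comps[1]
    denom = sa + sw
    return sa / denom if denom > 0 else 0.0


def phi_pt(coll: StratifiedCollection, labels: np.ndarray) -> float:
    """PhiPT between the groups defined by ``labels`` (no permutations)."""
    locus_data = _locus_counts(coll.allele_array())
    codes, _ = _recode(labels)
    return _phipt_from_locus_counts(locus_data, codes)


def pairwise_fst(
    coll: StratifiedCollection,
    stratum: str,
    n_perm: int = 999,
    seed: int = 0,
    estimator: str = "phi_pt",
) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise Fst between groups of a stratum, with permutation
    p-values (upper-tail, +1 corrected).

    Groups of size < 2 are excluded with a warning entry on the matrix's
    companion p array (NaN row/col).  Returns (FstMatrix, p_matrix).
    Small negative estimates are retained (they indicate Fst ~ 0).
    """
    groups = {k: v for k, v in coll.groups(stratum).items()}
    small = [k for k, v in groups.items() if len(v) < 2]
    for k in small:
        del groups[k]
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    m = len(names)
    fst = np.zeros((m, m))
    pmat = np.full((m, m), np.nan)
    rng = np.random.default_rng(seed)
    arr = coll.allele_array()
    for i, j in itertools.combinations(range(m), 2):
        idx = groups[names[i]] + groups[names[j]]
        sub = arr[idx]
        codes = np.array([0] * len(groups[names[i]]) + [1] * len(groups[names[j]]))
        if estimator == "phi_pt":
            locus_data = _locus_counts(sub)
            obs = _phipt_from_locus_counts(locus_data, codes)
            stat = lambda c: _phipt_from_locus_counts(locus_data, c)
        elif estimator == "weir_cockerham":
            obs = _wc_theta_arr(sub, codes)
            stat = lambda c: _wc_theta_arr(sub, c)
        else:
            raise ValueError(f"unknown estimator: {estimator}")
        fst[i, j] = fst[j, i] = obs
        if n_perm:
            cnt = 0
            for _ in range(n_perm):
                if stat(rng.permutation(codes)) >= obs - 1e-12:
                    cnt += 1
            pmat[i, j] = pmat[j, i] = (cnt + 1) / (n_perm + 1)
    np.fill_diagonal(pmat, np.nan)
    # DistanceMatrix requires non-negative values; clamp for the container,
    # raw values preserved separately would be overkill here: negatives are
    # sampling noise around zero.
    return DistanceMatrix(np.clip(fst, 0.0, None), ids=names), pmat


def _wc_theta_arr(arr: np.ndarray, codes: np.ndarray) -> float:
    """Weir & Cockerham (1984) theta over loci for an (n, L, 2) array."""
    r = int(codes.max()) + 1
    num = 0.0
    den = 0.0
    for j in range(arr.shape[1]):
        present = arr[:, j, 0] != MISSING
        a_all = arr[present, j, :]
        c = codes[present]
        pops = np.unique(c)
        if len(pops) < 2:
            continue
        alleles = np.unique(a_all)
        ni = np.array([(c == p).sum() for p in pops], dtype=float)  # diploids
        nbar = ni.mean()
        rr = len(pops)
        nc = (ni.sum() - (ni * ni).sum() / ni.sum()) / (rr - 1)
        for al in alleles:
            p_i = np.array(
                [(a_all[c == p] == al).sum() / (2 * (c == p).sum()) for p in pops]
            )
            h_i = np.array(
                [
                    ((a_all[c == p] == al).sum(axis=1) == 1).mean()
                    for p in pops
                ]
            )
            pbar = (ni * p_i).sum() / ni.sum()
            s2 = (ni * (p_i - pbar) ** 2).sum() / ((rr - 1) * nbar)
            hbar = (ni * h_i).sum() / ni.sum()
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (rr - 1) / rr * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            cterm = hbar / 2
            num += a
            den += a + b + cterm
    return num / den if den != 0 else 0.0


def weir_cockerham_theta(coll: StratifiedCollection, stratum: str) -> float:
    """Multi-locus Weir-Cockerham theta across the stratum's groups."""
    codes, _ = _recode(coll.labels(stratum))
    return _wc_theta_arr(coll.allele_array(), codes)


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices on the same
    labels.

    Pearson r over the off-diagonal upper triangle; p by joint
    row/column permutation of the second matrix (one-sided "greater" by
    default, or "two-sided").  ``exhaustive=True`` enumerates all n!
    permutations (small n only) for an exact p.
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices have different labels")
    n = dm1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels")
    d2 = dm2.filter(dm1.ids).data
    d1 = dm1.data
    iu = np.triu_indices(n, 1)
    x = d1[iu]

    def corr(mat):
        y = mat[iu]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2)

    def extreme(r):
        if alternative == "greater":
            return r >= r_obs - 1e-12
        return abs(r) >= abs(r_obs) - 1e-12

    if exhaustive:
        perms = itertools.permutations(range(n))
        cnt = 0
        tot = 0
        for p in perms:
            p = np.array(p)
            if extreme(corr(d2[np.ix_(p, p)])):
                cnt += 1
            tot += 1
        return r_obs, cnt / tot  # identity included: exact test
    rng = np.random.default_rng(seed)
    cnt = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if extreme(corr(d2[np.ix_(p, p)])):
            cnt += 1
    return r_obs, (cnt + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# per-population summaries


def pop_summary(coll: StratifiedCollection, stratum: str, rarefy_to: int | None = None) -> dict:
    """Per-group n, Ho, unbiased He, Fis and rarefied allelic richness.

    Ho is the mean fraction of heterozygous loci; He the Nei unbiased
    expected heterozygosity ``2n/(2n-1) (1 - sum p^2)`` averaged over
    loci; allelic richness is the hypergeometric expectation of the
    allele count in ``rarefy_to`` genes (default: 2 * smallest group
    size).  Loci with fewer typed genes than ``rarefy_to`` in a group
    are skipped for that group's richness.
    """
    from scipy.special import gammaln

    groups = coll.groups(stratum)
    if rarefy_to is None:
        rarefy_to = 2 * min(len(v) for v in groups.values())
    if rarefy_to > 2 * min(len(v) for v in groups.values()):
        raise ValueError("rarefy_to exceeds the smallest group's gene count")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = {}
    arr = coll.allele_array()
    for name, idx in groups.items():
        sub = arr[idx]
        ho_loci = []
        he_loci = []
        rich_loci = []
        for j in range(sub.shape[1]):
            present = sub[:, j, 0] != MISSING
            if present.sum() == 0:
                continue
            a = sub[present, j, :]
            ho_loci.append(float((a[:, 0] != a[:, 1]).mean()))
            genes = a.reshape(-1)
            ng = len(genes)
            alleles, counts = np.unique(genes, return_counts=True)
            p = counts / ng
            if ng > 1:
                he_loci.append(float(ng / (ng - 1) * (1 - (p * p).sum())))
            if ng >= rarefy_to:
                # E[alleles in rarefy_to genes] via hypergeometric
                probs = 1 - np.exp(log_comb(ng - counts, rarefy_to) - log_comb(ng, rarefy_to))
                probs[ng - counts < rarefy_to] = 1.0
                rich_loci.append(float(probs.sum()))
        ho = float(np.mean(ho_loci)) if ho_loci else float("nan")
        he = float(np.mean(he_loci)) if he_loci else float("nan")
        fis = 1 - ho / he if he and he > 0 else float("nan")
        out[name] = {
            "n": len(idx),
            "Ho": ho,
            "He": he,
            "Fis": fis,
            "allelic_richness": float(np.mean(rich_loci)) if rich_loci else float("nan"),
            "rarefied_to_genes": rarefy_to,
        }
    return out


# ---------------------------------------------------------------------------
# balanced compartment comparison


def balanced_fst(
    coll: StratifiedCollection,
    side_stratum: str = "compartment",
    side_a: str = "grape",
    side_b: str = "cellar",
    group_stratum: str = "estate",
    cap: int = 20,
    n_reps: int = 100,
    seed: int = 0,
    estimator: str = "phi_pt",
) -> tuple[float, float, np.ndarray]:
    """Balanced-subsample Fst between two compartments.

    Per replicate, at most ``cap`` individuals are drawn without
    replacement from each ``group_stratum`` group on each side (groups
    smaller than the cap are taken whole); the two sides are pooled into
    two metapopulations and Fst computed.  Capping removes the
    clonal-amplification bias of unbalanced vat samples.  Returns
    (mean, sd, replicate values); fully seeded, so the replicate vector
    is reproducible.
    """
    if cap < 2:
        raise ValueError("cap must be >= 2")
    side_labels = coll.labels(side_stratum)
    group_labels = coll.labels(group_stratum)
    idx_a = np.flatnonzero(side_labels == side_a)
    idx_b = np.flatnonzero(side_labels == side_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("one side of the comparison is empty")
    rng = np.random.default_rng(seed)
    arr = coll.allele_array()
    vals = np.empty(n_reps)
    for r in range(n_reps):
        chosen = []
        codes = []
        for side_code, idx_side in ((0, idx_a), (1, idx_b)):
            for g in np.unique(group_labels[idx_side]):
                members = idx_side[group_labels[idx_side] == g]
                take = members if len(members) <= cap else rng.choice(members, cap, replace=False)
                chosen.extend(int(i) for i in take)
                codes.extend([side_code] * len(take))
        sub = arr[np.array(chosen)]
        codes = np.array(codes)
        if estimator == "phi_pt":
            vals[r] = _phipt_from_locus_counts(_locus_counts(sub), codes)
        else:
            vals[r] = _wc_theta_arr(sub, codes)
    sd = float(vals.std(ddof=1)) if n_reps > 1 else 0.0
    return float(vals.mean()), sd, vals
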