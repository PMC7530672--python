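"""Relative directional migration between populations (pooled-pool
method with Jost's D).

For an ordered population pair (i -> j) a hypothetical pool population
is formed from the union of the two samples; the allelic
differentiation D between the pool and the *receiving* population j is
then converted to a gene-flow proxy (1 - D) / D.  A population
receiving many migrants from its partner resembles the mixture and so
sits close to the pool (small D, large proxy).  The full matrix is
normalised by its maximum, giving relative directional migration in
(0, 1]; bootstrap resampling over individuals yields percentile
intervals for the directional difference m_ij - m_ji, flagging
significant asymmetry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import MISSING, StratifiedCollection

__all__ = ["MigrationMatrix", "jost_d", "directional_migration"]

_EPS = 1e-6


@dataclass
class MigrationMatrix:
    """Directional relative migration values; diagonal is NaN.

    ``asymmetry`` maps unordered pairs to (low, high) percentile CIs of
    m_ij - m_ji (bootstrap over individuals); a pair is significantly
    asymmetric when the interval excludes zero.
    """

    labels: list[str]
    values: np.ndarray
    asymmetry: dict[tuple[str, str], tuple[float, float]] | None = None

    def significant_asymmetries(self) -> list[tuple[str, str]]:
        if not self.asymmetry:
            return []
        return [pair for pair, (lo, hi) in self.asymmetry.items() if lo > 0 or hi < 0]


def _freqs(arr: np.ndarray, locus: int) -> tuple[dict[int, float], int]:
    """Allele frequencies and diploid sample size at one locus."""
    present = arr[:, locus, 0] != MISSING
    genes = arr[present, locus, :].reshape(-1)
    if len(genes) == 0:
        return {}, 0
    alleles, counts = np.unique(genes, return_counts=True)
    return dict(zip(alleles.tolist(), (counts / len(genes)).tolist())), int(present.sum())


def jost_d(arr_a: np.ndarray, arr_b: np.ndarray) -> float:
    """Jost's D between two populations given (n, L, 2) allele arrays.

    Per locus the Nei-Chesser-corrected estimator with harmonic-mean
    sample size ñ (s = 2 populations):

        Hs = 2ñ/(2ñ-1) * (1 - mean_pop sum p^2)
        Ht = 1 - sum p̄^2 + Hs/(4ñ)
        D  = 2 * (Ht - Hs) / (1 - Hs)

    averaged over polymorphic loci and clipped to [0, 1]; loci
    monomorphic across both populations contribute D = 0.
    """
    if arr_a.shape[0] < 2 or arr_b.shape[0] < 2:
        raise ValueError("both populations need n >= 2")
    L = arr_a.shape[1]
    vals = []
    for j in range(L):
        fa, na = _freqs(arr_a, j)
        fb, nb = _freqs(arr_b, j)
        if na == 0 or nb == 0:
            continue
        alleles = set(fa) | set(fb)
        if len(alleles) < 2:
            vals.append(0.0)
            continue
        pa = np.array([fa.get(a, 0.0) for a in sorted(alleles)])
        pb = np.array([fb.get(a, 0.0) for a in sorted(alleles)])
        ntilde = 2.0 / (1.0 / na + 1.0 / nb)
        hs = (2 * ntilde / (2 * ntilde - 1)) * (1 - ((pa * pa).sum() + (pb * pb).sum()) / 2)
        pbar = (pa + pb) / 2
        ht = 1 - (pbar * pbar).sum() + hs / (4 * ntilde)
        if 1 - hs <= 0:
            vals.append(0.0)
            continue
        vals.append(float(np.clip(2 * (ht - hs) / (1 - hs), 0.0, 1.0)))
    if not vals:
        return 0.0
    return float(np.mean(vals))


def directional_d(pool: np.ndarray, focal: np.ndarray) -> float:
    """Directional Jost's D of a focal population from a migrant pool.

    Unlike the symmetric two-population D, the within-population
    heterozygosity term is the *focal* population's (bias-corrected), so
    a population whose gene pool is dominated by immigrants -- and thus
    nearly reproduces the pool -- scores near 0 while a closed
    population scores high.  Averaged over polymorphic loci.
    """
    L = focal.shape[1]
    vals = []
    for j in range(L):
        ff, nf = _freqs(focal, j)
        fp, npl = _freqs(pool, j)
        if nf == 0 or npl == 0:
            continue
        alleles = sorted(set(ff) | set(fp))
        if len(alleles) < 2:
            vals.append(0.0)
            continue
        pf = np.array([ff.get(a, 0.0) for a in alleles])
        pp = np.array([fp.get(a, 0.0) for a in alleles])
        hs = (2 * nf / (2 * nf - 1)) * (1 - (pf * pf).sum())
        pbar = (pf + pp) / 2
        ntilde = 2.0 / (1.0 / nf + 1.0 / npl)
        ht = 1 - (pbar * pbar).sum() + hs / (4 * ntilde)
        if 1 - hs <= 0:
            vals.append(0.0)
            continue
        vals.append(float(np.clip(2 * (ht - hs) / (1 - hs), 0.0, 1.0)))
    return float(np.mean(vals)) if vals else 0.0


def _relative_matrix(pop_arrays: list[np.ndarray]) -> np.ndarray:
    """Un-normalised directional gene-flow proxies between populations:
    m_{i->j} from the receiving side's directional D to the pair pool."""
    m = len(pop_arrays)
    raw = np.full((m, m), np.nan)
    for i, j in itertools.permutations(range(m), 2):
        pool = np.concatenate([pop_arrays[i], pop_arrays[j]])
        d = max(directional_d(pool, pop_arrays[j]), _EPS)
        raw[i, j] = (1.0 - d) / d
    return raw


def directional_migration(
    coll: StratifiedCollection,
    stratum: str,
    n_boot: int = 0,
    seed: int = 0,
    ci: float = 0.95,
) -> MigrationMatrix:
    """Relative directional migration between a stratum's groups.

    Groups with fewer than 2 individuals are excluded.  Values are
    normalised by the matrix maximum (max entry exactly 1).  With
    ``n_boot > 0``, individuals are resampled with replacement within
    each group and percentile intervals of the normalised directional
    differences are reported.
    """
    groups = {k: v for k, v in coll.groups(stratum).items() if len(v) >= 2}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    arr = coll.allele_array()
    pops = [arr[groups[k]] for k in names]
    raw = _relative_matrix(pops)
    values = raw / np.nanmax(raw)

    asym = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        diffs = {pair: [] for pair in itertools.combinations(range(len(names)), 2)}
        for _ in range(n_boot):
            res = [p[rng.integers(0, len(p), size=len(p))] for p in pops]
            r = _relative_matrix(res)
            r = r / np.nanmax(r)
            for (i, j), acc in diffs.items():
                acc.append(r[i, j] - r[j, i])
        alpha = (1 - ci) / 2
        asym = {}
        for (i, j), acc in diffs.items():
            lo, hi = np.quantile(acc, [alpha, 1 - alpha])
            asym[(names[i], names[j])] = (float(lo), float(hi))
    return MigrationMatrix(labels=names, values=values, asymmetry=asym)
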