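"""Genotype diversity indices and richness rarefaction/extrapolation.

All indices operate on genotype-class abundances (Ni individuals in
class i, N = sum Ni individuals, S classes):

* Shannon H' = -sum Pi ln Pi, Pi = Ni / N (natural log)
* Pielou evenness J' = H' / ln S  (defined as 1 when S = 1)
* Simpson D = sum Ni (Ni - 1) / (N (N - 1)), with complement 1 - D and
  inverse 1 / D

Richness at a standardised depth below N uses subsampling without
replacement (the hypergeometric closed form gives the expectation);
depths above N are extrapolated with the Chao1-based abundance
estimator from the singleton/doubleton counts f1, f2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .clonal import find_mlgs
from .io import StratifiedCollection

__all__ = [
    "GenotypeAbundance",
    "abundance_from_collection",
    "shannon",
    "simpson",
    "pielou",
    "diversity_report",
    "chao1",
    "rarefy_richness",
    "expected_richness",
]


@dataclass(frozen=True)
class GenotypeAbundance:
    """Abundance vector of genotype classes (order carries no meaning)."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) == 0 or any(c < 1 for c in self.counts):
            raise ValueError("counts must be positive and non-empty")

    @property
    def N(self) -> int:
        return sum(self.counts)

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


def abundance_from_collection(
    coll: StratifiedCollection, missing_policy: str = "strict"
) -> GenotypeAbundance:
    """Genotype-class abundances of a collection via MLG identification."""
    part = find_mlgs(coll, missing_policy)
    return GenotypeAbundance(tuple(len(m) for m in part.classes.values()))


def shannon(ab: GenotypeAbundance) -> float:
    """Shannon diversity H' in nats."""
    p = np.array(ab.counts, dtype=float) / ab.N
    return float(-(p * np.log(p)).sum())


def simpson(ab: GenotypeAbundance) -> tuple[float, float, float]:
    """Simpson's D (unbiased, sampling without replacement) and its
    complement 1 - D and inverse 1 / D (inf when D = 0)."""
    if ab.N < 2:
        raise ValueError("Simpson's D undefined for N < 2")
    n = np.array(ab.counts, dtype=float)
    d = float((n * (n - 1)).sum() / (ab.N * (ab.N - 1)))
    inv = math.inf if d == 0 else 1.0 / d
    return d, 1.0 - d, inv


def pielou(ab: GenotypeAbundance) -> float:
    """Pielou evenness J' = H'/ln S; 1 by convention when S = 1."""
    if ab.S == 1:
        return 1.0
    return shannon(ab) / math.log(ab.S)


def diversity_report(ab: GenotypeAbundance) -> dict:
    """All indices for one abundance vector, as a plain dict."""
    out = {"N": ab.N, "S": ab.S, "H_prime": shannon(ab), "J_prime": pielou(ab)}
    if ab.N >= 2:
        d, comp, inv = simpson(ab)
        out.update({"D": d, "one_minus_D": comp, "inv_D": inv})
    return out


def chao1(ab: GenotypeAbundance) -> float:
    """Chao1 asymptotic richness estimate (bias-corrected when f2 = 0)."""
    n, f1, f2 = ab.N, ab.f1, ab.f2
    if f2 > 0:
        return ab.S + (n - 1) / n * f1 * f1 / (2 * f2)
    return ab.S + (n - 1) / n * f1 * (f1 - 1) / 2.0


def expected_richness(ab: GenotypeAbundance, depth: int) -> float:
    """Closed-form expected richness.

    ``depth <= N``: hypergeometric expectation
    ``E[S_d] = sum_i (1 - C(N - Ni, d) / C(N, d))``.
    ``depth > N``: Chao1-based extrapolation
    ``S + f0 * (1 - (1 - f1 / (N f0 + f1)) ** (depth - N))`` with
    ``f0 = chao1 - S``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    N = ab.N
    if depth <= N:
        # 1 - C(N-Ni, d)/C(N, d) = P(class i appears in the subsample)
        total = 0.0
        for ni in ab.counts:
            total += 1.0 - hypergeom.pmf(0, N, ni, depth)
        return float(total)
    f0 = chao1(ab) - ab.S
    if f0 <= 0 or ab.f1 == 0:
        return float(ab.S)
    m = depth - N
    return float(ab.S + f0 * (1.0 - (1.0 - ab.f1 / (N * f0 + ab.f1)) ** m))


def rarefy_richness(
    ab: GenotypeAbundance, depth: int, reps: int = 1000, seed: int = 0
) -> tuple[float, float, list[tuple[int, float]]]:
    """Rarefied (or extrapolated) genotype richness.

    For ``depth <= N``, Monte-Carlo subsampling without replacement
    (``reps`` replicates, seeded): returns ``(mean_S, sd_S, curve)``
    where ``curve`` is the expected accumulation curve at a geometric
    grid of depths up to ``depth`` (closed form, no sampling noise).
    For ``depth > N``, the Chao1-based extrapolation (sd 0.0 — the
    estimator is deterministic; uncertainty would need a bootstrap).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    N = ab.N
    grid = sorted({1, min(depth, N)} | {int(x) for x in np.geomspace(1, depth, 12)})
    curve = [(d, expected_richness(ab, d)) for d in grid if d <= depth]
    if depth > N:
        est = expected_richness(ab, depth)
        return est, 0.0, curve
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(ab.S), ab.counts)
    vals = np.empty(reps)
    for r in range(reps):
        sub = rng.choice(pool, size=depth, replace=False)
        vals[r] = len(np.unique(sub))
    return float(vals.mean()), float(vals.std(ddof=1)) if reps > 1 else 0.0, curve
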