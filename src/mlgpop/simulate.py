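"""Forward-time island-model simulator for microsatellite genotypes.

The generator produces genotype tables with the statistical structure
the downstream analyses assume: a Wright-Fisher diploid metapopulation
with configurable (possibly asymmetric) backward migration, strict
single-step stepwise mutation (matching the Bruvo distance model),
partial selfing (producing the heterozygote deficit characteristic of
*S. cerevisiae*'s largely clonal/selfing life cycle), within-sample
clonal expansion (few genotypes dominating each fermentation sample,
drawn via a Dirichlet-multinomial), optional spiking of commercial-
starter-derived clonal variants, and random missing data.

At migration-drift equilibrium the island model predicts pairwise
Fst ~ 1 / (1 + 4 N m (d/(d-1))^2) for d demes, which the structure
module's estimators are validated against.

One root seed fully determines the output; per-stage child generators
are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, LocusPanel, MultilocusGenotype, StratifiedCollection

__all__ = ["SimulationConfig", "simulate_metapopulation", "spike_starters", "default_panel"]


def default_panel(n_loci: int = 17, motif_lens=None) -> LocusPanel:
    """A synthetic locus panel: n_loci loci with di-/tri-nucleotide
    motifs (cycled), named SSR01..SSRnn."""
    if motif_lens is None:
        motif_lens = [(2, 3)[i % 2] for i in range(n_loci)]
    return LocusPanel(tuple((f"SSR{i + 1:02d}", int(motif_lens[i])) for i in range(n_loci)))


@dataclass
class SimulationConfig:
    """Study-shaped metapopulation simulation parameters.

    Defaults emulate the sampling design of a vineyard survey: 12
    estates (demes) of census size 100 in 4 appellations, 17 loci,
    high selfing (0.95, yeast-like heterozygote deficit), strong
    within-sample clonal skew, and 30 isolates sampled per estate.
    """

    n_pops: int = 12
    pop_sizes: int | list[int] = 100
    n_loci: int = 17
    motif_lens: list[int] | None = None
    mutation_rate: float = 1e-4
    migration_matrix: np.ndarray | None = None  # default: no migration
    generations: int = 200
    selfing_rate: float = 0.95
    clonal_skew: float = 1.0  # Dirichlet concentration; smaller = more skew
    starter_profiles: list[MultilocusGenotype] = field(default_factory=list)
    starter_fraction: float = 0.0
    starter_max_edits: int = 2
    missing_rate: float = 0.0
    sample_size: int = 30
    demes_per_appellation: int = 3
    compartment_of_pop: list[str] | None = None  # per-deme label, default grape
    init_repeat_low: int = 10
    init_repeat_high: int = 40
    init_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.starter_fraction > 0 and not self.starter_profiles:
            raise ValueError("starter_fraction > 0 requires starter_profiles")
        for name, v in (
            ("mutation_rate", self.mutation_rate),
            ("selfing_rate", self.selfing_rate),
            ("starter_fraction", self.starter_fraction),
            ("missing_rate", self.missing_rate),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.migration_matrix is not None:
            m = np.asarray(self.migration_matrix, float)
            if m.shape != (self.n_pops, self.n_pops):
                raise ValueError("migration_matrix must be n_pops x n_pops")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("migration_matrix rows must sum to 1")
            if (m < 0).any():
                raise ValueError("migration rates must be non-negative")

    def resolved_migration(self) -> np.ndarray:
        if self.migration_matrix is None:
            return np.eye(self.n_pops)
        return np.asarray(self.migration_matrix, float)

    def resolved_sizes(self) -> np.ndarray:
        if np.isscalar(self.pop_sizes):
            return np.full(self.n_pops, int(self.pop_sizes))
        return np.asarray(self.pop_sizes, int)


def island_migration_matrix(n_pops: int, m: float) -> np.ndarray:
    """Symmetric island-model backward migration: stay with prob 1-m,
    immigrate uniformly from the other demes with total prob m."""
    M = np.full((n_pops, n_pops), m / (n_pops - 1))
    np.fill_diagonal(M, 1.0 - m)
    return M


def _evolve(cfg: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Forward Wright-Fisher with backward migration; returns per-deme
    (N_i, L, 2) repeat-count arrays."""
    sizes = cfg.resolved_sizes()
    M = cfg.resolved_migration()
    Mcum = M.cumsum(axis=1)
    d = cfg.n_pops
    L = cfg.n_loci
    # common ancestral pool: per-locus base repeat plus gaussian spread
    base = rng.integers(cfg.init_repeat_low, cfg.init_repeat_high + 1, size=L)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    tot = int(sizes.sum())
    spread = np.rint(rng.normal(0.0, cfg.init_sd, size=(tot, L, 2))).astype(int)
    A = np.maximum(base[None, :, None] + spread, 2)
    lrange = np.arange(L)[None, :]
    for _ in range(cfg.generations):
        new = np.empty_like(A)
        for i in range(d):
            N = int(sizes[i])
            # migration then reproduction: each offspring's parent deme(s)
            src1 = np.searchsorted(Mcum[i], rng.random(N))
            selfing = rng.random(N) < cfg.selfing_rate
            src2 = np.where(selfing, src1, np.searchsorted(Mcum[i], rng.random(N)))
            p1 = offsets[src1] + rng.integers(0, sizes[src1])
            p2 = np.where(selfing, p1, offsets[src2] + rng.integers(0, sizes[src2]))
            g1 = rng.integers(0, 2, size=(N, L))
            g2 = rng.integers(0, 2, size=(N, L))
            sl = slice(offsets[i], offsets[i + 1])
            new[sl, :, 0] = A[p1[:, None], lrange, g1]
            new[sl, :, 1] = A[p2[:, None], lrange, g2]
        # strict +/-1 stepwise mutation
        mut = rng.random(new.shape) < cfg.mutation_rate
        step = rng.integers(0, 2, size=new.shape) * 2 - 1
        A = np.maximum(new + mut * step, 2)
    return [A[offsets[i]:offsets[i + 1]] for i in range(d)]


def _sample_with_clonal_expansion(
    deme: np.ndarray, sample_size: int, skew: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample individuals with clonal expansion: distinct source
    individuals get Dirichlet(skew) weights, then the sample is drawn
    multinomially so a few genotypes dominate when skew is small."""
    N = deme.shape[0]
    k = min(sample_size, N)
    pool = rng.choice(N, size=k, replace=False)
    w = rng.dirichlet(np.full(k, skew))
    counts = rng.multinomial(sample_size, w)
    rows = np.repeat(pool, counts)
    return deme[rows]


def simulate_metapopulation(cfg: SimulationConfig) -> StratifiedCollection:
    """Run the simulation and return a genotype collection.

    Individuals carry estate/appellation/farming/compartment/vintage
    metadata; estates map 1:1 to demes, appellations to blocks of
    ``demes_per_appellation`` demes, farming alternates by estate.
    ``collection.truth`` records the seed, the migration matrix, the
    per-estate count of distinct sampled genotypes (before missing-data
    injection) and, after spiking, the starter provenance.
    """
    cfg.validate()
    panel = default_panel(cfg.n_loci, cfg.motif_lens)
    root = np.random.SeedSequence(cfg.seed)
    rng_evo, rng_sample, rng_missing, rng_spike = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    demes = _evolve(cfg, rng_evo)

    motif = panel.motif_lens
    genotypes: list[MultilocusGenotype] = []
    truth_classes: dict[str, int] = {}
    for i, deme in enumerate(demes):
        sample = _sample_with_clonal_expansion(deme, cfg.sample_size, cfg.clonal_skew, rng_sample)
        estate = f"estate_{i + 1:02d}"
        app = f"appellation_{i // cfg.demes_per_appellation + 1}"
        farming = "organic" if i % 2 == 0 else "conventional"
        comp = cfg.compartment_of_pop[i] if cfg.compartment_of_pop else "grape"
        truth_classes[estate] = len({tuple(map(tuple, np.sort(g, axis=1))) for g in sample})
        for k, rep in enumerate(sample):
            sizes_bp = rep * motif[:, None]
            g = MultilocusGenotype(
                f"{estate}_ind{k + 1:03d}",
                sizes_bp,
                {
                    "estate": estate,
                    "appellation": app,
                    "farming": farming,
                    "compartment": comp,
                    "vintage": "2012",
                },
            )
            genotypes.append(g)

    coll = StratifiedCollection(genotypes, panel)
    coll.truth = {
        "seed": cfg.seed,
        "migration_matrix": cfg.resolved_migration().tolist(),
        "distinct_genotypes_per_estate": truth_classes,
        "spiked": {},
    }

    if cfg.starter_fraction > 0:
        coll = spike_starters(
            coll,
            cfg.starter_profiles,
            cfg.starter_fraction,
            cfg.starter_max_edits,
            rng_spike,
        )

    if cfg.missing_rate > 0:
        spiked = set(coll.truth["spiked"])
        for g in coll:
            if g.individual_id in spiked:
                continue  # starter-derived isolates stay complete profiles
            drop = rng_missing.random(len(panel)) < cfg.missing_rate
            g.alleles[drop] = MISSING
    return coll


def spike_starters(
    coll: StratifiedCollection,
    starter_profiles: list[MultilocusGenotype],
    fraction: float,
    max_edits: int = 2,
    seed: int | np.random.Generator = 0,
) -> StratifiedCollection:
    """Replace round(fraction * n) individuals with starter-derived
    clonal variants.

    Each spiked individual is a copy of a randomly chosen starter
    profile with 0..max_edits single-step (+/-1 repeat) edits, each at
    a uniformly chosen locus/allele slot.  Provenance is recorded in
    ``collection.truth["spiked"]`` (individual_id -> starter name) and
    in each genotype's ``meta["starter_truth"]``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    if fraction > 0 and not starter_profiles:
        raise ValueError("no starter profiles supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = coll.copy()
    out.truth = dict(getattr(coll, "truth", {}) or {})
    out.truth.setdefault("spiked", {})
    n_spike = round(fraction * len(out))
    if n_spike == 0:
        return out
    motif = coll.panel.motif_lens
    chosen = rng.choice(len(out), size=n_spike, replace=False)
    spiked = {}
    for i in chosen:
        s = starter_profiles[rng.integers(0, len(starter_profiles))]
        rep = np.rint(s.alleles / motif[:, None]).astype(int)
        n_edits = rng.integers(0, max_edits + 1)
        for _ in range(n_edits):
            j = rng.integers(0, rep.shape[0])
            slot = rng.integers(0, 2)
            rep[j, slot] = max(rep[j, slot] + (rng.integers(0, 2) * 2 - 1), 2)
        g = out.genotypes[i]
        g.alleles = rep * motif[:, None]
        g.meta["starter_truth"] = s.individual_id
        spiked[g.individual_id] = s.individual_id
    for g in out:
        g.meta.setdefault("starter_truth", "")
    out.truth["spiked"] = spiked
    return out
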