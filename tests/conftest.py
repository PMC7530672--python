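"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from mlgpop.io import LocusPanel, MultilocusGenotype, StratifiedCollection


def make_panel(n_loci=3, motif=2):
    """Panel of n_loci loci with a single motif length and zero offsets."""
    return LocusPanel(tuple((f"L{i + 1}", motif) for i in range(n_loci)))


def make_geno(ind_id, pairs, meta=None, panel=None):
    """Genotype from a list of (a1, a2) allele-size pairs."""
    return MultilocusGenotype(ind_id, np.array(pairs, dtype=int), dict(meta or {}))


def make_coll(rows, n_loci=None, motif=2, panel=None):
    """Collection from rows of (id, pairs, meta)."""
    gs = [make_geno(i, p, m) for i, p, m in rows]
    if panel is None:
        panel = make_panel(n_loci or gs[0].n_loci, motif)
    return StratifiedCollection(gs, panel)


def random_collection(rng, n=12, n_loci=17, motif=2, meta_fn=None, missing_rate=0.0):
    """Random diploid collection in repeat-unit-friendly sizes."""
    rows = []
    for i in range(n):
        pairs = rng.integers(10, 40, size=(n_loci, 2)) * motif
        if missing_rate:
            drop = rng.random(n_loci) < missing_rate
            pairs[drop] = 0
        meta = meta_fn(i) if meta_fn else {"estate": f"E{i % 3}"}
        rows.append((f"ind{i:03d}", pairs, meta))
    return make_coll(rows, n_loci=n_loci, motif=motif)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
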