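"""Genotype, locus-panel, metadata and coordinate table I/O.

Diploid microsatellite genotypes are stored as amplicon sizes in base
pairs, two unordered allele calls per locus.  Missing data are encoded
with the sentinel ``MISSING`` (0), the common convention for
microsatellite tables: a locus is missing iff *both* allele slots are
missing; half-missing loci (one call present) are rejected at parse
time because single-allele calls are ambiguous for a diploid.

Individuals with more than ``max_missing`` missing loci (default 3) are
excluded on read and reported, so that downstream statistics only see
profiles typed at nearly all loci.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.  Never a valid amplicon size.
MISSING: int = 0

#: Metadata columns recognised as population strata / labels.
META_FIELDS = ("estate", "appellation", "farming", "compartment", "vintage")


class GenotypeParseError(ValueError):
    """Raised when a genotype table violates the admission rules."""


@dataclass(frozen=True)
class LocusPanel:
    """Ordered microsatellite locus panel.

    Parameters
    ----------
    loci
        Sequence of ``(locus_name, motif_len_bp)`` pairs.  Motif length
        is the repeat-unit size in base pairs and is used to convert
        amplicon sizes to repeat counts for stepwise-mutation-model
        distances.
    offsets
        Optional per-locus primer-flank offset in bp subtracted from the
        amplicon size before dividing by the motif length.  Defaults to
        zero for every locus.
    """

    loci: tuple[tuple[str, int], ...]
    offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        for name, motif in self.loci:
            if motif < 1:
                raise ValueError(f"motif length must be >= 1 at locus {name}")
        if self.offsets and len(self.offsets) != len(self.loci):
            raise ValueError("offsets length must match number of loci")
        if not self.offsets:
            object.__setattr__(self, "offsets", (0,) * len(self.loci))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.loci]

    @property
    def motif_lens(self) -> np.ndarray:
        return np.array([m for _, m in self.loci], dtype=int)

    def __len__(self) -> int:
        return len(self.loci)

    @classmethod
    def from_csv(cls, path) -> "LocusPanel":
        df = pd.read_csv(path)
        offs = tuple(int(x) for x in df["offset_bp"]) if "offset_bp" in df else ()
        return cls(tuple(zip(df["locus"].astype(str), df["motif_len_bp"].astype(int))), offs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "locus": self.names,
                "motif_len_bp": self.motif_lens,
                "offset_bp": list(self.offsets),
            }
        ).to_csv(path, index=False)


@dataclass
class MultilocusGenotype:
    """One individual's unordered diploid allele calls at L loci.

    ``alleles`` is an ``(L, 2)`` integer array of amplicon sizes in bp,
    with :data:`MISSING` (0) for absent calls.  Allele order within a
    locus carries no meaning; callers must treat each pair as a
    multiset.
    """

    individual_id: str
    alleles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=int)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("alleles must be an (L, 2) array")
        if ((a[:, 0] == MISSING) != (a[:, 1] == MISSING)).any():
            raise GenotypeParseError(
                f"individual {self.individual_id}: half-missing locus "
                "(one allele present, one absent)"
            )
        if (a < 0).any():
            raise ValueError("allele sizes must be positive or MISSING")
        self.alleles = a

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of loci missing (both slots absent)."""
        return self.alleles[:, 0] == MISSING

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def key(self) -> tuple:
        """Hashable canonical form: per-locus sorted allele pairs."""
        return tuple(map(tuple, np.sort(self.alleles, axis=1)))

    def copy(self) -> "MultilocusGenotype":
        return MultilocusGenotype(self.individual_id, self.alleles.copy(), dict(self.meta))


def to_repeat_units(g: MultilocusGenotype, panel: LocusPanel) -> np.ndarray:
    """Convert amplicon sizes (bp) to repeat counts.

    ``repeat = round((size_bp - offset) / motif_len)`` with round-half-
    even (numpy's rounding rule).  MISSING propagates as 0.
    """
    a = g.alleles.astype(float)
    off = np.asarray(panel.offsets, dtype=float)[:, None]
    motif = panel.motif_lens.astype(float)[:, None]
    out = np.rint((a - off) / motif).astype(int)
    out[g.alleles == MISSING] = MISSING
    return out


class StratifiedCollection:
    """A set of genotypes sharing one locus panel plus population strata.

    Strata are metadata keys (estate, appellation, farming, compartment,
    vintage, ...); every individual carries exactly one label per
    stratum it participates in.
    """

    def __init__(self, genotypes: list[MultilocusGenotype], panel: LocusPanel):
        for g in genotypes:
            if g.n_loci != len(panel):
                raise ValueError(
                    f"individual {g.individual_id} has {g.n_loci} loci, panel has {len(panel)}"
                )
        ids = [g.individual_id for g in genotypes]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        self.genotypes = list(genotypes)
        self.panel = panel
        #: (individual_id, reason) pairs recorded by readers/filters.
        self.rejected: list[tuple[str, str]] = []

    def __len__(self) -> int:
        return len(self.genotypes)

    def __iter__(self):
        return iter(self.genotypes)

    def __getitem__(self, i) -> MultilocusGenotype:
        return self.genotypes[i]

    @property
    def ids(self) -> list[str]:
        return [g.individual_id for g in self.genotypes]

    def allele_array(self) -> np.ndarray:
        """(n, L, 2) array of amplicon sizes; MISSING = 0."""
        return np.stack([g.alleles for g in self.genotypes]) if self.genotypes else np.empty((0, len(self.panel), 2), int)

    def repeat_array(self) -> np.ndarray:
        """(n, L, 2) array of repeat counts; MISSING = 0."""
        return np.stack([to_repeat_units(g, self.panel) for g in self.genotypes])

    def labels(self, stratum: str) -> np.ndarray:
        """Per-individual group label for a stratum; error if any missing."""
        vals = []
        for g in self.genotypes:
            if stratum not in g.meta or g.meta[stratum] in (None, ""):
                raise KeyError(f"individual {g.individual_id} has no '{stratum}' label")
            vals.append(str(g.meta[stratum]))
        return np.array(vals, dtype=object)

    def groups(self, stratum: str) -> dict[str, list[int]]:
        """Mapping group label -> indices, groups in sorted label order."""
        lab = self.labels(stratum)
        out: dict[str, list[int]] = {}
        for k in sorted(set(lab)):
            out[k] = [i for i, v in enumerate(lab) if v == k]
        return out

    def subset(self, indices) -> "StratifiedCollection":
        sub = StratifiedCollection([self.genotypes[i].copy() for i in indices], self.panel)
        return sub

    def copy(self) -> "StratifiedCollection":
        return self.subset(range(len(self)))

    def sorted_by_id(self) -> "StratifiedCollection":
        order = np.argsort(np.array(self.ids, dtype=object))
        return self.subset(order)

    def equals(self, other: "StratifiedCollection") -> bool:
        if self.panel != other.panel or len(self) != len(other):
            return False
        for a, b in zip(self.sorted_by_id(), other.sorted_by_id()):
            if a.individual_id != b.individual_id or not np.array_equal(a.alleles, b.alleles):
                return False
            if {k: str(v) for k, v in a.meta.items()} != {k: str(v) for k, v in b.meta.items()}:
                return False
        return True


# ---------------------------------------------------------------------------
# table readers / writers


def _meta_columns(coll: StratifiedCollection) -> list[str]:
    keys: list[str] = []
    for g in coll:
        for k in g.meta:
            if k not in keys:
                keys.append(k)
    return keys


def read_genotype_table(
    path,
    panel: LocusPanel,
    dialect: str = "two_column_wide",
    metadata=None,
    max_missing: int = 3,
) -> StratifiedCollection:
    """Read a wide genotype table into a collection.

    Dialects
    --------
    ``two_column_wide``
        Header ``individual_id, LOCUS.1, LOCUS.2, ...`` (two columns per
        panel locus, panel order enforced), optional trailing metadata
        columns.
    ``genalex``
        GenAlEx codominant layout: two preamble rows (counts; title and
        population names) before the header row ``individual_id, pop,
        LOCUS, , ...``; the ``pop`` column is stored as the ``estate``
        stratum.

    ``metadata`` may be a CSV path or DataFrame keyed by
    ``individual_id`` (exact, case-sensitive match); its columns are
    joined onto each genotype's ``meta``.

    Individuals with more than ``max_missing`` missing loci are
    excluded; the reasons are available on ``collection.rejected``.
    Half-missing loci and unknown locus columns raise
    :class:`GenotypeParseError`.
    """
    if dialect == "two_column_wide":
        df = pd.read_csv(path, dtype=str).fillna("0")
        meta_from_pop = None
    elif dialect == "genalex":
        raw = pd.read_csv(path, header=None, dtype=str, skiprows=2)
        raw.columns = [str(c).strip() for c in raw.iloc[0]]
        df = raw.iloc[1:].reset_index(drop=True).fillna("0")
        # second locus column of each pair is unnamed in GenAlEx; restore names
        cols = list(df.columns)
        fixed = []
        prev = None
        for c in cols:
            if c in ("", "0", "nan") and prev is not None and prev not in ("individual_id", "pop"):
                fixed.append(prev + ".2")
                prev = None
            else:
                base = c
                fixed.append(base if base in ("individual_id", "pop") else base + ".1")
                prev = base
        df.columns = fixed
        meta_from_pop = df["pop"] if "pop" in df else None
    else:
        raise ValueError(f"unknown dialect: {dialect}")

    expected = []
    for name in panel.names:
        expected.extend([f"{name}.1", f"{name}.2"])
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise GenotypeParseError(f"missing locus columns: {missing_cols}")
    known = set(expected) | {"individual_id", "pop"} | set(META_FIELDS) | {"latitude", "longitude"}
    unknown = [
        c for c in df.columns
        if c not in known and (c.endswith(".1") or c.endswith(".2"))
    ]
    if unknown:
        raise GenotypeParseError(f"unknown locus columns: {unknown}")
    if "individual_id" not in df.columns:
        raise GenotypeParseError("missing 'individual_id' column")

    meta_df = None
    if metadata is not None:
        meta_df = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata, dtype=str)
        meta_df = meta_df.set_index("individual_id")

    genotypes: list[MultilocusGenotype] = []
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        ind = str(row["individual_id"])
        alleles = np.empty((len(panel), 2), dtype=int)
        for j, name in enumerate(panel.names):
            try:
                a1 = int(float(row[f"{name}.1"]))
                a2 = int(float(row[f"{name}.2"]))
            except ValueError as exc:
                raise GenotypeParseError(f"individual {ind}, locus {name}: non-numeric allele") from exc
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeParseError(
                    f"individual {ind}, locus {name}: half-missing locus"
                )
            alleles[j] = (a1, a2)
        meta: dict = {}
        for k in df.columns:
            if k in META_FIELDS or k in ("latitude", "longitude"):
                meta[k] = str(row[k])
        if meta_from_pop is not None:
            meta.setdefault("estate", str(row["pop"]))
        if meta_df is not None and ind in meta_df.index:
            for k, v in meta_df.loc[ind].items():
                if pd.notna(v):
                    meta[k] = str(v)
        g = MultilocusGenotype(ind, alleles, meta)
        if g.n_missing > max_missing:
            rejected.append((ind, f"{g.n_missing} missing loci > max_missing={max_missing}"))
            continue
        genotypes.append(g)

    coll = StratifiedCollection(genotypes, panel)
    coll.rejected = rejected
    return coll


def write_genotype_table(
    coll: StratifiedCollection,
    path,
    dialect: str = "two_column_wide",
    pop_stratum: str = "estate",
) -> None:
    """Write a collection to CSV, sorted by individual_id (byte-stable)."""
    if len(coll) == 0:
        raise ValueError("cannot write an empty collection")
    coll = coll.sorted_by_id()
    locus_cols = []
    for name in coll.panel.names:
        locus_cols.extend([f"{name}.1", f"{name}.2"])
    arr = coll.allele_array()

    if dialect == "two_column_wide":
        data = {"individual_id": coll.ids}
        for j, name in enumerate(coll.panel.names):
            data[f"{name}.1"] = arr[:, j, 0]
            data[f"{name}.2"] = arr[:, j, 1]
        for k in _meta_columns(coll):
            data[k] = [g.meta.get(k, "") for g in coll]
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "genalex":
        pops = [g.meta.get(pop_stratum, "pop1") for g in coll]
        pop_order = sorted(set(pops))
        counts = [pops.count(p) for p in pop_order]
        buf = _io.StringIO()
        ncol = 2 + 2 * len(coll.panel)
        row1 = [str(len(coll.panel)), str(len(coll)), str(len(pop_order))] + [str(c) for c in counts]
        row2 = ["mlgpop export", "", ""] + pop_order
        header = ["individual_id", "pop"]
        for name in coll.panel.names:
            header.extend([name, ""])
        for row in (row1, row2):
            row = row + [""] * (ncol - len(row))
            buf.write(",".join(row[:ncol]) + "\n")
        buf.write(",".join(header) + "\n")
        for i, g in enumerate(coll):
            cells = [g.individual_id, pops[i]] + [str(x) for x in arr[i].ravel()]
            buf.write(",".join(cells) + "\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def read_coordinates(path) -> pd.DataFrame:
    """Read a site-coordinate CSV (``id, latitude, longitude`` in decimal
    degrees WGS84) into a DataFrame indexed by id."""
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "latitude", "longitude"):
        if col not in df.columns:
            raise ValueError(f"coordinates table missing column '{col}'")
    return df.set_index("id")[["latitude", "longitude"]].astype(float)
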