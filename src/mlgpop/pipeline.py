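"""End-to-end study-shaped analysis pipeline.

Stage order mirrors the analysis narrative: admission filtering
(missing-data rule) -> clone correction within estates -> starter
attribution and optional removal -> diversity indices -> AMOVA /
pairwise Fst / Mantel -> directional migration -> balanced
compartment Fst.  All outputs are plain JSON/CSV; given fixed seeds a
rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonal
from . import diversity as div
from . import migration as mig
from . import starters as st
from . import structure as struct
from .distance import geographic_distance_matrix
from .io import (
    LocusPanel,
    StratifiedCollection,
    read_coordinates,
    read_genotype_table,
)

__all__ = ["PipelineConfig", "PipelineError", "run", "run_collection"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the partial
    manifest accumulated so far."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Configuration for a full run; see field defaults for the study
    conventions (clone correction within estates, 75% starter rule,
    appellation-level structure statistics, 20-individual balanced
    compartment subsampling)."""

    genotypes: str | None = None
    panel: str | None = None
    metadata: str | None = None
    coordinates: str | None = None
    starters: str | None = None
    dialect: str = "two_column_wide"
    max_missing: int = 3
    clone_stratum: str = "estate"
    starter_threshold: float = 0.75
    remove_starter_related: bool = True
    amova_models: list[list[str]] = field(
        default_factory=lambda: [["appellation"], ["appellation", "estate"], ["estate"]]
    )
    n_perm: int = 199
    fst_stratum: str = "appellation"
    diversity_strata: list[str] = field(default_factory=lambda: ["farming", "appellation"])
    rarefy_depth: int | None = None
    rarefy_reps: int = 10
    migration_stratum: str = "appellation"
    migration_boot: int = 0
    balanced: dict | None = None  # e.g. {"side_a": "grape", "side_b": "cellar", "cap": 20, "reps": 100}
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jdump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def run(config: PipelineConfig, out_dir) -> dict:
    """Load inputs per config, run the analysis, write the report
    bundle to ``out_dir``.  Returns the run manifest."""
    panel = LocusPanel.from_csv(config.panel)
    coll = read_genotype_table(
        config.genotypes,
        panel,
        dialect=config.dialect,
        metadata=config.metadata,
        max_missing=config.max_missing,
    )
    starter_panel = None
    if config.starters:
        sdf = read_genotype_table(config.starters, panel, dialect=config.dialect, max_missing=0)
        starter_panel = st.StarterPanel([g.copy() for g in sdf])
    coords = read_coordinates(config.coordinates) if config.coordinates else None
    checksums = {
        k: _sha256(getattr(config, k))
        for k in ("genotypes", "panel", "metadata", "coordinates", "starters")
        if getattr(config, k)
    }
    return run_collection(coll, config, out_dir, starter_panel=starter_panel,
                          coords=coords, checksums=checksums)


def run_collection(
    coll: StratifiedCollection,
    config: PipelineConfig,
    out_dir,
    starter_panel: st.StarterPanel | None = None,
    coords=None,
    checksums: dict | None = None,
) -> dict:
    """Run the analysis stages on an in-memory collection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items() if not isinstance(v, np.ndarray)},
        "input_checksums": checksums or {},
        "seed": config.seed,
        "counts": {"genotyped": len(coll), "rejected_missing": len(coll.rejected)},
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("clone_correction")
        unique = clonal.clone_correct(coll, config.clone_stratum)
        manifest["counts"]["unique"] = len(unique)

        working = unique
        if starter_panel is not None:
            stage("starter_attribution")
            report = st.attribute(unique, starter_panel, config.starter_threshold)
            report.to_csv(out / "starter_report.csv")
            n_related = int(report["category"].isin(st.RELATED_CATEGORIES).sum())
            manifest["counts"]["starter_related"] = n_related
            if config.remove_starter_related:
                working = st.remove_related(unique, report)
            manifest["counts"]["starter_removed"] = len(working)

        stage("diversity")
        diversity_out = {}
        for stratum in config.diversity_strata:
            per = {}
            for label, idx in working.groups(stratum).items():
                ab = div.abundance_from_collection(working.subset(idx))
                rec = div.diversity_report(ab)
                if config.rarefy_depth:
                    mean_s, sd_s, _ = div.rarefy_richness(
                        ab, config.rarefy_depth, config.rarefy_reps, config.seed
                    )
                    rec["rarefied_richness"] = mean_s
                    rec["rarefied_sd"] = sd_s
                per[label] = rec
            diversity_out[stratum] = per
        _jdump(diversity_out, out / "diversity.json")

        stage("amova")
        amova_out = []
        for i, model in enumerate(config.amova_models):
            res = struct.amova(
                working, model, n_perm=config.n_perm, seed=config.seed + i
            )
            amova_out.append(
                {
                    "model": res.model,
                    "levels": res.levels,
                    "within_individual": res.within_individual,
                    "negative_components": res.negative_components,
                }
            )
        _jdump(amova_out, out / "amova.json")

        stage("pairwise_fst")
        fst, pmat = struct.pairwise_fst(
            working, config.fst_stratum, n_perm=config.n_perm, seed=config.seed
        )
        pd.DataFrame(fst.data, index=fst.ids, columns=fst.ids).to_csv(out / "fst.csv")
        pd.DataFrame(pmat, index=fst.ids, columns=fst.ids).to_csv(out / "fst_p.csv")

        if coords is not None:
            stage("mantel")
            geo = geographic_distance_matrix(coords.loc[list(fst.ids)])
            r, p = struct.mantel(fst, geo, n_perm=max(config.n_perm, 99), seed=config.seed)
            _jdump({"r": r, "p": p}, out / "mantel.json")

        stage("directional_migration")
        mm = mig.directional_migration(
            working, config.migration_stratum, n_boot=config.migration_boot, seed=config.seed
        )
        pd.DataFrame(mm.values, index=mm.labels, columns=mm.labels).to_csv(
            out / "migration.csv"
        )

        if config.balanced:
            stage("balanced_fst")
            b = dict(config.balanced)
            mean, sd, vals = struct.balanced_fst(
                working,
                side_stratum=b.get("side_stratum", "compartment"),
                side_a=b.get("side_a", "grape"),
                side_b=b.get("side_b", "cellar"),
                group_stratum=b.get("group_stratum", "estate"),
                cap=b.get("cap", 20),
                n_reps=b.get("reps", 100),
                seed=config.seed,
            )
            _jdump(
                {"mean_fst": mean, "sd_fst": sd, "replicates": vals.tolist()},
                out / "balanced_fst.json",
            )
    except (KeyError, ValueError) as exc:
        raise PipelineError(manifest["stages"][-1] if manifest["stages"] else "load", exc, manifest)

    counts = manifest["counts"]
    order = [counts.get(k) for k in ("genotyped", "unique", "starter_removed") if counts.get(k) is not None]
    assert order == sorted(order, reverse=True), "filtering stages must not add records"
    _jdump(manifest, out / "manifest.json")
    return manifest
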