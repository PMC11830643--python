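"""End-to-end orchestration: measure -> classify -> correlate -> rarefy -> pgls.

A run is described by a :class:`RunConfig` (loadable from YAML), executed
stage by stage with every output stamped into a JSON manifest carrying the
config hash and the per-stage seeds, so any output can be reproduced from
the manifest alone.  Stages fail hard: a taxon missing from the tree or an
unusable mesh stops the run naming the offender.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import disparity, mesh_io, morphometry, phylocomp, synthdata, traits

__all__ = ["RunConfig", "ModelSpec", "run_pipeline", "load_run_config"]

log = logging.getLogger("valvemorph")

DEFAULT_VARIABLES = ("pSV", "logSL", "XS")


@dataclass(frozen=True)
class ModelSpec:
    """One phylogenetic ANOVA: response and ordered model terms."""

    response: str
    terms: tuple
    n_perm: int = 999
    seed: int = 7


@dataclass
class RunConfig:
    """Inputs, per-stage settings and seeds for one pipeline run.

    Either ``trait_table`` + ``tree`` point at existing files, or
    ``simulate = True`` generates a synthetic cohort first (seeded by
    ``simulate_seed``).  ``mesh_dir`` optionally holds ``<taxon>_shell`` and
    ``<taxon>_interior`` mesh files to (re)measure.
    """

    out_dir: str = "valvemorph_run"
    trait_table: "str | None" = None
    tree: "str | None" = None
    mesh_dir: "str | None" = None
    simulate: bool = False
    simulate_seed: int = 0
    variables: tuple = DEFAULT_VARIABLES
    group_by: str = "family"
    internal_mode: str = morphometry.DEFAULT_INTERNAL_MODE
    log_base: float = morphometry.DEFAULT_LOG_BASE
    rarefaction_n_min: int = disparity.DEFAULT_N_MIN
    rarefaction_reps: int = disparity.DEFAULT_REPS
    rarefaction_seed: int = 42
    models: tuple = (
        ModelSpec("pSV", ("substratum", "logSL", "XS", "family")),
        ModelSpec("logSL", ("substratum", "pSV", "XS", "family")),
        ModelSpec("XS", ("substratum", "logSL", "pSV", "family")),
    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "models" in raw:
        raw["models"] = tuple(
            ModelSpec(m["response"], tuple(m["terms"]),
                      int(m.get("n_perm", 999)), int(m.get("seed", 7)))
            for m in raw["models"])
    if "variables" in raw:
        raw["variables"] = tuple(raw["variables"])
    return RunConfig(**raw)


def _measure_stage(config: RunConfig, records) -> pd.DataFrame:
    """Re-measure any specimens with meshes on disk."""
    mesh_dir = Path(config.mesh_dir)
    measured = []
    for rec in records:
        shells = sorted(mesh_dir.glob(f"{rec.taxon}_shell.*"))
        interiors = sorted(mesh_dir.glob(f"{rec.taxon}_interior.*"))
        if not shells or not interiors:
            continue
        shell = mesh_io.read_mesh(shells[0], role=mesh_io.SHELL_SOLID)
        interior = mesh_io.read_mesh(interiors[0],
                                     role=mesh_io.INTERIOR_SURFACE)
        metrics = morphometry.compute_metrics(
            shell, interior, internal_mode=config.internal_mode,
            log_base=config.log_base)
        rec.metrics.update(metrics.as_dict())
        measured.append(rec.taxon)
    log.info("measured %d specimens from %s", len(measured), mesh_dir)
    return traits.records_to_frame(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths (the manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(),
                "config": asdict(config), "outputs": {}}

    def emit(name, path):
        manifest["outputs"][name] = str(path)

    # --- inputs (load or simulate) ---------------------------------------
    if config.simulate:
        log.info("simulating default cohort (seed %d)", config.simulate_seed)
        cohort = synthdata.make_cohort(seed=config.simulate_seed)
        records, tree = cohort.records, cohort.tree
        tree_path = out / "tree.nwk"
        tree.write(path=str(tree_path), schema="newick",
                   suppress_rooting=True, unquoted_underscores=True)
        emit("tree", tree_path)
    else:
        if not config.trait_table or not config.tree:
            raise ValueError("need trait_table and tree unless simulate=True")
        records = traits.read_trait_table(config.trait_table)
        tree = phylocomp.load_tree(config.tree)

    # --- measure ----------------------------------------------------------
    if config.mesh_dir:
        frame = _measure_stage(config, records)
        metrics_path = out / "metrics.csv"
        frame.to_csv(metrics_path, index=False)
        emit("metrics", metrics_path)

    # --- classify ---------------------------------------------------------
    traits.classify_all(records)
    frame = traits.records_to_frame(records)
    classified_path = out / "classified.csv"
    frame.to_csv(classified_path, index=False)
    emit("classified", classified_path)
    log.info("classified %d specimens into %d substratum groups",
             len(frame), frame["substratum"].nunique())

    # --- tree/table agreement is a hard requirement -----------------------
    tips = set(phylocomp.tip_labels(tree))
    missing = sorted(set(frame["taxon"]) - tips)
    if missing:
        raise phylocomp.TaxonMismatchError(
            f"taxa in table but absent from tree: {', '.join(missing)}")

    # --- correlate --------------------------------------------------------
    corr = phylocomp.pearson_matrix(frame, config.variables)
    corr_path = out / "correlations.csv"
    corr.to_csv(corr_path)
    emit("correlations", corr_path)

    # --- rarefy -----------------------------------------------------------
    curves = []
    for variable in config.variables:
        for metric in ("variance", "range"):
            for group, sub in frame.groupby(config.group_by):
                curves.append(disparity.rarefy(
                    sub[variable].to_numpy(), metric, group=str(group),
                    variable=variable, n_min=config.rarefaction_n_min,
                    reps=config.rarefaction_reps,
                    seed=config.rarefaction_seed))
    curves_path = out / "curves.csv"
    disparity.curves_to_frame(curves).to_csv(curves_path, index=False)
    emit("curves", curves_path)

    # --- pgls -------------------------------------------------------------
    taxa = list(frame["taxon"])
    order = [taxa.index(t) for t in phylocomp.tip_labels(tree)]
    aligned = frame.iloc[order].reset_index(drop=True)
    C, _ = phylocomp.phylo_vcv(tree)
    for model in config.models:
        table = phylocomp.pgls_rrpp(model.response, list(model.terms),
                                    aligned, cov=C, n_perm=model.n_perm,
                                    seed=model.seed)
        anova_path = out / f"anova_{model.response}.csv"
        table.to_csv(anova_path)
        emit(f"anova_{model.response}", anova_path)
        log.info("fitted %s (n_perm=%d)", table.formula, model.n_perm)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    emit("manifest", manifest_path)
    return manifest
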