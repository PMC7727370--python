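"""End-to-end pipeline: thin -> collinearity filter -> M -> background ->
tune -> select -> replicates -> median map -> partial ROC -> LTPT -> binary map.

Configuration is a single YAML file; every stage writes its intermediate
artifacts to a per-species directory together with a machine-readable
run log (JSON lines: stage, parameters, sub-seed, output hashes), and
rerunning with the same config and master seed reproduces identical
outputs.  A failure in one species is recorded and the remaining species
still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import accessible_area as aa
from . import evaluation as ev
from .collinearity import filter_collinear
from .landscape import LandscapeStack, write_ascii_grid
from .maxent import permutation_importance, sample_background, save_lambdas
from .occurrences import (
    OccurrenceSet,
    extract_env_at_points,
    read_occurrences,
    thin_occurrences,
)
from .selection import (
    DEFAULT_FC_SETS,
    enumerate_candidates,
    results_table,
    run_replicates,
    select_best,
    tune,
)

__all__ = ["PipelineConfig", "read_landscape", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline settings (see the project README for the YAML layout)."""

    landscape_dir: str | None
    occurrences_csv: str | None
    species: dict[str, aa.SpeciesProfile]
    collinearity_threshold: float = 0.8
    thinning_km: float | None = None  # None -> one cell diagonal
    rm_min: float = 0.5
    rm_max: float = 4.0
    rm_step: float = 0.5
    fc_sets: tuple[tuple[str, ...], ...] | None = None
    n_replicates: int = 10
    test_fraction: float = 0.25
    max_iterations: int = 5000
    convergence_threshold: float = 1e-5
    background_cap: int = 10_000
    n_hinge_knots: int = 20
    n_threshold_knots: int = 20
    replicate_type: str = "subsample"
    combine_rule: str = "env_union_buffer"
    E: float = 0.05
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = {}
        for name, sp in raw.get("species", {}).items():
            species[name] = aa.SpeciesProfile(
                species=name,
                altitude_band=(float(sp["altitude_min_m"]), float(sp["altitude_max_m"])),
                synanthropy_class=sp["synanthropy"],
                dispersal_km=float(sp.get("dispersal_km", aa.DEFAULT_DISPERSAL_KM)),
            )
        mx = raw.get("maxent", {})
        tun = raw.get("tuning", {})
        evc = raw.get("evaluation", {})
        fc_sets = tun.get("fc_sets")
        return cls(
            landscape_dir=raw.get("landscape"),
            occurrences_csv=raw.get("occurrences"),
            species=species,
            collinearity_threshold=float(
                raw.get("collinearity", {}).get("threshold", 0.8)
            ),
            thinning_km=raw.get("thinning", {}).get("min_distance_km"),
            rm_min=float(tun.get("rm_min", 0.5)),
            rm_max=float(tun.get("rm_max", 4.0)),
            rm_step=float(tun.get("rm_step", 0.5)),
            fc_sets=None if fc_sets is None else tuple(tuple(f) for f in fc_sets),
            n_replicates=int(mx.get("replicates", 10)),
            test_fraction=float(mx.get("test_fraction", 0.25)),
            max_iterations=int(mx.get("max_iterations", 5000)),
            convergence_threshold=float(mx.get("convergence_threshold", 1e-5)),
            background_cap=int(mx.get("background_cap", 10_000)),
            n_hinge_knots=int(mx.get("n_hinge_knots", 20)),
            n_threshold_knots=int(mx.get("n_threshold_knots", 20)),
            replicate_type=mx.get("replicate_type", "subsample"),
            combine_rule=raw.get("combine_rule", "env_union_buffer"),
            E=float(evc.get("E", 0.05)),
            n_bootstrap=int(evc.get("n_bootstrap", 100)),
            bootstrap_fraction=float(evc.get("bootstrap_fraction", 0.5)),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["species"] = {
            name: {
                "altitude_min_m": p.altitude_band[0],
                "altitude_max_m": p.altitude_band[1],
                "synanthropy": p.synanthropy_class,
                "dispersal_km": p.dispersal_km,
            }
            for name, p in self.species.items()
        }
        return d


def read_landscape(path: str | Path) -> LandscapeStack:
    """Assemble a stack from a manifest directory; mismatched grids rejected."""
    return LandscapeStack.from_dir(path)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def record(self, stage: str, params: dict, outputs: list[Path] | None = None):
        entry = {"stage": stage, "params": params}
        if outputs:
            entry["outputs"] = {p.name: _hash_file(p) for p in outputs}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def _mask_to_asc(path, mask, stack):
    write_ascii_grid(path, mask.astype(float), stack, nodata_mask=stack.nodata_mask)


def run_species(
    stack: LandscapeStack,
    occ: OccurrenceSet,
    profile: aa.SpeciesProfile,
    config: PipelineConfig,
    out_dir: Path,
    species_seed: int,
) -> dict[str, Any]:
    """All pipeline stages for one species; returns a summary dict."""
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run_log.jsonl")
    ss = np.random.SeedSequence(species_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    bg_seed, rep_seed, roc_seed, imp_seed = seeds

    # 1. thin
    thin_km = config.thinning_km
    if thin_km is None:
        # one cell diagonal, in km (~111.32 km per degree at the equator)
        thin_km = float(np.hypot(stack.cell_size, stack.cell_size) * 111.32)
    thinned = thin_occurrences(occ, thin_km)
    log.record("thin", {"min_distance_km": thin_km,
                        "n_in": len(occ), "n_out": len(thinned)})

    # 2. collinearity filter
    retained, dropped, corr = filter_collinear(
        stack, threshold=config.collinearity_threshold
    )
    corr.to_csv(out_dir / "correlation.csv")
    log.record(
        "collinearity",
        {"threshold": config.collinearity_threshold,
         "retained": retained, "dropped": dropped},
        [out_dir / "correlation.csv"],
    )

    # 3. accessible area M
    area = aa.build_accessible_area(
        stack, thinned, profile, combine_rule=config.combine_rule
    )
    for name, grid in [
        ("M", area.mask),
        ("M_altitude", area.altitude_component),
        ("M_hii", area.hii_component),
        ("M_buffer", area.buffer_component),
    ]:
        _mask_to_asc(out_dir / f"{name}.asc", grid, stack)
    log.record(
        "accessible_area",
        {"combine_rule": area.combine_rule, "hii_band": area.hii_band_used,
         "n_cells": area.n_cells},
        [out_dir / "M.asc"],
    )

    # 4. background
    background = sample_background(
        area, stack, cap=config.background_cap, seed=bg_seed,
        layer_names=retained,
    )
    presence_table = extract_env_at_points(stack, thinned, retained)
    log.record("background", {"size": background.size, "seed": bg_seed})

    # 5-6. tune and select
    fc_sets = config.fc_sets if config.fc_sets is not None else DEFAULT_FC_SETS
    candidates = enumerate_candidates(
        config.rm_min, config.rm_max, config.rm_step, fc_sets
    )
    results = tune(
        presence_table, background, candidates,
        max_iterations=config.max_iterations,
        convergence_threshold=config.convergence_threshold,
        n_hinge_knots=config.n_hinge_knots,
        n_threshold_knots=config.n_threshold_knots,
    )
    best = select_best(results)
    results_table(results).to_csv(out_dir / "tuning.csv", index=False)
    save_lambdas(best.model, out_dir / "best_model.lambdas")
    log.record(
        "tune",
        {"n_candidates": len(results), "best_fc": best.config.fc_label,
         "best_rm": best.config.rm, "best_aicc": best.aicc, "k": best.k},
        [out_dir / "tuning.csv", out_dir / "best_model.lambdas"],
    )

    # variable contributions of the selected model (permutation surrogate)
    contrib = permutation_importance(
        best.model, presence_table, background.env_table, seed=imp_seed
    )
    contrib.to_csv(out_dir / "contributions.csv")

    # 7-8. replicates and median map
    ensemble = run_replicates(
        best.config, presence_table, background, stack, area.mask,
        n_replicates=config.n_replicates,
        test_fraction=config.test_fraction,
        seed=rep_seed,
        replicate_type=config.replicate_type,
        max_iterations=config.max_iterations,
        convergence_threshold=config.convergence_threshold,
        n_hinge_knots=config.n_hinge_knots,
        n_threshold_knots=config.n_threshold_knots,
    )
    median = ensemble.aggregated
    write_ascii_grid(out_dir / "median_map.asc", np.nan_to_num(median, nan=-9999.0),
                     stack, nodata_mask=~np.isfinite(median))
    log.record(
        "replicates",
        {"n_replicates": config.n_replicates,
         "test_fraction": config.test_fraction,
         "replicate_type": config.replicate_type, "seed": rep_seed},
        [out_dir / "median_map.asc"],
    )

    # 9. partial ROC on the pooled held-out presences
    held = sorted({int(i) for idx in ensemble.test_indices for i in idx})
    test_points = thinned.subset(held)
    roc = ev.partial_roc(
        median, test_points, stack,
        ev.EvaluationConfig(
            E=config.E, n_bootstrap=config.n_bootstrap,
            bootstrap_fraction=config.bootstrap_fraction, seed=roc_seed,
        ),
    )
    pd.DataFrame(
        {"replicate": np.arange(1, len(roc.auc_ratios) + 1),
         "auc_ratio": roc.auc_ratios}
    ).to_csv(out_dir / "partial_roc.csv", index=False)
    (out_dir / "evaluation_summary.csv").write_text(
        "mean_ratio,p_value,E,n_bootstrap\n"
        f"{roc.mean_ratio},{roc.p_value},{roc.E},{config.n_bootstrap}\n"
    )
    log.record(
        "partial_roc",
        {"mean_ratio": roc.mean_ratio, "p_value": roc.p_value,
         "E": config.E, "seed": roc_seed},
        [out_dir / "partial_roc.csv"],
    )

    # 10-11. LTPT and binary map
    threshold = ev.ltpt_threshold(median, thinned, stack, E=config.E)
    binary = ev.binarize(median, threshold)
    write_ascii_grid(
        out_dir / "binary_map.asc", binary.filled(False).astype(float),
        stack, nodata_mask=np.asarray(binary.mask),
    )
    geo = ev.suitable_region_geojson(binary, stack)
    (out_dir / "suitable_region.geojson").write_text(json.dumps(geo))
    log.record(
        "ltpt",
        {"threshold": threshold, "E": config.E},
        [out_dir / "binary_map.asc", out_dir / "suitable_region.geojson"],
    )

    return {
        "species": profile.species,
        "n_thinned": len(thinned),
        "retained_layers": retained,
        "best_fc": best.config.fc_label,
        "best_rm": best.config.rm,
        "best_aicc": best.aicc,
        "mean_auc_ratio": roc.mean_ratio,
        "p_value": roc.p_value,
        "ltpt_threshold": threshold,
        "status": "ok",
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stack: LandscapeStack | None = None,
    occurrences: dict[str, OccurrenceSet] | None = None,
) -> dict[str, dict[str, Any]]:
    """Run every configured species; per-species failures are isolated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stack is None:
        if config.landscape_dir is None:
            raise ValueError("config has no landscape directory and none was passed")
        stack = read_landscape(config.landscape_dir)
    if occurrences is None:
        if config.occurrences_csv is None:
            raise ValueError("config has no occurrence CSV and none was passed")
        occurrences = read_occurrences(config.occurrences_csv)

    master = np.random.SeedSequence(config.seed)
    species_names = list(config.species)
    children = master.spawn(len(species_names))
    summaries: dict[str, dict[str, Any]] = {}
    for name, child in zip(species_names, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            if name not in occurrences:
                raise ValueError(f"no occurrence records for species {name!r}")
            summaries[name] = run_species(
                stack, occurrences[name], config.species[name], config,
                out_dir / name.replace(" ", "_"), sub_seed,
            )
        except Exception as exc:  # keep other species running
            summaries[name] = {"species": name, "status": "failed",
                               "error": str(exc)}
    (out_dir / "summary.json").write_text(
        json.dumps({"seed": config.seed, "species": summaries},
                   indent=1, default=str)
    )
    return summaries
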