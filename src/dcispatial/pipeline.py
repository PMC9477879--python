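"""End-to-end orchestration: simulate -> regions -> colocalize -> compare.

A single :class:`RunConfig` document resolves every stage's parameters.
Runs are deterministic for a fixed seed and emit a manifest (config hash,
seed, versions, per-stage counts) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cells import SampleType
from .compare import GroupedMeasurements, pairwise_wilcoxon_holm
from .io import write_cells, write_duct_mask_geojson
from .regions import MIN_COMPONENT_CELLS, T_HIGH_DEFAULT, T_LOW_DEFAULT
from .spatial_stats import (
    DEFAULT_PAIRS,
    abundances_to_frame,
    analyze_section,
    results_to_frame,
)
from .synthetic import SimulationParams, simulate_section

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}


@dataclass
class RunConfig:
    """One document resolving every stage of a pipeline run."""

    n_pure: int = 5
    n_idc_dcis: int = 5
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    t_low: float = T_LOW_DEFAULT
    t_high: float = T_HIGH_DEFAULT
    min_cells: int = MIN_COMPONENT_CELLS
    pairs: list = field(default_factory=lambda: [[a.value, b.value] for a, b in DEFAULT_PAIRS])
    rng_seed: int = 0
    out_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.n_pure < 0 or self.n_idc_dcis < 0:
            raise ValueError("section counts must be non-negative")
        unknown = set(self.simulation) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        if not (0 <= self.t_low < self.t_high <= 1):
            raise ValueError("thresholds must satisfy 0 <= t_low < t_high <= 1")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _section_params(config: RunConfig, seed: int) -> SimulationParams:
    overrides = dict(config.simulation)
    overrides["rng_seed"] = seed
    return SimulationParams(**overrides)


def run(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Simulates the configured sections (pure DCIS sections skip duct
    segmentation and polygon typing — they effectively contain only duct
    regions — and get a single whole-section index per pair; IDC/DCIS
    sections get per-component indices), then compares each pair's index
    across the three groups with Holm-adjusted rank-sum tests.
    """
    out = Path(config.out_dir)
    pairs = [tuple(p) for p in config.pairs]
    coloc_rows = []
    abund_rows = []
    section_log = []

    for i in range(config.n_pure + config.n_idc_dcis):
        is_pure = i < config.n_pure
        stype = SampleType.PURE_DCIS if is_pure else SampleType.IDC_DCIS
        sid = f"{'pure' if is_pure else 'idc_dcis'}_{i:03d}"
        params = _section_params(config, seed=config.rng_seed * 10007 + i)
        section = simulate_section(params, stype, section_id=sid)
        analysis = analyze_section(
            section.cells,
            ducts=None if is_pure else section.ducts,
            pairs=pairs,
            t_low=config.t_low,
            t_high=config.t_high,
            min_cells=config.min_cells,
            rng_seed=config.rng_seed,
        )
        coloc_rows.append(results_to_frame(analysis.colocalization))
        abund_rows.append(abundances_to_frame(analysis.abundances))
        section_log.append(
            {
                "section_id": sid,
                "sample_type": stype.value,
                "n_cells": section.cells.n_cells,
                "n_ducts": len(section.ducts),
            }
        )
        if write_outputs:
            write_cells(section.cells, out / "sections" / f"{sid}.cells.csv")
            write_duct_mask_geojson(
                section.ducts, out / "sections" / f"{sid}.ducts.geojson"
            )

    results = pd.concat(coloc_rows, ignore_index=True)
    abundances = pd.concat(abund_rows, ignore_index=True)
    comparisons = compare_results(results)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "rng_seed": config.rng_seed,
        "dcispatial_version": __version__,
        "sections": section_log,
        "n_results": int(len(results)),
        "n_null_indices": int(results["insufficient_data"].sum()),
    }
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "colocalization.csv", index=False)
        abundances.to_csv(out / "abundances.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["results"] = results
    manifest["abundances"] = abundances
    manifest["comparisons"] = comparisons
    return manifest


def compare_results(results: pd.DataFrame) -> pd.DataFrame:
    """Holm-adjusted pairwise group contrasts, one family per class pair.

    Groups are ``whole_section`` (pure DCIS), ``synchronous_DCIS`` and
    ``IDC``; null (insufficient-data) indices are dropped, not zero-filled.
    """
    rows = []
    for (a, b), sub in results.groupby(["class_a", "class_b"], sort=True):
        usable = sub[~sub["insufficient_data"] & sub["mh_index"].notna()]
        if usable.empty:
            continue
        gm = GroupedMeasurements.from_frame(
            usable.rename(columns={"mh_index": "value", "component": "group"})[
                ["value", "group"]
            ]
        )
        if gm.data["group"].nunique() < 2:
            continue
        table = pairwise_wilcoxon_holm(gm)
        table.insert(0, "class_a", a)
        table.insert(1, "class_b", b)
        rows.append(table)
    if not rows:
        return pd.DataFrame(
            columns=[
                "class_a", "class_b", "group_a", "group_b",
                "n_a", "n_b", "p_raw", "p_holm",
            ]
        )
    return pd.concat(rows, ignore_index=True)
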