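"""End-to-end orchestration: generate -> fit -> simulate -> allocate ->
report -> health expectancy, with a manifest so any run is reproducible
from the manifest alone.

Every output CSV starts with a ``# manifest: <hash>`` comment line; the
hash is a SHA-256 digest of the canonical JSON of the pipeline
configuration, so outputs from different configurations never collide
silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dementia import allocate_dementia, default_allocation_table
from .engine import RunConfig, run_replicates
from .errors import ConfigurationError
from .mortality import build_lifetable, make_toy_schedule
from .state import (DISEASES, DISEASES_AND_IMPAIRMENTS, DISEASES_ONLY,
                    IMPAIRMENT_FLAGS, SEX_LEVELS, default_registry,
                    registry_to_json)
from .sullivan import decompose_change, sullivan, surface_from_snapshot
from .synthetic import (PanelDataset, SyntheticConfig, default_truth_bundle,
                        generate_base_population, generate_panel,
                        write_population_csv)
from .tables import (multimorbidity_table, percent_change_table,
                     prevalence_table, mental_illhealth_overlap)
from .transitions import fit_bundle

REPORT_CONDITIONS = [d for d in DISEASES] + ["cind"] + list(IMPAIRMENT_FLAGS)


@dataclass
class PipelineConfig:
    """Everything a full run needs; see docs for field meanings."""

    n_individuals: int = 30_000
    panel_n: int | None = None          # panel size for fitting (default: n)
    seed: int = 0
    start_year: int = 2014
    start_month: int = 7
    horizon_year: int = 2035
    snapshot_month: int = 7
    n_replicates: int = 1
    scale_factor: float = 100.0
    panel_mode: str = "monthly"
    report_years: tuple[int, ...] = ()   # empty: auto (2015/2025/2035 window)
    from_age: int = 65

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "report_years" in raw:
            raw["report_years"] = tuple(raw["report_years"])
        return cls(**raw)

    def to_canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=list)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            self.to_canonical_json().encode()).hexdigest()[:16]

    def chosen_report_years(self, snapshot_years) -> list[int]:
        if self.report_years:
            return [y for y in self.report_years if y in snapshot_years]
        preferred = [y for y in (2015, 2025, 2035) if y in snapshot_years]
        if len(preferred) >= 2:
            return preferred
        ys = sorted(snapshot_years)
        return sorted({ys[0], ys[-1]})


def _write_csv(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the result summary dict.

    Artifacts written under ``outdir``: base/panel CSVs, registry and
    bundle JSON, mortality schedule, per-year snapshot CSVs (replicate 0,
    post allocation), reporting tables, health-expectancy and
    decomposition tables, replicate ranges, and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash
    seed = int(config.seed) & 0x7FFFFFFF
    registry = default_registry()
    summary: dict = {"manifest_hash": h}

    # --- generate ---------------------------------------------------------
    syn = SyntheticConfig(n_individuals=config.n_individuals, seed=seed,
                          scale_factor=config.scale_factor)
    base = generate_base_population(syn)
    write_population_csv(base, outdir / "base_population.csv",
                         header_comment=f"manifest: {h}")
    (outdir / "registry.json").write_text(registry_to_json(registry))

    schedule = make_toy_schedule(range(config.start_year,
                                       config.horizon_year + 1))
    schedule.table.to_csv(outdir / "mortality_schedule.csv", index=False)

    # --- fit --------------------------------------------------------------
    truth = default_truth_bundle(registry)
    panel_n = config.panel_n or config.n_individuals
    panel_base = (base if panel_n == len(base)
                  else generate_base_population(syn.with_n(panel_n,
                                                           seed + 1)))
    panel = generate_panel(panel_base, truth, seed=seed + 2,
                           mode=config.panel_mode, schedule=schedule,
                           registry=registry,
                           start_year=config.start_year)
    panel.to_csv(outdir / "panel.csv", header_comment=f"manifest: {h}")
    bundle = fit_bundle(panel, registry)
    (outdir / "bundle.json").write_text(bundle.to_json())
    (outdir / "truth_bundle.json").write_text(truth.to_json())

    # --- simulate + allocate ---------------------------------------------
    run_cfg = RunConfig(start_year=config.start_year,
                        start_month=config.start_month,
                        horizon_year=config.horizon_year,
                        snapshot_month=config.snapshot_month,
                        seed=seed, n_replicates=config.n_replicates,
                        scale_factor=config.scale_factor)
    outputs = run_replicates(base, bundle, schedule, run_cfg,
                             registry=registry)
    table = default_allocation_table()
    table.to_csv(outdir / "allocation_table.csv")
    allocated = [allocate_dementia(o, table, seed=seed + 100 + o.replicate)
                 for o in outputs]

    years = config.chosen_report_years(allocated[0].years)
    for year in years:
        _write_csv(allocated[0].snapshots[year],
                   outdir / f"snapshot_{year}.csv", h)

    # --- report -----------------------------------------------------------
    prev = prevalence_table(allocated[0], REPORT_CONDITIONS,
                            config.scale_factor)
    prev = prev[prev["year"].isin(years)]
    _write_csv(prev, outdir / "prevalence.csv", h)

    mm_tables = {}
    for cset in (DISEASES_ONLY, DISEASES_AND_IMPAIRMENTS):
        mm = multimorbidity_table(allocated[0], cset, config.scale_factor)
        mm = mm[mm["year"].isin(years)]
        mm_tables[cset.name] = mm
        _write_csv(mm, outdir / f"multimorbidity_{cset.name}.csv", h)

    if len(years) >= 2:
        changes = pd.concat(
            [percent_change_table(mm_tables["diseases_only"], years[0], y)
             for y in years[1:]], ignore_index=True)
        _write_csv(changes, outdir / "percent_change.csv", h)

    overlap = mental_illhealth_overlap(
        allocated[0].snapshots[years[0]], DISEASES_AND_IMPAIRMENTS)
    _write_csv(overlap, outdir / "mental_illhealth_overlap.csv", h)

    # --- replicate ranges -------------------------------------------------
    if config.n_replicates > 1:
        per_rep = []
        for alloc in allocated:
            mm = multimorbidity_table(alloc, DISEASES_ONLY,
                                      config.scale_factor)
            mm = mm[mm["year"].isin(years)].copy()
            mm["replicate"] = alloc.replicate
            per_rep.append(mm)
        stacked = pd.concat(per_rep, ignore_index=True)
        rng_tbl = (stacked.groupby(["year", "age_group", "category"])
                   ["prevalence_pct"]
                   .agg(["min", "max"]).reset_index())
        rng_tbl["range"] = rng_tbl["max"] - rng_tbl["min"]
        _write_csv(rng_tbl, outdir / "replicate_ranges.csv", h)
        summary["replicate_range_2plus_65plus"] = float(
            rng_tbl[(rng_tbl["age_group"] == "65+")
                    & (rng_tbl["category"] == "2+")]["range"].max())

    # --- health expectancy ------------------------------------------------
    he_rows, dec_rows = [], []
    terminal = schedule.terminal_age
    ages = np.arange(config.from_age, terminal + 1)
    year_a, year_b = years[0], years[-1]
    for sex in SEX_LEVELS:
        lts, surfs = {}, {}
        for year in years:
            lt = build_lifetable(schedule, year, sex, config.from_age)
            surf = surface_from_snapshot(allocated[0].snapshots[year],
                                         DISEASES_ONLY, sex, ages)
            lts[year], surfs[year] = lt, surf
            res = sullivan(lt, surf, config.from_age)
            he_rows.append({
                "year": year, "sex": sex, "total_le": res.total_le,
                **{f"years_{c}": res.years[c] for c in res.years},
                "years_2plus": res.years_at_least(2),
                "years_4plus": res.years_at_least(4),
            })
        if year_a != year_b:
            for cat in ("2+", "4+"):
                d = decompose_change(lts[year_a], surfs[year_a],
                                     lts[year_b], surfs[year_b], cat,
                                     config.from_age)
                dec_rows.append({
                    "sex": sex, "category": cat,
                    "year_a": year_a, "year_b": year_b,
                    "delta_years": d.delta,
                    "mortality_years": d.mortality_component,
                    "prevalence_years": d.prevalence_component,
                    "prevalence_share_pct": d.shares["prevalence"],
                })
    he = pd.DataFrame(he_rows)
    _write_csv(he, outdir / "health_expectancy.csv", h)
    if dec_rows:
        dec = pd.DataFrame(dec_rows)
        _write_csv(dec, outdir / "decomposition.csv", h)
        summary["decomposition"] = dec_rows

    summary["years"] = years
    summary["health_expectancy"] = he_rows
    mm65 = mm_tables["diseases_only"]
    summary["mm_2plus_65plus_pct"] = {
        int(y): float(mm65[(mm65["year"] == y) & (mm65["age_group"] == "65+")
                           & (mm65["category"] == "2+")]
                      ["prevalence_pct"].iloc[0])
        for y in years}

    manifest = {
        "hash": h,
        "config": json.loads(config.to_canonical_json()),
        "seed": seed,
        "version": __version__,
        "stages": ["generate", "fit", "simulate", "allocate", "report",
                   "healthexp"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
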