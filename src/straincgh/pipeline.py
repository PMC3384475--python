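"""End-to-end orchestration: simulate/ingest -> background-correct ->
normalize -> call -> gene content -> clustering -> island scan -> report
bundle. Runs are fully determined by (config, seed); every stage and every
parameter that affects output is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import calling, cluster, content, io, islands, normalize, simulate
from ._utils import ConfigError, round_half_up

log = logging.getLogger("straincgh")


@dataclass
class RunConfig:
    """Everything a run needs; load from YAML with :func:`load_config`."""

    outdir: Path = Path("straincgh-run")
    seed: int = 0
    mode: str = "synthetic"  # or "data"
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    noise: simulate.NoiseModel = field(default_factory=simulate.NoiseModel)
    derivatives: tuple[str, ...] = ("pMOL28", "pMOL30")
    # data mode inputs
    annotation: Path | None = None
    genesets: Path | None = None
    scans: tuple[Path, ...] = ()
    # normalization
    offset: float = normalize.DEFAULT_OFFSET
    span: float = 0.3
    loess_iterations: int = 4
    # calling
    cutoff: float = calling.DEFAULT_CUTOFF
    fold_mode: str = "per-spot"
    use_calibrated_cutoff: bool = False
    # clustering
    n_boot: int = 1000
    # island scan
    min_genes: int = 5
    max_gap: int = 2
    min_variable_frac: float = 0.8
    min_absent: int = 4

    def validate(self) -> None:
        if self.mode not in ("synthetic", "data"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "data":
            if self.annotation is None:
                raise ConfigError("data mode needs an annotation path")
            for p in (self.annotation, self.genesets, *self.scans):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
            if not self.scans:
                raise ConfigError("data mode needs at least one scan")


def _generator_from_dict(d: Mapping[str, Any]) -> simulate.GeneratorConfig:
    kwargs: dict[str, Any] = {}
    for key, value in d.items():
        if key == "island_plans":
            kwargs[key] = tuple(
                simulate.IslandPlan(
                    p["replicon"], int(p["count"]),
                    tuple(p.get("size_range", (5, 150))),
                )
                for p in value
            )
        elif key in ("replicons", "loci_per_replicon"):
            kwargs[key] = tuple((str(a), int(b)) for a, b in value)
        elif key in ("island_presence", "plasmid_presence"):
            items = value.items() if isinstance(value, Mapping) else value
            kwargs[key] = tuple((str(a), float(b)) for a, b in items)
        elif key in ("plasmid_replicons",):
            kwargs[key] = tuple(value)
        elif key == "grid":
            kwargs[key] = tuple(int(v) for v in value)
        else:
            kwargs[key] = value
    return simulate.GeneratorConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    known = {f.name for f in fields(RunConfig)}
    updates: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if key == "generator":
            updates[key] = _generator_from_dict(value)
        elif key == "noise":
            updates[key] = simulate.NoiseModel(**value)
        elif key in ("outdir", "annotation", "genesets"):
            updates[key] = Path(value)
        elif key == "scans":
            updates[key] = tuple(Path(v) for v in value)
        elif key == "derivatives":
            updates[key] = tuple(value)
        else:
            updates[key] = value
    cfg = replace(cfg, **updates)
    cfg.validate()
    return cfg


def _locus_fold(folds: calling.FoldChangeVector, probe_to_locus: pd.Series) -> pd.Series:
    """Mean valid fold per locus (NaN when every probe is flagged)."""
    locus = probe_to_locus.reindex(folds.fold.index)
    return folds.fold.groupby(locus.to_numpy(), sort=False).mean()


def run_pipeline(config: RunConfig) -> tuple[dict[str, Path], dict[str, Any]]:
    """Execute every stage; returns (file manifest, summary record)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, Path] = {}
    try:
        # --- stage 1: inputs -------------------------------------------------
        if config.mode == "synthetic":
            log.info(
                "simulate: seed=%d loci=%d groups=%d+%d derivatives=%s",
                config.seed, config.generator.n_loci,
                config.generator.n_group_i, config.generator.n_group_ii,
                list(config.derivatives),
            )
            model, contents, scans = simulate.simulate_panel(
                config.generator, config.noise, config.seed, config.derivatives
            )
            table = model.gene_table()
            io.write_gene_table(table, outdir / "annotation.tsv", outdir / "genesets.tsv")
            manifest["annotation"] = outdir / "annotation.tsv"
            manifest["genesets"] = outdir / "genesets.tsv"
            manifest["truth"] = io.write_truth(contents, model, outdir / "truth.tsv")
            island_sets = [r.name for r in model.islands()]
            by_strain = dict(zip([c.strain_id for c in contents], scans))
            panel = [c for c in contents if c.group in ("I", "II")]
            derivative_contents = [c for c in contents if c.group == "derivative"]
        else:
            log.info("ingest: %d scans, annotation=%s", len(config.scans), config.annotation)
            table = io.read_gene_table(config.annotation, config.genesets)
            scans = [io.read_spot_table(p) for p in config.scans]
            by_strain = {s.strain_id: s for s in scans}
            panel = None
            derivative_contents = []
            island_sets = list(table.gene_sets)
            model = None

        probe_to_locus = table.probe_to_locus()

        # --- stage 2+3: normalize and call ----------------------------------
        def folds_for(scan: io.ArrayScan) -> calling.FoldChangeVector:
            corrected, params = normalize.correct_scan(scan, offset=config.offset)
            ma = normalize.ma_values(corrected)
            normalize.printtip_loess(ma, span=config.span, iterations=config.loess_iterations)
            return calling.fold_change(
                corrected, mode=config.fold_mode, offset=config.offset,
                params_test=params["test"],
            )

        cutoff = config.cutoff
        calibration = None
        if derivative_contents:
            pairs = []
            for c in derivative_contents:
                fv = folds_for(by_strain[c.strain_id])
                truth = {
                    row.probe_id: row.locus_tag in c.present
                    for row in model.loci.itertuples(index=False)
                }
                pairs.append((fv, truth))
            calibration = calling.calibrate_cutoff(pairs)
            log.info(
                "calibrate: cutoff*=%.1f fp=%d fn=%d (known present=%d absent=%d)",
                calibration.cutoff,
                int(calibration.fp[np.argmin(calibration.total)]),
                int(calibration.fn[np.argmin(calibration.total)]),
                calibration.n_known_present, calibration.n_known_absent,
            )
            if config.use_calibrated_cutoff:
                cutoff = calibration.cutoff
        log.info("call: cutoff=%.1f fold_mode=%s offset=%.1f", cutoff,
                 config.fold_mode, config.offset)

        strain_ids = (
            [c.strain_id for c in panel] if panel is not None else list(by_strain)
        )
        calls_by_strain: dict[str, pd.Series] = {}
        folds_by_strain: dict[str, pd.Series] = {}
        for sid in strain_ids:
            fv = folds_for(by_strain[sid])
            calls_by_strain[sid] = calling.call_presence(fv, cutoff, probe_to_locus)
            folds_by_strain[sid] = _locus_fold(fv, probe_to_locus)
        matrix = calling.presence_matrix(
            calls_by_strain, folds_by_strain, gene_order=table.loci
        )

        # --- stage 4: gene content ------------------------------------------
        core, core_pct = content.core_set(matrix)
        shared = content.pairwise_overlap(matrix)
        occupancy = content.region_occupancy(matrix, table)
        log.info("content: core=%d (%.1f%%) of %d genes", len(core), core_pct,
                 len(matrix.genes))

        # --- stage 5: clustering --------------------------------------------
        log.info("cluster: complete linkage, n_boot=%d seed=%d", config.n_boot, config.seed)
        tree = cluster.bootstrap_support(matrix, n_boot=config.n_boot, seed=config.seed)
        island_occ = (
            occupancy.values.loc[[s for s in island_sets if s in occupancy.values.index]]
            if island_sets else None
        )
        group_i, group_ii = cluster.cut_two_groups(tree, island_occ)

        # --- stage 6: island scan -------------------------------------------
        log.info(
            "scan: min_genes=%d max_gap=%d min_variable_frac=%.2f min_absent=%d",
            config.min_genes, config.max_gap, config.min_variable_frac, config.min_absent,
        )
        found = islands.scan_islands(
            matrix, table,
            min_genes=config.min_genes, max_gap=config.max_gap,
            min_variable_frac=config.min_variable_frac, min_absent=config.min_absent,
            groups=(group_i, group_ii),
        )

        # --- stage 7: outputs -----------------------------------------------
        manifest.update(io.write_outputs(matrix, occupancy, found, tree, outdir))
        shared.counts.to_csv(outdir / "shared_counts.tsv", sep="\t")
        shared.pct.to_csv(outdir / "shared_pct.tsv", sep="\t", float_format="%.1f")
        manifest["shared_counts"] = outdir / "shared_counts.tsv"
        manifest["shared_pct"] = outdir / "shared_pct.tsv"
        groups_path = outdir / "groups.tsv"
        with open(groups_path, "w", encoding="utf-8") as fh:
            fh.write("strain\tgroup\n")
            for sid in sorted(group_i):
                fh.write(f"{sid}\tI\n")
            for sid in sorted(group_ii):
                fh.write(f"{sid}\tII\n")
        manifest["groups"] = groups_path
        if calibration is not None:
            calib_path = outdir / "calibration.tsv"
            pd.DataFrame(
                {"cutoff": calibration.grid, "fp": calibration.fp, "fn": calibration.fn}
            ).to_csv(calib_path, sep="\t", index=False)
            manifest["calibration"] = calib_path

        summary = summarize_run(manifest)
        summary["cutoff_used"] = cutoff
        if calibration is not None:
            summary["calibrated_cutoff"] = calibration.cutoff
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest["summary"] = outdir / "summary.json"
        io.write_manifest(manifest, outdir / "manifest.json")
        manifest["manifest"] = outdir / "manifest.json"
        return manifest, summary
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def summarize_run(manifest: Mapping[str, Path]) -> dict[str, Any]:
    """Abstract-level summary recomputed from the written report bundle."""
    required = ("presence_matrix", "occupancy", "islands_report", "groups")
    missing = [
        k for k in required if k not in manifest or not Path(manifest[k]).exists()
    ]
    if missing:
        raise ConfigError(f"incomplete manifest, missing: {missing}")
    matrix = io.read_presence_matrix(manifest["presence_matrix"])
    core, core_pct = content.core_set(matrix)
    occ = pd.read_csv(manifest["occupancy"], sep="\t", index_col="region", na_values="NA")
    groups = pd.read_csv(manifest["groups"], sep="\t", index_col="strain")["group"]
    report = pd.read_csv(manifest["islands_report"], sep="\t")

    def group_mean(label: str) -> float | None:
        cols = [s for s in groups.index[groups == label] if s in occ.columns]
        if not cols:
            return None
        return round_half_up(float(np.nanmean(occ[cols].to_numpy(dtype=float))), 1)

    return {
        "n_strains": len(matrix.strains),
        "n_genes": len(matrix.genes),
        "core_size": len(core),
        "core_fraction_pct": core_pct,
        "group_i": sorted(groups.index[groups == "I"]),
        "group_ii": sorted(groups.index[groups == "II"]),
        "group_i_mge_occupancy_mean_pct": group_mean("I"),
        "group_ii_mge_occupancy_mean_pct": group_mean("II"),
        "n_islands_detected": int(len(report)),
    }
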