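"""End-to-end orchestration: summarize -> MCW series -> PC_AUC ->
subsampling -> prioritization, from one YAML-serializable config.

Outputs are plain TSVs plus a JSON manifest recording seeds, stage status
and output-file hashes; rerunning the same config reproduces the TSVs
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .io import (
    read_expression_table,
    summarize,
    write_summary_table,
    write_expression_table,
)
from .mcw import DESIGNS, run_series, read_gmt
from .pcauc import pc_auc_curve
from .prioritize import cv_foldchange, make_random_lists, export_ranked_gene_list
from .replication import run_subsampling_study
from .simulate import preset, simulate, PRESETS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

DEFAULT_DESIGNS = ("unrestricted", "timepoint_restricted", "expression_restricted_2dp")


class ConfigError(ValueError):
    """Invalid run configuration (as opposed to invalid data)."""


@dataclass
class RunConfig:
    """One pipeline run.  Defaults follow the reference analysis settings:
    10,000 permutations per comparison, 1,000 subsampling iterations."""

    outdir: str = "regenhet_out"
    # either a synthetic preset ...
    preset: str | None = None
    n_probesets: int = 2000
    # ... or real input files
    expression_path: str | None = None
    metadata_path: str | None = None
    designs: tuple[str, ...] = DEFAULT_DESIGNS
    gene_sets: str | None = None  # GMT for functionally-restricted runs
    mapping_path: str | None = None  # probeset -> gene symbol TSV
    n_perm: int = 10_000
    n_iter: int = 1_000
    ks: tuple[int, ...] = (3, 4, 5, 6)
    seed: int = 0
    run_subsampling: bool = True
    run_prioritization: bool = True

    def validate(self) -> None:
        if (self.preset is None) == (self.expression_path is None):
            raise ConfigError("set exactly one of preset / expression_path")
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.expression_path is not None and self.metadata_path is None:
            raise ConfigError("expression_path requires metadata_path")
        bad = set(self.designs) - set(DESIGNS)
        if bad:
            raise ConfigError(f"unknown designs: {sorted(bad)}")
        if "functionally_restricted" in self.designs and not self.gene_sets:
            raise ConfigError("functionally_restricted requires gene_sets")
        if self.n_perm < 1 or self.n_iter < 1:
            raise ConfigError("n_perm and n_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("designs", "ks"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest.

    A stage failure is recorded in the manifest and re-raised after the
    manifest is written, so partial runs remain inspectable.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    failure: Exception | None = None

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = "ok"
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    try:
        # --- input
        if config.preset is not None:
            sim_cfg = preset(config.preset, seed=config.seed,
                             n_probesets=config.n_probesets)
            matrix, truth = simulate(sim_cfg)
            vpath = outdir / "expression.tsv"
            mpath = outdir / "samples.tsv"
            write_expression_table(matrix, vpath, mpath)
            tpath = outdir / "simulation_truth.tsv"
            truth.probesets.to_csv(tpath, sep="\t")
            record("simulate", [vpath, mpath, tpath])
        else:
            matrix = read_expression_table(config.expression_path, config.metadata_path)

        # --- summary
        summary = summarize(matrix)
        spath = outdir / "summary.tsv"
        write_summary_table(summary, spath)
        record("summarize", [spath])

        # --- MCW series + PC_AUC
        gene_sets = read_gmt(config.gene_sets) if config.gene_sets else {}
        mcw_files = []
        for design in config.designs:
            if design == "functionally_restricted":
                for set_name, members in gene_sets.items():
                    series = run_series(
                        summary, "cv", design, config.n_perm, config.seed,
                        subset=[m for m in members
                                if m in set(summary.wide("cv").index)],
                    )
                    f = outdir / f"mcw_cv_{design}_{set_name.replace(':', '_')}.tsv"
                    series.write_tsv(f)
                    mcw_files.append(f)
                continue
            for measure in ("cv", "mean") if design == "unrestricted" else ("cv",):
                series = run_series(summary, measure, design, config.n_perm, config.seed)
                f = outdir / f"mcw_{measure}_{design}.tsv"
                series.write_tsv(f)
                mcw_files.append(f)
                if measure == "cv":
                    curve = pc_auc_curve(series)
                    cf = outdir / f"pcauc_{design}.tsv"
                    curve.write_tsv(cf)
                    mcw_files.append(cf)
        record("mcw_pcauc", mcw_files)

        # --- subsampling
        if config.run_subsampling:
            study = run_subsampling_study(
                matrix, ks=config.ks, n_iter=config.n_iter, seed=config.seed
            )
            f = outdir / "subsampling.tsv"
            study.write_tsv(f)
            record("subsampling", [f])

        # --- prioritization
        if config.run_prioritization:
            needed = {0.5, 1.0, 1.5, 2.0}
            if needed <= set(summary.timepoints):
                ranking = cv_foldchange(summary)
                f = outdir / "ranked_probesets.tsv"
                ranking.in_rank_order.to_csv(f, sep="\t", index=False)
                files = [f]
                if config.mapping_path:
                    g = outdir / "ranked_genes.txt"
                    export_ranked_gene_list(ranking, config.mapping_path, g)
                    files.append(g)
                for i, rnd in enumerate(
                    make_random_lists(ranking, n_lists=10, seed=config.seed), 1
                ):
                    rf = outdir / f"random_list_{i:02d}.tsv"
                    rnd.in_rank_order[["probeset", "rank"]].to_csv(
                        rf, sep="\t", index=False
                    )
                    files.append(rf)
                record("prioritize", files)
            else:
                manifest["stages"]["prioritize"] = "skipped (0.5/1/1.5/2 d not all present)"
    except Exception as exc:  # noqa: BLE001 — manifest must record the failure
        failure = exc
        manifest["stages"]["failed"] = repr(exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if failure is not None:
        raise failure
    return manifest
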