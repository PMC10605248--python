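"""End-to-end orchestration: simulate, analyze, report, with a manifest.

A run executes the requested stages in dependency order on one global
seed, writes every result as TSV/JSON/PNG under the output directory,
and finishes with a Markdown report plus a manifest recording the seed,
a config hash and a SHA-256 digest of every output file.  Identical
seed and config give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .concordance import classify_degs, fc_lec_overlay
from .errors import AnalysisError, ConfigurationError, InputError
from .expression import CountMatrix, cpm, enrichment_ranking, nb_de_test
from .optics import auto_rois, compare_conditions, focal_ratio_curve
from .overlap import default_x_grid, overlap_sweep
from .plotting import (
    plot_contingency,
    plot_focal_curves,
    plot_overlap_sweep,
    plot_volcano,
)
from .synthetic import (
    CountsSimConfig,
    PlantedSet,
    StackSimConfig,
    reference_identity_sets,
    simulate_counts,
    simulate_dose_series,
)

log = logging.getLogger("lenscope")

ALL_STAGES = (
    "simulate_counts",
    "simulate_stacks",
    "optics",
    "de",
    "enrich",
    "overlap",
    "concordance",
    "report",
)

# Planted-set sizes as fractions of the gene universe (they scale with
# n_genes so reduced runs keep the same structure).
PLANT_FRACTIONS = {
    "3D_up": 291 / 10320,
    "2D_up": 191 / 10320,
    "internal_up": 200 / 10320,
    "external_up": 200 / 10320,
}
PLANT_GROUPS = {
    "3D_up": ("3D",),
    "2D_up": ("2D",),
    "internal_up": ("internal",),
    "external_up": ("external",),
}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serialisable)."""

    out_dir: str = "lenscope_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    fdr_cut: float = 0.05
    log2fc_cut: float = 1.0
    cpm_cut: float = 0.2
    x_step: float = 0.0025
    x_max: float = 0.10
    tail_convention: str = "greater"
    planted_log2_fold: float = 2.0
    concordance_rate: float = 0.8
    counts: dict = field(default_factory=dict)  # CountsSimConfig overrides
    stacks: dict = field(default_factory=dict)  # StackSimConfig overrides
    taus: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9)
    n_stacks_per_dose: int = 12
    inputs: dict = field(default_factory=dict)  # pre-existing counts/meta paths

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "taus" in raw:
            raw["taus"] = tuple(raw["taus"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _default_planted_sets(n_genes: int, fold: float) -> tuple[PlantedSet, ...]:
    sets = []
    start = 0
    for name, frac in PLANT_FRACTIONS.items():
        size = max(1, int(round(frac * n_genes)))
        sets.append(
            PlantedSet(name, tuple(range(start, start + size)), fold, PLANT_GROUPS[name])
        )
        start += size
    if start >= n_genes:
        raise ConfigurationError("n_genes too small for the default planted sets")
    return tuple(sets)


def _child_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.matrix: CountMatrix | None = None
        self.truth = None
        self.de_3d2d = None
        self.de_region = None
        self.rank_3d = None
        self.rank_lens = None
        self.sweep = None
        self.contingency = None
        self.comparison = None
        self.outputs: list[Path] = []

    # -- stages ---------------------------------------------------------

    def stage_simulate_counts(self) -> None:
        cfg = self.config
        overrides = dict(cfg.counts)
        n_genes = int(overrides.pop("n_genes", 10320))
        sim_cfg = CountsSimConfig(
            n_genes=n_genes,
            planted_sets=_default_planted_sets(n_genes, cfg.planted_log2_fold),
            shared_enriched_fraction_rho=overrides.pop(
                "shared_enriched_fraction_rho", 0.2
            ),
            seed=_child_seed(cfg.seed, "counts"),
            **overrides,
        )
        sim = simulate_counts(sim_cfg)
        self.matrix, self.truth = sim.matrix, sim.truth
        lio.write_counts(sim.matrix, self.out / "counts.tsv", self.out / "samples.tsv")
        lio.write_truth(sim, self.out / "planted_truth.json")
        self._record("counts.tsv", "samples.tsv", "planted_truth.json")

    def stage_simulate_stacks(self) -> None:
        cfg = self.config
        overrides = {"disk_transmittance": 0.85, "noise_model": "poisson"}
        overrides.update(cfg.stacks)
        base = StackSimConfig(**overrides)
        self.stacks_by_dose = simulate_dose_series(
            base, cfg.taus, cfg.n_stacks_per_dose, seed=_child_seed(cfg.seed, "stacks")
        )
        first = next(iter(self.stacks_by_dose.values()))[0]
        lio.write_zstack(first, self.out / "example_stack.tif", config=base)
        self._record("example_stack.tif", "example_stack.tif.json")

    def stage_optics(self) -> None:
        if not hasattr(self, "stacks_by_dose"):
            raise InputError("optics stage requires simulate_stacks")
        curves = {}
        for cond, stacks in self.stacks_by_dose.items():
            curves[cond] = []
            for st in stacks:
                rois = auto_rois(st)
                curves[cond].append(focal_ratio_curve(st, rois))
        doses = {cond: float(cond.split("=")[1]) for cond in curves}
        self.comparison = compare_conditions(curves, doses=doses)
        self.comparison.summary.to_csv(
            self.out / "focal_summary.tsv", sep="\t", index=False
        )
        self.comparison.mean_curves.to_csv(
            self.out / "focal_curves.tsv", sep="\t", index=False
        )
        self._record("focal_summary.tsv", "focal_curves.tsv")

    def _require_counts(self, stage: str) -> CountMatrix:
        if self.matrix is None:
            paths = self.config.inputs
            if {"counts", "samples"} <= set(paths):
                self.matrix = lio.read_counts(paths["counts"], paths["samples"])
            else:
                raise InputError(
                    f"stage '{stage}' needs counts: run simulate_counts or set "
                    "inputs.counts / inputs.samples"
                )
        return self.matrix

    def stage_de(self) -> None:
        cfg = self.config
        matrix = self._require_counts("de")
        self.de_3d2d = nb_de_test(
            matrix, "3D", "2D", cfg.fdr_cut, cfg.log2fc_cut, cfg.cpm_cut
        )
        lio.write_de_result(self.de_3d2d, self.out / "de_3D_vs_2D.tsv")
        self._record("de_3D_vs_2D.tsv")

    def stage_enrich(self) -> None:
        matrix = self._require_counts("enrich")
        mean_cpm = {
            g: cpm(matrix.subset_groups([g])).mean(axis=1)
            for g in ("3D", "lens", "WB")
        }
        self.rank_3d = enrichment_ranking(mean_cpm["3D"], mean_cpm["WB"], label="3D")
        self.rank_lens = enrichment_ranking(mean_cpm["lens"], mean_cpm["WB"], label="lens")
        lio.write_ranking(self.rank_3d, self.out / "enrichment_3D.tsv")
        lio.write_ranking(self.rank_lens, self.out / "enrichment_lens.tsv")
        self._record("enrichment_3D.tsv", "enrichment_lens.tsv")

    def stage_overlap(self) -> None:
        if self.rank_3d is None:
            raise InputError("overlap stage requires enrich")
        cfg = self.config
        self.sweep = overlap_sweep(
            self.rank_3d,
            self.rank_lens,
            default_x_grid(cfg.x_step, cfg.x_max),
            convention=cfg.tail_convention,
        )
        lio.write_overlap_sweep(
            self.sweep, self.out / "overlap_sweep.tsv", self.out / "overlap_genes.json"
        )
        self._record("overlap_sweep.tsv", "overlap_genes.json")

    def stage_concordance(self) -> None:
        cfg = self.config
        matrix = self._require_counts("concordance")
        self.de_region = nb_de_test(
            matrix, "internal", "external", cfg.fdr_cut, cfg.log2fc_cut, cfg.cpm_cut
        )
        lio.write_de_result(self.de_region, self.out / "de_internal_vs_external.tsv")
        if self.truth is None:
            raise InputError(
                "concordance stage needs planted truth to build synthetic "
                "reference sets; run simulate_counts"
            )
        rng = np.random.default_rng(_child_seed(cfg.seed, "reference_sets"))
        fc_set, lec_set = reference_identity_sets(
            self.truth.genes_of("internal_up"),
            self.truth.genes_of("external_up"),
            concordance=cfg.concordance_rate,
            rng=rng,
        )
        lio.write_gene_set(fc_set, self.out / "reference_fc.txt")
        lio.write_gene_set(lec_set, self.out / "reference_lec.txt")
        self.contingency, annotated = classify_degs(self.de_region, fc_set, lec_set)
        overlay, overlay_summary = fc_lec_overlay(self.de_region, fc_set, lec_set)
        annotated.to_csv(self.out / "concordance_annotated.tsv", sep="\t")
        overlay_summary.to_csv(self.out / "overlay_summary.tsv", sep="\t", index=False)
        payload = {
            "observed": self.contingency.observed.astype(int).tolist(),
            "expected": self.contingency.expected.tolist(),
            "chi_square": self.contingency.chi_square,
            "p_value": self.contingency.p_value,
            "continuity_correction": self.contingency.continuity_correction,
            "row_labels": list(self.contingency.row_labels),
            "col_labels": list(self.contingency.col_labels),
        }
        (self.out / "contingency.json").write_text(json.dumps(payload, indent=2))
        self._record(
            "de_internal_vs_external.tsv",
            "reference_fc.txt",
            "reference_lec.txt",
            "concordance_annotated.tsv",
            "overlay_summary.tsv",
            "contingency.json",
        )

    def stage_report(self) -> None:
        lines = ["# lenscope run report", ""]
        if self.comparison is not None:
            plot_focal_curves(self.comparison, self.out / "fig_focal_curves.png")
            self._record("fig_focal_curves.png")
            lines += [
                "## Light focusing by condition",
                "",
                "![focal curves](fig_focal_curves.png)",
                "",
                "```\n" + self.comparison.summary.to_string(index=False) + "\n```",
                "",
            ]
            if self.comparison.trend_rho is not None:
                lines.append(
                    f"Spearman trend of peak ratio vs dose: rho = "
                    f"{self.comparison.trend_rho:.3f} (p = {self.comparison.trend_p:.2e})"
                )
                lines.append("")
        if self.de_3d2d is not None:
            plot_volcano(self.de_3d2d, self.out / "fig_volcano_3D_vs_2D.png")
            self._record("fig_volcano_3D_vs_2D.png")
            up_a = len(self.de_3d2d.genes_called("up_A"))
            up_b = len(self.de_3d2d.genes_called("up_B"))
            lines += [
                "## Differential expression (3D vs 2D)",
                "",
                "![volcano](fig_volcano_3D_vs_2D.png)",
                "",
                f"{self.de_3d2d.n_degs} DEGs at FDR < {self.de_3d2d.fdr_cut} and "
                f"|log2FC| > {self.de_3d2d.log2fc_cut}: {up_a} up in 3D, {up_b} up in 2D.",
                "",
            ]
        if self.sweep is not None:
            plot_overlap_sweep(self.sweep, self.out / "fig_overlap_sweep.png")
            self._record("fig_overlap_sweep.png")
            t = self.sweep.table
            last = t.iloc[-1]
            lines += [
                "## Enrichment overlap sweep (3D vs lens)",
                "",
                "![overlap sweep](fig_overlap_sweep.png)",
                "",
                f"At the top {100 * last['x']:g}%: {int(last['observed'])} shared genes, "
                f"{last['expected']:.1f} expected by chance "
                f"(hypergeometric p = {last['p_value']:.2e}, tail '{self.sweep.tail_convention}').",
                "",
            ]
        if self.contingency is not None:
            plot_contingency(self.contingency, self.out / "fig_contingency.png")
            self._record("fig_contingency.png")
            lines += [
                "## Regional DEG vs reference identity",
                "",
                "![contingency](fig_contingency.png)",
                "",
                f"chi-squared = {self.contingency.chi_square:.2f}, "
                f"p = {self.contingency.p_value:.2e}.",
                "",
            ]
        (self.out / "report.md").write_text("\n".join(lines))
        self._record("report.md")

    # -- bookkeeping ----------------------------------------------------

    def _record(self, *names: str) -> None:
        for name in names:
            self.outputs.append(self.out / name)

    def write_manifest(self) -> Path:
        entries = {}
        for path in self.outputs:
            entries[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "stages": list(self.config.stages),
            "outputs": entries,
        }
        path = self.out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the configured stages in dependency order.

    A stage failure aborts the run with the failing stage named; outputs
    written before the failure are retained on disk.
    """
    run = PipelineRun(config)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s", stage)
        method = getattr(run, f"stage_{stage}")
        try:
            method()
        except Exception as exc:
            run.write_manifest()
            raise AnalysisError(f"stage '{stage}' failed: {exc}") from exc
    run.write_manifest()
    return run
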