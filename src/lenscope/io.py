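"""Readers and writers for the package's on-disk formats.

Stacks travel as multi-page TIFF (one page per z-slice) with a JSON
sidecar holding z-positions and the generating config; counts as TSV
(genes in rows) with a TSV sample sheet and a JSON planted-truth file;
analysis results as plain TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .expression import CountMatrix, DEResult, EnrichmentRanking
from .optics import FocalCurve, ZStack
from .overlap import OverlapSweep
from .synthetic import PlantedTruth, SimulatedCounts

__all__ = [
    "write_zstack",
    "read_zstack",
    "write_counts",
    "read_counts",
    "write_truth",
    "write_de_result",
    "read_de_result",
    "write_ranking",
    "read_ranking",
    "write_focal_curve",
    "write_overlap_sweep",
    "read_gene_set",
    "write_gene_set",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_zstack(stack: ZStack, path: str | Path, config=None) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with z-positions."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.intensities), photometric="minisblack")
    meta = {"z_positions_um": list(map(float, stack.z_positions))}
    if stack.pixel_size is not None:
        meta["pixel_size_um"] = stack.pixel_size
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_zstack(path: str | Path) -> ZStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        z = np.asarray(meta["z_positions_um"], dtype=float)
        pixel_size = meta.get("pixel_size_um")
    else:
        z = np.arange(data.shape[0], dtype=float)
        pixel_size = None
    return ZStack(intensities=data, z_positions=z, pixel_size=pixel_size)


def write_counts(matrix: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    """Counts TSV (genes in rows, header = sample ids) + sample sheet TSV."""
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    if "group" not in meta.columns:
        raise InputError("sample sheet must have a 'group' column")
    return CountMatrix(counts=counts, sample_meta=meta)


def write_truth(sim: SimulatedCounts, path: str | Path) -> None:
    """JSON planted-truth file: each set's gene ids, fold and groups."""
    truth: PlantedTruth = sim.truth
    payload = {
        "seed": sim.config.seed,
        "n_genes": sim.config.n_genes,
        "dispersion_alpha": sim.config.dispersion_alpha,
        "sets": [
            {
                "name": ps.name,
                "genes": [truth.gene_ids[g] for g in ps.genes],
                "log2_fold": ps.log2_fold,
                "groups": list(ps.groups),
            }
            for ps in truth.sets
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_de_result(de: DEResult, path: str | Path) -> None:
    out = de.table.copy()
    out.insert(0, "gene", out.index)
    header = (
        f"# contrast: {de.group_a} vs {de.group_b}; fdr_cut={de.fdr_cut}; "
        f"log2fc_cut={de.log2fc_cut}; cpm_cut={de.cpm_cut}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)


def read_de_result(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene")


def write_ranking(ranking: EnrichmentRanking, path: str | Path) -> None:
    out = ranking.table.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path, label: str = "") -> EnrichmentRanking:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    if not {"score", "rank"} <= set(table.columns):
        raise InputError("ranking TSV needs 'score' and 'rank' columns")
    return EnrichmentRanking(table=table[["score", "rank"]], label=label)


def write_focal_curve(curve: FocalCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_overlap_sweep(sweep: OverlapSweep, table_path: str | Path,
                        intersections_path: str | Path | None = None) -> None:
    sweep.table.to_csv(table_path, sep="\t", index=False)
    if intersections_path is not None:
        Path(intersections_path).write_text(
            json.dumps({f"{x:g}": genes for x, genes in sweep.intersections.items()},
                       indent=2)
        )


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line; a two-column (gene, identity) TSV also works."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line.split("\t")[0])
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
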