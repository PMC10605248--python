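"""Synthetic z-stacks and count matrices with planted, recoverable structure.

Two generators stand in for the study's raw data so every downstream
analysis is testable without downloads.

**Z-stacks** use a geometric defocus-cone model: a transparent spheroid
concentrates transmitted light into a radially symmetric Gaussian spot
whose width grows linearly away from the focal plane,

    sigma(z) = sigma0 + s * |z - z_f|,
    A(z)     = F * (1 - tau) / (2 * pi * sigma(z)^2),

so the slice-integrated flux above background is conserved across z and
the peak amplitude is maximal at the planted focal plane z_f.  Opacity
tau in [0, 1] attenuates the transmitted flux multiplicatively — the
simplest monotone link between a cataractogenic treatment dose and lost
focusing; tau = 1 transmits nothing.  Slices are quantized to 16-bit
unsigned, matching common microscope cameras.

**Count matrices** draw gene-by-sample counts from a negative binomial
with mean s_i * q_g * 2^delta(g, group(i)) and a common dispersion:
q_g is a log-normal baseline, s_i scales each sample to a target library
size, and delta is the planted log2 fold change (0 when unplanted).  The
``shared_enriched_fraction_rho`` knob plants genes enriched in BOTH the
"lens" and "3D" groups relative to their references, creating a known
cross-dataset enrichment overlap for the sweep analysis to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import CountMatrix
from .optics import ZStack

__all__ = [
    "StackSimConfig",
    "CountsSimConfig",
    "PlantedSet",
    "PlantedTruth",
    "SimulatedCounts",
    "simulate_zstack",
    "simulate_counts",
    "simulate_dose_series",
    "reference_identity_sets",
]

DEFAULT_GROUP_SIZES: dict[str, int] = {
    "2D": 3,
    "3D": 3,
    "internal": 4,
    "external": 3,
    "lens": 3,
    "WB": 3,
}


@dataclass(frozen=True)
class StackSimConfig:
    """Parameters of the defocus-cone z-stack generator.

    Distances are micrometres, widths pixels.  ``disk_transmittance``
    scales the background inside the spheroid disk (1.0 = invisible
    disk); lowering it gives segmentation an object to find.
    """

    image_side: int = 256
    n_slices: int = 21
    z_min: float = -100.0
    z_max: float = 0.0
    z_f: float = -50.0
    background_b: float = 1000.0
    spot_flux_F: float = 2.0e6
    sigma0: float = 4.0
    cone_slope_s: float = 0.3
    opacity_tau: float = 0.0
    spheroid_radius: float = 60.0
    disk_transmittance: float = 1.0
    noise_model: str = "none"  # none | poisson | gaussian
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_side < 32:
            raise ConfigurationError("image_side must be >= 32")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if not (self.z_min <= self.z_f <= self.z_max):
            raise ConfigurationError("z_f must satisfy z_min <= z_f <= z_max")
        if not 0.0 <= self.opacity_tau <= 1.0:
            raise ConfigurationError("opacity_tau must be in [0, 1]")
        if self.sigma0 <= 0:
            raise ConfigurationError("sigma0 must be > 0")
        if self.cone_slope_s < 0:
            raise ConfigurationError("cone_slope_s must be >= 0")
        if self.background_b < 0:
            raise ConfigurationError("background_b must be >= 0")
        if self.spot_flux_F < 0:
            raise ConfigurationError("spot_flux_F must be >= 0")
        if self.spheroid_radius <= 0:
            raise ConfigurationError("spheroid_radius must be > 0")
        if not 0.0 < self.disk_transmittance <= 1.0:
            raise ConfigurationError("disk_transmittance must be in (0, 1]")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ConfigurationError("noise_model must be none, poisson or gaussian")
        if self.noise_model == "gaussian" and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def spot_amplitude(cfg: StackSimConfig, z: float) -> float:
    """Closed-form peak amplitude A(z) of the defocus-cone spot."""
    sigma = cfg.sigma0 + cfg.cone_slope_s * abs(z - cfg.z_f)
    return cfg.spot_flux_F * (1.0 - cfg.opacity_tau) / (2.0 * math.pi * sigma**2)


def simulate_zstack(cfg: StackSimConfig) -> ZStack:
    """Render a multi-slice stack under the defocus-cone model.

    Deterministic for a fixed seed; slices are quantized to uint16 with
    clipping after noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_side
    if cfg.n_slices == 1:
        z_positions = np.array([cfg.z_min], dtype=float)
    else:
        z_positions = np.linspace(cfg.z_min, cfg.z_max, cfg.n_slices)
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    in_disk = r2 <= cfg.spheroid_radius**2

    slices = np.empty((cfg.n_slices, n, n), dtype=np.uint16)
    for k, z in enumerate(z_positions):
        img = np.full((n, n), cfg.background_b, dtype=float)
        img[in_disk] *= cfg.disk_transmittance
        sigma = cfg.sigma0 + cfg.cone_slope_s * abs(z - cfg.z_f)
        amp = spot_amplitude(cfg, z)
        if amp > 0:
            img[in_disk] += amp * np.exp(-r2[in_disk] / (2.0 * sigma**2))
        if cfg.noise_model == "poisson":
            img = rng.poisson(img).astype(float)
        elif cfg.noise_model == "gaussian":
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        slices[k] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return ZStack(intensities=slices, z_positions=z_positions)


def simulate_dose_series(
    base: StackSimConfig,
    taus: Sequence[float],
    n_per_dose: int = 12,
    seed: int = 0,
) -> dict[str, list[ZStack]]:
    """Replicate stacks across an opacity dose series.

    Returns ``{"tau=<t>": [ZStack, ...]}`` with independent seeds per
    stack, mirroring a dose-response experiment with ``n_per_dose``
    organoids per condition.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, list[ZStack]] = {}
    for tau in taus:
        cond = f"tau={tau:g}"
        out[cond] = []
        for child in ss.spawn(n_per_dose):
            s = int(child.generate_state(1)[0] % (2**31))
            out[cond].append(simulate_zstack(replace(base, opacity_tau=tau, seed=s)))
    return out


@dataclass(frozen=True)
class PlantedSet:
    """A named gene set carrying a log2 fold change in specific groups."""

    name: str
    genes: tuple[int, ...]
    log2_fold: float
    groups: tuple[str, ...]


@dataclass(frozen=True)
class CountsSimConfig:
    """Parameters of the NB count-matrix generator.

    Defaults mirror the study design: a 10,320-gene universe and group
    sizes of 3 (2D, 3D, external, lens, WB) or 4 (internal) samples.
    ``shared_enriched_fraction_rho`` plants ``enriched_fraction`` of the
    genome as enriched in "lens" and in "3D" with that fraction of the
    two sets shared.
    """

    n_genes: int = 10320
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    baseline_log_mean_mu: float = 3.0
    baseline_log_mean_sd: float = 1.5
    dispersion_alpha: float = 0.1
    planted_sets: tuple[PlantedSet, ...] = ()
    shared_enriched_fraction_rho: float = 0.0
    enriched_fraction: float = 0.10
    enrichment_log2_fold: float = 2.0
    library_size_range: tuple[float, float] = (5.0e5, 1.5e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.group_sizes:
            raise ConfigurationError("group_sizes must be non-empty")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigurationError("group_sizes entries must be >= 1")
        if self.dispersion_alpha < 0:
            raise ConfigurationError("dispersion_alpha must be >= 0")
        if not 0.0 <= self.shared_enriched_fraction_rho <= 1.0:
            raise ConfigurationError("shared_enriched_fraction_rho must be in [0, 1]")
        if not 0.0 < self.enriched_fraction <= 1.0:
            raise ConfigurationError("enriched_fraction must be in (0, 1]")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("library_size_range must be positive and ordered")
        for ps in self.planted_sets:
            if not ps.genes:
                raise ConfigurationError(f"planted set {ps.name!r} is empty")
            if max(ps.genes) >= self.n_genes or min(ps.genes) < 0:
                raise ConfigurationError(
                    f"planted set {ps.name!r} has gene index outside [0, n_genes)"
                )
            unknown = set(ps.groups) - set(self.group_sizes)
            if unknown:
                raise ConfigurationError(
                    f"planted set {ps.name!r} targets unknown groups {sorted(unknown)}"
                )


@dataclass
class PlantedTruth:
    """Ground truth of a simulated count matrix."""

    sets: tuple[PlantedSet, ...]
    gene_ids: pd.Index

    def fold_by_gene(self, group: str) -> dict[str, float]:
        """Planted log2 fold of every affected gene id in ``group``."""
        out: dict[str, float] = {}
        for ps in self.sets:
            if group in ps.groups:
                for g in ps.genes:
                    out[self.gene_ids[g]] = out.get(self.gene_ids[g], 0.0) + ps.log2_fold
        return out

    def genes_of(self, set_name: str) -> list[str]:
        for ps in self.sets:
            if ps.name == set_name:
                return [self.gene_ids[g] for g in ps.genes]
        raise KeyError(set_name)


@dataclass
class SimulatedCounts:
    matrix: CountMatrix
    truth: PlantedTruth
    config: CountsSimConfig


def _rho_sets(cfg: CountsSimConfig, rng: np.random.Generator) -> tuple[PlantedSet, ...]:
    """Auto-planted 'lens' and '3D' enrichment sets sharing a rho fraction."""
    n_e = int(round(cfg.enriched_fraction * cfg.n_genes))
    n_shared = int(round(cfg.shared_enriched_fraction_rho * n_e))
    taken = {g for ps in cfg.planted_sets for g in ps.genes}
    free = np.array([g for g in range(cfg.n_genes) if g not in taken])
    need = 2 * n_e - n_shared
    if len(free) < need:
        raise ConfigurationError(
            "not enough unplanted genes for the rho-shared enrichment sets"
        )
    pick = rng.choice(free, size=need, replace=False)
    shared = pick[:n_shared]
    lens_only = pick[n_shared : n_e]
    three_d_only = pick[n_e : need]
    fold = cfg.enrichment_log2_fold
    return (
        PlantedSet("lens_enriched", tuple(np.sort(np.r_[shared, lens_only])), fold, ("lens",)),
        PlantedSet("3D_enriched", tuple(np.sort(np.r_[shared, three_d_only])), fold, ("3D",)),
    )


def simulate_counts(cfg: CountsSimConfig) -> SimulatedCounts:
    """Draw an NB count matrix across all configured groups.

    Deterministic for a fixed seed.  Raises a configuration error if two
    planted sets assign a fold to the same (gene, group) pair.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sets = tuple(cfg.planted_sets)
    if cfg.shared_enriched_fraction_rho > 0:
        sets = sets + _rho_sets(cfg, rng)

    groups = list(cfg.group_sizes)
    delta = np.zeros((cfg.n_genes, len(groups)))
    assigned: set[tuple[int, str]] = set()
    for ps in sets:
        for grp in ps.groups:
            j = groups.index(grp)
            for g in ps.genes:
                if (g, grp) in assigned:
                    raise ConfigurationError(
                        f"gene index {g} has conflicting planted folds in group {grp!r}"
                    )
                assigned.add((g, grp))
                delta[g, j] = ps.log2_fold

    q = np.exp(rng.normal(cfg.baseline_log_mean_mu, cfg.baseline_log_mean_sd, cfg.n_genes))
    gene_ids = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene")

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    lo, hi = cfg.library_size_range
    for j, grp in enumerate(groups):
        expr = q * np.exp2(delta[:, j])
        total = expr.sum()
        for k in range(cfg.group_sizes[grp]):
            target = rng.uniform(lo, hi)
            mean = expr * (target / total)
            if cfg.dispersion_alpha == 0:
                counts = rng.poisson(mean)
            else:
                r = 1.0 / cfg.dispersion_alpha
                counts = rng.negative_binomial(r, r / (r + mean))
            sample = f"{grp}_{k + 1}"
            columns[sample] = counts
            meta_rows.append({"sample": sample, "group": grp})

    counts_df = pd.DataFrame(columns, index=gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    meta["library_size"] = counts_df.sum(axis=0)
    matrix = CountMatrix(counts=counts_df, sample_meta=meta)
    truth = PlantedTruth(sets=sets, gene_ids=gene_ids)
    return SimulatedCounts(matrix=matrix, truth=truth, config=cfg)


def reference_identity_sets(
    internal_up: Iterable[str],
    external_up: Iterable[str],
    concordance: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[set[str], set[str]]:
    """Build synthetic fiber-cell / epithelial reference gene sets.

    Each internal-up gene is assigned to the fiber-cell (FC) set with
    probability ``concordance`` and to the epithelial (LEC) set
    otherwise, and symmetrically for external-up genes — emulating a
    reference atlas that mostly, but not perfectly, agrees with the
    regional expression pattern.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fc: set[str] = set()
    lec: set[str] = set()
    for g in internal_up:
        (fc if rng.random() < concordance else lec).add(g)
    for g in external_up:
        (lec if rng.random() < concordance else fc).add(g)
    return fc, lec
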