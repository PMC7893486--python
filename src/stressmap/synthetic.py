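"""Synthetic multi-donor atlas, mask, gene-set and single-cell generators.

The generators emulate the statistical structure the analysis assumes, with
a recorded ground truth so every pipeline stage can be tested for recovery:

* expression: x_{g,s,d} = mu_g + (beta_g + u_{g,d}) * 1[s in-mask] + eps,
  with a broad log2-scale baseline mu_g, a planted in-network shift beta_g
  (= delta for a random subset of genes, 0 otherwise), per-donor gene-wise
  heterogeneity u_{g,d} ~ N(0, tau_g^2) with tau_g uniform over a range, and
  residual noise eps ~ N(0, sigma^2);
* geometry: a contiguous voxel block in a small MNI-like volume (2 mm
  isotropic voxels by default); in-network samples sit at distinct in-mask
  voxel centers (sub-half-voxel jitter), out-of-network samples at distinct
  out-of-mask centers;
* gene sets: members drawn so that the odds of membership among planted
  genes versus the rest equal a requested enrichment factor, plus a receptor
  universe tag list, a neuropeptide list, and disjoint corticosteroid
  (GR/MR) target sets;
* single cell: negative-binomial counts over clusters assigned to the three
  cell classes, with a configurable multiplicative elevation of planted-gene
  means in glutamatergic clusters.

Every generator is a pure function of its configuration (including the
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .atlas_io import DonorExpression, GeneSetCollection, StressMask


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study-scale defaults: six donors, ~20k-gene atlas scaled to 2000 genes,
    111 in-network and 1839 out-of-network samples."""

    donor_count: int = 6
    gene_count: int = 2000
    in_samples: int = 111
    out_samples: int = 1839
    effect_size: float = 0.8
    planted_fraction: float = 0.1
    tau_range: tuple[float, float] = (0.0, 0.3)
    sigma: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    structure_props: dict[str, float] = field(
        default_factory=lambda: {
            "cortex": 0.70,
            "cerebellum": 0.15,
            "hippocampal formation": 0.15,
        }
    )
    voxel_size: float = 2.0
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    jitter: float = 0.45  # max |offset| per axis, as a fraction of voxel size
    # gene-set generation
    n_gene_sets: int = 10
    gene_set_size: int = 100
    planted_set_factor: float = 5.0
    receptor_universe_size: int = 1203
    neuropeptide_size: int = 100
    grmr_fracs: tuple[float, float, float] = (0.035, 0.062, 0.023)
    # single-cell generation
    sc_clusters_per_class: int = 8
    sc_cells_per_cluster: int = 40
    sc_elevation: float = 3.0
    sc_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.donor_count, self.gene_count, self.in_samples, self.out_samples) < 1:
            raise ConfigError("counts must be positive")
        if not 0 <= self.planted_fraction <= 1:
            raise ConfigError("planted_fraction must lie in [0, 1]")
        if self.tau_range[0] < 0 or self.tau_range[1] < self.tau_range[0]:
            raise ConfigError("invalid tau_range")
        if not 0 <= self.jitter < 0.5:
            raise ConfigError("jitter must be < half a voxel width")
        total = sum(self.structure_props.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("structure proportions must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for recovery tests."""

    planted_genes: list[str]
    effect_sizes: dict[str, float]
    tau_per_gene: dict[str, float]
    planted_set_overlaps: dict[str, float]
    seed: int
    donor_count: int
    gene_count: int
    in_samples: int
    out_samples: int
    donor_in_counts: dict[str, int] = field(default_factory=dict)
    donor_out_counts: dict[str, int] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    return [base + (1 if i < total % parts else 0) for i in range(parts)]


# ---------------------------------------------------------------------------
# mask
# ---------------------------------------------------------------------------


def generate_mask(cfg: SimConfig) -> StressMask:
    """Contiguous cubic voxel block, centered, sized to hold the in-network samples."""
    side = max(1, math.ceil(cfg.in_samples ** (1.0 / 3.0)))
    shape = cfg.volume_shape
    if any(side > n for n in shape):
        raise ConfigError(
            f"in_samples={cfg.in_samples} needs a {side}^3 block exceeding volume {shape}"
        )
    start = [(n - side) // 2 for n in shape]
    voxels = frozenset(
        (start[0] + i, start[1] + j, start[2] + k)
        for i in range(side)
        for j in range(side)
        for k in range(side)
    )
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    return StressMask(affine=affine, shape=shape, voxels=voxels)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def generate_atlas(
    cfg: SimConfig,
) -> tuple[list[DonorExpression], pd.DataFrame, SyntheticTruth]:
    """Multi-donor expression with a planted in-network shift.

    Returns the per-donor matrices, the combined sample table (MNI
    coordinates, structure labels, is_cortex) and the ground truth.
    In-network samples are cortical; out-of-network structures follow
    ``cfg.structure_props``.
    """
    mask = generate_mask(cfg)
    if cfg.in_samples > len(mask.voxels):
        raise ConfigError("in_samples exceeds mask capacity")
    n_out_voxels = int(np.prod(cfg.volume_shape)) - len(mask.voxels)
    if cfg.out_samples > n_out_voxels:
        raise ConfigError("out_samples exceeds out-of-mask voxel capacity")
    rng = _rng(cfg, stream=1)
    G = cfg.gene_count
    gene_ids = [f"G{i:05d}" for i in range(1, G + 1)]
    n_planted = round(cfg.planted_fraction * G)
    planted_idx = np.sort(rng.choice(G, size=n_planted, replace=False))
    beta = np.zeros(G)
    beta[planted_idx] = cfg.effect_size
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    tau = rng.uniform(cfg.tau_range[0], cfg.tau_range[1], size=G)

    # geometry: distinct voxel centers, jittered by < half a voxel
    mask_vox = np.array(sorted(mask.voxels))
    in_pick = mask_vox[rng.choice(len(mask_vox), size=cfg.in_samples, replace=False)]
    all_idx = np.argwhere(np.ones(cfg.volume_shape, dtype=bool))
    in_set = set(map(tuple, mask_vox.tolist()))
    out_vox = np.array([v for v in all_idx.tolist() if tuple(v) not in in_set])
    out_pick = out_vox[rng.choice(len(out_vox), size=cfg.out_samples, replace=False)]

    donor_ids = [f"donor{i}" for i in range(1, cfg.donor_count + 1)]
    in_counts = _split_counts(cfg.in_samples, cfg.donor_count)
    out_counts = _split_counts(cfg.out_samples, cfg.donor_count)

    out_structures = list(cfg.structure_props)
    out_probs = np.array([cfg.structure_props[s] for s in out_structures])

    donors: list[DonorExpression] = []
    sample_rows = []
    in_cursor = out_cursor = 0
    for d, donor_id in enumerate(donor_ids):
        n_in, n_out = in_counts[d], out_counts[d]
        vox = np.vstack(
            [in_pick[in_cursor : in_cursor + n_in], out_pick[out_cursor : out_cursor + n_out]]
        )
        in_cursor += n_in
        out_cursor += n_out
        centers = vox * cfg.voxel_size
        jitter = rng.uniform(-cfg.jitter, cfg.jitter, size=centers.shape) * cfg.voxel_size
        xyz = centers + jitter
        in_flag = np.zeros(n_in + n_out)
        in_flag[:n_in] = 1.0
        u = rng.normal(0.0, 1.0, size=G) * tau
        eps = rng.normal(0.0, cfg.sigma, size=(G, n_in + n_out))
        values = mu[:, None] + np.outer(beta + u, in_flag) + eps
        sample_ids = [f"{donor_id}_s{i:04d}" for i in range(1, n_in + n_out + 1)]
        donors.append(
            DonorExpression(
                donor_id=donor_id,
                gene_ids=gene_ids,
                sample_ids=sample_ids,
                values=values,
            )
        )
        structures = ["cortex"] * n_in + list(
            rng.choice(out_structures, size=n_out, p=out_probs)
        )
        for s_id, (x, y, z), struct in zip(sample_ids, xyz, structures):
            sample_rows.append(
                {
                    "sample_id": s_id,
                    "donor_id": donor_id,
                    "mni_x": x,
                    "mni_y": y,
                    "mni_z": z,
                    "structure": struct,
                    "is_cortex": struct == "cortex",
                }
            )
    samples = pd.DataFrame(sample_rows)
    truth = SyntheticTruth(
        planted_genes=[gene_ids[i] for i in planted_idx],
        effect_sizes={gene_ids[i]: cfg.effect_size for i in planted_idx},
        tau_per_gene={g: float(t) for g, t in zip(gene_ids, tau)},
        planted_set_overlaps={},
        seed=cfg.seed,
        donor_count=cfg.donor_count,
        gene_count=G,
        in_samples=cfg.in_samples,
        out_samples=cfg.out_samples,
        donor_in_counts=dict(zip(donor_ids, in_counts)),
        donor_out_counts=dict(zip(donor_ids, out_counts)),
    )
    return donors, samples, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def _membership_probs(
    n_planted: int, n_other: int, target_size: int, factor: float
) -> tuple[float, float]:
    """Per-gene inclusion probabilities with odds(planted)/odds(other)=factor
    and expected set size ``target_size``."""
    if math.isinf(factor):
        if target_size > n_planted:
            raise ConfigError("infinite enrichment factor needs target_size <= planted genes")
        return 1.0, 0.0
    if factor <= 0:
        raise ConfigError("enrichment factor must be positive")
    if target_size > n_planted + n_other:
        raise ConfigError("target_size exceeds gene universe")

    def expected(p0: float) -> float:
        p1 = factor * p0 / (1.0 + (factor - 1.0) * p0)
        return n_planted * p1 + n_other * p0 - target_size

    p0 = scipy.optimize.brentq(expected, 1e-12, 1.0 - 1e-12)
    p1 = factor * p0 / (1.0 + (factor - 1.0) * p0)
    return p1, p0


def generate_gene_sets(truth: SyntheticTruth, cfg: SimConfig) -> GeneSetCollection:
    """Marker-like sets with known enrichment against the planted genes.

    Produces ``planted_set`` (odds of membership ``cfg.planted_set_factor``
    times higher among planted genes), ``random_set_1..n-1`` (factor 1), a
    ``receptor_universe`` tag list, a ``neuropeptides`` list, and disjoint
    ``gr_targets_only`` / ``mr_targets_only`` / ``gr_mr_targets`` sets.
    Records the factors in ``truth.planted_set_overlaps``.
    """
    rng = _rng(cfg, stream=2)
    G = truth.gene_count
    gene_ids = [f"G{i:05d}" for i in range(1, G + 1)]
    planted = np.zeros(G, dtype=bool)
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g in truth.planted_genes:
        planted[pos[g]] = True
    n_p = int(planted.sum())
    sets: dict[str, list[str]] = {}

    def draw(factor: float) -> list[str]:
        if math.isinf(factor):
            if cfg.gene_set_size > n_p:
                raise ConfigError(
                    "infinite enrichment factor needs gene_set_size <= planted genes"
                )
            members = rng.choice(
                np.array(gene_ids)[planted], size=cfg.gene_set_size, replace=False
            )
            return sorted(members)
        p1, p0 = _membership_probs(n_p, G - n_p, cfg.gene_set_size, factor)
        probs = np.where(planted, p1, p0)
        keep = rng.random(G) < probs
        return [g for g, k in zip(gene_ids, keep) if k]

    sets["planted_set"] = draw(cfg.planted_set_factor)
    truth.planted_set_overlaps["planted_set"] = cfg.planted_set_factor
    for i in range(1, cfg.n_gene_sets):
        name = f"random_set_{i}"
        sets[name] = draw(1.0)
        truth.planted_set_overlaps[name] = 1.0

    if cfg.receptor_universe_size > G:
        raise ConfigError("receptor universe larger than the gene universe")
    receptors = sorted(rng.choice(gene_ids, size=cfg.receptor_universe_size, replace=False))
    sets["receptor_universe"] = receptors
    sets["neuropeptides"] = sorted(
        rng.choice(gene_ids, size=min(cfg.neuropeptide_size, G), replace=False)
    )

    sizes = [max(1, round(f * G)) for f in cfg.grmr_fracs]
    if sum(sizes) > G:
        raise ConfigError("GR/MR target fractions exceed the gene universe")
    pick = rng.choice(gene_ids, size=sum(sizes), replace=False)
    sets["gr_targets_only"] = sorted(pick[: sizes[0]])
    sets["mr_targets_only"] = sorted(pick[sizes[0] : sizes[0] + sizes[1]])
    sets["gr_mr_targets"] = sorted(pick[sizes[0] + sizes[1] :])
    return GeneSetCollection(name="synthetic_sets", sets=sets, universe=gene_ids)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def generate_sc(
    cfg: SimConfig, planted_genes: list[str] | None = None
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Negative-binomial genes x cells counts over class-labelled clusters.

    Planted genes (default: the genes ``generate_atlas`` would plant under
    the same config) have their mean counts multiplied by ``cfg.sc_elevation``
    in glutamatergic clusters.  Returns (counts, gene_ids, cell table).
    """
    rng = _rng(cfg, stream=3)
    G = cfg.gene_count
    gene_ids = [f"G{i:05d}" for i in range(1, G + 1)]
    if planted_genes is None:
        atlas_rng = _rng(cfg, stream=1)
        n_planted = round(cfg.planted_fraction * G)
        planted_idx = np.sort(atlas_rng.choice(G, size=n_planted, replace=False))
        planted_genes = [gene_ids[i] for i in planted_idx]
    pos = {g: i for i, g in enumerate(gene_ids)}
    planted = np.zeros(G, dtype=bool)
    for g in planted_genes:
        if g in pos:
            planted[pos[g]] = True

    classes = ("GABAergic", "glutamatergic", "non-neuronal")
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    r = cfg.sc_dispersion
    blocks, cell_rows = [], []
    cell_counter = 0
    for cls in classes:
        for c in range(cfg.sc_clusters_per_class):
            cluster_id = f"{cls[:4]}_{c + 1}"
            mean = base_mean.copy()
            if cls == "glutamatergic":
                mean[planted] *= cfg.sc_elevation
            n_cells = cfg.sc_cells_per_cluster
            p_nb = r / (r + mean)
            counts = rng.negative_binomial(r, p_nb[:, None], size=(G, n_cells))
            blocks.append(counts)
            for _ in range(n_cells):
                cell_counter += 1
                cell_rows.append(
                    {
                        "cell_id": f"cell{cell_counter:05d}",
                        "cluster_id": cluster_id,
                        "cell_class": cls,
                    }
                )
    counts = np.hstack(blocks).astype(float)
    return counts, gene_ids, pd.DataFrame(cell_rows)
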