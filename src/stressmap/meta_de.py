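"""Meta-analytic differential expression between in- and out-of-network samples.

Each donor contributes one effect per gene: the difference in mean z-scored
expression between samples inside and outside the network mask,

    y_d = mean(in) - mean(out),        v_d = s_in^2/n_in + s_out^2/n_out,

with sample variances (ddof=1).  Per gene, donor effects are pooled with a
DerSimonian-Laird (DL) random-effects meta-analysis: fixed-effect weights
w_d = 1/v_d give the Q statistic, the moment estimator

    tau^2 = max(0, (Q - (k-1)) / C),   C = sum(w) - sum(w^2)/sum(w),

and random-effects weights w*_d = 1/(v_d + tau^2) give the pooled effect
mu = sum(w* y)/sum(w*) with SE = sum(w*)^(-1/2), a two-sided normal p-value
and a 95% CI.  Benjamini-Hochberg correction is applied across the genes of
one contrast scope.

A fold change cannot be derived from z-scores, so log2FC is the same DL
pooling applied to the *unstandardized* log2-scale mean differences
(sign convention: in-network minus out-of-network).

Bootstrap stability follows the resampling scheme of the source study:
repeatedly draw the same number of cortex samples as the network holds,
regardless of network membership, re-run the contrast against the original
in-network set, and track how often the reference gene list is recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .atlas_io import DonorExpression
from .mask_mapping import ContrastSpec, select_contrast

logger = logging.getLogger("stressmap")

#: sampling variances of 0 (constant groups) are floored here to avoid
#: infinite fixed-effect weights
VAR_FLOOR = 1e-8

#: normal 97.5% quantile used for the 95% confidence interval
Z_CRIT_95 = 1.959964


@dataclass(frozen=True)
class GeneEffect:
    """One donor's mean-difference effect for one gene."""

    gene_id: str
    donor_id: str
    y: float
    v: float
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("sampling variance must be >= 0")


@dataclass
class MetaResult:
    """DL-pooled result for one gene."""

    gene_id: str
    k: int
    mu_hat: float
    se: float
    z_stat: float
    p: float
    tau2: float
    q_stat: float
    ci_lo: float
    ci_hi: float
    p_bh: float = float("nan")
    log2fc: float = float("nan")
    significant: bool = False


@dataclass
class StabilityReport:
    """Outcome of the sample-resampling bootstrap."""

    B: int
    n_resample: int
    per_gene_frequency: dict[str, float]
    per_iteration_overlap: list[int]
    fraction_iterations_with_overlap: float
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.per_gene_frequency),
                "frequency": list(self.per_gene_frequency.values()),
            }
        )


# ---------------------------------------------------------------------------
# standardization and per-donor effects
# ---------------------------------------------------------------------------


def zscore_by_donor(
    expr: DonorExpression, scope_sample_ids: list[str]
) -> DonorExpression:
    """Per-gene z-scoring of one donor over the given sample scope.

    Returns the donor's matrix restricted to the scope samples with each gene
    standardized to mean 0, sd 1 (ddof=1) over that scope.  Genes with zero
    variance are set to all-zeros and listed in ``constant_genes``.
    """
    if expr.standardized:
        raise ValueError("expression is already standardized")
    if len(scope_sample_ids) < 2:
        raise ValueError("z-scoring needs >= 2 samples in scope")
    sub = expr.subset_samples(scope_sample_ids)
    if sub.n_samples != len(scope_sample_ids):
        missing = set(scope_sample_ids) - set(expr.sample_ids)
        raise ValueError(f"scope sample ids not in donor {expr.donor_id}: {sorted(missing)[:5]}")
    vals = sub.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat] = 0.0
    constant = tuple(g for g, f in zip(sub.gene_ids, flat) if f)
    if constant:
        logger.warning(
            "donor %s: %d constant gene(s) set to zero after z-scoring",
            expr.donor_id,
            len(constant),
        )
    return DonorExpression(
        donor_id=sub.donor_id,
        gene_ids=sub.gene_ids,
        sample_ids=sub.sample_ids,
        values=z,
        standardized=True,
        constant_genes=constant,
    )


def _effect_arrays(
    values: np.ndarray, in_idx: np.ndarray, out_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized y and v for all genes of one donor."""
    x_in = values[:, in_idx]
    x_out = values[:, out_idx]
    y = x_in.mean(axis=1) - x_out.mean(axis=1)
    v = x_in.var(axis=1, ddof=1) / x_in.shape[1] + x_out.var(axis=1, ddof=1) / x_out.shape[1]
    return y, v


def donor_effect(
    expr_z: DonorExpression, in_ids: list[str], out_ids: list[str], gene: str
) -> GeneEffect:
    """Mean-difference effect of one gene for one donor.

    y = mean(in) - mean(out); v = s_in^2/n_in + s_out^2/n_out (ddof=1).
    Both groups must have at least two samples.
    """
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValueError("both groups need >= 2 samples for a valid effect")
    pos = {s: i for i, s in enumerate(expr_z.sample_ids)}
    in_idx = np.array([pos[s] for s in in_ids])
    out_idx = np.array([pos[s] for s in out_ids])
    g = expr_z.gene_ids.index(gene)
    y, v = _effect_arrays(expr_z.values[[g], :], in_idx, out_idx)
    return GeneEffect(
        gene_id=gene,
        donor_id=expr_z.donor_id,
        y=float(y[0]),
        v=float(v[0]),
        n_in=len(in_ids),
        n_out=len(out_ids),
    )


# ---------------------------------------------------------------------------
# DerSimonian-Laird pooling
# ---------------------------------------------------------------------------


def _dl_pool_arrays(
    Y: np.ndarray, V: np.ndarray
) -> dict[str, np.ndarray]:
    """DL pooling for G genes x k donors at once; NaN marks a missing donor."""
    valid = np.isfinite(Y) & np.isfinite(V)
    Vf = np.where(valid, np.maximum(V, VAR_FLOOR), 1.0)
    Y0 = np.where(valid, Y, 0.0)
    w = np.where(valid, 1.0 / Vf, 0.0)
    k = valid.sum(axis=1)
    if (k == 0).any():
        raise ValueError("gene with zero valid donor effects")
    sw = w.sum(axis=1)
    y_fe = (w * Y0).sum(axis=1) / sw
    q = (w * (Y0 - y_fe[:, None]) ** 2 * valid).sum(axis=1)
    c = sw - (w**2).sum(axis=1) / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where(k > 1, np.maximum(0.0, (q - (k - 1)) / c), 0.0)
    ws = np.where(valid, 1.0 / (Vf + tau2[:, None]), 0.0)
    sws = ws.sum(axis=1)
    mu = (ws * Y0).sum(axis=1) / sws
    se = sws**-0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mu / se, np.sign(mu) * np.inf)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return {
        "k": k,
        "mu_hat": mu,
        "se": se,
        "z_stat": z,
        "p": p,
        "tau2": tau2,
        "q_stat": q,
        "ci_lo": mu - Z_CRIT_95 * se,
        "ci_hi": mu + Z_CRIT_95 * se,
    }


def dl_meta(effects: list[GeneEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of one gene's donor effects.

    With a single donor, tau^2 = 0 and the pooled effect equals that donor's
    effect.  Zero sampling variances are floored at ``VAR_FLOOR``.
    """
    if not effects:
        raise ValueError("no effects to pool")
    gene_ids = {e.gene_id for e in effects}
    if len(gene_ids) != 1:
        raise ValueError(f"effects span multiple genes: {sorted(gene_ids)}")
    if any(e.v == 0 for e in effects):
        logger.warning("gene %s: zero sampling variance floored at %g", effects[0].gene_id, VAR_FLOOR)
    Y = np.array([[e.y for e in effects]], dtype=float)
    V = np.array([[e.v for e in effects]], dtype=float)
    out = _dl_pool_arrays(Y, V)
    return MetaResult(
        gene_id=effects[0].gene_id,
        k=int(out["k"][0]),
        mu_hat=float(out["mu_hat"][0]),
        se=float(out["se"][0]),
        z_stat=float(out["z_stat"][0]),
        p=float(out["p"][0]),
        tau2=float(out["tau2"][0]),
        q_stat=float(out["q_stat"][0]),
        ci_lo=float(out["ci_lo"][0]),
        ci_hi=float(out["ci_hi"][0]),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contrast-level differential expression
# ---------------------------------------------------------------------------


def _contrast_tables(
    donors: list[DonorExpression],
    selection: dict[str, tuple[list[str], list[str]]],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-donor effect matrices for one contrast.

    Returns (gene_ids, Yz, Vz, Yraw, Vraw), each matrix G x k with NaN for
    donors skipped on a group-size guard.
    """
    by_id = {d.donor_id: d for d in donors}
    gene_ids = donors[0].gene_ids
    for d in donors[1:]:
        if d.gene_ids != gene_ids:
            raise ValueError("donors must share an identical gene list")
    cols: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    used_donors = []
    G = len(gene_ids)
    for donor_id, (in_ids, out_ids) in selection.items():
        if donor_id not in by_id:
            raise ValueError(f"membership references unknown donor {donor_id!r}")
        if len(in_ids) < 2 or len(out_ids) < 2:
            logger.info(
                "donor %s skipped: group sizes (%d, %d) below 2",
                donor_id,
                len(in_ids),
                len(out_ids),
            )
            continue
        expr = by_id[donor_id]
        scope = list(in_ids) + [s for s in out_ids if s not in set(in_ids)]
        z = zscore_by_donor(expr, scope)
        pos = {s: i for i, s in enumerate(z.sample_ids)}
        in_idx = np.array([pos[s] for s in in_ids])
        out_idx = np.array([pos[s] for s in out_ids])
        yz, vz = _effect_arrays(z.values, in_idx, out_idx)
        raw = expr.subset_samples(scope)
        pos_r = {s: i for i, s in enumerate(raw.sample_ids)}
        yr, vr = _effect_arrays(
            raw.values,
            np.array([pos_r[s] for s in in_ids]),
            np.array([pos_r[s] for s in out_ids]),
        )
        cols.append((yz, vz, yr, vr))
        used_donors.append(donor_id)
    if not cols:
        raise ValueError("no donor has both groups with >= 2 samples")
    Yz = np.column_stack([c[0] for c in cols])
    Vz = np.column_stack([c[1] for c in cols])
    Yr = np.column_stack([c[2] for c in cols])
    Vr = np.column_stack([c[3] for c in cols])
    return gene_ids, Yz, Vz, Yr, Vr


def run_de(
    donors: list[DonorExpression],
    membership: pd.DataFrame,
    spec: ContrastSpec | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Full differential-expression contrast: z-score, effects, DL pool, BH.

    Returns one row per gene (input gene order) with columns
    gene_id, k, mu_hat, se, z, p, p_bh, tau2, q, ci_lo, ci_hi, log2fc,
    significant.  Significance is BH-adjusted p < alpha; the
    whole-brain-minus-cerebellum scope additionally requires
    |log2fc| > ``lfc_threshold``.
    """
    spec = spec or ContrastSpec()
    selection = select_contrast(membership, spec)
    gene_ids, Yz, Vz, Yr, Vr = _contrast_tables(donors, selection)
    pooled = _dl_pool_arrays(Yz, Vz)
    pooled_raw = _dl_pool_arrays(Yr, Vr)
    p_bh = bh_adjust(pooled["p"])
    log2fc = pooled_raw["mu_hat"]
    significant = p_bh < alpha
    if spec.scope == "whole_brain_minus_cerebellum":
        significant = significant & (np.abs(log2fc) > lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "k": pooled["k"],
            "mu_hat": pooled["mu_hat"],
            "se": pooled["se"],
            "z": pooled["z_stat"],
            "p": pooled["p"],
            "p_bh": p_bh,
            "tau2": pooled["tau2"],
            "q": pooled["q_stat"],
            "ci_lo": pooled["ci_lo"],
            "ci_hi": pooled["ci_hi"],
            "log2fc": log2fc,
            "significant": significant,
        }
    )


def summarize_direction(de: pd.DataFrame) -> tuple[int, int, int]:
    """Counts of (higher-expressed, lower-expressed, total) significant genes."""
    if de.empty:
        raise ValueError("empty DE table")
    sig = de[de["significant"]]
    n_up = int((sig["mu_hat"] > 0).sum())
    n_down = int((sig["mu_hat"] < 0).sum())
    return n_up, n_down, int(len(sig))


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------


def _stratified_allocation(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` draws over strata."""
    quota = total * counts / counts.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return np.minimum(base, counts)


def bootstrap_stability(
    donors: list[DonorExpression],
    membership: pd.DataFrame,
    reference_de: list[str],
    B: int = 1000,
    n_resample: int = 111,
    seed: int | None = None,
    alpha: float = 0.05,
) -> StabilityReport:
    """Sample-resampling bootstrap of the cortical network contrast.

    Each iteration draws ``n_resample`` cortex samples without replacement —
    stratified across donors proportionally to their cortex sample counts —
    regardless of network membership, and contrasts the original in-network
    cortex samples against the drawn set with the same z-score / DL / BH
    procedure.  Reports the per-gene significance frequency, the per-iteration
    overlap with ``reference_de``, and the fraction of iterations with at
    least one overlapping gene.
    """
    cortex = membership[membership["is_cortex"]]
    donor_ids = sorted(cortex["donor_id"].unique())
    pool_counts = np.array(
        [int((cortex["donor_id"] == d).sum()) for d in donor_ids]
    )
    if n_resample > pool_counts.sum():
        raise ValueError(
            f"n_resample={n_resample} exceeds available cortex samples ({pool_counts.sum()})"
        )
    in_by_donor = {
        d: cortex.loc[(cortex["donor_id"] == d) & cortex["in_network"], "sample_id"].tolist()
        for d in donor_ids
    }
    pool_by_donor = {
        d: cortex.loc[cortex["donor_id"] == d, "sample_id"].to_numpy()
        for d in donor_ids
    }
    gene_ids = donors[0].gene_ids
    ref = set(reference_de)
    rng = np.random.default_rng(seed)
    alloc = _stratified_allocation(pool_counts, n_resample)
    sig_counts = np.zeros(len(gene_ids), dtype=int)
    overlaps: list[int] = []
    for _ in range(B):
        selection: dict[str, tuple[list[str], list[str]]] = {}
        for d, n_d in zip(donor_ids, alloc):
            drawn = rng.choice(pool_by_donor[d], size=int(n_d), replace=False)
            selection[d] = (in_by_donor[d], list(drawn))
        _, Yz, Vz, _, _ = _contrast_tables(donors, selection)
        pooled = _dl_pool_arrays(Yz, Vz)
        sig = bh_adjust(pooled["p"]) < alpha
        sig_counts += sig
        sig_genes = {g for g, s in zip(gene_ids, sig) if s}
        overlaps.append(len(sig_genes & ref))
    freq = {g: c / B for g, c in zip(gene_ids, sig_counts)} if B else {}
    frac = float(np.mean([o > 0 for o in overlaps])) if B else 0.0
    return StabilityReport(
        B=B,
        n_resample=n_resample,
        per_gene_frequency=freq,
        per_iteration_overlap=overlaps,
        fraction_iterations_with_overlap=frac,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# donor-consistency check
# ---------------------------------------------------------------------------


def leave_one_donor_out(
    donors: list[DonorExpression],
    membership: pd.DataFrame,
    spec: ContrastSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-pool excluding each donor in turn; report per-gene effect shifts.

    Returns a long table (excluded_donor, gene_id, mu_hat, delta_mu,
    significant, flipped) where delta_mu is the change versus the full-data
    pooled effect and ``flipped`` marks genes whose significance status
    changed.
    """
    if len(donors) < 2:
        raise ValueError("leave-one-donor-out needs >= 2 donors")
    full = run_de(donors, membership, spec, alpha=alpha)
    full_mu = full["mu_hat"].to_numpy()
    full_sig = full["significant"].to_numpy()
    frames = []
    for excluded in [d.donor_id for d in donors]:
        subset = [d for d in donors if d.donor_id != excluded]
        sub_membership = membership[membership["donor_id"] != excluded]
        lodo = run_de(subset, sub_membership, spec, alpha=alpha)
        frames.append(
            pd.DataFrame(
                {
                    "excluded_donor": excluded,
                    "gene_id": lodo["gene_id"],
                    "mu_hat": lodo["mu_hat"],
                    "delta_mu": lodo["mu_hat"].to_numpy() - full_mu,
                    "significant": lodo["significant"],
                    "flipped": lodo["significant"].to_numpy() != full_sig,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
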