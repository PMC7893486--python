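"""Gene-set over-representation statistics.

All enrichment claims reduce to a 2x2 contingency table over an explicit
gene universe:

                 in set   not in set
    in query        a         b
    not in query    c         d

with odds ratio OR = (a*d)/(b*c) (OR > 1 enrichment, 0 < OR < 1 depletion)
and a Fisher exact p-value — one-sided "greater" by default, matching the
directional enrichment claim; two-sided (summation of tables at most as
probable as the observed one) is available by flag.  BH/FDR correction is
applied within each collection of tests.

The expression-ranked background implements the convention of testing
against the top fraction of genes by mean cortical expression instead of the
whole genome, to correct over-representation tests for non-selective,
ubiquitously expressed ontologies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .atlas_io import DonorExpression, GeneSetCollection
from .meta_de import bh_adjust

logger = logging.getLogger("stressmap")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 query-by-set counts within a universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")

    @classmethod
    def from_sets(
        cls, query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
    ) -> "ContingencyTable":
        uni = set(universe)
        q = set(query) & uni
        s = set(gene_set) & uni
        a = len(q & s)
        return cls(a=a, b=len(q) - a, c=len(s) - a, d=len(uni) - len(q) - len(s) + a)


@dataclass
class EnrichmentResult:
    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    direction: str = "none"


def fisher_or(t: ContingencyTable, sided: str = "greater") -> tuple[float, float]:
    """Odds ratio and Fisher exact p-value for one 2x2 table.

    OR = (a*d)/(b*c); b*c = 0 with a*d > 0 gives +inf, a*d = 0 gives 0, and
    the jointly degenerate tables (a=d=0 and b=c=0) give NaN.  ``sided`` is
    ``greater`` (hypergeometric upper tail, default) or ``two-sided``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    elif a * d == 0:
        odds = 0.0
    else:
        odds = (a * d) / (b * c)
    if sided == "greater":
        # P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)
        p = float(scipy.stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    elif sided == "two-sided":
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return odds, min(p, 1.0)


def _direction(odds: float, p_adj: float, alpha: float) -> str:
    if not (p_adj < alpha) or math.isnan(odds):
        return "none"
    if odds > 1:
        return "enriched"
    if 0 <= odds < 1:
        return "depleted"
    return "none"


def enrich_collection(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    sided: str = "greater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Fisher test per gene set, BH-corrected across the collection.

    Query members outside the universe are dropped (logged); sets disjoint
    from the universe are dropped with a warning.  Rows are ordered by
    (p, set_name).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("%d query gene(s) outside the universe dropped", dropped)
    rows = []
    for set_name, members in collection.sets.items():
        s = set(members) & uni
        if not s:
            logger.warning("gene set %r disjoint from universe: dropped", set_name)
            continue
        t = ContingencyTable.from_sets(q, s, uni)
        odds, p = fisher_or(t, sided=sided)
        rows.append(
            {
                "set_name": set_name,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "a", "b", "c", "d", "odds_ratio", "p", "p_adj", "direction"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["direction"] = [
        _direction(o, pa, alpha) for o, pa in zip(df["odds_ratio"], df["p_adj"])
    ]
    return df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def expression_background(
    donors: Sequence[DonorExpression],
    membership: pd.DataFrame,
    fraction: float = 0.2,
) -> list[str]:
    """Top fraction of genes by mean unstandardized cortical expression.

    Per donor, the mean over that donor's cortex samples; donors weighted
    equally; the top ceil(fraction * G) genes returned, ties broken by gene
    id (ascending).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    gene_ids = donors[0].gene_ids
    means = []
    for d in donors:
        cortex_ids = membership.loc[
            (membership["donor_id"] == d.donor_id) & membership["is_cortex"],
            "sample_id",
        ]
        keep = set(cortex_ids)
        idx = [i for i, s in enumerate(d.sample_ids) if s in keep]
        if not idx:
            continue
        means.append(d.values[:, idx].mean(axis=1))
    if not means:
        raise ValueError("no cortex samples available for the background")
    pooled = np.mean(means, axis=0)
    n_top = math.ceil(fraction * len(gene_ids))
    order = sorted(range(len(gene_ids)), key=lambda i: (-pooled[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n_top]]


def receptor_or(
    de_genes: Sequence[str],
    trait_sets: GeneSetCollection,
    receptor_universe: Sequence[str],
    neuropeptide_list: Sequence[str] | None = None,
    sided: str = "greater",
) -> pd.DataFrame:
    """Per-trait odds ratios of DE membership among receptors (and peptides).

    For each trait set, the 2x2 table is built within the receptor universe:
    rows split receptors by DE membership, columns by trait membership, so
    the OR measures the increased chance of a receptor being differentially
    expressed when it belongs to the trait.  The same construction is applied
    over the neuropeptide list when given.  Traits empty after intersection
    with a universe yield NaN for that universe.
    """
    if not receptor_universe:
        raise ValueError("empty receptor universe")
    universes = [("receptors", list(receptor_universe))]
    if neuropeptide_list is not None:
        universes.append(("neuropeptides", list(neuropeptide_list)))
    rows = []
    for trait, members in trait_sets.sets.items():
        row: dict[str, object] = {"trait": trait}
        for label, uni in universes:
            s = set(members) & set(uni)
            if not s or not uni:
                row[f"or_{label}"] = float("nan")
                row[f"p_{label}"] = float("nan")
                row[f"n_{label}"] = len(s)
                continue
            t = ContingencyTable.from_sets(de_genes, s, uni)
            odds, p = fisher_or(t, sided=sided)
            row[f"or_{label}"] = odds
            row[f"p_{label}"] = p
            row[f"n_{label}"] = len(s)
        rows.append(row)
    return pd.DataFrame(rows)


def grmr_enrichment(
    de_genes: Sequence[str],
    gr_only: Sequence[str],
    mr_only: Sequence[str],
    gr_mr_overlap: Sequence[str],
    universe: Sequence[str],
    sided: str = "greater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of DE genes among GR-only, MR-only and joint GR+MR targets.

    The three corticosteroid-receptor target sets must be disjoint; genes in
    more than one set are resolved to the joint GR+MR set with a warning.
    Exactly three Fisher tests, BH-corrected over the three.
    """
    gr = set(gr_only)
    mr = set(mr_only)
    both = set(gr_mr_overlap)
    clashes = (gr & mr) | (gr & both) | (mr & both)
    if clashes:
        logger.warning(
            "%d gene(s) in multiple GR/MR target sets resolved to the joint set",
            len(clashes),
        )
        both |= clashes
        gr -= clashes
        mr -= clashes
    rows = []
    for name, members in (("GR_only", gr), ("MR_only", mr), ("GR_MR", both)):
        if not members:
            rows.append(
                {
                    "set_name": name,
                    "a": 0,
                    "b": 0,
                    "c": 0,
                    "d": 0,
                    "odds_ratio": float("nan"),
                    "p": float("nan"),
                }
            )
            continue
        t = ContingencyTable.from_sets(de_genes, members, universe)
        odds, p = fisher_or(t, sided=sided)
        rows.append(
            {"set_name": name, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "odds_ratio": odds, "p": p}
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    padj = np.full(len(df), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["p_adj"] = padj
    df["direction"] = [
        _direction(o, pa, alpha) if not math.isnan(p) else "none"
        for o, p, pa in zip(df["odds_ratio"], df["p"], df["p_adj"])
    ]
    return df
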