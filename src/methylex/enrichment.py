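"""GO-term over/under-representation in highly gene-body-CG-methylated genes.

The focal set defaults to the genes in the top decile of gene-body CG
methylation; each GO term is tested with a two-sided Fisher's exact test on
the 2x2 table (focal-with-term, focal-without, background-with,
background-without), with Benjamini-Hochberg adjusted p-values reported
alongside the raw ones.  Genes with no annotation stay in the universe —
they inform the "without term" cells.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger("methylex")


def top_fraction(region_table: pd.DataFrame, measure: str = "m_cg",
                 fraction: float = 0.10) -> set[str]:
    """Gene ids whose *measure* lies strictly above the (1 - fraction) quantile.

    Ties exactly at the threshold are excluded, so when every value is
    equal the returned set is empty (with a warning).
    """
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must lie in (0, 1), got {fraction}")
    values = region_table[measure].dropna()
    if len(values) < 10:
        raise ValidationError(
            f"measure {measure!r} is non-missing for only {len(values)} genes")
    threshold = float(np.quantile(values.to_numpy(), 1 - fraction))
    chosen = set(values.index[values > threshold])
    if not chosen:
        logger.warning("top_fraction: no gene strictly above the %.0f%% "
                       "threshold (ties)", 100 * (1 - fraction))
    return chosen


def go_fisher(focal: Iterable[str], universe: Iterable[str],
              annotations: Mapping[str, Iterable[str]],
              alternative: str = "two-sided") -> pd.DataFrame:
    """Per-GO-term Fisher's exact test of a focal gene set against its universe.

    Returns a DataFrame indexed by term with the four 2x2 cell counts, the
    sample odds ratio, raw and BH-adjusted p-values, and the direction
    ("enriched" when the odds ratio exceeds 1, "depleted" below 1,
    "balanced" at exactly 1).  Terms annotating no gene in the universe are
    skipped with a log entry.
    """
    from statsmodels.stats.multitest import multipletests

    universe = set(universe)
    focal = set(focal)
    if not focal <= universe:
        raise ValidationError("focal set is not a subset of the universe")
    background = universe - focal

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        if not genes:
            logger.info("go_fisher: term %s annotates no gene in universe; "
                        "skipped", term)
            continue
        a = len(genes & focal)           # focal, with term
        b = len(focal) - a               # focal, without
        c = len(genes & background)      # background, with term
        d = len(background) - c          # background, without
        if (b == 0 and d == 0) or (a == 0 and c == 0):
            odds = 1.0                   # term in every (or no) gene: degenerate
        elif b * c == 0:
            odds = float("inf") if a * d > 0 else 0.0
        else:
            odds = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        direction = ("enriched" if odds > 1
                     else "depleted" if odds < 1 else "balanced")
        rows.append({"term": term, "focal_with": a, "focal_without": b,
                     "background_with": c, "background_without": d,
                     "odds_ratio": odds, "pvalue": float(p),
                     "direction": direction})
    if not rows:
        return pd.DataFrame(columns=["focal_with", "focal_without",
                                     "background_with", "background_without",
                                     "odds_ratio", "pvalue", "p_adjusted",
                                     "direction"])
    out = pd.DataFrame(rows).set_index("term")
    out["p_adjusted"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out = out[["focal_with", "focal_without", "background_with",
               "background_without", "odds_ratio", "pvalue", "p_adjusted",
               "direction"]]
    logger.info("go_fisher: tested %d terms (%d focal genes, %d universe)",
                len(out), len(focal), len(universe))
    return out
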