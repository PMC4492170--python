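"""Per-gene region methylation, TE summaries, TSS metaprofiles and
chromosome-level statistics.

Each gene defines three strand-oriented regions: the 1 kb up-stream flank
(5' of the TSS), the gene body (the whole transcribed span, introns
included), and the 1 kb down-stream flank (3' of the transcript end),
plus the first 500 bp of the gene body measured from the TSS.  Flanks are
truncated at contig edges.  The nine region x context percent-methylation
measures are the methylation predictors of the expression model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONTEXTS, GeneRecord, ValidationError
from .methylome_core import MethylationTrack, _percent_from_subset, pooled_percent

logger = logging.getLogger("methylex")

#: the nine methylation measures, region-prefixed: m_=body, u_=up-stream, d_=down-stream
METHYLATION_MEASURES = ["m_cg", "m_chg", "m_chh",
                        "u_cg", "u_chg", "u_chh",
                        "d_cg", "d_chg", "d_chh"]

_REGION_PREFIX = {"body": "m", "upstream": "u", "downstream": "d"}


@dataclass(frozen=True)
class GeneRegions:
    """Half-open genomic intervals of a gene's analysis regions."""

    upstream: tuple[int, int]
    body: tuple[int, int]
    downstream: tuple[int, int]
    first500: tuple[int, int]

    def interval(self, name: str) -> tuple[int, int]:
        try:
            return getattr(self, name)
        except AttributeError:
            raise ValueError(f"unknown region {name!r}") from None


def define_regions(gene: GeneRecord, flank: int = 1000,
                   chromosome_length: int | None = None,
                   first_bp: int = 500) -> GeneRegions:
    """Up-stream / body / down-stream intervals for a gene, strand-aware.

    For a "+"-strand gene spanning [s, e): up-stream is [s-flank, s), body
    [s, e), down-stream [e, e+flank); mirrored for "-" genes.  Intervals
    are truncated at position 0 and at *chromosome_length* when given.  The
    first-500bp sub-interval covers the body's first ``min(first_bp, body
    length)`` bases from the TSS.
    """
    s, e = gene.start, gene.end
    length = chromosome_length

    def clip(a: int, b: int) -> tuple[int, int]:
        a = max(a, 0)
        if length is not None:
            b = min(b, length)
        return (a, max(a, b))

    if gene.strand == "+":
        up = clip(s - flank, s)
        down = clip(e, e + flank)
        first = (s, min(s + first_bp, e))
    else:
        up = clip(e, e + flank)
        down = clip(s - flank, s)
        first = (max(e - first_bp, s), e)
    return GeneRegions(upstream=up, body=(s, e), downstream=down, first500=first)


# ---------------------------------------------------------------------------
# region methylation table
# ---------------------------------------------------------------------------

def _region_percent(track: MethylationTrack, chrom: str,
                    interval: tuple[int, int], per_site_mean: bool,
                    min_coverage: int) -> pd.Series:
    sub = track.query(chrom, *interval)
    return _percent_from_subset(sub, per_site_mean, min_coverage)


def region_methylation(track: MethylationTrack, genes: Sequence[GeneRecord],
                       expression: Mapping[str, float] | None = None,
                       flank: int = 1000, per_site_mean: bool = False,
                       min_coverage: int = 1) -> pd.DataFrame:
    """Build the per-gene region x context methylation table.

    One row per gene, indexed by gene id, with the nine methylation
    predictors (``m_/u_/d_`` x ``cg/chg/chh``), the first-500bp levels,
    gene-architecture fields (``l_exon``, ``l_intron``, ``n_exon``),
    chromosome, and — when *expression* is given or carried on the genes —
    the raw expression value.  Regions without a covered cytosine in a
    context get NaN.
    """
    track_chroms = set(track.chromosomes)
    gene_chroms = {g.chromosome for g in genes}
    missing = sorted(gene_chroms - track_chroms)
    if missing and not (gene_chroms & track_chroms):
        raise ValidationError(
            f"no gene chromosome matches the track; unmatched: {missing}")
    if missing:
        logger.warning("region_methylation: %d gene chromosomes absent from "
                       "track: %s", len(missing), missing)

    rows = {}
    for g in genes:
        chrom_len = (track.chromosome_length(g.chromosome)
                     if g.chromosome in track_chroms else None)
        regions = define_regions(g, flank=flank, chromosome_length=chrom_len)
        row: dict[str, float] = {}
        for region, prefix in _REGION_PREFIX.items():
            pct = _region_percent(track, g.chromosome, regions.interval(region),
                                  per_site_mean, min_coverage)
            for ctx in CONTEXTS:
                row[f"{prefix}_{ctx.lower()}"] = pct[ctx]
        pct = _region_percent(track, g.chromosome, regions.first500,
                              per_site_mean, min_coverage)
        for ctx in CONTEXTS:
            row[f"first500_{ctx.lower()}"] = pct[ctx]
        row["l_exon"] = g.exon_length
        row["l_intron"] = g.intron_length
        row["n_exon"] = g.exon_count
        row["chromosome"] = g.chromosome
        if expression is not None and g.gene_id in expression:
            row["expression"] = float(expression[g.gene_id])
        elif g.expression is not None:
            row["expression"] = float(g.expression)
        rows[g.gene_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    logger.info("region_methylation: %d genes summarized", len(table))
    return table


# ---------------------------------------------------------------------------
# transposable elements
# ---------------------------------------------------------------------------

def te_methylation(track: MethylationTrack, repeats: pd.DataFrame,
                   min_length: int = 100,
                   per_site_mean: bool = False,
                   min_coverage: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent methylation of genomic repeats and their families.

    Repeats shorter than *min_length* bp are excluded.  Returns a
    ``(per_repeat, per_family)`` pair; family percentages pool the read
    counts of all member copies, and the family table also carries the copy
    number.
    """
    lengths = repeats["end"] - repeats["start"]
    kept = repeats[lengths >= min_length].reset_index(drop=True)
    dropped = len(repeats) - len(kept)
    if dropped:
        logger.info("te_methylation: excluded %d repeats shorter than %d bp",
                    dropped, min_length)

    per_repeat_rows = []
    fam_counts: dict[str, dict[str, np.ndarray]] = {}
    for _, rep in kept.iterrows():
        sub = track.query(rep["chromosome"], int(rep["start"]), int(rep["end"]))
        row = {"chromosome": rep["chromosome"], "start": int(rep["start"]),
               "end": int(rep["end"]), "family": rep["family"]}
        pct = _percent_from_subset(sub, per_site_mean, min_coverage)
        fam = fam_counts.setdefault(
            rep["family"], {"copies": np.zeros(1, dtype=int),
                            "meth": np.zeros(3), "total": np.zeros(3)})
        fam["copies"][0] += 1
        for i, ctx in enumerate(CONTEXTS):
            row[f"pct_{ctx.lower()}"] = pct[ctx]
            m = sub[sub["context"] == ctx]
            fam["meth"][i] += m["count_methylated"].sum()
            fam["total"][i] += (m["count_methylated"].sum()
                               + m["count_unmethylated"].sum())
        per_repeat_rows.append(row)

    per_repeat = pd.DataFrame(per_repeat_rows)
    fam_rows = []
    for family, acc in fam_counts.items():
        row = {"family": family, "copies": int(acc["copies"][0])}
        for i, ctx in enumerate(CONTEXTS):
            row[f"pct_{ctx.lower()}"] = pooled_percent(acc["meth"][i],
                                                       acc["total"][i])
        fam_rows.append(row)
    per_family = pd.DataFrame(fam_rows).sort_values(
        "copies", ascending=False).reset_index(drop=True)
    return per_repeat, per_family


# ---------------------------------------------------------------------------
# TSS metaprofile
# ---------------------------------------------------------------------------

@dataclass
class TSSProfile:
    """TSS-anchored methylation metaprofile.

    ``data`` holds one row per (bin, context): the bin's start offset
    relative to the TSS in gene orientation (negative = up-stream), the
    percent methylation, and the pooled read count.
    """

    bin_size: int
    flank: int
    data: pd.DataFrame   # columns: offset, context, percent, n


def tss_profile(track: MethylationTrack, genes: Sequence[GeneRecord],
                bin_size: int = 100, flank: int = 2000,
                per_gene_mean: bool = False,
                min_coverage: int = 1) -> TSSProfile:
    """Strand-oriented methylation profile around transcription start sites.

    Bins tile [-flank, +flank) in gene orientation.  By default read counts
    are pooled across genes within a bin; *per_gene_mean* instead averages
    per-gene percentages.
    """
    if not genes:
        raise ValidationError("tss_profile requires at least one gene")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(n_bins) * bin_size - flank
    meth = {c: np.zeros(n_bins) for c in CONTEXTS}
    total = {c: np.zeros(n_bins) for c in CONTEXTS}
    gene_pct_sum = {c: np.zeros(n_bins) for c in CONTEXTS}
    gene_pct_n = {c: np.zeros(n_bins) for c in CONTEXTS}

    for g in genes:
        tss = g.tss
        if g.strand == "+":
            lo, hi = tss - flank, tss + flank
        else:
            lo, hi = tss - flank + 1, tss + flank + 1
        sub = track.query(g.chromosome, max(lo, 0), hi)
        if sub.empty:
            continue
        cov = (sub["count_methylated"] + sub["count_unmethylated"]).to_numpy()
        keep = cov >= min_coverage
        pos = sub["position"].to_numpy()[keep]
        m = sub["count_methylated"].to_numpy()[keep]
        t = cov[keep]
        ctx = sub["context"].to_numpy()[keep]
        rel = (pos - tss) if g.strand == "+" else (tss - pos)
        bins = (rel + flank) // bin_size
        ok = (bins >= 0) & (bins < n_bins)
        for c in CONTEXTS:
            mask = ok & (ctx == c)
            if not mask.any():
                continue
            bm = np.bincount(bins[mask], weights=m[mask], minlength=n_bins)
            bt = np.bincount(bins[mask], weights=t[mask], minlength=n_bins)
            meth[c] += bm
            total[c] += bt
            covered = bt > 0
            gene_pct_sum[c][covered] += 100.0 * bm[covered] / bt[covered]
            gene_pct_n[c][covered] += 1

    rows = []
    for c in CONTEXTS:
        for b in range(n_bins):
            if per_gene_mean:
                pct = (gene_pct_sum[c][b] / gene_pct_n[c][b]
                       if gene_pct_n[c][b] > 0 else float("nan"))
            else:
                pct = pooled_percent(meth[c][b], total[c][b])
            rows.append({"offset": int(offsets[b]), "context": c,
                         "percent": pct, "n": int(total[c][b])})
    return TSSProfile(bin_size=bin_size, flank=flank, data=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# region contrast (two-proportion test)
# ---------------------------------------------------------------------------

@dataclass
class RegionContrast:
    """Two-proportion z-test between pooled counts of two gene regions."""

    region_a: str
    region_b: str
    context: str
    percent_a: float
    percent_b: float
    difference: float          # percent_a - percent_b, percentage points
    statistic: float           # z
    pvalue: float
    counts: tuple[int, int, int, int]   # meth_a, total_a, meth_b, total_b


def region_contrast(track: MethylationTrack, genes: Sequence[GeneRecord],
                    region_a: str, region_b: str, context: str,
                    flank: int = 1000) -> RegionContrast:
    """Compare pooled percent methylation of two regions across all genes.

    Regions are named ``upstream``, ``body``, ``downstream`` or
    ``first500``.  The test is a two-sided two-proportion z-test on the
    pooled (methylated, total) read counts.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    counts = {region_a: [0, 0], region_b: [0, 0]}
    for g in genes:
        chrom_len = track.chromosome_length(g.chromosome) \
            if g.chromosome in set(track.chromosomes) else None
        regions = define_regions(g, flank=flank, chromosome_length=chrom_len)
        for name in (region_a, region_b):
            sub = track.query(g.chromosome, *regions.interval(name))
            sub = sub[sub["context"] == context]
            counts[name][0] += int(sub["count_methylated"].sum())
            counts[name][1] += int((sub["count_methylated"]
                                    + sub["count_unmethylated"]).sum())
    ma, ta = counts[region_a]
    mb, tb = counts[region_b]
    if ta == 0 or tb == 0:
        raise ValidationError("region_contrast: zero total reads in a region")
    pa, pb = ma / ta, mb / tb
    pool = (ma + mb) / (ta + tb)
    se = np.sqrt(pool * (1 - pool) * (1 / ta + 1 / tb))
    z = (pa - pb) / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return RegionContrast(region_a=region_a, region_b=region_b, context=context,
                          percent_a=100 * pa, percent_b=100 * pb,
                          difference=100 * (pa - pb), statistic=float(z),
                          pvalue=float(p), counts=(ma, ta, mb, tb))


# ---------------------------------------------------------------------------
# correlations and chromosome ANOVA
# ---------------------------------------------------------------------------

def methylation_correlations(table: pd.DataFrame
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the nine methylation measures.

    Uses pairwise-complete observations.  Returns ``(r, n, p)`` DataFrames;
    a measure with zero variance gets NaN in its row/column with a warning.
    """
    cols = METHYLATION_MEASURES
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    complete = table[cols].notna()
    if complete.all(axis=1).sum() < 3:
        raise ValidationError("methylation_correlations: fewer than 3 genes "
                              "with complete data")
    for i, a in enumerate(cols):
        n.iloc[i, i] = int(table[a].notna().sum())
        for j in range(i + 1, k):
            b = cols[j]
            mask = complete[a] & complete[b]
            x, y = table.loc[mask, a], table.loc[mask, b]
            n.iloc[i, j] = n.iloc[j, i] = int(mask.sum())
            if mask.sum() < 3 or x.std() == 0 or y.std() == 0:
                if x.std() == 0 or y.std() == 0:
                    logger.warning("methylation_correlations: zero variance "
                                   "in %s or %s", a, b)
                r.iloc[i, j] = r.iloc[j, i] = float("nan")
                p.iloc[i, j] = p.iloc[j, i] = float("nan")
                continue
            res = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = float(res.statistic)
            p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue)
    return r, n, p


def chromosome_anova(table: pd.DataFrame, log_base: float = 10.0
                     ) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of expression and body methylation by chromosome.

    Fits one ANOVA for each of log(expression), ``m_cg``, ``m_chg`` and
    ``m_chh`` with chromosome as the factor; returns a DataFrame with F, the
    numerator/denominator degrees of freedom and the p-value per response.
    """
    chroms = table["chromosome"].dropna().unique()
    if len(chroms) < 2:
        raise ValidationError("chromosome_anova requires >= 2 chromosomes")
    responses: dict[str, pd.Series] = {}
    if "expression" in table:
        expr = table["expression"]
        pos = expr > 0
        responses["log_expression"] = np.log(expr[pos]) / np.log(log_base)
    for col in ("m_cg", "m_chg", "m_chh"):
        responses[col] = table[col]
    rows = []
    for name, y in responses.items():
        sub = pd.DataFrame({"y": y, "chrom": table.loc[y.index, "chromosome"]}).dropna()
        groups = [g["y"].to_numpy() for _, g in sub.groupby("chrom")
                  if len(g) >= 2]
        if len(groups) < 2:
            raise ValidationError(f"chromosome_anova: response {name} has "
                                  "fewer than 2 usable chromosomes")
        f, pval = stats.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(len(g) for g in groups) - len(groups)
        rows.append({"response": name, "F": float(f), "df1": df1, "df2": df2,
                     "pvalue": float(pval)})
    return pd.DataFrame(rows).set_index("response")
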