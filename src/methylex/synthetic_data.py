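"""Synthetic miniature input bundles with the statistical structure the
analysis assumes.

The generator works at two coupled tiers:

* :func:`simulate_regions` draws the *gene-level* quantities directly — a
  9-dimensional Gaussian-copula vector of region x context methylation
  propensities per gene, gene architecture, and expression from a
  polynomial model plus Gaussian noise.  This is the cohort the regression
  machinery consumes, at any gene count, in milliseconds per thousand
  genes.

* :func:`generate_bundle` materializes a full input bundle around such a
  cohort: a random genome FASTA, non-overlapping gene models with 1 kb
  intergenic clearance, repeat intervals, and a per-cytosine count table
  whose beta-binomial counts are centred on each gene's drawn region
  propensities (with intergenic, repeat-family and unmethylated spike-in
  strata of their own).  Every pipeline stage can then run from files.

Methylation is generated at region resolution, not per-cytosine biological
realism: the analysis consumes region summaries, so region-level fidelity
is what the tests need.  All randomness flows from a single seed; equal
seeds give byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_model import PREDICTORS, PolynomialModelSpec, predict
from .gene_regions import METHYLATION_MEASURES
from .io_formats import (GeneRecord, ValidationError, write_cytosine_table,
                         write_expression_table, write_genome,
                         write_gff3_genes, write_go_annotations,
                         write_repeats_bed)
from .methylome_core import classify_context_array

logger = logging.getLogger("methylex")

_CTX = ("cg", "chg", "chh")


def default_correlation() -> np.ndarray:
    """Default 9x9 latent correlation over the methylation measures.

    Encodes the qualitative structure of the observed inter-measure
    correlations: very strong within-region CHG-CHH coupling (~0.7, the two
    non-CG pathways share machinery), strong flank-flank same-context
    coupling, a weak body-CG vs up-stream-CG correlation (0.14), and
    slightly negative flank-CHH vs body-CG correlations.  Positive
    semi-definite by construction (smallest eigenvalue ~0.19).
    """
    C = np.eye(9)
    pairs = {
        (1, 2): 0.70, (4, 5): 0.70, (7, 8): 0.70,
        (0, 1): 0.30, (3, 4): 0.50, (6, 7): 0.50,
        (0, 2): 0.25, (3, 5): 0.35, (6, 8): 0.35,
        (0, 3): 0.14, (0, 6): 0.14, (3, 6): 0.50,
        (1, 4): 0.40, (1, 7): 0.40, (4, 7): 0.55,
        (2, 5): 0.40, (2, 8): 0.40, (5, 8): 0.55,
        (0, 5): -0.05, (0, 8): -0.05, (0, 4): 0.05, (0, 7): 0.05,
        (1, 3): 0.30, (1, 6): 0.30, (2, 3): 0.25, (2, 6): 0.25,
        (1, 5): 0.35, (1, 8): 0.35, (2, 4): 0.35, (2, 7): 0.35,
        (3, 7): 0.35, (3, 8): 0.25, (4, 6): 0.35, (5, 6): 0.25,
        (4, 8): 0.45, (5, 7): 0.45,
    }
    for (i, j), v in pairs.items():
        C[i, j] = C[j, i] = v
    return C


@dataclass
class SyntheticConfig:
    """All generator parameters.

    Methylation targets are cohort-mean methylated proportions per region
    and context (CG, CHG, CHH); expression noise defaults to the residual
    scale of the reference fit (SD 0.64 in log10 units), or is calibrated
    to ``target_r2`` when ``residual_sd`` is None.  Read depth is negative
    binomial with mean 19 and a long tail (median 6).
    """

    seed: int = 0
    n_genes: int = 5000
    n_chromosomes: int = 4
    chromosome_lengths: tuple[int, ...] | None = None   # auto-sized if None
    gc_fraction: float = 0.40

    # gene architecture
    exon_count_mean: float = 3.5          # n_exon ~ 1 + Poisson(mean - 1)
    exon_length_log_mean: float = math.log(400.0)
    exon_length_log_sd: float = 0.5
    intron_length_log_mean: float = math.log(250.0)
    intron_length_log_sd: float = 0.7

    # cohort-mean methylated proportions (CG, CHG, CHH)
    body_targets: tuple[float, float, float] = (0.56, 0.038, 0.012)
    first500_targets: tuple[float, float, float] = (0.28, 0.032, 0.019)
    upstream_targets: tuple[float, float, float] = (0.35, 0.11, 0.027)
    downstream_targets: tuple[float, float, float] = (0.35, 0.11, 0.027)
    intergenic_targets: tuple[float, float, float] = (0.75, 0.45, 0.072)
    te_targets: tuple[float, float, float] = (0.73, 0.36, 0.063)
    first_bp: int = 500
    flank: int = 1000

    # latent copula: per-measure probit spread, measure order as
    # METHYLATION_MEASURES (m_cg..d_chh)
    latent_sds: tuple[float, ...] = (0.8, 0.8, 0.7, 0.8, 0.8, 0.7, 0.8, 0.8, 0.7)
    correlation: np.ndarray = field(default_factory=default_correlation)

    # per-cytosine counts
    overdispersion: float = 0.08          # beta-binomial rho
    depth_mean: float = 19.0
    depth_size: float = 0.36              # NB size giving median 6 at mean 19

    # expression
    expression_model: PolynomialModelSpec | None = None   # default: published
    residual_sd: float | None = 0.64
    target_r2: float = 0.201775           # used when residual_sd is None
    log_base: float = 10.0

    # spike-in
    spikein_name: str = "lambda"
    spikein_length: int = 48502
    spikein_gc: float = 0.50
    conversion_failure_rate: float = 0.006

    # repeats
    n_repeat_families: int = 6
    n_repeats: int = 60
    repeat_length_log_mean: float = math.log(300.0)
    repeat_length_log_sd: float = 0.6

    # GO annotations
    n_go_terms: int = 30
    go_terms_per_gene_mean: float = 2.0
    planted_term: str = "GO:0016301"      # kinase-activity-like planted signal
    planted_base_rate: float = 0.10
    planted_odds_ratio: float = 4.0

    def model(self) -> PolynomialModelSpec:
        if self.expression_model is not None:
            return self.expression_model
        from .surface_analysis import published_model
        return published_model()

    def validate(self) -> None:
        for name in ("body_targets", "first500_targets", "upstream_targets",
                     "downstream_targets", "intergenic_targets", "te_targets"):
            t = getattr(self, name)
            if not all(0.0 <= v <= 1.0 for v in t):
                raise ValidationError(f"{name} outside [0, 1]: {t}")
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (9, 9) or not np.allclose(C, C.T):
            raise ValidationError("correlation matrix must be symmetric 9x9")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValidationError("correlation matrix is not positive "
                                  "semi-definite (infeasible targets)")


# ---------------------------------------------------------------------------
# gene-level tier
# ---------------------------------------------------------------------------

def _probit_means(targets: Sequence[float], sds: Sequence[float]) -> np.ndarray:
    """Latent offsets so that E[Phi(mu + s Z)] equals each target."""
    t = np.asarray(targets, dtype=float)
    s = np.asarray(sds, dtype=float)
    return stats.norm.ppf(np.clip(t, 1e-12, 1 - 1e-12)) * np.sqrt(1 + s ** 2)


def calibrate_residual_sd(signal: np.ndarray, target_r2: float) -> float:
    """Residual SD making the expected R² of a fit equal *target_r2*.

    With signal variance V, noise variance V (1 - R²) / R² gives a signal
    fraction of exactly R².
    """
    v = float(np.var(signal))
    if v == 0:
        raise ValidationError("cannot calibrate residual SD to a constant signal")
    return math.sqrt(v * (1 - target_r2) / target_r2)


def simulate_regions(config: SyntheticConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Draw the gene-level cohort: region methylation, architecture, expression.

    Returns a region-methylation table (percent units, same schema as
    :func:`methylex.gene_regions.region_methylation` plus ``expression``)
    and a ground-truth dict (model coefficients, residual SD, latent
    parameters).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes

    # architecture
    n_exon = 1 + rng.poisson(max(config.exon_count_mean - 1, 0.0), size=n)
    l_exon = np.array([
        rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd,
                      size=k).sum() for k in n_exon]).round().astype(int)
    l_exon = np.maximum(l_exon, n_exon)        # every exon at least 1 bp
    l_intron = np.array([
        rng.lognormal(config.intron_length_log_mean,
                      config.intron_length_log_sd, size=k - 1).sum()
        for k in n_exon]).round().astype(int)
    l_intron = np.where(n_exon > 1, np.maximum(l_intron, n_exon - 1), 0)

    # correlated latent propensities -> probit-normal percents
    sds = np.asarray(config.latent_sds, dtype=float)
    targets = np.array(list(config.body_targets) + list(config.upstream_targets)
                       + list(config.downstream_targets))
    mus = _probit_means(targets, sds)
    L = np.linalg.cholesky(np.asarray(config.correlation)
                           + 1e-12 * np.eye(9))
    z = rng.standard_normal((n, 9)) @ L.T
    pct = 100.0 * stats.norm.cdf(mus + sds * z)

    # first-500bp shares the body latent draw but has its own mean target
    f_mus = _probit_means(config.first500_targets, sds[:3])
    f_pct = 100.0 * stats.norm.cdf(f_mus + sds[:3] * z[:, :3])

    table = pd.DataFrame(pct, columns=METHYLATION_MEASURES)
    for i, ctx in enumerate(_CTX):
        table[f"first500_{ctx}"] = f_pct[:, i]
    table["l_exon"] = l_exon
    table["l_intron"] = l_intron
    table["n_exon"] = n_exon
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    table["chromosome"] = [chroms[i % len(chroms)] for i in range(n)]
    table.index = pd.Index([f"gene{i + 1:05d}" for i in range(n)],
                           name="gene_id")

    expression, resid_sd, truth_expr = _draw_expression(table, config, rng)
    table["expression"] = expression

    truth = {
        "seed": config.seed,
        "n_genes": n,
        "latent_mus": mus.tolist(),
        "latent_sds": sds.tolist(),
        "first500_mus": f_mus.tolist(),
        "targets_percent": (100 * targets).tolist(),
        "residual_sd": resid_sd,
        **truth_expr,
    }
    return table, truth


def _draw_expression(table: pd.DataFrame, config: SyntheticConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, float, dict]:
    model = config.model()
    X = table[PREDICTORS].astype(float)
    Z = (X - X.mean()) / X.std(ddof=1)
    signal = predict(model, Z)
    resid_sd = (config.residual_sd if config.residual_sd is not None
                else calibrate_residual_sd(signal, config.target_r2))
    y = signal + rng.normal(0.0, resid_sd, size=len(table))
    expression = np.power(config.log_base, y)
    signal_var = float(np.var(signal))
    truth = {
        "model": json.loads(model.to_json()),
        "signal_variance": signal_var,
        "expected_r2": signal_var / (signal_var + resid_sd ** 2),
        "log_base": config.log_base,
    }
    return expression, float(resid_sd), truth


def generate_expression(region_table: pd.DataFrame, config: SyntheticConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.Series, dict[str, set[str]], dict]:
    """Expression (raw scale) and GO annotations for an existing region table.

    Expression is the configured polynomial model evaluated on the table's
    standardized predictors plus Gaussian noise, exponentiated back to the
    raw scale.  GO terms are assigned at random, except the planted term,
    which is over-represented among top-decile body-CG genes at the
    configured odds ratio.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    expression, resid_sd, truth = _draw_expression(region_table, config, rng)
    go = _draw_go(region_table, config, rng)
    truth["residual_sd"] = resid_sd
    return (pd.Series(expression, index=region_table.index, name="expression"),
            go, truth)


def _draw_go(table: pd.DataFrame, config: SyntheticConfig,
             rng: np.random.Generator) -> dict[str, set[str]]:
    terms = [f"GO:{7000000 + i}" for i in range(config.n_go_terms)]
    n = len(table)
    annotations: dict[str, set[str]] = {g: set() for g in table.index}
    counts = rng.poisson(config.go_terms_per_gene_mean, size=n)
    for gene, k in zip(table.index, counts):
        if k:
            annotations[gene].update(
                rng.choice(terms, size=min(k, len(terms)), replace=False))
    # planted term: membership odds multiplied in the top body-CG decile
    threshold = np.quantile(table["m_cg"].to_numpy(), 0.9)
    top = table["m_cg"].to_numpy() > threshold
    odds0 = config.planted_base_rate / (1 - config.planted_base_rate)
    odds1 = odds0 * config.planted_odds_ratio
    p_top = odds1 / (1 + odds1)
    prob = np.where(top, p_top, config.planted_base_rate)
    member = rng.random(n) < prob
    for gene, m in zip(table.index, member):
        if m:
            annotations[gene].add(config.planted_term)
    return annotations


# ---------------------------------------------------------------------------
# genome tier
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    return bases.tobytes().decode("ascii")


def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    lengths: Sequence[int] | None = None,
                    include_spikein: bool = True) -> dict[str, str]:
    """I.i.d. random genome at the configured GC, plus the spike-in contig."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if lengths is None:
        lengths = (config.chromosome_lengths
                   if config.chromosome_lengths is not None
                   else [_auto_chromosome_length(config)] * config.n_chromosomes)
    if any(ln < 10_000 for ln in lengths):
        raise ValidationError("chromosome lengths must be >= 10 kb")
    genome = {f"chr{i + 1}": _random_sequence(rng, int(ln), config.gc_fraction)
              for i, ln in enumerate(lengths)}
    if include_spikein:
        genome[config.spikein_name] = _random_sequence(
            rng, config.spikein_length, config.spikein_gc)
    return genome


def _auto_chromosome_length(config: SyntheticConfig) -> int:
    mean_exon = math.exp(config.exon_length_log_mean
                         + config.exon_length_log_sd ** 2 / 2)
    mean_intron = math.exp(config.intron_length_log_mean
                           + config.intron_length_log_sd ** 2 / 2)
    span = (config.exon_count_mean * mean_exon
            + (config.exon_count_mean - 1) * mean_intron)
    pitch = 2.0 * span + 2 * config.flank + 1000
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    return max(int(per_chrom * pitch + 2 * config.flank), 10_000)


def _partition(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split *total* into *parts* positive integers (Dirichlet weights)."""
    if parts <= 0 or total < parts:
        return [total] if parts == 1 else []
    w = rng.dirichlet(np.full(parts, 2.0))
    sizes = np.maximum(1, np.floor(w * total).astype(int))
    # fix rounding drift deterministically
    while sizes.sum() > total:
        sizes[int(np.argmax(sizes))] -= 1
    while sizes.sum() < total:
        sizes[int(np.argmin(sizes))] += 1
    return sizes.tolist()


def generate_genes(genome: Mapping[str, str], config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   region_table: pd.DataFrame | None = None
                   ) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Place non-overlapping gene models and repeat intervals on the genome.

    Genes keep at least ``config.flank`` bp of clearance from each other
    and the contig ends, so flanks are genuinely intergenic.  When a
    *region_table* is given its per-gene architecture (exon/intron totals,
    exon counts, chromosome assignment) is materialized exactly; otherwise
    a fresh architecture is drawn.  Repeats are placed in the remaining
    intergenic space, away from gene flanks, with round-robin family labels.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if region_table is None:
        region_table, _ = simulate_regions(config, rng)
    chrom_names = [c for c in genome if c != config.spikein_name]

    genes: list[GeneRecord] = []
    cursors = {c: config.flank + 100 for c in chrom_names}
    for gene_id, row in region_table.iterrows():
        chrom = row["chromosome"]
        if chrom not in genome:
            raise ValidationError(f"gene chromosome {chrom!r} not in genome")
        span = int(row["l_exon"] + row["l_intron"])
        gap = int(rng.integers(config.flank, config.flank + 500))
        start = cursors[chrom] + gap
        end = start + span
        if end + config.flank > len(genome[chrom]):
            raise ValidationError(
                f"genome too small for requested gene count (failed at "
                f"{gene_id} on {chrom})")
        n_ex = int(row["n_exon"])
        exon_sizes = _partition(rng, int(row["l_exon"]), n_ex)
        intron_sizes = (_partition(rng, int(row["l_intron"]), n_ex - 1)
                        if n_ex > 1 else [])
        exons = []
        pos = start
        for i, es in enumerate(exon_sizes):
            exons.append((pos, pos + es))
            pos += es
            if i < len(intron_sizes):
                pos += intron_sizes[i]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gene_id=str(gene_id), chromosome=chrom,
                                strand=strand, exons=exons))
        cursors[chrom] = end

    repeats = _place_repeats(genome, genes, config, rng)
    logger.info("generate_genes: placed %d genes, %d repeats",
                len(genes), len(repeats))
    return genes, repeats


def _place_repeats(genome, genes, config, rng) -> pd.DataFrame:
    families = [f"fam{i + 1}" for i in range(config.n_repeat_families)]
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        occupied.setdefault(g.chromosome, []).append(
            (g.start - config.flank, g.end + config.flank))
    rows = []
    placed = 0
    for chrom in (c for c in genome if c != config.spikein_name):
        gaps = []
        last = 0
        for s, e in sorted(occupied.get(chrom, [])):
            if s - last > 400:
                gaps.append((last, s))
            last = max(last, e)
        if len(genome[chrom]) - last > 400:
            gaps.append((last, len(genome[chrom])))
        for gs, ge in gaps:
            if placed >= config.n_repeats:
                break
            length = int(rng.lognormal(config.repeat_length_log_mean,
                                       config.repeat_length_log_sd))
            length = max(min(length, ge - gs - 200), 60)
            start = int(rng.integers(gs + 100, ge - length - 100)) \
                if ge - length - 100 > gs + 100 else gs + 100
            rows.append({"chromosome": chrom, "start": start,
                         "end": start + length,
                         "family": families[placed % len(families)]})
            placed += 1
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "family"])


# ---------------------------------------------------------------------------
# per-cytosine tier
# ---------------------------------------------------------------------------

def generate_methylation(genome: Mapping[str, str],
                         genes: Sequence[GeneRecord],
                         repeats: pd.DataFrame,
                         config: SyntheticConfig,
                         rng: np.random.Generator | None = None,
                         region_table: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Beta-binomial per-cytosine counts over the whole genome.

    Each cytosine's methylation mean comes from the stratum it falls in:
    the enclosing gene's drawn region propensity (up-stream / first-500bp /
    rest-of-body / down-stream, per context), its repeat family's
    TE-calibrated mean, the intergenic background, or — on the spike-in
    contig — the conversion failure rate.  Read depth is negative binomial;
    zero-depth sites are absent from the table, as in real exports.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if region_table is None:
        region_table, _ = simulate_regions(config, rng)
    gene_by_id = {g.gene_id: g for g in genes}

    family_means = _family_means(repeats, config, rng)
    frames = []
    for chrom, seq in genome.items():
        n = len(seq)
        if chrom == config.spikein_name:
            mean_maps = {ctx: np.full(n, config.conversion_failure_rate,
                                      dtype=np.float32) for ctx in _CTX}
        else:
            mean_maps = {ctx: np.full(n, config.intergenic_targets[i],
                                      dtype=np.float32)
                         for i, ctx in enumerate(_CTX)}
            _paint_repeats(mean_maps, repeats, family_means, chrom)
            _paint_genes(mean_maps, genes, region_table, config, chrom,
                         gene_by_id)
        frames.append(_draw_counts(seq, chrom, mean_maps, config, rng))
    table = pd.concat(frames, ignore_index=True)
    logger.info("generate_methylation: %d cytosine records", len(table))
    return table


def _family_means(repeats: pd.DataFrame, config: SyntheticConfig,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    means = {}
    for family in sorted(pd.unique(repeats["family"])) if len(repeats) else []:
        jitter = rng.normal(0.0, 0.3, size=3)
        base = stats.norm.ppf(np.clip(config.te_targets, 1e-9, 1 - 1e-9))
        means[family] = stats.norm.cdf(base + jitter).astype(np.float32)
    return means


def _paint_repeats(mean_maps, repeats, family_means, chrom) -> None:
    sub = repeats[repeats["chromosome"] == chrom] if len(repeats) else repeats
    for _, rep in sub.iterrows():
        fm = family_means[rep["family"]]
        for i, ctx in enumerate(_CTX):
            mean_maps[ctx][int(rep["start"]):int(rep["end"])] = fm[i]


def _paint_genes(mean_maps, genes, region_table, config, chrom,
                 gene_by_id) -> None:
    from .gene_regions import define_regions

    for gene_id in region_table.index:
        g = gene_by_id.get(str(gene_id))
        if g is None or g.chromosome != chrom:
            continue
        row = region_table.loc[gene_id]
        regions = define_regions(g, flank=config.flank,
                                 chromosome_length=len(mean_maps["cg"]),
                                 first_bp=config.first_bp)
        body_len = g.end - g.start
        f_len = regions.first500[1] - regions.first500[0]
        for i, ctx in enumerate(_CTX):
            up = row[f"u_{ctx}"] / 100.0
            down = row[f"d_{ctx}"] / 100.0
            body = row[f"m_{ctx}"] / 100.0
            first = row[f"first500_{ctx}"] / 100.0
            if body_len > f_len:
                # rest-of-body mean chosen so the whole body pools to target
                rest = (body_len * body - f_len * first) / (body_len - f_len)
                rest = min(max(rest, 0.0), 1.0)
            else:
                first = body          # tiny gene: body target applies throughout
                rest = body
            m = mean_maps[ctx]
            m[regions.upstream[0]:regions.upstream[1]] = up
            m[regions.downstream[0]:regions.downstream[1]] = down
            m[g.start:g.end] = rest
            m[regions.first500[0]:regions.first500[1]] = first


def _draw_counts(seq: str, chrom: str, mean_maps, config: SyntheticConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    parts = []
    for strand, base in (("+", b"C"), ("-", b"G")):
        pos = np.flatnonzero(arr == base)
        if pos.size == 0:
            continue
        ctx = classify_context_array(seq, pos, np.full(pos.size, strand))
        keep = np.isin(ctx, ("CG", "CHG", "CHH"))
        pos, ctx = pos[keep], ctx[keep]
        p_nb = config.depth_size / (config.depth_size + config.depth_mean)
        depth = rng.negative_binomial(config.depth_size, p_nb, size=pos.size)
        covered = depth > 0
        pos, ctx, depth = pos[covered], ctx[covered], depth[covered]
        mean = np.empty(pos.size, dtype=np.float64)
        for c in _CTX:
            mask = ctx == c.upper()
            mean[mask] = mean_maps[c][pos[mask]]
        rho = config.overdispersion
        if rho > 0:
            a = np.clip(mean, 1e-9, 1 - 1e-9) * (1 - rho) / rho
            b = (1 - np.clip(mean, 1e-9, 1 - 1e-9)) * (1 - rho) / rho
            p_site = rng.beta(a, b)
            p_site = np.where(mean <= 0, 0.0, np.where(mean >= 1, 1.0, p_site))
        else:
            p_site = mean
        meth = rng.binomial(depth, p_site)
        parts.append(pd.DataFrame({
            "chromosome": chrom,
            "position": pos.astype(np.int64),
            "strand": strand,
            "context": ctx,
            "count_methylated": meth.astype(np.int64),
            "count_unmethylated": (depth - meth).astype(np.int64),
        }))
    if not parts:
        return pd.DataFrame(columns=["chromosome", "position", "strand",
                                     "context", "count_methylated",
                                     "count_unmethylated"])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["position", "strand"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """A complete in-memory synthetic input bundle plus its ground truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneRecord]
    repeats: pd.DataFrame
    cytosines: pd.DataFrame
    region_truth: pd.DataFrame      # true per-gene region percentages
    expression: dict[str, float]
    go_annotations: dict[str, set[str]]
    truth: dict


def generate_bundle(config: SyntheticConfig,
                    outdir: str | Path | None = None) -> Bundle:
    """Generate the whole input bundle from one seed, optionally writing files.

    With *outdir* set, writes ``genome.fa``, ``genes.gff3``, ``repeats.bed``,
    ``cytosines.tsv``, ``expression.tsv``, ``go.tsv`` and ``truth.json``.
    Equal seeds give byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    region_table, truth = simulate_regions(config, rng)
    go = _draw_go(region_table, config, rng)

    spans = (region_table["l_exon"] + region_table["l_intron"]).groupby(
        region_table["chromosome"]).sum()
    counts = region_table["chromosome"].value_counts()
    lengths = []
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        need = int(spans.get(chrom, 0)
                   + (counts.get(chrom, 0) + 1) * (2 * config.flank + 700)
                   + 2 * config.flank)
        lengths.append(max(need, 10_000))
    genome = generate_genome(config, rng, lengths=lengths)
    genes, repeats = generate_genes(genome, config, rng,
                                    region_table=region_table)
    cytosines = generate_methylation(genome, genes, repeats, config, rng,
                                     region_table=region_table)
    expression = {g: float(region_table.loc[g, "expression"])
                  for g in region_table.index}
    truth["region_table"] = "region_truth"
    bundle = Bundle(config=config, genome=genome, genes=genes,
                    repeats=repeats, cytosines=cytosines,
                    region_truth=region_table, expression=expression,
                    go_annotations=go, truth=truth)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(bundle.genome, outdir / "genome.fa")
    write_gff3_genes(bundle.genes, outdir / "genes.gff3")
    write_repeats_bed(bundle.repeats, outdir / "repeats.bed")
    write_cytosine_table(bundle.cytosines, outdir / "cytosines.tsv")
    write_expression_table(bundle.expression, outdir / "expression.tsv")
    write_go_annotations(bundle.go_annotations, outdir / "go.tsv")
    truth = dict(bundle.truth)
    truth["region_table"] = json.loads(
        bundle.region_truth.to_json(orient="index"))
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonable)
        fh.write("\n")
    logger.info("write_bundle: bundle written to %s", outdir)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
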