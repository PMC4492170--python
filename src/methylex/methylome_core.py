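"""Cytosine context classification and genome-scale methylation summaries.

Percent methylation is *pooled* by default: 100 x (sum of methylated read
observations) / (sum of all read observations) over the cytosines of a
stratum.  A per-site mean-of-fractions mode is available behind a flag for
sensitivity analysis; the two disagree whenever coverage varies across
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, CYTOSINE_COLUMNS, ValidationError

logger = logging.getLogger("methylex")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(genome: Mapping[str, str], chromosome: str, position: int,
                     strand: str) -> str:
    """Classify the methylation context of a cytosine residue.

    The context is determined by the two bases 3' of the cytosine on its own
    strand: CG if the next base is G, CHG if the base after next is G, CHH
    otherwise (H = A, C or T).  Returns ``"undefined"`` when fewer than two
    downstream bases exist or any of them is N.

    Raises :class:`ValidationError` if the base at *position* is not a
    cytosine on the given strand (i.e. C on "+", G on "-").
    """
    seq = genome[chromosome]
    base = seq[position]
    if strand == "+":
        if base != "C":
            raise ValidationError(
                f"{chromosome}:{position} on + strand is {base!r}, not C")
        downstream = seq[position + 1: position + 3]
    else:
        if base != "G":
            raise ValidationError(
                f"{chromosome}:{position} on - strand is {base!r} "
                "(not C in minus-strand sense)")
        downstream = seq[max(position - 2, 0): position][::-1].translate(_COMPLEMENT)
    if len(downstream) < 2 or "N" in downstream[:2]:
        return "undefined"
    if downstream[0] == "G":
        return "CG"
    if downstream[1] == "G":
        return "CHG"
    return "CHH"


def classify_context_array(sequence: str, positions: np.ndarray,
                           strands: np.ndarray) -> np.ndarray:
    """Vectorized context classification over one chromosome sequence.

    Positions where the base is not a cytosine on the requested strand are
    returned as ``"invalid"`` rather than raising, so callers can report the
    first offender with its coordinate.
    """
    seq = np.frombuffer(sequence.encode("ascii"), dtype="S1")
    n = len(seq)
    positions = np.asarray(positions)
    plus = np.asarray(strands) == "+"
    out = np.full(len(positions), "undefined", dtype="U9")

    def base_at(idx: np.ndarray, ok: np.ndarray) -> np.ndarray:
        b = np.full(len(idx), b"N", dtype="S1")
        valid = ok & (idx >= 0) & (idx < n)
        b[valid] = seq[idx[valid]]
        return b

    # plus strand: downstream = pos+1, pos+2
    b0 = base_at(positions, plus)
    d1 = base_at(positions + 1, plus)
    d2 = base_at(positions + 2, plus)
    out[plus & (b0 != b"C")] = "invalid"
    ok = plus & (b0 == b"C") & (d1 != b"N") & (d2 != b"N") & \
        (positions + 2 < n)
    out[ok & (d1 == b"G")] = "CG"
    out[ok & (d1 != b"G") & (d2 == b"G")] = "CHG"
    out[ok & (d1 != b"G") & (d2 != b"G")] = "CHH"

    # minus strand: cytosine appears as G on forward; downstream = pos-1, pos-2
    minus = ~plus
    b0 = base_at(positions, minus)
    d1 = base_at(positions - 1, minus)     # complement(C)=G tested directly below
    d2 = base_at(positions - 2, minus)
    out[minus & (b0 != b"G")] = "invalid"
    ok = minus & (b0 == b"G") & (d1 != b"N") & (d2 != b"N") & (positions - 2 >= 0)
    out[ok & (d1 == b"C")] = "CG"          # complement of C is G on minus sense
    out[ok & (d1 != b"C") & (d2 == b"C")] = "CHG"
    out[ok & (d1 != b"C") & (d2 != b"C")] = "CHH"
    return out


# ---------------------------------------------------------------------------
# the track
# ---------------------------------------------------------------------------

class MethylationTrack:
    """Per-cytosine methylation counts, queryable by genomic interval.

    Wraps the six-column cytosine DataFrame with per-chromosome sorted
    position indexes so interval queries are O(log n).  An optional genome
    mapping supplies chromosome lengths for window tiling.
    """

    def __init__(self, records: pd.DataFrame,
                 genome: Mapping[str, str] | None = None):
        df = records[CYTOSINE_COLUMNS].sort_values(
            ["chromosome", "position", "strand"], kind="mergesort")
        self.data = df.reset_index(drop=True)
        self.genome = genome
        self._by_chrom: dict[str, pd.DataFrame] = {
            str(c): sub for c, sub in self.data.groupby("chromosome", sort=True)}
        if genome is not None:
            for chrom in self._by_chrom:
                if chrom not in genome:
                    raise ValidationError(f"track chromosome {chrom!r} not in genome")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def __len__(self) -> int:
        return len(self.data)

    def chromosome_length(self, chrom: str) -> int:
        if self.genome is not None and chrom in self.genome:
            return len(self.genome[chrom])
        sub = self._by_chrom[chrom]
        return int(sub["position"].iloc[-1]) + 1

    def query(self, chromosome: str, start: int, end: int) -> pd.DataFrame:
        """Records with ``start <= position < end`` on *chromosome*."""
        sub = self._by_chrom.get(chromosome)
        if sub is None:
            return self.data.iloc[0:0]
        pos = sub["position"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        return sub.iloc[lo:hi]

    def context_totals(self, subset: pd.DataFrame | None = None,
                       min_coverage: int = 1) -> pd.DataFrame:
        """Pooled (methylated, total) read counts per context.

        Sites with coverage below *min_coverage* are excluded.
        """
        df = self.data if subset is None else subset
        cov = df["count_methylated"] + df["count_unmethylated"]
        df = df[cov >= min_coverage]
        grouped = df.groupby("context", observed=True).agg(
            methylated=("count_methylated", "sum"),
            unmethylated=("count_unmethylated", "sum"))
        grouped = grouped.reindex(CONTEXTS, fill_value=0)
        grouped["total"] = grouped["methylated"] + grouped["unmethylated"]
        return grouped[["methylated", "total"]]


def pooled_percent(methylated: float, total: float) -> float:
    """100 x methylated / total, or NaN when there is no coverage."""
    return 100.0 * methylated / total if total > 0 else float("nan")


def _percent_from_subset(df: pd.DataFrame, per_site_mean: bool,
                         min_coverage: int) -> pd.Series:
    """Per-context percent methylation for an arbitrary record subset."""
    cov = df["count_methylated"] + df["count_unmethylated"]
    df = df[cov >= min_coverage]
    out = {}
    for ctx, sub in df.groupby("context", observed=True):
        cov = sub["count_methylated"] + sub["count_unmethylated"]
        covered = cov > 0
        if not covered.any():
            out[ctx] = float("nan")
        elif per_site_mean:
            out[ctx] = float(100.0 * (sub["count_methylated"][covered]
                                      / cov[covered]).mean())
        else:
            out[ctx] = pooled_percent(sub["count_methylated"].sum(), cov.sum())
    return pd.Series({c: out.get(c, float("nan")) for c in CONTEXTS})


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def global_levels(track: MethylationTrack, per_site_mean: bool = False,
                  min_coverage: int = 1) -> dict[str, float]:
    """Genome-wide percent methylation per context plus the pooled overall level.

    Returns ``{"CG": ..., "CHG": ..., "CHH": ..., "total": ...}``; a context
    with no covered cytosine is reported NaN with a warning.
    """
    if len(track) == 0:
        raise ValidationError("global_levels: empty track")
    totals = track.context_totals(min_coverage=min_coverage)
    if per_site_mean:
        levels = _percent_from_subset(track.data, True, min_coverage).to_dict()
    else:
        levels = {ctx: pooled_percent(row["methylated"], row["total"])
                  for ctx, row in totals.iterrows()}
    for ctx, value in levels.items():
        if np.isnan(value):
            logger.warning("global_levels: no covered cytosines in %s context", ctx)
    if per_site_mean:
        cov = track.data["count_methylated"] + track.data["count_unmethylated"]
        keep = cov >= max(min_coverage, 1)
        levels["total"] = float(
            100.0 * (track.data["count_methylated"][keep] / cov[keep]).mean())
    else:
        levels["total"] = pooled_percent(totals["methylated"].sum(),
                                         totals["total"].sum())
    return levels


@dataclass
class WindowProfile:
    """Tiling-window methylation profile; one row per window in ``data``."""

    window_size: int
    data: pd.DataFrame    # chromosome, start, end, pct_cg/chg/chh/total, n_* counts


def window_methylation(track: MethylationTrack, window_size: int = 1000,
                       per_site_mean: bool = False,
                       min_coverage: int = 1) -> WindowProfile:
    """Percent methylation per context in non-overlapping tiling windows.

    Windows tile each chromosome from 0 in steps of *window_size*; the last
    partial window is retained.  Windows with no covered cytosine in a
    context get NaN there.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    rows = []
    for chrom in track.chromosomes:
        length = track.chromosome_length(chrom)
        sub = track._by_chrom[chrom]
        cov = (sub["count_methylated"] + sub["count_unmethylated"]).to_numpy()
        keep = cov >= min_coverage
        pos = sub["position"].to_numpy()[keep]
        meth = sub["count_methylated"].to_numpy()[keep]
        total = cov[keep]
        ctx = sub["context"].to_numpy()[keep]
        widx = pos // window_size
        n_windows = int(np.ceil(length / window_size))
        for w in range(n_windows):
            start = w * window_size
            end = min(start + window_size, length)
            inw = widx == w
            row: dict[str, object] = {"chromosome": chrom, "start": start, "end": end}
            all_meth = all_tot = 0
            site_fracs_all = []
            for c in CONTEXTS:
                m = inw & (ctx == c)
                tm, tt = int(meth[m].sum()), int(total[m].sum())
                key = c.lower()
                row[f"n_{key}"] = tt
                if per_site_mean:
                    fr = meth[m] / total[m] if m.any() else np.array([])
                    row[f"pct_{key}"] = float(100 * fr.mean()) if fr.size else float("nan")
                    site_fracs_all.append(fr)
                else:
                    row[f"pct_{key}"] = pooled_percent(tm, tt)
                all_meth += tm
                all_tot += tt
            if per_site_mean:
                fr = np.concatenate(site_fracs_all) if site_fracs_all else np.array([])
                row["pct_total"] = float(100 * fr.mean()) if fr.size else float("nan")
            else:
                row["pct_total"] = pooled_percent(all_meth, all_tot)
            row["n_total"] = all_tot
            rows.append(row)
    data = pd.DataFrame(rows)
    logger.info("window_methylation: %d windows of %d bp", len(data), window_size)
    return WindowProfile(window_size=window_size, data=data)


def conversion_efficiency(track: MethylationTrack, spikein_chromosome: str) -> float:
    """Bisulfite conversion efficiency from an unmethylated spike-in control.

    Returns ``1 - (pooled methylated / pooled total)`` over every cytosine
    of the spike-in chromosome, all contexts pooled.  On a fully
    unmethylated control every methylated call is a conversion failure.
    """
    if spikein_chromosome not in track._by_chrom:
        raise ValidationError(
            f"spike-in chromosome {spikein_chromosome!r} not present in track")
    sub = track._by_chrom[spikein_chromosome]
    meth = int(sub["count_methylated"].sum())
    total = meth + int(sub["count_unmethylated"].sum())
    if total == 0:
        raise ValidationError(
            f"spike-in chromosome {spikein_chromosome!r} has zero coverage")
    return 1.0 - meth / total
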