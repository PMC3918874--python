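"""Genome-wide bin-table analysis of siRNA production versus copy number.

The analysis unit is a table of consecutive 100 bp genomic bins carrying a
siRNA read count, a total-RNA read count and a copy number. Preparation
adds a pseudocount of one read to both counts per bin, excludes bins whose
raw total exceeds a cap, and excludes user-specified regions (e.g. sequence
that is single copy in the assembly but high copy in the cell).

Three copy-number normalization schemes are supported:

* ``total_times_cn`` — total counts multiplied by copy number (undoing the
  1/copy dilution of multi-mapped reads) while siRNA counts are kept
  per-producing-copy;
* ``none`` — raw counts;
* ``both_times_cn`` — both counts multiplied by copy number.

The siRNA:total ratio is identical under ``none`` and ``both_times_cn`` —
any copy-number normalization cancels in the ratio — which is why the
top-ratio analysis needs no normalization at all.

Group comparisons use a two-sided Wilcoxon rank-sum test with exact
enumeration for small groups and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .copynumber import CopyNumberTrack
from .mapping import BinTrack

SCHEMES = ("total_times_cn", "none", "both_times_cn")
CN_SPLITS = ("lt2_ge2", "lt5_ge5", "drop_gt5_then_lt2_ge2")
DEFAULT_BOUNDARIES = tuple(range(0, 18, 2))
CN_HIST_EDGES = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, math.inf)
CN_HIST_LABELS = ("1-2", "2-4", "4-8", "8-16", "16-32", ">32")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def rank_sum_test(
    x,
    y,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    When both groups have at most ``exact_max_n`` observations the p-value
    is computed by exact enumeration of all group assignments of the pooled
    (mid-ranked) values; otherwise a normal approximation with tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise AnalysisError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    W = ranks[:n].sum()
    U = W - n * (n + 1) / 2.0

    if n <= exact_max_n and m <= exact_max_n:
        p = _exact_two_sided_p(ranks, n, W)
    else:
        p = _normal_two_sided_p(pooled, ranks, n, m, U)
    return float(U), float(min(p, 1.0))


def _exact_two_sided_p(ranks: np.ndarray, n: int, W_obs: float) -> float:
    """Exact permutation p: fraction of group assignments at least as far
    from the null mean of the rank sum as the observed one."""
    N = len(ranks)
    mu = n * ranks.sum() / N
    obs = abs(W_obs - mu) - 1e-9
    hits = 0
    total = 0
    for comb in itertools.combinations(range(N), n):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= obs:
            hits += 1
        total += 1
    return hits / total


def _normal_two_sided_p(
    pooled: np.ndarray, ranks: np.ndarray, n: int, m: int, U: float
) -> float:
    N = n + m
    mu = n * m / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = abs(U - mu)
    z = max(diff - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    return 2.0 * sps.norm.sf(z)


# ---------------------------------------------------------------------------
# Bin table preparation
# ---------------------------------------------------------------------------

def make_bin_table(
    sirna: BinTrack,
    total: BinTrack,
    cn: CopyNumberTrack,
    max_total: int = 100_000,
    exclusion_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Join siRNA, total-RNA and copy-number tracks on a shared bin grid.

    Returns a DataFrame with one row per bin and columns ``chrom``,
    ``bin_start``, ``sirna_raw``, ``total_raw``, ``sirna``, ``total``
    (pseudocounted: raw + 1), ``copy_number``, ``excluded`` and
    ``exclusion_reason``. Bins with raw total above ``max_total`` and bins
    intersecting an exclusion region are flagged, not dropped.
    """
    if sirna.bin_size != total.bin_size:
        raise AnalysisError(
            f"bin grids differ: {sirna.bin_size} vs {total.bin_size}"
        )
    if sirna.chrom_sizes != total.chrom_sizes:
        raise AnalysisError("siRNA and total tracks cover different chromosomes")
    bin_size = sirna.bin_size
    cn_binned = cn.bin_means(bin_size)

    rows = []
    for chrom in sorted(sirna.chrom_sizes):
        n = sirna.n_bins(chrom)
        s = sirna.combined(chrom)
        t = total.combined(chrom)
        c = cn_binned.get(chrom, np.ones(n))
        if not (len(s) == len(t) == len(c) == n):
            raise AnalysisError(f"mismatched bin grids on {chrom}")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(n) * bin_size,
                    "sirna_raw": s,
                    "total_raw": t,
                    "copy_number": c,
                }
            )
        )
    if not rows:
        return _empty_table()
    table = pd.concat(rows, ignore_index=True)
    table["sirna"] = table["sirna_raw"] + 1
    table["total"] = table["total_raw"] + 1
    table["excluded"] = False
    table["exclusion_reason"] = ""

    over = table["total_raw"] > max_total
    table.loc[over, "excluded"] = True
    table.loc[over, "exclusion_reason"] = "total_above_max"

    for chrom, start, end in exclusion_regions or ():
        hit = (
            (table["chrom"] == chrom)
            & (table["bin_start"] < end)
            & (table["bin_start"] + bin_size > start)
        )
        table.loc[hit, "excluded"] = True
        table.loc[hit & (table["exclusion_reason"] == ""), "exclusion_reason"] = (
            "excluded_region"
        )
    table.attrs["bin_size"] = bin_size
    table.attrs["pseudocount"] = 1
    return table


def _empty_table() -> pd.DataFrame:
    cols = [
        "chrom", "bin_start", "sirna_raw", "total_raw", "copy_number",
        "sirna", "total", "excluded", "exclusion_reason",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def normalize(table: pd.DataFrame, scheme: str = "total_times_cn") -> pd.DataFrame:
    """Add normalized abundance columns ``sirna_norm``/``total_norm``.

    Raw and pseudocounted counts are retained unchanged.
    """
    if scheme not in SCHEMES:
        raise AnalysisError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    out = table.copy()
    if len(out) == 0:
        out["sirna_norm"] = pd.Series(dtype=float)
        out["total_norm"] = pd.Series(dtype=float)
        out.attrs["scheme"] = scheme
        return out
    cn = out["copy_number"].to_numpy(dtype=float)
    if scheme == "total_times_cn":
        out["sirna_norm"] = out["sirna"].astype(float)
        out["total_norm"] = out["total"] * cn
    elif scheme == "none":
        out["sirna_norm"] = out["sirna"].astype(float)
        out["total_norm"] = out["total"].astype(float)
    else:  # both_times_cn
        out["sirna_norm"] = out["sirna"] * cn
        out["total_norm"] = out["total"] * cn
    out.attrs["scheme"] = scheme
    out.attrs["bin_size"] = table.attrs.get("bin_size")
    return out


# ---------------------------------------------------------------------------
# Category comparison
# ---------------------------------------------------------------------------

@dataclass
class CategoryStats:
    label: str
    lo: float
    hi: float
    n_single: int
    n_multi: int
    p: float  # NaN when a group is empty
    median_single: float
    median_multi: float
    mean_rank_single: float = math.nan
    mean_rank_multi: float = math.nan

    @property
    def applicable(self) -> bool:
        return not math.isnan(self.p)

    @property
    def multi_higher(self) -> bool:
        """True when the multi-copy group stochastically dominates."""
        return self.mean_rank_multi > self.mean_rank_single


def _cn_groups(table: pd.DataFrame, cn_split: str) -> tuple[pd.Series, pd.DataFrame]:
    if cn_split not in CN_SPLITS:
        raise AnalysisError(f"unknown cn_split {cn_split!r}; choose from {CN_SPLITS}")
    t = table
    if cn_split == "drop_gt5_then_lt2_ge2":
        t = t[t["copy_number"] <= 5]
        is_multi = t["copy_number"] >= 2
    elif cn_split == "lt5_ge5":
        is_multi = t["copy_number"] >= 5
    else:
        is_multi = t["copy_number"] >= 2
    return is_multi, t


def category_compare(
    table: pd.DataFrame,
    boundaries=DEFAULT_BOUNDARIES,
    cn_split: str = "lt2_ge2",
) -> list[CategoryStats]:
    """Per-abundance-category single- vs multi-copy siRNA comparison.

    Bins are grouped into categories of log2(normalized total abundance)
    using consecutive ``boundaries`` intervals, split by copy number, and
    the normalized siRNA abundances of the two groups are compared with a
    two-sided rank-sum test per category. Categories with an empty group
    return p = NaN.
    """
    if "total_norm" not in table.columns:
        raise AnalysisError("table must be normalized first (call normalize)")
    boundaries = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise AnalysisError("boundaries must be strictly increasing")
    live = table[~table["excluded"]] if len(table) else table
    is_multi, live = _cn_groups(live, cn_split)
    out = []
    logt = np.log2(live["total_norm"].to_numpy(dtype=float)) if len(live) else np.array([])
    for lo, hi in zip(boundaries, boundaries[1:]):
        label = f"{lo}-{hi}"
        in_cat = (logt >= lo) & (logt < hi)
        cat = live[in_cat]
        mask = is_multi.loc[cat.index]
        multi = cat[mask]
        single = cat[~mask]
        sv = single["sirna_norm"].to_numpy(dtype=float)
        mv = multi["sirna_norm"].to_numpy(dtype=float)
        if len(sv) == 0 or len(mv) == 0:
            p = rank_s = rank_m = math.nan
        else:
            _, p = rank_sum_test(sv, mv)
            ranks = _midranks(np.concatenate([sv, mv]))
            rank_s = float(ranks[: len(sv)].mean())
            rank_m = float(ranks[len(sv) :].mean())
        out.append(
            CategoryStats(
                label=label,
                lo=lo,
                hi=hi,
                n_single=len(sv),
                n_multi=len(mv),
                p=p,
                median_single=float(np.median(sv)) if len(sv) else math.nan,
                median_multi=float(np.median(mv)) if len(mv) else math.nan,
                mean_rank_single=rank_s,
                mean_rank_multi=rank_m,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Top-ratio enrichment
# ---------------------------------------------------------------------------

@dataclass
class RatioEnrichment:
    n_top: int
    n_bulk: int
    top_hist: dict[str, int] = field(default_factory=dict)
    bulk_hist: dict[str, int] = field(default_factory=dict)
    mean_cn_top: float = math.nan
    mean_cn_bulk: float = math.nan
    p: float = math.nan
    top_index: pd.Index | None = None


def _cn_histogram(cn: np.ndarray) -> dict[str, int]:
    hist, _ = np.histogram(cn, bins=CN_HIST_EDGES)
    return {label: int(c) for label, c in zip(CN_HIST_LABELS, hist)}


def top_ratio_analysis(
    table: pd.DataFrame,
    top_fraction: float = 0.01,
    drop_noise: bool = True,
    noise_log2_total: float = 2.0,
) -> RatioEnrichment:
    """Copy-number makeup of the bins with the highest siRNA:total ratio.

    The ratio uses pseudocounted raw counts, so no copy-number
    normalization is involved (it would cancel). Bins in the lowest
    abundance category (log2 pseudocounted total below
    ``noise_log2_total``) are removed as noise when ``drop_noise`` is set.
    Ties in the ratio ranking are broken by (chrom, bin_start) for
    determinism. Returns copy-number histograms of the top fraction vs the
    rest and a two-sided rank-sum p comparing copy number between the sets.
    """
    if not 0 < top_fraction < 1:
        raise AnalysisError("top_fraction must be in (0, 1)")
    live = table[~table["excluded"]].copy() if len(table) else table.copy()
    if drop_noise and len(live):
        live = live[np.log2(live["total"].to_numpy(dtype=float)) >= noise_log2_total]
    n_top = int(len(live) * top_fraction)
    if n_top < 2:
        raise AnalysisError(
            f"top fraction of {len(live)} bins yields {n_top} bins (< 2)"
        )
    ratio = live["sirna"].to_numpy(dtype=float) / live["total"].to_numpy(dtype=float)
    live = live.assign(_ratio=ratio).sort_values(
        ["_ratio", "chrom", "bin_start"], ascending=[False, True, True], kind="mergesort"
    )
    top = live.iloc[:n_top]
    bulk = live.iloc[n_top:]
    cn_top = top["copy_number"].to_numpy(dtype=float)
    cn_bulk = bulk["copy_number"].to_numpy(dtype=float)
    _, p = rank_sum_test(cn_top, cn_bulk)
    return RatioEnrichment(
        n_top=len(top),
        n_bulk=len(bulk),
        top_hist=_cn_histogram(cn_top),
        bulk_hist=_cn_histogram(cn_bulk),
        mean_cn_top=float(cn_top.mean()),
        mean_cn_bulk=float(cn_bulk.mean()),
        p=p,
        top_index=top.index,
    )


def chromosome_profile(table: pd.DataFrame, chrom: str) -> pd.DataFrame:
    """Aligned per-bin siRNA:total ratio and copy number for one chromosome."""
    sub = table[table["chrom"] == chrom] if len(table) else table
    if len(table) and len(sub) == 0:
        raise AnalysisError(f"unknown chromosome {chrom!r}")
    sub = sub.sort_values("bin_start") if len(sub) else sub
    return pd.DataFrame(
        {
            "bin_start": sub["bin_start"].to_numpy() if len(sub) else [],
            "ratio": (
                sub["sirna"].to_numpy(dtype=float) / sub["total"].to_numpy(dtype=float)
                if len(sub)
                else []
            ),
            "copy_number": sub["copy_number"].to_numpy() if len(sub) else [],
        }
    )


def write_profile_bedgraph(
    profile: pd.DataFrame, chrom: str, bin_size: int, ratio_path, cn_path
) -> None:
    with open(ratio_path, "w") as fr, open(cn_path, "w") as fc:
        for _, row in profile.iterrows():
            start = int(row["bin_start"])
            fr.write(f"{chrom}\t{start}\t{start + bin_size}\t{row['ratio']:.6g}\n")
            fc.write(f"{chrom}\t{start}\t{start + bin_size}\t{row['copy_number']:.4f}\n")
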