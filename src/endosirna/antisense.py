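"""Census of antisense transcript overlaps with protein-coding genes.

Collates ORF annotations with the three yeast ncRNA classes — CUTs
(cryptic unstable transcripts, degraded by the nuclear exosome), SUTs
(stable unannotated transcripts) and XUTs (Xrn1-sensitive unstable
transcripts, degraded in the cytoplasm) — and counts, for a ladder of
minimum-overlap thresholds, how many ORFs have at least one opposite-strand
feature overlapping them. ORF-ORF overlaps (convergent/divergent gene
pairs) are tallied separately from ORF-ncRNA overlaps.

Also compares siRNA production between ORFs with and without an antisense
partner, and the corresponding mRNA-level comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .mapping import BinTrack

KLASSES = ("ORF", "CUT", "SUT", "XUT")
UNSTABLE_KLASSES = ("CUT", "XUT")  # SUTs are not known to be degraded
DEFAULT_MIN_OVERLAPS = tuple(range(50, 501, 50))


class AntisenseError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    feature_id: str
    klass: str
    unstable: bool | None = None  # None -> default by klass
    expressed_in_glucose: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise AntisenseError(
                f"malformed interval {self.feature_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AntisenseError(f"strand must be + or -, got {self.strand!r}")
        if self.klass not in KLASSES:
            raise AntisenseError(f"klass must be one of {KLASSES}, got {self.klass!r}")

    @property
    def is_unstable(self) -> bool:
        if self.unstable is not None:
            return self.unstable
        return self.klass in UNSTABLE_KLASSES

    @property
    def length(self) -> int:
        return self.end - self.start


FeatureSet = list[Feature]


def overlap_length(a: Feature, b: Feature) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _reciprocal_overlap(a: Feature, b: Feature) -> float:
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def collate_annotations(
    orfs: FeatureSet,
    cuts: FeatureSet,
    suts: FeatureSet,
    xuts: FeatureSet,
    reclass_overlap_fraction: float = 0.5,
) -> tuple[FeatureSet, FeatureSet]:
    """Merge the ncRNA classes and filter ORFs to those expressed in glucose.

    SUTs that were later re-annotated as XUTs are removed: a SUT whose
    reciprocal overlap with a same-strand XUT reaches
    ``reclass_overlap_fraction`` is dropped from the merged set.

    Returns ``(expressed_orfs, ncrnas)``.
    """
    xut_trees: dict[tuple[str, str], IntervalTree] = {}
    for x in xuts:
        xut_trees.setdefault((x.chrom, x.strand), IntervalTree()).addi(
            x.start, x.end, x
        )
    kept_suts = []
    for s in suts:
        tree = xut_trees.get((s.chrom, s.strand))
        reclassified = tree is not None and any(
            _reciprocal_overlap(s, iv.data) >= reclass_overlap_fraction
            for iv in tree.overlap(s.start, s.end)
        )
        if not reclassified:
            kept_suts.append(s)
    expressed = [o for o in orfs if o.expressed_in_glucose]
    return expressed, list(cuts) + kept_suts + list(xuts)


@dataclass
class CensusRow:
    min_overlap: int
    orf_orf: int
    orf_xut: int
    orf_cut: int
    orf_sut: int
    orf_ncrna: int
    orf_unstable_ncrna: int

    @property
    def pct_unstable(self) -> int:
        if self.orf_ncrna == 0:
            return 0
        return round(100 * self.orf_unstable_ncrna / self.orf_ncrna)


def _strand_trees(features: FeatureSet) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f in features:
        trees.setdefault((f.chrom, f.strand), IntervalTree()).addi(f.start, f.end, f)
    return trees


def overlap_census(
    orfs: FeatureSet,
    features: FeatureSet,
    min_overlaps: Iterable[int] = DEFAULT_MIN_OVERLAPS,
) -> pd.DataFrame:
    """Count ORFs with an opposite-strand overlap, per threshold and class.

    For each minimum overlap, an ORF is counted in a class column if at
    least one opposite-strand feature of that class overlaps it by at least
    the threshold (in shared coordinates). Each ORF counts at most once per
    column; the ncRNA total counts ORFs overlapped by any ncRNA class, and
    the unstable column those overlapped by at least one unstable ncRNA.
    ORF-ORF overlaps are reported separately.
    """
    min_overlaps = sorted(min_overlaps)
    if not min_overlaps or min_overlaps[0] <= 0:
        raise AntisenseError("min_overlap thresholds must be positive")

    ncrnas = [f for f in features if f.klass != "ORF"]
    other_orfs = [f for f in features if f.klass == "ORF"]
    nc_trees = _strand_trees(ncrnas)
    orf_trees = _strand_trees(other_orfs + orfs)

    # best (largest) opposite-strand overlap per ORF, per column
    best: dict[str, dict[str, int]] = {
        col: {} for col in ("ORF", "CUT", "SUT", "XUT", "ncRNA", "unstable")
    }
    for orf in orfs:
        opp = "-" if orf.strand == "+" else "+"
        for iv in nc_trees.get((orf.chrom, opp), IntervalTree()).overlap(
            orf.start, orf.end
        ):
            f = iv.data
            ov = max(0, min(orf.end, f.end) - max(orf.start, f.start))
            if ov <= 0:
                continue
            d = best[f.klass]
            d[orf.feature_id] = max(d.get(orf.feature_id, 0), ov)
            d = best["ncRNA"]
            d[orf.feature_id] = max(d.get(orf.feature_id, 0), ov)
            if f.is_unstable:
                d = best["unstable"]
                d[orf.feature_id] = max(d.get(orf.feature_id, 0), ov)
        for iv in orf_trees.get((orf.chrom, opp), IntervalTree()).overlap(
            orf.start, orf.end
        ):
            f = iv.data
            if f.feature_id == orf.feature_id:
                continue
            ov = max(0, min(orf.end, f.end) - max(orf.start, f.start))
            if ov > 0:
                d = best["ORF"]
                d[orf.feature_id] = max(d.get(orf.feature_id, 0), ov)

    rows = []
    for thr in min_overlaps:
        def count(col: str) -> int:
            return sum(1 for v in best[col].values() if v >= thr)

        rows.append(
            CensusRow(
                min_overlap=thr,
                orf_orf=count("ORF"),
                orf_xut=count("XUT"),
                orf_cut=count("CUT"),
                orf_sut=count("SUT"),
                orf_ncrna=count("ncRNA"),
                orf_unstable_ncrna=count("unstable"),
            )
        )
    return pd.DataFrame(
        {
            "min_overlap": [r.min_overlap for r in rows],
            "ORF-ORF": [r.orf_orf for r in rows],
            "ORF-XUT": [r.orf_xut for r in rows],
            "ORF-CUT": [r.orf_cut for r in rows],
            "ORF-SUT": [r.orf_sut for r in rows],
            "ORF-ncRNA": [r.orf_ncrna for r in rows],
            "ORF-unstable-ncRNA": [r.orf_unstable_ncrna for r in rows],
            "pct_unstable": [r.pct_unstable for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# siRNA / mRNA comparison of antisense vs non-antisense ORFs
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    p: float  # NaN when a group is empty or too small

    @property
    def applicable(self) -> bool:
        return not math.isnan(self.p)


def _per_orf_counts(
    orfs: FeatureSet, counts: "BinTrack | Mapping[str, float]"
) -> dict[str, float]:
    if isinstance(counts, BinTrack):
        out = {}
        for orf in orfs:
            if orf.chrom not in counts.chrom_sizes:
                out[orf.feature_id] = 0.0
                continue
            arr = counts.combined(orf.chrom)
            b0 = orf.start // counts.bin_size
            b1 = (orf.end - 1) // counts.bin_size
            out[orf.feature_id] = float(arr[b0 : b1 + 1].sum())
        return out
    return {k: float(v) for k, v in counts.items()}


def orf_sirna_comparison(
    orfs: FeatureSet,
    features: FeatureSet,
    sirna: "BinTrack | Mapping[str, float]",
    polyA_counts: Mapping[str, float],
    min_overlap: int = 250,
    min_reads: int = 100,
) -> GroupComparison:
    """Compare siRNA abundance of ORFs with and without an antisense partner.

    ORFs passing the poly(A)+ expression filter (``> min_reads`` reads) are
    partitioned by whether an opposite-strand ncRNA overlaps them by at
    least ``min_overlap`` bp; per-ORF siRNA read sums over the ORF footprint
    are compared with a two-sided Student's t-test. An empty group yields a
    NaN p, not an exception.
    """
    expressed = [o for o in orfs if polyA_counts.get(o.feature_id, 0) > min_reads]
    with_ids: set[str] = set()
    if expressed:
        nc_trees = _strand_trees([f for f in features if f.klass != "ORF"])
        for orf in expressed:
            opp = "-" if orf.strand == "+" else "+"
            for iv in nc_trees.get((orf.chrom, opp), IntervalTree()).overlap(
                orf.start, orf.end
            ):
                ov = max(0, min(orf.end, iv.end) - max(orf.start, iv.begin))
                if ov >= min_overlap:
                    with_ids.add(orf.feature_id)
                    break
    per_orf = _per_orf_counts(expressed, sirna)
    grp_with = np.array([per_orf[o.feature_id] for o in expressed if o.feature_id in with_ids])
    grp_without = np.array(
        [per_orf[o.feature_id] for o in expressed if o.feature_id not in with_ids]
    )
    if len(grp_with) < 2 or len(grp_without) < 2:
        return GroupComparison(
            n_with=len(grp_with),
            n_without=len(grp_without),
            mean_with=float(grp_with.mean()) if len(grp_with) else math.nan,
            mean_without=float(grp_without.mean()) if len(grp_without) else math.nan,
            p=math.nan,
        )
    _, p = sps.ttest_ind(grp_with, grp_without)
    return GroupComparison(
        n_with=len(grp_with),
        n_without=len(grp_without),
        mean_with=float(grp_with.mean()),
        mean_without=float(grp_without.mean()),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# BED / GFF3 input
# ---------------------------------------------------------------------------

def read_features_bed(path: str | Path, klass: str) -> FeatureSet:
    """Load a BED6 file as features of one class."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            out.append(Feature(chrom, start, end, strand, name, klass))
    return out


def read_features_gff3(path: str | Path, klass_attr: str = "klass") -> FeatureSet:
    """Load features from GFF3; class from the `klass` attribute or the type column."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            klass = attrs.get(klass_attr, f[2] if f[2] in KLASSES else "ORF")
            out.append(
                Feature(
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    feature_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    klass=klass,
                )
            )
    return out
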