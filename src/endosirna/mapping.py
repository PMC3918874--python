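"""Read placement with a repeat-aware multi-mapper policy, and binned tracks.

Reads are placed by exhaustive exact (or 1-mismatch) substring search on
both strands of the genome. A read with several equally good sites is
assigned to one of them uniformly at random — the standard treatment of
multi-mapping reads, which divides a repeat family's reads evenly amongst
its copies and so dilutes per-copy counts by 1/copy-number. The number of
equivalent sites is retained on each placement.

Counts are accumulated in consecutive fixed-width bins; a read is
attributed to the bin containing its 5' end, which makes count conservation
exact (sum of bins == placed reads).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GenomeBuild, reverse_complement
from .reads import ReadSet


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class Placement:
    read_id: str
    chrom: str
    start: int  # 0-based leftmost genome coordinate
    strand: str
    read_length: int
    n_equivalent_sites: int
    chosen_site_index: int
    n_mismatches: int = 0


@dataclass
class BinTrack:
    """Per-(chrom, strand) binned read counts on a half-open bin grid.

    Unstranded tracks use strand key ``"."``.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    counts: dict[tuple[str, str], np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def get(self, chrom: str, strand: str = ".") -> np.ndarray:
        key = (chrom, strand)
        if key in self.counts:
            return self.counts[key]
        return np.zeros(self.n_bins(chrom), dtype=np.int64)

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def combined(self, chrom: str) -> np.ndarray:
        """Strand-summed counts for one chromosome."""
        out = np.zeros(self.n_bins(chrom), dtype=np.int64)
        for (c, _s), arr in self.counts.items():
            if c == chrom:
                out += arr
        return out

    def write_bedgraph(self, path: str | Path, strand: str | None = None) -> None:
        with open(path, "w") as fh:
            for (chrom, s), arr in sorted(self.counts.items()):
                if strand is not None and s != strand:
                    continue
                size = self.chrom_sizes[chrom]
                for i, v in enumerate(arr):
                    if v:
                        fh.write(
                            f"{chrom}\t{i * self.bin_size}\t"
                            f"{min((i + 1) * self.bin_size, size)}\t{int(v)}\n"
                        )


class GenomeIndex:
    """Exact-substring index: every genome window of one length -> sites.

    Forward-strand windows only are indexed; minus-strand hits are found by
    looking up the reverse complement of the query.
    """

    def __init__(self, chromosomes: dict[str, str], length: int):
        if length < 1:
            raise MappingError("index length must be >= 1")
        self.length = length
        self.sites: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(chromosomes):
            seq = chromosomes[chrom]
            if length > len(seq):
                continue
            add = self.sites
            for i in range(len(seq) - length + 1):
                add[seq[i : i + length]].append((chrom, i))
        if not self.sites:
            raise MappingError("no chromosome is long enough for this read length")
        self.sites = dict(self.sites)

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """All perfect-match sites of `seq` on either strand, sorted."""
        fwd = self.sites.get(seq, ())
        hits = [(c, p, "+") for c, p in fwd]
        rc = reverse_complement(seq)
        if rc != seq:
            hits += [(c, p, "-") for c, p in self.sites.get(rc, ())]
        else:
            hits += [(c, p, "-") for c, p in fwd]
        hits.sort()
        return hits

    def lookup_one_mismatch(self, seq: str) -> list[tuple[str, int, str]]:
        """All 1-mismatch sites (exact sites excluded), sorted, deduplicated."""
        seen = set()
        arr = list(seq)
        for i, orig in enumerate(arr):
            for b in "ACGT":
                if b == orig:
                    continue
                arr[i] = b
                for hit in self.lookup("".join(arr)):
                    seen.add(hit)
            arr[i] = orig
        seen -= set(self.lookup(seq))
        return sorted(seen)


def map_reads(
    reads: ReadSet,
    build: GenomeBuild,
    max_mismatch: int = 0,
    seed: int = 0,
    index_cache: dict[int, GenomeIndex] | None = None,
) -> list[Placement]:
    """Place every read at a random choice among its best-scoring sites.

    Sites are ranked by mismatch count (0 before 1); among the minimal-
    mismatch sites one is chosen uniformly at random from a dedicated,
    seeded RNG stream, so E[reads per copy of an m-copy family] = total/m.
    Reads with no site within ``max_mismatch`` are omitted (reported via the
    returned placements' read ids).
    """
    if max_mismatch not in (0, 1):
        raise MappingError("max_mismatch must be 0 or 1")
    if not reads.reads:
        raise MappingError("empty read set")
    rng = np.random.default_rng(seed)
    indexes = index_cache if index_cache is not None else {}
    placements: list[Placement] = []
    for r in reads.reads:
        L = len(r.sequence)
        if L not in indexes:
            indexes[L] = GenomeIndex(build.chromosomes, L)
        idx = indexes[L]
        hits = idx.lookup(r.sequence)
        nmm = 0
        if not hits and max_mismatch >= 1:
            hits = idx.lookup_one_mismatch(r.sequence)
            nmm = 1
        if not hits:
            continue
        choice = int(rng.integers(0, len(hits))) if len(hits) > 1 else 0
        chrom, start, strand = hits[choice]
        placements.append(
            Placement(
                read_id=r.read_id,
                chrom=chrom,
                start=start,
                strand=strand,
                read_length=L,
                n_equivalent_sites=len(hits),
                chosen_site_index=choice,
                n_mismatches=nmm,
            )
        )
    return placements


def bin_counts(
    placements: list[Placement],
    chrom_sizes: dict[str, int],
    bin_size: int = 100,
    stranded: bool = False,
) -> BinTrack:
    """Accumulate placements into consecutive bins by 5' end.

    The 5' end is ``start`` for plus-strand placements and
    ``start + read_length - 1`` for minus-strand placements.
    """
    if bin_size < 1:
        raise MappingError("bin_size must be >= 1")
    per_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for p in placements:
        five_prime = p.start if p.strand == "+" else p.start + p.read_length - 1
        strand = p.strand if stranded else "."
        per_key[(p.chrom, strand)].append(five_prime // bin_size)
    counts = {}
    for (chrom, strand), idxs in per_key.items():
        n = -(-chrom_sizes[chrom] // bin_size)
        counts[(chrom, strand)] = np.bincount(idxs, minlength=n).astype(np.int64)
    return BinTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes), counts=counts)


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

def write_sam(
    placements: list[Placement],
    build: GenomeBuild,
    path: str | Path,
) -> None:
    """Export placements as a minimal SAM file (sequence/quality omitted)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in sorted(build.chromosomes):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(build.chromosomes[name])}\n")
        for p in placements:
            flag = 16 if p.strand == "-" else 0
            fh.write(
                f"{p.read_id}\t{flag}\t{p.chrom}\t{p.start + 1}\t255\t"
                f"{p.read_length}M\t*\t0\t0\t*\t*\tNH:i:{p.n_equivalent_sites}\n"
            )


def read_sam(path: str | Path) -> list[Placement]:
    """Import placements from a SAM file (internal or external origin)."""
    import pysam

    placements = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            n_sites = rec.get_tag("NH") if rec.has_tag("NH") else 1
            placements.append(
                Placement(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    read_length=rec.infer_query_length() or rec.query_length,
                    n_equivalent_sites=int(n_sites),
                    chosen_site_index=0,
                )
            )
    return placements
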