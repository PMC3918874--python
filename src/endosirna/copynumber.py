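"""Genomic copy-number track from short-segment multiplicity.

The genome is split into overlapping k bp segments at 1 bp intervals
(k = 20 by default); each segment's multiplicity is the number of
perfect-match occurrences of its sequence genome-wide. Binned to the same
grid as the read counts, the mean segment multiplicity per bin is a direct
measure of how many genomic sequences match each bin — the copy number that
multi-mapper read assignment divides counts by.

Reverse-complement occurrences are counted by default, since reads map to
either strand; a flag disables this.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .genome import GenomeBuild, reverse_complement


class CopyNumberError(ValueError):
    pass


class CopyNumberTrack:
    """Per-base segment multiplicity and its per-bin mean."""

    def __init__(self, k: int, multiplicity: dict[str, np.ndarray], chrom_sizes: dict[str, int]):
        self.k = k
        self.multiplicity = multiplicity  # chrom -> array over segment starts
        self.chrom_sizes = chrom_sizes

    def bin_means(self, bin_size: int = 100) -> dict[str, np.ndarray]:
        """Mean multiplicity of segments whose start lies in each bin.

        Tail bins past the last segment start inherit the value of the last
        populated bin, so the track covers the full bin grid with values >= 1.
        """
        out = {}
        for chrom, mult in self.multiplicity.items():
            n = -(-self.chrom_sizes[chrom] // bin_size)
            starts = np.arange(len(mult)) // bin_size
            sums = np.bincount(starts, weights=mult, minlength=n)
            counts = np.bincount(starts, minlength=n)
            vals = np.ones(n)
            filled = counts > 0
            vals[filled] = sums[filled] / counts[filled]
            if filled.any():
                last = np.nonzero(filled)[0][-1]
                vals[last + 1 :] = vals[last]
            out[chrom] = vals
        return out

    def mean(self) -> float:
        total = sum(m.sum() for m in self.multiplicity.values())
        n = sum(len(m) for m in self.multiplicity.values())
        return float(total / n)

    def write_bedgraph(self, path: str | Path, bin_size: int = 100) -> None:
        binned = self.bin_means(bin_size)
        with open(path, "w") as fh:
            for chrom in sorted(binned):
                size = self.chrom_sizes[chrom]
                for i, v in enumerate(binned[chrom]):
                    fh.write(
                        f"{chrom}\t{i * bin_size}\t{min((i + 1) * bin_size, size)}\t"
                        f"{v:.4f}\n"
                    )


def kmer_copy_number(
    build: GenomeBuild | dict[str, str],
    k: int = 20,
    count_reverse_complement: bool = True,
) -> CopyNumberTrack:
    """Multiplicity of every overlapping k bp segment of the genome.

    For each segment start, multiplicity = number of perfect-match
    occurrences of that segment's sequence anywhere in the genome, plus its
    reverse-complement occurrences when ``count_reverse_complement`` is set
    (a palindromic segment is not double-counted). Every segment matches
    itself, so multiplicity >= 1 everywhere.
    """
    chromosomes = build.chromosomes if isinstance(build, GenomeBuild) else build
    if not chromosomes:
        raise CopyNumberError("empty genome")
    for name, seq in chromosomes.items():
        if len(seq) < k:
            raise CopyNumberError(f"chromosome {name} shorter than k={k}")

    counts: Counter[str] = Counter()
    for name in sorted(chromosomes):
        seq = chromosomes[name]
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1

    multiplicity = {}
    for name in sorted(chromosomes):
        seq = chromosomes[name]
        n = len(seq) - k + 1
        mult = np.empty(n, dtype=np.int64)
        for i in range(n):
            kmer = seq[i : i + k]
            m = counts[kmer]
            if count_reverse_complement:
                rc = reverse_complement(kmer)
                if rc != kmer:
                    m += counts.get(rc, 0)
            mult[i] = m
        multiplicity[name] = mult
    sizes = {name: len(seq) for name, seq in chromosomes.items()}
    return CopyNumberTrack(k=k, multiplicity=multiplicity, chrom_sizes=sizes)
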