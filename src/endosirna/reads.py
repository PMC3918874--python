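"""Sequencing-read simulation from kinetic steady states.

Two library types are emulated, mirroring the two sequenced fractions the
analysis consumes: a ``total`` RNA library sampled from single-stranded
sense/antisense abundances, and a ``sirna`` library sampled from
dsRNA-derived siRNA levels (both strands of a duplex contribute equally).

Reads are error-free exact substrings of the genome by default, with an
optional uniform substitution rate; each read records its true origin so
mapping can be evaluated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome import GenomeBuild, reverse_complement
from .kinetics import DEFAULT_SIRNA_LENGTH


class ReadSimError(ValueError):
    pass


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    true_chrom: str
    true_start: int  # 0-based position of the read's leftmost genome base
    true_strand: str
    library: str  # "total" | "sirna"
    locus_id: str | None = None


@dataclass
class ReadSet:
    reads: list[SimRead]
    seed: int
    library: str

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path: str | Path, quality: str = "I") -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")

    def write_manifest(self, path: str | Path) -> None:
        """TSV truth table: one row per read."""
        with open(path, "w") as fh:
            fh.write("read_id\tchrom\tstart\tstrand\tlibrary\tlocus_id\n")
            for r in self.reads:
                fh.write(
                    f"{r.read_id}\t{r.true_chrom}\t{r.true_start}\t{r.true_strand}\t"
                    f"{r.library}\t{r.locus_id or '.'}\n"
                )


# abundances: (locus_id, strand) -> expected molecule count for that family.
Abundances = Mapping[tuple[str, str], float]


def sample_reads(
    build: GenomeBuild,
    abundances: Abundances,
    n_reads: int,
    read_length: int,
    library: str,
    seed: int,
    error_rate: float = 0.0,
) -> ReadSet:
    """Draw reads multinomially across (locus copy, strand) cells.

    A family's abundance is split evenly across its copies; within a copy,
    read start positions are uniform over the transcript footprint. For the
    ``sirna`` library the abundance keys may use strand ``"ds"`` to denote
    dsRNA-derived siRNA, which is sampled from both strands with equal
    probability, at the configured siRNA read length.
    """
    if n_reads <= 0:
        raise ReadSimError("n_reads must be > 0")
    if library not in ("total", "sirna"):
        raise ReadSimError(f"unknown library {library!r}")

    rng = np.random.default_rng(seed)

    cells: list[tuple[str, str, object]] = []  # (locus_id, strand, placement)
    weights: list[float] = []
    for (locus_id, strand), level in abundances.items():
        if level < 0:
            raise ReadSimError("abundances must be >= 0")
        if level == 0:
            continue
        placements = build.placements_for(locus_id)
        if not placements:
            raise ReadSimError(f"no placements for locus {locus_id!r}")
        strands = ("+", "-") if strand == "ds" else (strand,)
        for p in placements:
            if p.end - p.start < read_length:
                raise ReadSimError(
                    f"read_length {read_length} exceeds footprint of {p.name}"
                )
            for s in strands:
                cells.append((locus_id, s, p))
                weights.append(level / (len(placements) * len(strands)))
    if not cells:
        raise ReadSimError("all abundances are zero")

    w = np.asarray(weights)
    counts = rng.multinomial(n_reads, w / w.sum())

    reads: list[SimRead] = []
    idx = 0
    for (locus_id, strand, p), c in zip(cells, counts):
        if c == 0:
            continue
        starts = rng.integers(p.start, p.end - read_length + 1, size=c)
        chrom_seq = build.chromosomes[p.chrom]
        for st in starts:
            seq = chrom_seq[st : st + read_length]
            if strand == "-":
                seq = reverse_complement(seq)
            if error_rate > 0:
                seq = _add_errors(rng, seq, error_rate)
            reads.append(
                SimRead(
                    read_id=f"{library}_{idx}",
                    sequence=seq,
                    true_chrom=p.chrom,
                    true_start=int(st),
                    true_strand=strand,
                    library=library,
                    locus_id=locus_id,
                )
            )
            idx += 1
    return ReadSet(reads=reads, seed=seed, library=library)


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for h in hits:
        i = int(np.searchsorted(bases, arr[h]))
        arr[h] = bases[(i + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode()


def sirna_read_length(configured: int | None = None) -> int:
    return configured or DEFAULT_SIRNA_LENGTH
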