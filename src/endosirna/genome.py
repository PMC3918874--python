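"""Synthetic genomes with planted single- and multi-copy locus families.

Builds a random background chromosome and plants locus families into it,
either as a single copy, a tandem array, dispersed copies, or a tandem
cluster on a separate extrachromosomal element (emulating a high-copy
plasmid). Inter-copy sequence divergence is modelled as substitutions only,
so every copy of a family has the same length and a well-defined per-base
alignment to the family consensus.

Coordinates are 0-based half-open internally; BED output keeps that
convention and GFF3 output is converted to 1-based closed intervals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")

ARRANGEMENTS = ("single", "tandem", "dispersed", "extrachromosomal_cluster")

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlacementError(ValueError):
    """Planted loci cannot be placed within the background genome."""


@dataclass(frozen=True)
class LocusSpec:
    """A locus family to plant in the genome.

    Parameters
    ----------
    locus_id:
        Unique family name.
    unit_length:
        Length in bp of one copy.
    copy_number:
        Number of copies (>= 1).
    arrangement:
        ``single``, ``tandem`` (adjacent copies on the main chromosome),
        ``dispersed`` (copies at separated positions) or
        ``extrachromosomal_cluster`` (tandem copies on their own element).
    divergence:
        Expected fraction of positions at which two copies differ
        (substitutions only), in [0, 1).
    sense_rate, antisense_rate:
        Transcription initiation rates per copy per unit time, carried
        through to the kinetics stage.
    """

    locus_id: str
    unit_length: int
    copy_number: int = 1
    arrangement: str = "single"
    divergence: float = 0.0
    sense_rate: float = 0.0
    antisense_rate: float = 0.0

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError(f"divergence must be in [0, 1), got {self.divergence}")
        if self.unit_length < 1:
            raise ValueError("unit_length must be positive")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(
                f"arrangement must be one of {ARRANGEMENTS}, got {self.arrangement!r}"
            )
        if self.arrangement == "single" and self.copy_number != 1:
            raise ValueError("arrangement 'single' requires copy_number == 1")
        if self.sense_rate < 0 or self.antisense_rate < 0:
            raise ValueError("transcription rates must be >= 0")

    @property
    def total_length(self) -> int:
        return self.unit_length * self.copy_number


@dataclass(frozen=True)
class CopyPlacement:
    """Genomic location of one copy of a planted locus."""

    locus_id: str
    copy_index: int
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    @property
    def name(self) -> str:
        return f"{self.locus_id}.{self.copy_index}"


@dataclass
class GenomeBuild:
    """A synthetic genome plus the ground truth of what was planted where."""

    chromosomes: dict[str, str]
    placements: list[CopyPlacement]
    specs: list[LocusSpec] = field(default_factory=list)
    rng_seed: int | None = None

    def spec(self, locus_id: str) -> LocusSpec:
        for s in self.specs:
            if s.locus_id == locus_id:
                return s
        raise KeyError(locus_id)

    def placements_for(self, locus_id: str) -> list[CopyPlacement]:
        return [p for p in self.placements if p.locus_id == locus_id]

    def sequence_of(self, placement: CopyPlacement) -> str:
        return self.chromosomes[placement.chrom][placement.start : placement.end]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    # ------------------------------------------------------------------ IO
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.chromosomes):
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_bed(self, path: str | Path) -> None:
        """BED6 of planted copies, 0-based half-open."""
        with open(path, "w") as fh:
            for p in self.placements:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\n"
                )

    def write_gff3(self, path: str | Path) -> None:
        """GFF3 of planted copies, 1-based closed."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for p in self.placements:
                attrs = f"ID={p.name};locus_id={p.locus_id};copy_index={p.copy_index}"
                fh.write(
                    f"{p.chrom}\tendosirna\tplanted_locus\t{p.start + 1}\t{p.end}\t"
                    f".\t{p.strand}\t.\t{attrs}\n"
                )

    def write_manifest(self, path: str | Path) -> None:
        """TSV truth table of locus families and their copies."""
        with open(path, "w") as fh:
            fh.write(
                "locus_id\tcopy_index\tchrom\tstart\tend\tstrand\t"
                "copy_number\tarrangement\tdivergence\tsense_rate\tantisense_rate\n"
            )
            for p in self.placements:
                s = self.spec(p.locus_id)
                fh.write(
                    f"{p.locus_id}\t{p.copy_index}\t{p.chrom}\t{p.start}\t{p.end}\t"
                    f"{p.strand}\t{s.copy_number}\t{s.arrangement}\t{s.divergence}\t"
                    f"{s.sense_rate}\t{s.antisense_rate}\n"
                )

    def sha256(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.chromosomes):
            h.update(name.encode())
            h.update(self.chromosomes[name].encode())
        return h.hexdigest()


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position independently with probability `rate`.

    Substitutions always change the base (drawn uniformly from the three
    alternatives), so `rate` is the expected per-base difference from the
    input sequence.
    """
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        # shift by 1..3 in base index space: guaranteed different base
        idx = np.searchsorted(BASES, out[hits])
        out[hits] = BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return out


def _place_intervals(
    rng: np.random.Generator,
    lengths: Sequence[int],
    genome_length: int,
    occupied: list[tuple[int, int]],
    min_gap: int = 1,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Choose non-overlapping intervals of the given lengths on [0, genome_length)."""
    chosen: list[tuple[int, int]] = []
    taken = list(occupied)
    for length in lengths:
        if length > genome_length:
            raise PlacementError(
                f"planted length {length} exceeds genome length {genome_length}"
            )
        for _ in range(max_tries):
            start = int(rng.integers(0, genome_length - length + 1))
            end = start + length
            if all(
                end + min_gap <= s or start >= e + min_gap for s, e in taken
            ):
                taken.append((start, end))
                chosen.append((start, end))
                break
        else:
            raise PlacementError(
                "could not place planted loci without overlap; "
                "background too small or too crowded"
            )
    return chosen


def build_genome(
    specs: Iterable[LocusSpec],
    background_length: int,
    seed: int,
    main_chrom: str = "chrI",
) -> GenomeBuild:
    """Generate a genome with the requested locus families planted.

    The main chromosome is i.i.d. uniform random sequence of
    ``background_length`` bp into which chromosomal loci are written
    (overwriting background, so the chromosome length is exactly
    ``background_length``). ``extrachromosomal_cluster`` families go on
    their own element named ``plasmid_<locus_id>``.

    Copies of a family are derived from one consensus sequence; each copy is
    independently mutated at rate divergence/2 so that the *pairwise*
    expected difference between copies is ``divergence`` per base.
    """
    specs = list(specs)
    ids = [s.locus_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("locus_id values must be unique")
    chromosomal = [s for s in specs if s.arrangement != "extrachromosomal_cluster"]
    planted = sum(s.total_length for s in chromosomal)
    if planted >= background_length:
        raise PlacementError(
            f"planted length {planted} must be smaller than background_length "
            f"{background_length}"
        )

    rng = np.random.default_rng(seed)
    chrom = _random_sequence(rng, background_length)
    placements: list[CopyPlacement] = []
    occupied: list[tuple[int, int]] = []
    chromosomes: dict[str, str] = {}

    for spec in specs:
        consensus = _random_sequence(rng, spec.unit_length)
        per_copy_rate = spec.divergence / 2.0
        copies = [
            _mutate(rng, consensus, per_copy_rate) for _ in range(spec.copy_number)
        ]
        if spec.arrangement == "extrachromosomal_cluster":
            name = f"plasmid_{spec.locus_id}"
            seq = np.concatenate(copies)
            chromosomes[name] = seq.tobytes().decode()
            for i in range(spec.copy_number):
                placements.append(
                    CopyPlacement(
                        spec.locus_id,
                        i,
                        name,
                        i * spec.unit_length,
                        (i + 1) * spec.unit_length,
                    )
                )
        elif spec.arrangement in ("single", "tandem"):
            block = _place_intervals(
                rng, [spec.total_length], background_length, occupied
            )[0]
            occupied.append(block)
            for i in range(spec.copy_number):
                start = block[0] + i * spec.unit_length
                end = start + spec.unit_length
                chrom[start:end] = copies[i]
                placements.append(
                    CopyPlacement(spec.locus_id, i, main_chrom, start, end)
                )
        else:  # dispersed
            spots = _place_intervals(
                rng,
                [spec.unit_length] * spec.copy_number,
                background_length,
                occupied,
                min_gap=2,  # distinct, non-adjacent positions
            )
            occupied.extend(spots)
            for i, (start, end) in enumerate(spots):
                chrom[start:end] = copies[i]
                placements.append(
                    CopyPlacement(spec.locus_id, i, main_chrom, start, end)
                )

    chromosomes[main_chrom] = chrom.tobytes().decode()
    placements.sort(key=lambda p: (p.chrom, p.start))
    return GenomeBuild(
        chromosomes=chromosomes, placements=placements, specs=specs, rng_seed=seed
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into a name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed_placements(path: str | Path) -> list[CopyPlacement]:
    """Reconstruct copy placements from a BED6 file written by `write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            locus_id, copy_index = name.rsplit(".", 1)
            out.append(
                CopyPlacement(
                    locus_id, int(copy_index), chrom, int(start), int(end), strand
                )
            )
    return out
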