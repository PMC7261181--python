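"""Genome, coverage-track and interval data model with bedGraph/BED I/O.

All internal coordinates are 0-based half-open, the convention of the
bedGraph and BED formats this module reads and writes.  Coverage tracks are
unstranded step functions; absent positions carry value 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence
from pathlib import Path

import numpy as np


class GenomeIOError(ValueError):
    """Malformed genomic input (unknown chromosome, bad coordinates, ...)."""


class UnknownChromosomeError(GenomeIOError):
    pass


class CoordinateError(GenomeIOError):
    pass


class NegativeValueError(GenomeIOError):
    pass


class LabelVocabularyError(GenomeIOError):
    pass


@dataclass(frozen=True)
class GenomeDef:
    """Named chromosomes with lengths and a designated mitochondrial contig.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    mito_name
        Name of the mitochondrial contig; must be one of the chromosomes.
        Mitochondrial DNA replicates asynchronously and is therefore fully
        double-labeled, making it the internal normalization control.
    """

    chromosomes: tuple[tuple[str, int], ...]
    mito_name: str

    def __init__(self, chromosomes: Iterable[tuple[str, int]], mito_name: str):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise GenomeIOError("duplicate chromosome names")
        for n, l in chroms:
            if l < 1:
                raise GenomeIOError(f"chromosome {n} has non-positive length {l}")
        if mito_name not in names:
            raise UnknownChromosomeError(
                f"mito_name {mito_name!r} not among chromosomes"
            )
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "mito_name", mito_name)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    @property
    def nuclear_names(self) -> list[str]:
        return [n for n in self.names if n != self.mito_name]


@dataclass
class CoverageTrack:
    """Per-chromosome step function over half-open intervals (bedGraph).

    ``intervals[chrom]`` is a list of ``(start, end, value)`` triples, sorted,
    non-overlapping, with ``end > start`` and non-negative values.
    """

    intervals: dict[str, list[tuple[int, int, float]]]
    sample_id: str = ""

    def validate(self, genome: GenomeDef) -> None:
        for chrom, ivs in self.intervals.items():
            clen = genome.length_of(chrom)
            prev_end = 0
            first = True
            for s, e, v in ivs:
                if not (0 <= s < e <= clen):
                    raise CoordinateError(
                        f"{chrom}:{s}-{e} out of bounds (length {clen})"
                    )
                if v < 0:
                    raise NegativeValueError(f"negative value {v} at {chrom}:{s}-{e}")
                if not first and s < prev_end:
                    raise CoordinateError(f"overlap at {chrom}:{s}-{e}")
                prev_end = e
                first = False

    def total_mass(self, chroms: Sequence[str] | None = None) -> float:
        """Signal mass: sum of value * interval length."""
        total = 0.0
        for chrom, ivs in self.intervals.items():
            if chroms is not None and chrom not in chroms:
                continue
            total += sum(v * (e - s) for s, e, v in ivs)
        return total

    def mass_on(self, chrom: str) -> float:
        return sum(v * (e - s) for s, e, v in self.intervals.get(chrom, []))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: [(s, e, v * factor) for s, e, v in ivs] for c, ivs in self.intervals.items()},
            sample_id=self.sample_id,
        )

    def per_bp(self, chrom: str, length: int) -> np.ndarray:
        """Dense per-bp signal vector for one chromosome."""
        arr = np.zeros(length, dtype=float)
        for s, e, v in self.intervals.get(chrom, []):
            arr[s:e] += v
        return arr


@dataclass
class IntervalSet:
    """Labeled genomic intervals, e.g. ERD/LRD/TZ domains or a blacklist."""

    records: list[tuple[str, int, int, str, float | None]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def with_label(self, label: str) -> "IntervalSet":
        return IntervalSet([r for r in self.records if r[3] == label])

    def labels(self) -> set[str]:
        return {r[3] for r in self.records}

    def by_chrom(self) -> dict[str, list[tuple[int, int, str, float | None]]]:
        out: dict[str, list] = {}
        for chrom, s, e, lab, score in self.records:
            out.setdefault(chrom, []).append((s, e, lab, score))
        for ivs in out.values():
            ivs.sort(key=lambda r: (r[0], r[1]))
        return out

    def validate(self, genome: GenomeDef) -> None:
        for chrom, s, e, lab, _ in self.records:
            clen = genome.length_of(chrom)
            if not (0 <= s < e <= clen):
                raise CoordinateError(f"{chrom}:{s}-{e} out of bounds (length {clen})")


@dataclass
class BinnedTrack:
    """Fixed-width binned signal; bins tile each chromosome from position 0.

    ``values[chrom]`` is a float vector of length ``ceil(length / bin_width)``;
    NaN marks missing bins (blacklisted), which downstream averages and
    smoothing exclude rather than treat as zero.
    """

    bin_width: int
    values: dict[str, np.ndarray]
    sample_id: str = ""

    @staticmethod
    def n_bins(length: int, bin_width: int) -> int:
        return math.ceil(length / bin_width)

    def same_grid(self, other: "BinnedTrack") -> bool:
        if self.bin_width != other.bin_width:
            return False
        if set(self.values) != set(other.values):
            return False
        return all(len(self.values[c]) == len(other.values[c]) for c in self.values)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_width,
            {c: v.copy() for c, v in self.values.items()},
            sample_id=self.sample_id,
        )

    def restrict(self, chroms: Iterable[str]) -> "BinnedTrack":
        """Track limited to the given chromosomes (e.g. nuclear only)."""
        keep = set(chroms)
        return BinnedTrack(
            self.bin_width,
            {c: v for c, v in self.values.items() if c in keep},
            sample_id=self.sample_id,
        )

    def bin_coords(self, chrom: str, genome: GenomeDef) -> list[tuple[int, int]]:
        clen = genome.length_of(chrom)
        return [
            (i * self.bin_width, min((i + 1) * self.bin_width, clen))
            for i in range(len(self.values[chrom]))
        ]

    def to_coverage(self, genome: GenomeDef) -> CoverageTrack:
        ivs: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, vals in self.values.items():
            clen = genome.length_of(chrom)
            lst = []
            for i, v in enumerate(vals):
                if np.isnan(v) or v == 0:
                    continue
                lst.append((i * self.bin_width, min((i + 1) * self.bin_width, clen), float(v)))
            ivs[chrom] = lst
        return CoverageTrack(ivs, sample_id=self.sample_id)


# ---------------------------------------------------------------------------
# Readers / writers


def _data_lines(path: str | Path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            yield line.split()


def read_chrom_sizes(path: str | Path, mito_name: str) -> GenomeDef:
    """Read a two-column (name, length) chromosome-sizes table."""
    chroms = []
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise GenomeIOError(f"bad chrom-sizes line: {' '.join(fields)}")
        chroms.append((fields[0], int(fields[1])))
    return GenomeDef(chroms, mito_name=mito_name)


def read_bedgraph(path: str | Path, genome: GenomeDef, sample_id: str = "") -> CoverageTrack:
    """Parse a 4-column bedGraph into a CoverageTrack.

    Unsorted input is sorted; overlapping intervals are an error.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for fields in _data_lines(path):
        if len(fields) < 4:
            raise GenomeIOError(f"bedGraph line has <4 columns: {' '.join(fields)}")
        chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        clen = genome.length_of(chrom)
        if not (0 <= s < e):
            raise CoordinateError(f"bad interval {chrom}:{s}-{e}")
        if e > clen:
            raise CoordinateError(f"{chrom}:{s}-{e} exceeds chromosome length {clen}")
        if v < 0:
            raise NegativeValueError(f"negative value {v} at {chrom}:{s}-{e}")
        per_chrom.setdefault(chrom, []).append((s, e, v))
    for chrom, ivs in per_chrom.items():
        ivs.sort(key=lambda t: (t[0], t[1]))
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise CoordinateError(f"overlapping bedGraph intervals on {chrom} at {s2}")
    track = CoverageTrack(per_chrom, sample_id=sample_id or Path(path).stem)
    track.validate(genome)
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as 4-column bedGraph; zero-value intervals omitted."""
    try:
        with open(path, "w") as fh:
            for chrom in track.intervals:
                for s, e, v in track.intervals[chrom]:
                    if v == 0:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    except OSError as exc:
        raise GenomeIOError(f"cannot write bedGraph to {path}: {exc}") from exc


def read_intervals(
    path: str | Path,
    genome: GenomeDef,
    label_vocabulary: Iterable[str] | None = None,
    default_label: str = "region",
) -> IntervalSet:
    """Read a 3-6 column BED file into an IntervalSet.

    The label comes from the BED name column when present, otherwise
    ``default_label``.  Column 5 (score), when present and numeric, is kept —
    origin files store firing time there.  Strand columns are ignored:
    fragmentation destroys strand identity, so all tracks are unstranded.
    """
    vocab = set(label_vocabulary) if label_vocabulary is not None else None
    records = []
    for fields in _data_lines(path):
        if len(fields) < 3:
            raise GenomeIOError(f"BED line has <3 columns: {' '.join(fields)}")
        chrom, s, e = fields[0], int(fields[1]), int(fields[2])
        clen = genome.length_of(chrom)
        if not (0 <= s < e <= clen):
            raise CoordinateError(f"bad BED interval {chrom}:{s}-{e} (length {clen})")
        label = fields[3] if len(fields) >= 4 else default_label
        if vocab is not None and label not in vocab:
            raise LabelVocabularyError(f"label {label!r} not in vocabulary {sorted(vocab)}")
        score = None
        if len(fields) >= 5:
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        records.append((chrom, s, e, label, score))
    return IntervalSet(records)


def write_intervals(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, label, score in ivset.records:
            if score is None:
                fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\t{label}\t{score:.6g}\n")
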