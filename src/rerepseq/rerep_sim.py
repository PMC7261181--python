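"""Generative model of BrdU strand labeling and selective fragmentation.

The chemistry being modeled: BrdU incorporated into nascent DNA is photolyzed
by UVA to uracil; UDG excision and APE1 cleavage convert each such site into a
single-strand nick.  Nicks on opposite strands that fall within a short offset
of one another constitute a staggered double-strand break.  DNA replicated
once carries BrdU on one strand only and cannot acquire opposed nicks;
rereplicated (twice-replicated) DNA is labeled on both strands and shatters
into gel-extractable fragments.  Size selection of the fragment pool therefore
enriches rereplicated sequence.

Replication itself is modeled semiconservatively on a deterministic
origin-firing schedule: position ``x`` on a chromosome is replicated by time
``t`` iff ``min_o(firing_time(o) + |x - pos(o)| / fork_speed) <= t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from rerepseq.genome_io import CoverageTrack, GenomeDef, IntervalSet

Interval = tuple[int, int]


class ScheduleError(ValueError):
    """Invalid labeling schedule (e.g. zero phases)."""


class FragmentBoundsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# interval helpers (sorted, disjoint, half-open)


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted((s, e) for s, e in ivs if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OriginMap:
    """Replication origins with firing times, plus a global fork speed.

    ``origins[chrom]`` lists ``(position_bp, firing_time_min)`` with strictly
    increasing positions.  Forks proceed bidirectionally at ``fork_speed``
    bp/min from each origin once it fires.
    """

    origins: dict[str, list[tuple[int, float]]]
    fork_speed: float

    def __post_init__(self):
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        for chrom, lst in self.origins.items():
            pos = [p for p, _ in lst]
            if not lst:
                raise ValueError(f"chromosome {chrom} has no origins")
            if sorted(pos) != pos or len(set(pos)) != len(pos):
                raise ValueError(f"origin positions on {chrom} not strictly increasing")

    @classmethod
    def from_interval_set(cls, origins_bed: IntervalSet, fork_speed: float) -> "OriginMap":
        """Origins from a BED where the score column holds the firing time."""
        per: dict[str, list[tuple[int, float]]] = {}
        for chrom, s, e, _lab, score in origins_bed:
            per.setdefault(chrom, []).append(((s + e) // 2, float(score or 0.0)))
        for lst in per.values():
            lst.sort()
        return cls(per, fork_speed)

    def replicated_region(self, chrom: str, t: float, length: int) -> list[Interval]:
        """Union of intervals replicated by time t on one chromosome."""
        ivs = []
        for pos, ft in self.origins.get(chrom, []):
            if ft > t:
                continue
            reach = (t - ft) * self.fork_speed
            ivs.append((max(0, int(pos - reach)), min(length, int(pos + reach))))
        return merge_intervals(ivs)

    def full_replication_time(self, chrom: str, length: int) -> float:
        """Time at which the whole chromosome has been replicated."""
        oris = self.origins.get(chrom, [])
        pts = np.array([0, length - 1] + [p for p, _ in oris])
        times = np.full(pts.shape, np.inf)
        for pos, ft in oris:
            times = np.minimum(times, ft + np.abs(pts - pos) / self.fork_speed)
        return float(times.max())


@dataclass(frozen=True)
class Phase:
    """One cell-cycle phase of the labeling schedule."""

    brdu: bool
    sampling_time: float | str = "complete"  # minutes, "complete", or "asynchronous"


@dataclass(frozen=True)
class LabelSchedule:
    """Ordered cell-cycle phases; only the final phase may be sampled mid-S.

    ``rerep_domains``, when given, re-fire within the final phase: the covered
    intervals replicate a second time in one cycle, yielding extra
    double-labeled copies — the licensing-bypass rereplication scenario.
    """

    phases: tuple[Phase, ...]
    rerep_domains: IntervalSet | None = None

    def __post_init__(self):
        if len(self.phases) == 0:
            raise ScheduleError("schedule must contain at least one phase")
        for ph in self.phases[:-1]:
            if ph.sampling_time != "complete":
                raise ScheduleError("sampling_time allowed only on the final phase")


@dataclass
class DuplexMolecule:
    """A double-stranded molecule with per-strand BrdU-labeled intervals."""

    chrom: str
    start: int
    end: int
    top_labeled: list[Interval] = field(default_factory=list)
    bottom_labeled: list[Interval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def double_labeled_region(self) -> list[Interval]:
        return intersect_intervals(self.top_labeled, self.bottom_labeled)

    def is_fully_double_labeled(self) -> bool:
        return total_length(self.double_labeled_region()) == self.length


@dataclass(frozen=True)
class DigestParams:
    """Fragmentation dials for the UVA/UDG/APE1 digest.

    ``p_nick`` is the single abstraction of UVA dose and digestion time: the
    probability that a labelable site on a labeled stretch is converted to a
    nick.  ``labelable_density`` approximates thymidine frequency per bp.
    Opposed nicks within ``dsb_max_offset`` bp form a staggered double-strand
    break.  ``size_min``/``size_max`` is the gel-extraction window.
    """

    p_nick: float = 0.03
    labelable_density: float = 0.3
    dsb_max_offset: int = 16
    size_min: int = 100
    size_max: int = 3000
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_nick <= 1):
            raise ValueError("p_nick must be in (0, 1]")
        if not (0 < self.labelable_density <= 1):
            raise ValueError("labelable_density must be in (0, 1]")
        if self.dsb_max_offset <= 0:
            raise ValueError("dsb_max_offset must be positive")
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")

    @property
    def nick_rate(self) -> float:
        """Per-labeled-bp nick probability."""
        return self.p_nick * self.labelable_density


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    left_is_break: bool
    right_is_break: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_internal(self) -> bool:
        return self.left_is_break and self.right_is_break


# ---------------------------------------------------------------------------
# replication


def _replicate_duplex(
    mol: DuplexMolecule, region: list[Interval], brdu: bool
) -> list[DuplexMolecule]:
    """Semiconservative pass over `region`: one duplex in, two daughters out.

    Each daughter keeps one parental strand; the nascent strand is labeled
    over exactly the replicated region when BrdU is present.
    """
    nascent = [iv for iv in region] if brdu else []
    a = DuplexMolecule(mol.chrom, mol.start, mol.end, list(mol.top_labeled), nascent)
    b = DuplexMolecule(mol.chrom, mol.start, mol.end, list(nascent), list(mol.bottom_labeled))
    return [a, b]


def replicate_population(
    genome: GenomeDef,
    origins: OriginMap,
    schedule: LabelSchedule,
    n_cells: int,
    rng_seed: int = 0,
    mito_copies: int = 50,
) -> list[DuplexMolecule]:
    """Run the labeling schedule over a population of cells.

    Returns the pooled molecules of all cells.  Nuclear chromosomes start as
    one unlabeled duplex per cell and follow the schedule; the mitochondrial
    contig replicates continuously regardless of cell-cycle phase and is
    emitted fully double-labeled at ``mito_copies`` per cell — the property
    that makes it the internal normalization control.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(schedule.phases) == 0:
        raise ScheduleError("schedule must contain at least one phase")

    rng = np.random.default_rng(rng_seed)
    rerep_by_chrom = schedule.rerep_domains.by_chrom() if schedule.rerep_domains else {}
    molecules: list[DuplexMolecule] = []

    nuclear = [(c, l) for c, l in genome.chromosomes if c != genome.mito_name]
    full_times = {c: origins.full_replication_time(c, l) for c, l in nuclear}

    for _cell in range(n_cells):
        cell: dict[str, list[DuplexMolecule]] = {
            c: [DuplexMolecule(c, 0, l)] for c, l in nuclear
        }
        for phase_idx, phase in enumerate(schedule.phases):
            final = phase_idx == len(schedule.phases) - 1
            for chrom, length in nuclear:
                st = phase.sampling_time
                if st == "complete":
                    region = [(0, length)]
                elif st == "asynchronous":
                    t = rng.uniform(0.0, full_times[chrom])
                    region = origins.replicated_region(chrom, t, length)
                else:
                    region = origins.replicated_region(chrom, float(st), length)
                daughters: list[DuplexMolecule] = []
                for mol in cell[chrom]:
                    daughters.extend(_replicate_duplex(mol, region, phase.brdu))
                if final and chrom in rerep_by_chrom:
                    # re-firing within the final phase: the covered intervals
                    # replicate again, adding a double-labeled copy per duplex
                    for s, e, _lab, _sc in rerep_by_chrom[chrom]:
                        for _ in range(len(cell[chrom])):
                            daughters.append(
                                DuplexMolecule(chrom, s, e, [(s, e)], [(s, e)])
                            )
                cell[chrom] = daughters
        for mols in cell.values():
            molecules.extend(mols)
        mito_len = genome.length_of(genome.mito_name)
        for _ in range(mito_copies):
            molecules.append(
                DuplexMolecule(
                    genome.mito_name, 0, mito_len, [(0, mito_len)], [(0, mito_len)]
                )
            )
    return molecules


def double_labeled_fraction(molecules: Iterable[DuplexMolecule], genome: GenomeDef) -> float:
    """Fraction of nuclear duplexes labeled on both strands over their full span."""
    n = 0
    dbl = 0
    for mol in molecules:
        if mol.chrom == genome.mito_name:
            continue
        n += 1
        if mol.is_fully_double_labeled():
            dbl += 1
    if n == 0:
        raise ValueError("no nuclear molecules")
    return dbl / n


# ---------------------------------------------------------------------------
# digestion


def _sample_nicks(labeled: Sequence[Interval], rate: float, rng: np.random.Generator) -> np.ndarray:
    """Nick positions on one strand: Bernoulli(rate) per labeled bp."""
    chunks = []
    for s, e in labeled:
        n = rng.binomial(e - s, rate)
        if n:
            # distinct uniform positions; resampling duplicates is cheaper
            # than a full permutation at genomic interval sizes
            pos = np.unique(rng.integers(s, e, size=n))
            while len(pos) < n:
                extra = rng.integers(s, e, size=n - len(pos))
                pos = np.unique(np.concatenate((pos, extra)))
            chunks.append(pos)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(chunks))


def _pair_core_py(top: np.ndarray, bottom: np.ndarray, max_offset: int) -> np.ndarray:
    out = np.empty(min(len(top), len(bottom)), dtype=np.int64)
    k = 0
    i = j = 0
    nt, nb = len(top), len(bottom)
    while i < nt and j < nb:
        d = top[i] - bottom[j]
        if -max_offset <= d <= max_offset:
            out[k] = (top[i] + bottom[j]) // 2
            k += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return out[:k]


try:  # jitted pairing: the only sequential inner loop in the simulator
    from numba import njit

    _pair_core = njit(cache=False)(_pair_core_py)
except ImportError:  # pragma: no cover
    _pair_core = _pair_core_py


def _pair_nicks_greedy(top: np.ndarray, bottom: np.ndarray, max_offset: int) -> list[int]:
    """Greedy left-to-right pairing of opposed nicks into break midpoints."""
    return _pair_core(
        np.ascontiguousarray(top, dtype=np.int64),
        np.ascontiguousarray(bottom, dtype=np.int64),
        max_offset,
    ).tolist()


def digest_molecule(
    mol: DuplexMolecule,
    params: DigestParams,
    rng: np.random.Generator,
    forced_top: Sequence[int] | None = None,
    forced_bottom: Sequence[int] | None = None,
) -> list[Fragment]:
    """Fragment one molecule by the opposed-nick rule.

    Nicks arise only on labeled stretches of each strand.  A double-strand
    break is called at the midpoint (floor) of each greedily paired couple of
    opposed nicks separated by at most ``dsb_max_offset`` bp; each nick is
    used at most once.  Molecule ends are not breaks: the flanking segments
    are emitted with a terminal flag.

    ``forced_top``/``forced_bottom`` replace stochastic nick sampling with
    fixed nick positions (each still thinned by ``p_nick`` unless it is 1).
    """
    if forced_top is not None or forced_bottom is not None:
        def forced(sites):
            sites = np.sort(np.asarray(sites if sites is not None else [], dtype=np.int64))
            if params.p_nick >= 1.0:
                return sites
            keep = rng.random(len(sites)) < params.p_nick
            return sites[keep]

        top = forced(forced_top)
        bottom = forced(forced_bottom)
    else:
        if not mol.top_labeled or not mol.bottom_labeled:
            # opposed nicks are impossible; skip sampling entirely
            return [Fragment(mol.chrom, mol.start, mol.end, False, False)]
        top = _sample_nicks(mol.top_labeled, params.nick_rate, rng)
        bottom = _sample_nicks(mol.bottom_labeled, params.nick_rate, rng)

    breaks = _pair_nicks_greedy(top, bottom, params.dsb_max_offset)
    if not breaks:
        return [Fragment(mol.chrom, mol.start, mol.end, False, False)]
    bounds = [mol.start] + breaks + [mol.end]
    frags = []
    for k, (s, e) in enumerate(zip(bounds, bounds[1:])):
        if e <= s:
            continue
        frags.append(
            Fragment(mol.chrom, s, e, left_is_break=k > 0, right_is_break=k < len(bounds) - 2)
        )
    return frags


def size_select(fragments: Iterable[Fragment], params: DigestParams) -> list[Fragment]:
    """Gel-extraction window: keep internal fragments within [size_min, size_max]."""
    return [
        f
        for f in fragments
        if f.is_internal and params.size_min <= f.length <= params.size_max
    ]


def fragments_to_track(
    fragments: Iterable[Fragment], genome: GenomeDef, sample_id: str = ""
) -> CoverageTrack:
    """Per-bp fragment pileup as a step-function coverage track."""
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for f in fragments:
        clen = genome.length_of(f.chrom)
        if not (0 <= f.start < f.end <= clen):
            raise FragmentBoundsError(f"fragment {f.chrom}:{f.start}-{f.end} out of bounds")
        starts, ends = by_chrom.setdefault(f.chrom, ([], []))
        starts.append(f.start)
        ends.append(f.end)
    arrays = {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in by_chrom.items()
    }
    return _track_from_arrays(arrays, genome, sample_id)


def _track_from_arrays(
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    genome: GenomeDef,
    sample_id: str = "",
) -> CoverageTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, (starts, ends) in by_chrom.items():
        clen = genome.length_of(chrom)
        if len(starts) and (starts.min() < 0 or ends.max() > clen):
            raise FragmentBoundsError(f"fragment out of bounds on {chrom}")
        d = np.zeros(clen + 1, dtype=np.int64)
        np.add.at(d, starts, 1)
        np.add.at(d, ends, -1)
        cov = np.cumsum(d[:-1])
        # step-function run-length encoding
        change = np.flatnonzero(np.diff(cov)) + 1
        iv_starts = np.concatenate(([0], change))
        iv_ends = np.concatenate((change, [len(cov)]))
        ivs = [
            (int(s), int(e), float(cov[s]))
            for s, e in zip(iv_starts, iv_ends)
            if cov[s] != 0
        ]
        intervals[chrom] = ivs
    return CoverageTrack(intervals, sample_id=sample_id)


def simulate_sample(
    genome: GenomeDef,
    origins: OriginMap,
    schedule: LabelSchedule,
    n_cells: int,
    params: DigestParams,
    rng_seed: int,
    mito_copies: int = 50,
    background_rate: float = 2e-5,
    sample_id: str = "",
) -> tuple[CoverageTrack, int]:
    """Simulate one sequencing sample: replicate, digest, size-select, pile up.

    ``background_rate`` adds nonspecific fragments (per bp per cell) uniformly
    over nuclear chromosomes, emulating library background independent of
    labeling state.  Returns the coverage track and the retained fragment
    count (the RPM denominator).
    """
    rng = np.random.default_rng(rng_seed)
    molecules = replicate_population(
        genome, origins, schedule, n_cells, rng_seed=int(rng.integers(2**31)),
        mito_copies=mito_copies,
    )
    # array fast path: per molecule, break positions -> size-filtered internal
    # fragment bounds, without per-fragment objects
    chunks: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {}
    n_retained = 0
    for mol in molecules:
        if not mol.top_labeled or not mol.bottom_labeled:
            continue
        top = _sample_nicks(mol.top_labeled, params.nick_rate, rng)
        bottom = _sample_nicks(mol.bottom_labeled, params.nick_rate, rng)
        breaks = _pair_core(top, bottom, params.dsb_max_offset)
        if len(breaks) < 2:
            continue
        lens = np.diff(breaks)
        keep = (lens >= params.size_min) & (lens <= params.size_max)
        if not keep.any():
            continue
        s_list, e_list = chunks.setdefault(mol.chrom, ([], []))
        s_list.append(breaks[:-1][keep])
        e_list.append(breaks[1:][keep])
        n_retained += int(keep.sum())
    if background_rate > 0:
        for chrom in genome.nuclear_names:
            clen = genome.length_of(chrom)
            n_bg = rng.poisson(background_rate * clen * n_cells)
            if n_bg:
                starts = rng.integers(0, max(1, clen - params.size_min), size=n_bg)
                lengths = rng.integers(params.size_min, min(params.size_max, 1000), size=n_bg)
                s_list, e_list = chunks.setdefault(chrom, ([], []))
                s_list.append(starts.astype(np.int64))
                e_list.append(np.minimum(starts + lengths, clen).astype(np.int64))
                n_retained += int(n_bg)
    arrays = {
        c: (np.concatenate(s), np.concatenate(e)) for c, (s, e) in chunks.items()
    }
    track = _track_from_arrays(arrays, genome, sample_id=sample_id)
    return track, n_retained
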