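"""Synthetic study conditions: genomes, origin maps and labeling schedules.

These builders define the packaged desk-scale experiments:

* a replication-timing time course (pre-label one strand through a complete
  BrdU cycle, then sample the second S-phase at increasing times, so early
  origins become double-labeled before late ones);
* a fully-labeled multi-cycle control (three complete BrdU cycles, uniform
  3/4 double labeling, no timing structure);
* a licensing-bypass rereplication experiment (G1-arrested cells in which
  designated domains re-fire, yielding double-labeled copies of those
  domains only).

The default scale is a two-chromosome ~1 Mb nuclear genome with 20 origins
of staggered firing time plus a high-copy mitochondrial contig — large
enough for timing-domain structure at 100 bp bins and 10 kb smoothing,
small enough to simulate in seconds.
"""

from __future__ import annotations

import numpy as np

from rerepseq.genome_io import BinnedTrack, GenomeDef, IntervalSet
from rerepseq.rerep_sim import (
    DigestParams,
    LabelSchedule,
    OriginMap,
    Phase,
)

# yeast-like defaults: ~2 kb/min forks, origins every 50 kb, S-phase ~22 min
FORK_SPEED = 2000.0
ORIGIN_SPACING = 50_000
FIRING_SPREAD = 10.0  # minutes between first and last origin firing


def demo_genome(
    n_chrom: int = 2, chrom_len: int = 500_000, mito_len: int = 10_000
) -> GenomeDef:
    chroms = [(f"chr{i + 1}", chrom_len) for i in range(n_chrom)]
    chroms.append(("chrM", mito_len))
    return GenomeDef(chroms, mito_name="chrM")


def demo_origins(genome: GenomeDef, fork_speed: float = FORK_SPEED) -> OriginMap:
    """Evenly spaced origins with firing times staggered over FIRING_SPREAD.

    Firing times are a fixed permutation of an even grid, so early and late
    origins interleave along and across chromosomes rather than clustering.
    """
    positions = {
        chrom: list(
            range(ORIGIN_SPACING // 2, genome.length_of(chrom), ORIGIN_SPACING)
        )
        for chrom in genome.nuclear_names
    }
    n_total = sum(len(p) for p in positions.values())
    # multiplicative shuffle: visits every index once (gcd(7, n) == 1 for n=20)
    step = 7 if np.gcd(7, n_total) == 1 else 3
    times = [((i * step) % n_total) * FIRING_SPREAD / n_total for i in range(n_total)]
    origins = {}
    i = 0
    for chrom, pos in positions.items():
        origins[chrom] = [(p, times[i + k]) for k, p in enumerate(pos)]
        i += len(pos)
    return OriginMap(origins, fork_speed)


def origin_table(origins: OriginMap) -> list[tuple[str, int, float]]:
    """Flat (chrom, position, firing_time) rows in genomic order."""
    return [
        (chrom, pos, ft)
        for chrom, lst in origins.origins.items()
        for pos, ft in lst
    ]


def early_origin_ids(origins: OriginMap) -> set[str]:
    """Origins firing before the median firing time, as `ori@chrom:pos` ids."""
    rows = origin_table(origins)
    med = float(np.median([ft for _, _, ft in rows]))
    return {f"ori@{c}:{p}" for c, p, ft in rows if ft < med}


def origin_windows(origins: OriginMap, flank: int = 25_000) -> IntervalSet:
    """+/-flank windows around each origin, the rows of the ranked-list analysis."""
    return IntervalSet(
        [
            (chrom, pos - flank, pos + flank, "ori", ft)
            for chrom, lst in origins.origins.items()
            for pos, ft in lst
        ]
    )


def early_origin_window_ids(origins: OriginMap, flank: int = 25_000) -> set[str]:
    """Window ids of origins firing before the median time (the 'early' query set)."""
    rows = origin_table(origins)
    med = float(np.median([ft for _, _, ft in rows]))
    return {
        f"ori@{c}:{p - flank}-{p + flank}" for c, p, ft in rows if ft < med
    }


def timing_course_schedule(sampling_time: float | str) -> LabelSchedule:
    """Pre-label one strand in a complete BrdU cycle, sample the second S-phase."""
    return LabelSchedule(
        (Phase(brdu=True, sampling_time="complete"), Phase(brdu=True, sampling_time=sampling_time))
    )


def multi_cycle_schedule(n_cycles: int = 3) -> LabelSchedule:
    """Fully-labeled control: n complete BrdU cycles, no synchronization."""
    return LabelSchedule(tuple(Phase(brdu=True, sampling_time="complete") for _ in range(n_cycles)))


def rerep_bypass_schedule(rerep_domains: IntervalSet) -> LabelSchedule:
    """Licensing bypass from G1 arrest: only the designated domains replicate."""
    return LabelSchedule(
        (Phase(brdu=True, sampling_time=0.0),), rerep_domains=rerep_domains
    )


def demo_rerep_domains(genome: GenomeDef, fraction: float = 0.20) -> IntervalSet:
    """Broad rereplication domains covering `fraction` of the nuclear genome.

    One domain per chromosome, each spanning two origin positions (and hence
    both replication-timing classes and at least one TAD boundary), placed
    mid-arm on the first chromosome and distally on the second.
    """
    nuc = genome.nuclear_names
    total = sum(genome.length_of(c) for c in nuc)
    dom_len = int(fraction * total / len(nuc))
    records = []
    for k, chrom in enumerate(nuc):
        clen = genome.length_of(chrom)
        start = int(0.12 * clen) if k % 2 == 0 else clen - dom_len - int(0.1 * clen)
        records.append((chrom, start, start + dom_len, "rerep", None))
    return IntervalSet(records)


def demo_tads(genome: GenomeDef, tad_width: int = 40_000) -> IntervalSet:
    """Regular TAD partition of each nuclear chromosome."""
    records = []
    for chrom in genome.nuclear_names:
        clen = genome.length_of(chrom)
        for s in range(0, clen, tad_width):
            records.append((chrom, s, min(s + tad_width, clen), "TAD", None))
    return IntervalSet(records)


def timing_profile(
    genome: GenomeDef, origins: OriginMap, bin_width: int = 1000
) -> BinnedTrack:
    """Replication-timing profile on the published 0-2 scale.

    Per bin: the time its midpoint replicates, linearly rescaled so the
    earliest-replicating position scores 2 (replicated) and the latest 1
    (not replicated) — the convention of published timing tracks.
    """
    t_by_chrom = {}
    for chrom in genome.nuclear_names:
        clen = genome.length_of(chrom)
        n = BinnedTrack.n_bins(clen, bin_width)
        mids = np.minimum(np.arange(n) * bin_width + bin_width / 2, clen - 1)
        t = np.full(n, np.inf)
        for pos, ft in origins.origins[chrom]:
            t = np.minimum(t, ft + np.abs(mids - pos) / origins.fork_speed)
        t_by_chrom[chrom] = t
    tmax = max(t.max() for t in t_by_chrom.values())
    tmin = min(t.min() for t in t_by_chrom.values())
    vals = {
        c: 2.0 - (t - tmin) / (tmax - tmin) for c, t in t_by_chrom.items()
    }
    return BinnedTrack(bin_width, vals, sample_id="timing")


def make_timing_annotation(
    profile: BinnedTrack, genome: GenomeDef
) -> IntervalSet:
    """ERD/LRD/TZ segmentation of a timing profile.

    Top-quartile runs become ERDs, bottom-quartile runs LRDs, and every gap
    (including chromosome ends) a transition zone.
    """
    from rerepseq.timing_domains import classify_timing_regions

    classified = classify_timing_regions(profile)
    records = []
    for chrom, ivs in classified.by_chrom().items():
        clen = genome.length_of(chrom)
        cursor = 0
        for s, e, lab, _sc in ivs:
            if s > cursor:
                records.append((chrom, cursor, s, "TZ", None))
            records.append((chrom, s, e, "ERD" if lab == "early" else "LRD", None))
            cursor = e
        if cursor < clen:
            records.append((chrom, cursor, clen, "TZ", None))
    return IntervalSet(records)


def default_digest_params(seed: int = 0) -> DigestParams:
    """Fragmentation dials targeting 300-600 bp mean fragment length."""
    return DigestParams(
        p_nick=0.03,
        labelable_density=0.3,
        dsb_max_offset=16,
        size_min=100,
        size_max=3000,
        rng_seed=seed,
    )
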