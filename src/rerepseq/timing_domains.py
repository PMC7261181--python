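"""Replication-timing domain classification and enrichment analysis.

Covers: quartile classification of a 0-2 replication-timing profile into
early/late regions; origin-centered signal heatmaps; extension of ERD/LRD
domains to the midpoints of flanking transition zones; size-normalized
(0-100%) domain profiles with meta-profiles; and a rank-based enrichment
statistic (unweighted Kolmogorov-Smirnov-style running sum with a label
permutation null) for asking whether early or late domains concentrate at
the top of a signal-ranked domain list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rerepseq.genome_io import BinnedTrack, GenomeDef, IntervalSet


class TimingError(ValueError):
    pass


class DegenerateProfileError(TimingError):
    pass


# ---------------------------------------------------------------------------
# quartile classification


def classify_timing_regions(profile: BinnedTrack) -> IntervalSet:
    """Early/late regions from a replication-timing profile.

    On the published 0-2 timing scale (2 = replicated, 1 = not replicated),
    early regions are maximal runs of adjacent bins at or above the 75th
    percentile of bin values and late regions are runs at or below the 25th
    percentile (linear-interpolation percentiles, pooled over chromosomes).
    """
    pooled = np.concatenate([v[~np.isnan(v)] for v in profile.values.values()])
    if len(pooled) < 4:
        raise TimingError("need at least 4 non-missing bins")
    if np.all(pooled == pooled[0]):
        raise DegenerateProfileError("all profile values identical; quartiles degenerate")
    q25, q75 = np.percentile(pooled, [25, 75])
    bw = profile.bin_width
    records = []
    for chrom, vals in profile.values.items():
        for label, mask in (
            ("early", vals >= q75),
            ("late", vals <= q25),
        ):
            mask = np.asarray(mask) & ~np.isnan(vals)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [idx.size - 1]))
            for a, b in zip(starts, ends):
                records.append(
                    (chrom, int(idx[a]) * bw, (int(idx[b]) + 1) * bw, label, None)
                )
    records.sort(key=lambda r: (r[0], r[1]))
    return IntervalSet(records)


# ---------------------------------------------------------------------------
# feature-centered heatmap


def feature_heatmap(
    track: BinnedTrack, centers: IntervalSet, flank: int
) -> tuple[np.ndarray, list[str]]:
    """Signal matrix around feature midpoints, rows sorted by row sum.

    One row per feature covering ``[mid - flank, mid + flank)`` at the
    track's bin width; positions past chromosome ends are NaN-padded.  Rows
    sort by row sum descending, ties broken by feature id (lexicographic).
    Returns ``(matrix, row_ids)`` where ids are ``label@chrom:start-end``.
    """
    if len(centers) == 0:
        raise TimingError("empty feature set")
    if flank <= 0:
        raise TimingError("flank must be positive")
    bw = track.bin_width
    width = 2 * (flank // bw)
    rows = []
    ids = []
    for chrom, s, e, label, _score in centers:
        mid = (s + e) // 2
        c0 = (mid - flank) // bw
        vals = track.values[chrom]
        row = np.full(width, np.nan)
        for k in range(width):
            b = c0 + k
            if 0 <= b < len(vals):
                row[k] = vals[b]
        rows.append(row)
        ids.append(f"{label}@{chrom}:{s}-{e}")
    mat = np.vstack(rows)
    sums = np.nansum(mat, axis=1)
    order = sorted(range(len(ids)), key=lambda i: (-sums[i], ids[i]))
    return mat[order], [ids[i] for i in order]


# ---------------------------------------------------------------------------
# domain extension and scaled profiles


def extend_domains_to_tz_midpoints(domains: IntervalSet) -> IntervalSet:
    """Extend each ERD/LRD to the midpoint of its flanking transition zones.

    Domains must tile each chromosome without overlap, with TZ intervals
    between ERD/LRD blocks.  A boundary with no adjoining TZ (a domain at a
    chromosome edge, or one already abutting the tiled region's end) keeps
    its original coordinate.  Extended domains abut exactly at TZ midpoints,
    so transition-zone signal is never counted twice.
    """
    out = []
    for chrom, ivs in domains.by_chrom().items():
        for (s, e, lab, sc), prev, nxt in zip(
            ivs, [None] + ivs[:-1], ivs[1:] + [None]
        ):
            if prev is not None and prev[1] > s:
                raise TimingError(f"overlapping domains on {chrom} at {s}")
            if lab == "TZ":
                continue
            left = (prev[0] + prev[1]) // 2 if prev is not None and prev[2] == "TZ" else s
            right = (nxt[0] + nxt[1]) // 2 if nxt is not None and nxt[2] == "TZ" else e
            out.append((chrom, left, right, lab, sc))
    out.sort(key=lambda r: (r[0], r[1]))
    return IntervalSet(out)


def scaled_domain_profile(
    track: BinnedTrack, domains: IntervalSet, n_points: int = 101
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Resample each domain to n_points relative positions (0-100% scaling).

    Domains of any physical size map onto a common relative axis by linear
    interpolation of bin values (bin centers as abscissae) at equally spaced
    bp coordinates across the domain.  Returns ``(matrix, row_ids,
    meta_profile)`` where the meta-profile is the per-position mean over
    domains ignoring missing values.
    """
    if n_points < 2:
        raise TimingError("n_points must be >= 2")
    bw = track.bin_width
    rows, ids = [], []
    for chrom, s, e, lab, _sc in domains:
        if e - s < 2 * bw:
            raise TimingError(f"domain {chrom}:{s}-{e} shorter than 2 bins")
        vals = track.values[chrom]
        centers = (np.arange(len(vals)) + 0.5) * bw
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            rows.append(np.full(n_points, np.nan))
        else:
            coords = s + np.linspace(0.0, 1.0, n_points) * (e - s)
            rows.append(np.interp(coords, centers[ok], vals[ok]))
        ids.append(f"{lab}@{chrom}:{s}-{e}")
    mat = np.vstack(rows)
    meta = np.nanmean(mat, axis=0)
    return mat, ids, meta


# ---------------------------------------------------------------------------
# ranked-list enrichment


@dataclass(frozen=True)
class RankedDomainList:
    """Domains ordered by mean signal, descending; ties broken by id."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __len__(self):
        return len(self.ids)


def rank_domains(
    track: BinnedTrack, domains: IntervalSet, genome: GenomeDef | None = None
) -> RankedDomainList:
    """Rank domains by length-weighted mean of non-missing bins within each."""
    bw = track.bin_width
    scored = []
    for chrom, s, e, lab, _sc in domains:
        vals = track.values[chrom]
        b0, b1 = s // bw, min((e - 1) // bw + 1, len(vals))
        seg = vals[b0:b1]
        mean = float(np.nanmean(seg)) if np.any(~np.isnan(seg)) else float("nan")
        scored.append((f"{lab}@{chrom}:{s}-{e}", mean))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return RankedDomainList(
        tuple(i for i, _ in scored), tuple(v for _, v in scored)
    )


def _running_es(is_hit: np.ndarray) -> float:
    n = len(is_hit)
    nh = int(is_hit.sum())
    steps = np.where(is_hit, 1.0 / nh, -1.0 / (n - nh))
    walk = np.cumsum(steps)
    hi, lo = walk.max(), walk.min()
    # equal-magnitude extremes tie toward the positive deviation
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked: RankedDomainList,
    query_set: set[str],
    n_permutations: int = 1000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Unweighted running-sum enrichment of a query set in a ranked list.

    Walking the list from top to bottom, a query member increments the sum by
    1/|query| and a non-member decrements it by 1/(N - |query|); the score is
    the maximum-magnitude deviation (positive deviation preferred on exact
    magnitude ties).  The p-value is the add-one-smoothed fraction of random
    membership permutations whose |ES| is at least the observed |ES|.
    """
    n = len(ranked)
    k = len(query_set & set(ranked.ids))
    if k == 0 or k == n:
        raise TimingError("query set must be a proper non-empty subset of the list")
    is_hit = np.array([i in query_set for i in ranked.ids])
    es = _running_es(is_hit)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    labels = is_hit.copy()
    for _ in range(n_permutations):
        rng.shuffle(labels)
        if abs(_running_es(labels)) >= abs(es):
            exceed += 1
    pval = (exceed + 1) / (n_permutations + 1)
    return es, float(pval)
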