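"""Normalization chain: RPM, mitochondrial scaling, blacklist, averaging, QC.

Mitochondrial DNA replicates continuously and is therefore uniformly
double-labeled in every sample, making its fragment yield a sample-intrinsic
digestion/loading control: after RPM normalization, each sample is rescaled
so that all samples carry the same mitochondrial signal mass.

The blacklist is built at bin resolution from the time-point-0 replicates:
any maximal run of adjacent non-mitochondrial bins whose replicate-averaged
value strictly exceeds the genomic mean plus one population standard
deviation is excluded (set to missing) in every sample and time point.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from rerepseq.genome_io import BinnedTrack, CoverageTrack, GenomeDef, IntervalSet


class NormalizationError(ValueError):
    pass


class GridMismatchError(NormalizationError):
    pass


def rpm_normalize(track: CoverageTrack, total_units: float) -> CoverageTrack:
    """Scale every value by 1e6 / total_units (reads- or fragments-per-million)."""
    if total_units <= 0:
        raise NormalizationError(f"total_units must be positive, got {total_units}")
    return track.scaled(1e6 / total_units)


def mito_fraction(track: CoverageTrack, genome: GenomeDef) -> float:
    total = track.total_mass()
    if total == 0:
        raise NormalizationError(f"sample {track.sample_id!r} has zero total signal")
    return track.mass_on(genome.mito_name) / total


def mito_scale(tracks: list[CoverageTrack], genome: GenomeDef) -> list[CoverageTrack]:
    """Rescale each sample by (mean mito fraction) / (its mito fraction).

    With RPM-normalized inputs (equal total mass), this equalizes the
    mitochondrial signal mass of every sample, so between-sample differences
    in nuclear signal reflect differential fragmentation rather than depth.
    """
    fracs = []
    for t in tracks:
        f = mito_fraction(t, genome)
        if f == 0:
            raise NormalizationError(
                f"sample {t.sample_id!r} has zero mitochondrial signal"
            )
        fracs.append(f)
    mean_frac = float(np.mean(fracs))
    return [t.scaled(mean_frac / f) for t, f in zip(tracks, fracs)]


def _check_grids(tracks: list[BinnedTrack]) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise GridMismatchError("binned tracks are on different bin grids")


def make_blacklist(
    t0_tracks: list[BinnedTrack], genome: GenomeDef
) -> IntervalSet:
    """Blacklist from time-point-0 replicates: runs of bins > mean + 1 SD.

    The per-bin mean across replicates is thresholded at the grand mean plus
    one population standard deviation of all non-mitochondrial bins (strict
    inequality).  Mitochondrial bins are the normalizer and are never
    blacklisted nor counted in the threshold.
    """
    if not t0_tracks:
        raise NormalizationError("need at least one time-point-0 replicate")
    _check_grids(t0_tracks)
    bw = t0_tracks[0].bin_width
    avg = {
        c: np.nanmean(np.vstack([t.values[c] for t in t0_tracks]), axis=0)
        for c in t0_tracks[0].values
    }
    pooled = np.concatenate(
        [avg[c] for c in avg if c != genome.mito_name]
    )
    pooled = pooled[~np.isnan(pooled)]
    mu = float(pooled.mean())
    sigma = float(pooled.std())  # population SD
    threshold = mu + sigma
    records = []
    for chrom, vals in avg.items():
        if chrom == genome.mito_name:
            continue
        clen = genome.length_of(chrom)
        over = np.asarray(vals > threshold)  # NaN compares False
        idx = np.flatnonzero(over)
        if idx.size == 0:
            continue
        run_breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], run_breaks + 1))
        ends = np.concatenate((run_breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            s = int(idx[a]) * bw
            e = min((int(idx[b]) + 1) * bw, clen)
            records.append((chrom, s, e, "blacklist", None))
    return IntervalSet(records)


def apply_blacklist(track: BinnedTrack, blacklist: IntervalSet) -> BinnedTrack:
    """Set every bin overlapping a blacklist interval to missing (NaN)."""
    out = track.copy()
    bw = out.bin_width
    for chrom, s, e, _lab, _sc in blacklist:
        if chrom not in out.values:
            continue
        b0 = s // bw
        b1 = (e - 1) // bw + 1
        out.values[chrom][b0 : min(b1, len(out.values[chrom]))] = np.nan
    return out


def average_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin mean across replicates; a bin missing anywhere is missing."""
    if not tracks:
        raise NormalizationError("no replicates to average")
    _check_grids(tracks)
    out = {}
    for chrom in tracks[0].values:
        stack = np.vstack([t.values[chrom] for t in tracks])
        out[chrom] = stack.mean(axis=0)  # NaN propagates: missing anywhere -> missing
    return BinnedTrack(tracks[0].bin_width, out, sample_id="mean")


def replicate_spearman(a: BinnedTrack, b: BinnedTrack) -> float:
    """Spearman rank correlation over jointly non-missing bins (average-rank ties)."""
    _check_grids([a, b])
    xs, ys = [], []
    for chrom in a.values:
        av, bv = a.values[chrom], b.values[chrom]
        ok = ~np.isnan(av) & ~np.isnan(bv)
        xs.append(av[ok])
        ys.append(bv[ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise NormalizationError(f"need >=3 jointly non-missing bins, got {len(x)}")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
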