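"""Fixed-width binning and edge-aware sliding-window smoothing.

Bin aggregation is the length-weighted mean per-bp signal (a density, so
units are invariant under re-binning); uncovered positions count as zero.
Smoothing is a centered moving average that passes bins through unchanged
within half a window of either chromosome end.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from rerepseq.genome_io import BinnedTrack, CoverageTrack, GenomeDef


class BinningError(ValueError):
    pass


def bin_track(track: CoverageTrack, genome: GenomeDef, bin_width: int) -> BinnedTrack:
    """Bin a coverage track to fixed-width bins tiling each chromosome from 0.

    The bin value is the mean per-bp signal within the bin; the last bin is
    truncated at the chromosome end and its mean uses the truncated length,
    so signal mass (sum of value x bin span) is conserved exactly.
    """
    if bin_width < 1:
        raise BinningError(f"bin_width must be >= 1, got {bin_width}")
    values: dict[str, np.ndarray] = {}
    for chrom, clen in genome.chromosomes:
        n = BinnedTrack.n_bins(clen, bin_width)
        mass = np.zeros(n, dtype=float)
        for s, e, v in track.intervals.get(chrom, []):
            b0 = s // bin_width
            b1 = (e - 1) // bin_width
            if b0 == b1:
                mass[b0] += v * (e - s)
                continue
            mass[b0] += v * ((b0 + 1) * bin_width - s)
            if b1 > b0 + 1:
                mass[b0 + 1 : b1] += v * bin_width
            mass[b1] += v * (e - b1 * bin_width)
        spans = np.full(n, bin_width, dtype=float)
        spans[-1] = clen - (n - 1) * bin_width
        values[chrom] = mass / spans
    return BinnedTrack(bin_width, values, sample_id=track.sample_id)


def smooth_track(binned: BinnedTrack, window: int) -> BinnedTrack:
    """Centered moving-average smoothing over a window given in bp.

    The window is coerced up to an odd multiple of the bin width.  Bins whose
    centered window extends past either chromosome end are passed through
    unsmoothed (the half-window edge rule).  Missing (NaN) bins are excluded
    from window means; a fully missing window stays missing.
    """
    bw = binned.bin_width
    if window < bw:
        raise BinningError(f"window {window} smaller than bin width {bw}")
    k = math.ceil(window / bw)
    if k % 2 == 0:
        k += 1
    half = k // 2
    out: dict[str, np.ndarray] = {}
    for chrom, vals in binned.values.items():
        n = len(vals)
        res = vals.copy()
        if n >= k:
            win = np.lib.stride_tricks.sliding_window_view(vals, k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                sm = np.nanmean(win, axis=1)
            interior = slice(half, n - half)
            # keep missing bins missing even when neighbors carry signal
            res[interior] = np.where(np.isnan(vals[interior]), np.nan, sm)
        out[chrom] = res
    return BinnedTrack(bw, out, sample_id=binned.sample_id)
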