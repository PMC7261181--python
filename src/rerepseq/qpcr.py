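"""qPCR quantification arithmetic and primer/amplicon bookkeeping.

Quantification follows the mitochondrial-normalized 2^-Cq scheme: technical
triplicates are averaged to one Cq per biological replicate, converted to
relative quantity 2^-Cq, divided by the same sample's mitochondrial COX2
quantity, and optionally expressed as fold change over the T0 baseline.

Amplicon coordinates are 1-based inclusive, the convention under which every
published amplicon span matches its declared length; they are converted to
0-based half-open internally when intersected with coverage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from rerepseq.genome_io import CoverageTrack

_DNA = set("ACGT")


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRecord:
    """One primer pair and its genomic target."""

    species: str
    id: str
    forward_seq: str
    reverse_seq: str
    chrom: str
    start_1based: int
    end_1based: int
    declared_length: int

    def __post_init__(self):
        if self.start_1based > self.end_1based:
            raise QpcrError(f"{self.id}: start {self.start_1based} > end {self.end_1based}")
        for seq in (self.forward_seq, self.reverse_seq):
            if not seq or set(seq) - _DNA:
                raise QpcrError(f"{self.id}: primer sequence {seq!r} not plain ACGT")

    @property
    def half_open(self) -> tuple[int, int]:
        """0-based half-open coordinates of the amplicon."""
        return self.start_1based - 1, self.end_1based


def amplicon_span_length(record: AmpliconRecord) -> int:
    """Amplicon length from 1-based inclusive coordinates: end - start + 1."""
    return record.end_1based - record.start_1based + 1


def span_matches_declared(record: AmpliconRecord) -> bool:
    return amplicon_span_length(record) == record.declared_length


def load_amplicon_table(path: str | Path | None = None) -> list[AmpliconRecord]:
    """Load an amplicon table (tab-delimited); default is the packaged panel."""
    if path is None:
        with resources.files("rerepseq.data").joinpath("amplicons.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        AmpliconRecord(
            species=r.species,
            id=r.id,
            forward_seq=r.forward,
            reverse_seq=r.reverse,
            chrom=r.chrom,
            start_1based=int(r.start_1based),
            end_1based=int(r.end_1based),
            declared_length=int(r.declared_length),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Cq arithmetic


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited Cq table: sample_id, target_id, replicate, Cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_id", "replicate", "Cq"}
    if not required <= set(df.columns):
        raise QpcrError(f"Cq table must have columns {sorted(required)}")
    return df


def collapse_technical_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical-triplicate Cq values to one Cq per (sample, target)."""
    return (
        table.groupby(["sample_id", "target_id"], as_index=False)["Cq"]
        .mean()
    )


def normalized_quantity(cq_target: float, cq_normalizer: float) -> float:
    """Mitochondria-normalized relative quantity 2^(Cq_normalizer - Cq_target).

    Equivalent to 2^-Cq(target) / 2^-Cq(normalizer): invariant to any
    constant shift applied to both Cq values, so independent of input amount.
    """
    return float(2.0 ** (cq_normalizer - cq_target))


def normalize_cq_table(
    collapsed: pd.DataFrame, normalizer_target: str = "COX2"
) -> pd.DataFrame:
    """Per-sample normalized quantities for every non-normalizer target."""
    norm = collapsed[collapsed.target_id == normalizer_target].set_index("sample_id")["Cq"]
    missing = set(collapsed.sample_id) - set(norm.index)
    if missing:
        raise QpcrError(f"normalizer {normalizer_target!r} absent for samples {sorted(missing)}")
    rows = []
    for r in collapsed.itertuples():
        if r.target_id == normalizer_target:
            continue
        rows.append(
            {
                "sample_id": r.sample_id,
                "target_id": r.target_id,
                "quantity": normalized_quantity(r.Cq, norm[r.sample_id]),
            }
        )
    return pd.DataFrame(rows)


def fold_enrichment_over_baseline(
    quantities: pd.DataFrame, baseline_sample: str
) -> pd.DataFrame:
    """Fold change of each sample's normalized quantity over the T0 baseline."""
    base = quantities[quantities.sample_id == baseline_sample].set_index("target_id")[
        "quantity"
    ]
    if (base <= 0).any() or base.empty:
        raise QpcrError(f"baseline sample {baseline_sample!r} missing or non-positive")
    out = quantities.copy()
    out["fold"] = [
        q / base[t] for q, t in zip(out.quantity, out.target_id)
    ]
    return out


def summarize_biological_replicates(folds: pd.Series) -> tuple[float, float]:
    """Mean and standard error of the mean across biological replicates."""
    arr = np.asarray(folds, dtype=float)
    n = len(arr)
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(arr.mean()), sem


# ---------------------------------------------------------------------------
# simulator bridge


def simulated_qpcr_signal(
    track: CoverageTrack, record: AmpliconRecord, normalizer_record: AmpliconRecord
) -> float:
    """Amplicon mean coverage divided by normalizer amplicon mean coverage.

    The in-silico analogue of the qPCR read-out: relative abundance of the
    target locus in the size-selected fragment pool, normalized to the
    mitochondrial control locus.
    """
    def mean_cov(rec: AmpliconRecord) -> float:
        s, e = rec.half_open
        mass = 0.0
        for iv_s, iv_e, v in track.intervals.get(rec.chrom, []):
            lo, hi = max(s, iv_s), min(e, iv_e)
            if lo < hi:
                mass += v * (hi - lo)
        return mass / (e - s)

    norm = mean_cov(normalizer_record)
    if norm == 0:
        raise QpcrError(f"zero coverage over normalizer amplicon {normalizer_record.id}")
    return mean_cov(record) / norm
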