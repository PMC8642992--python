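"""Junction-read counting, TPM normalization, circ/linear ratios, RNase R.

A read supports a circle iff it contains the circle's junction 2*anchor-mer
(last *anchor* nt followed by first *anchor* nt of the circular sequence) as
an exact substring; this mirrors junction-probe logic and keeps counting
deterministic and testable.  TPM is the usual length-normalized per-sample
rescaling to one million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotate import BackspliceEvent
from .errors import InputError

__all__ = [
    "CountMatrix",
    "count_bsj_reads",
    "tpm_normalize",
    "circ_linear_ratio",
    "rnase_r_resistance",
]


@dataclass
class CountMatrix:
    """Raw counts (features x samples) with feature lengths and sample design.

    ``design`` has one row per sample: columns ``sample``, ``condition``
    (tumor/normal) and ``pair`` (1-based pair index).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise InputError("CountMatrix: counts and lengths indices differ")
        if set(self.counts.columns) != set(self.design["sample"]):
            raise InputError("CountMatrix: counts columns and design samples differ")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("CountMatrix: negative count")

    @property
    def tpm(self) -> pd.DataFrame:
        return tpm_normalize(self.counts, self.lengths)

    def write(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="circ_id")


def _iter_read_seqs(reads: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        for rec in SeqIO.parse(str(reads), "fastq"):
            yield str(rec.seq).upper()
    else:
        for seq in reads:
            yield seq.upper()


def count_bsj_reads(
    reads: str | Path | Iterable[str],
    events: list[BackspliceEvent],
    anchor: int = 10,
) -> pd.Series:
    """Count junction-spanning reads per circle.

    Each read is counted at most once per circle.  Circles sharing an
    identical junction k-mer are ambiguous; a warning lists the pairs and the
    reads count toward every member.
    """
    if anchor < 1:
        raise InputError("anchor must be >= 1")
    kmers = {ev.circ_id: ev.junction_kmer(anchor) for ev in events}
    by_kmer: dict[str, list[str]] = {}
    for cid, k in kmers.items():
        by_kmer.setdefault(k, []).append(cid)
    dupes = [cids for cids in by_kmer.values() if len(cids) > 1]
    if dupes:
        warnings.warn(
            "ambiguous junction k-mers shared by: "
            + "; ".join(",".join(c) for c in dupes)
        )
    counts = {ev.circ_id: 0 for ev in events}
    items = list(by_kmer.items())
    for seq in _iter_read_seqs(reads):
        for kmer, cids in items:
            if kmer in seq:
                for cid in cids:
                    counts[cid] += 1
    return pd.Series(counts, name="bsj_reads")


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM: per-kb rates rescaled so each sample sums to 1e6.

    All-zero samples stay all-zero (no division by zero).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise InputError("tpm_normalize: missing length for some features")
    if (lengths <= 0).any():
        raise InputError("tpm_normalize: non-positive feature length")
    if (counts.to_numpy() < 0).any():
        raise InputError("tpm_normalize: negative count")
    rate = counts.div(lengths / 1000.0, axis=0)
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def circ_linear_ratio(circ_tpm: pd.DataFrame, linear_tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample circ/linear abundance ratio for matched features.

    Rows must match one-to-one (same feature ids in both tables).  Where the
    linear abundance is 0 the ratio is undefined and reported as NaN
    (serialized "NA"), never 0, and excluded from summaries.
    """
    if not circ_tpm.index.equals(linear_tpm.index) or list(circ_tpm.columns) != list(
        linear_tpm.columns
    ):
        raise InputError("circ_linear_ratio: unmatched features or samples")
    lin = linear_tpm.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = circ_tpm.to_numpy(dtype=float) / lin
    ratio[lin == 0] = np.nan
    return pd.DataFrame(ratio, index=circ_tpm.index, columns=circ_tpm.columns)


def rnase_r_resistance(
    counts_untreated: pd.Series,
    counts_treated: pd.Series,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Retained fraction (treated/untreated) per feature.

    Features with fraction >= ``threshold`` are flagged resistant — the
    in-silico counterpart of surviving 3'->5' exonuclease digestion.
    Undefined fractions (untreated == 0) are NaN and never flagged.
    """
    if not counts_untreated.index.equals(counts_treated.index):
        raise InputError("rnase_r_resistance: unmatched features")
    unt = counts_untreated.to_numpy(dtype=float)
    trt = counts_treated.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = trt / unt
    frac[unt == 0] = np.nan
    resistant = np.where(np.isnan(frac), False, frac >= threshold)
    return pd.DataFrame(
        {"retained_fraction": frac, "resistant": resistant},
        index=counts_untreated.index,
    )
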