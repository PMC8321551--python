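"""Small-RNA diagnostic statistics.

Three diagnostics distinguish a piRNA population: the read-length
distribution (piRNAs sit at 23-28 nt with a 24-26 nt peak), the 1U/10A
nucleotide bias (uridine at position 1 of primary piRNAs, adenosine at
position 10 of ping-pong responders), and the ping-pong signature itself:
an excess of opposite-strand read pairs whose 5' ends overlap by exactly
10 nt, summarised as a Z-score of the 10-nt overlap count against the
other overlap lengths.

Overlap geometry, on 0-based coordinates with a minus-strand read's 5'
end at its rightmost aligned base: a plus read with 5' end at p and a
minus read with 5' end at q overlap by o = q - p + 1 nucleotides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SmallRNASet:
    """Mapped small RNAs: one row per read placement.

    Columns: read_id, reference (feature or contig label), five_prime
    (0-based; for minus-strand reads the rightmost aligned reference
    base), strand, sequence (5'->3' as sequenced).
    """

    frame: pd.DataFrame

    REQUIRED = ("read_id", "reference", "five_prime", "strand", "sequence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SmallRNASet missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        if not len(self.frame):
            return np.array([], dtype=np.int64)
        return self.frame["sequence"].str.len().to_numpy()

    @classmethod
    def from_truth(cls, truth: pd.DataFrame, locus: str | None = None) -> "SmallRNASet":
        """Build from a simulator truth table, optionally one locus."""
        frame = truth if locus is None else truth[truth["locus_id"] == locus]
        return cls(
            frame.rename(columns={"locus_id": "reference"})[
                ["read_id", "reference", "five_prime", "strand", "sequence"]
            ].reset_index(drop=True)
        )

    @classmethod
    def from_tsv(cls, path) -> "SmallRNASet":
        return cls(pd.read_csv(path, sep="\t"))


# ------------------------------------------------------------------- lengths


@dataclass(frozen=True)
class LengthResult:
    histogram: pd.Series  # index = length over the closed range
    fraction_in_range: float | None  # fraction of reads 23-28 nt
    modal_length: int | None  # smallest length on ties


def length_histogram(
    reads: SmallRNASet, low: int = 18, high: int = 35, piRNA_range: tuple[int, int] = (23, 28)
) -> LengthResult:
    lengths = reads.lengths
    idx = pd.RangeIndex(low, high + 1, name="length")
    hist = pd.Series(0, index=idx, dtype=int)
    if lengths.size == 0:
        return LengthResult(hist, None, None)
    values, counts = np.unique(lengths, return_counts=True)
    inside = (values >= low) & (values <= high)
    hist.loc[values[inside]] = counts[inside]
    lo, hi = piRNA_range
    frac = float(hist.loc[lo:hi].sum() / lengths.size)
    modal = int(hist.idxmax())  # idxmax returns the first (smallest) on ties
    return LengthResult(hist, frac, modal)


# ---------------------------------------------------------------------- bias


@dataclass(frozen=True)
class BiasResult:
    u1_fraction: float
    a10_fraction: float | None
    u1_or_a10_fraction: float | None
    n_u1: int  # reads entering the 1U statistic
    n_a10: int  # reads of length >= 10 entering the 10A and union statistics


def nucleotide_bias(reads: SmallRNASet) -> BiasResult:
    """1U / 10A fractions on the sequenced strand.

    1U counts T at position 1 of every read; 10A counts A at position 10
    among reads of length >= 10 (shorter reads are excluded from the 10A
    and union statistics, and the per-statistic n is reported).
    """
    seqs = reads.frame["sequence"]
    n = len(seqs)
    if n == 0:
        return BiasResult(float("nan"), None, None, 0, 0)
    u1 = seqs.str[0] == "T"
    long_enough = seqs.str.len() >= 10
    n10 = int(long_enough.sum())
    u1_frac = float(u1.mean())
    if n10 == 0:
        return BiasResult(u1_frac, None, None, n, 0)
    a10 = seqs.str[9] == "A"
    a10_frac = float(a10[long_enough].mean())
    union = float((u1 | a10)[long_enough].mean())
    return BiasResult(u1_frac, a10_frac, union, n, n10)


# ----------------------------------------------------------------- ping-pong


@dataclass
class OverlapHistogram:
    """5'-5' overlap pair counts for overlap lengths 1..o_max."""

    counts: np.ndarray  # counts[o - 1] is the weight at overlap o
    o_max: int
    weighting: str  # "reads" | "species"

    def count(self, overlap: int) -> float:
        if not 1 <= overlap <= self.o_max:
            raise ValueError(f"overlap {overlap} outside 1..{self.o_max}")
        return float(self.counts[overlap - 1])

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=pd.RangeIndex(1, self.o_max + 1, name="overlap"))


def pingpong_histogram(
    reads: SmallRNASet, o_max: int = 30, weighting: str = "reads"
) -> OverlapHistogram:
    """Count opposite-strand 5'-5' overlap pairs per overlap length.

    With ``reads`` weighting every read pair contributes 1; with
    ``species`` weighting each distinct (plus 5', minus 5') position pair
    contributes 1 regardless of multiplicity.  References are processed
    independently and summed.
    """
    if weighting not in ("reads", "species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    frame = reads.frame
    counts = np.zeros(o_max, dtype=float)
    both_strands_seen = False
    for _, group in frame.groupby("reference", sort=False):
        plus = group.loc[group["strand"] == "+", "five_prime"].to_numpy(np.int64)
        minus = group.loc[group["strand"] == "-", "five_prime"].to_numpy(np.int64)
        if plus.size == 0 or minus.size == 0:
            continue
        both_strands_seen = True
        p_pos, p_n = np.unique(plus, return_counts=True)
        q_pos, q_n = np.unique(minus, return_counts=True)
        if weighting == "species":
            p_n = np.ones_like(p_n)
            q_n = np.ones_like(q_n)
        for o in range(1, o_max + 1):
            # overlap o pairs a plus 5' at p with a minus 5' at p + o - 1
            j = np.searchsorted(q_pos, p_pos + o - 1)
            j = np.clip(j, 0, q_pos.size - 1)
            match = q_pos[j] == p_pos + o - 1
            counts[o - 1] += float((p_n[match] * q_n[j[match]]).sum())
    if len(frame) and not both_strands_seen:
        warnings.warn("ping-pong histogram over single-strand input: all counts zero")
    return OverlapHistogram(counts, o_max, weighting)


def pingpong_zscore(hist: OverlapHistogram, focal: int = 10) -> float | None:
    """Z-score of the focal (10 nt) overlap against the other overlap
    lengths: (c_10 - mean of background) / sample sd of background.
    Returns None (undefined) when the background sd is zero."""
    if hist.o_max < focal + 1:
        raise ValueError(f"o_max must be >= {focal + 1}")
    background = np.delete(hist.counts, focal - 1)
    numerator = hist.counts[focal - 1] - background.mean()
    sd = background.std(ddof=1)
    if sd == 0:
        # a perfectly flat histogram has no excess (z = 0); any other
        # degenerate background leaves the score undefined
        return 0.0 if numerator == 0 else None
    return float(numerator / sd)
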