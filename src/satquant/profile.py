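"""Consensus-coordinate pileups with multimer folding.

Reads from a tandem repeat are aligned to a concatenated consensus
multimer (a doubled monomer for 1.688-type families; Left+Right+Left for
an Rsp-type dimer) so that reads spanning a repeat junction still align
contiguously.  The hit coordinates are then folded back onto a single
monomer (or the Left+Right dimer) by modular arithmetic, producing a
per-position depth profile whose total is exactly the number of aligned
bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import dna, io
from .repeats import ConsensusRepeat

BLAST_M6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class ConsensusHit:
    """One query placement on the multimer (0-based half-open)."""

    query_id: str
    start: int
    end: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.query_id}: invalid interval [{self.start}, {self.end})")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.query_id}: identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class Multimer:
    sequence: str
    folded_length: int


@dataclass
class ProfileTrack:
    reference: str
    folded_length: int
    depth: np.ndarray
    mode: str = "footprint"  # footprint | five_prime

    def normalized(self) -> np.ndarray:
        """Depth scaled to mean 1 (undefined for an empty track)."""
        mean = self.depth.mean()
        if mean == 0:
            raise ValueError("cannot normalise an all-zero track")
        return self.depth / mean

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"position": np.arange(self.folded_length), "depth": self.depth})
        mean = self.depth.mean()
        frame["normalized_depth"] = self.depth / mean if mean > 0 else 0.0
        return frame


def build_multimer(consensus: ConsensusRepeat) -> Multimer:
    """Monomer families -> monomer x 2, folded length = monomer length;
    dimer families -> Left+Right+Left (trimer), folded length =
    |Left| + |Right|."""
    if consensus.unit_structure == "monomer":
        (_, seq), = consensus.units
        return Multimer(seq + seq, len(seq))
    (_, left), (_, right) = consensus.units
    return Multimer(left + right + left, len(left) + len(right))


def read_blast_m6(path: str | Path) -> list[ConsensusHit]:
    """Ingest BLAST tabular (outfmt 6) hits against the multimer.

    1-based inclusive subject coordinates are converted to 0-based
    half-open; hits with reversed subject coordinates are normalised with
    strand '-'.
    """
    frame = pd.read_csv(path, sep="\t", header=None, comment=None)
    if frame.shape[1] != 12:
        raise ValueError(
            f"{path}: expected 12 BLAST outfmt-6 columns, got {frame.shape[1]} (line 1)"
        )
    frame.columns = BLAST_M6_COLUMNS
    hits = []
    for lineno, row in enumerate(frame.itertuples(index=False), 1):
        sstart, send = int(row.sstart), int(row.send)
        if sstart <= send:
            start, end, strand = sstart - 1, send, "+"
        else:
            start, end, strand = send - 1, sstart, "-"
        try:
            hits.append(
                ConsensusHit(str(row.qseqid), start, end, strand, float(row.pident) / 100.0)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def align_to_consensus(
    queries, multimer: Multimer | str, min_identity: float = 0.9
) -> list[ConsensusHit]:
    """Exhaustive ungapped scan of each query against the multimer, both
    strands; reports the maximal-identity placement(s) at or above
    ``min_identity`` (all ties).  A toy-scale stand-in for BLAST.
    """
    if isinstance(queries, (str, Path)):
        path = Path(queries)
        queries = (
            io.read_fastq(path) if path.suffix in (".fastq", ".fq") else
            list(io.read_fasta(path).items())
        )
    seq = multimer.sequence if isinstance(multimer, Multimer) else multimer
    ref = dna.encode(seq)
    hits: list[ConsensusHit] = []
    for query_id, qseq in queries:
        q = dna.encode(qseq)
        L = q.size
        if L > ref.size:
            raise ValueError(f"{query_id}: query longer than multimer")
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        best: list[tuple[int, str, float]] = []
        best_ident: float | None = None
        for strand, qq in (("+", q), ("-", dna.revcomp_array(q))):
            ident = (windows == qq).mean(axis=1)
            top = float(ident.max())
            if top < min_identity:
                continue
            if best_ident is None or top > best_ident:
                best = [(int(p), strand, top) for p in np.nonzero(ident == top)[0]]
                best_ident = top
            elif top == best_ident:
                best += [(int(p), strand, top) for p in np.nonzero(ident == top)[0]]
        for pos, strand, ident in sorted(best):
            hits.append(ConsensusHit(query_id, pos, pos + L, strand, ident))
    return hits


def fold_coordinates(hit: ConsensusHit, folded_length: int) -> np.ndarray:
    """Folded position of every multimer base in the hit interval:
    x mod folded_length, so junction-spanning hits wrap contiguously."""
    if folded_length <= 0:
        raise ValueError("folded_length must be > 0")
    return np.arange(hit.start, hit.end) % folded_length


def pileup_profile(
    hits: list[ConsensusHit],
    folded_length: int,
    reference: str = "consensus",
    mode: str = "footprint",
) -> ProfileTrack:
    """Accumulate folded depth over hits.

    ``footprint`` adds depth 1 at every base of each hit; ``five_prime``
    adds depth 1 only at each hit's 5' end (the hit start for plus-strand
    hits, end - 1 for minus)."""
    if mode not in ("footprint", "five_prime"):
        raise ValueError(f"unknown mode {mode!r}")
    depth = np.zeros(folded_length, dtype=float)
    for hit in hits:
        if mode == "footprint":
            np.add.at(depth, fold_coordinates(hit, folded_length), 1.0)
        else:
            fp = hit.start if hit.strand == "+" else hit.end - 1
            depth[fp % folded_length] += 1.0
    return ProfileTrack(reference, folded_length, depth, mode)


def compare_profiles(a: ProfileTrack, b: ProfileTrack) -> float | None:
    """Pearson r between two folded depth profiles (mean-1 scaling leaves
    r unchanged).  None when either track is constant."""
    if a.folded_length != b.folded_length:
        raise ValueError("profiles have different folded lengths")
    if a.depth.std() == 0 or b.depth.std() == 0:
        return None
    return float(stats.pearsonr(a.depth, b.depth).statistic)
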