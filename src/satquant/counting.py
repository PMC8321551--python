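"""Multimapper-aware read counting over repeat annotations.

Reads inside tandem satellite arrays are almost never uniquely mappable, so
how a read's equally best alignments are assigned determines the repeat
quantification.  Three policies are provided:

``unique``
    keep only reads with a single best hit (the published convention for
    heterochromatic satellite ChIP scoring);
``random``
    assign each read to one of its best hits, chosen uniformly from a
    seeded stream over hits in sorted order (reproducible across runs);
``fractional``
    split each read 1/n over its n best hits (deterministic; the default).

A hit contributes its weight to the feature containing its 5'-most genomic
coordinate, which avoids double counting at feature boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam

from . import dna, io
from ._rng import stream
from .annotation import RepeatAnnotation

POLICIES = ("unique", "random", "fractional")


class Hit(NamedTuple):
    contig: str
    five_prime: int  # 0-based 5'-most reference coordinate of the read
    strand: str
    mismatches: int


@dataclass
class WeightedAlignment:
    """One mapped read: its best-hit set and (after assignment) weights."""

    read_id: str
    length: int
    best_hits: list[Hit]
    assigned: list[tuple[Hit, float]] = field(default_factory=list)

    @property
    def n_best(self) -> int:
        return len(self.best_hits)

    @property
    def weight_sum(self) -> float:
        return sum(w for _, w in self.assigned)


# ----------------------------------------------------------------- ingestion


def read_alignments(path: str | Path) -> tuple[list[WeightedAlignment], int]:
    """Ingest a SAM/BAM file into per-read best-hit sets.

    All records sharing a read name are grouped; the best hits are those
    with the minimal mismatch count (NM tag; falls back to negated
    alignment score with a warning when NM is absent).  Returns the
    alignments (assignment pending) and the number of unmapped reads.
    """
    groups: dict[str, list[tuple[Hit, int]]] = {}
    lengths: dict[str, int] = {}
    order: list[str] = []
    n_unmapped = 0
    warned = False
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.reference_name is None or rec.reference_start is None:
                raise ValueError(f"{path}: malformed record for read {rec.query_name!r}")
            strand = "-" if rec.is_reverse else "+"
            fp = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            if rec.has_tag("NM"):
                cost = int(rec.get_tag("NM"))
            elif rec.has_tag("AS"):
                if not warned:
                    warnings.warn(f"{path}: NM tag missing, falling back to alignment score")
                    warned = True
                cost = -int(rec.get_tag("AS"))
            else:
                raise ValueError(
                    f"{path}: read {rec.query_name!r} has neither NM nor AS tag"
                )
            name = rec.query_name
            if name not in groups:
                groups[name] = []
                order.append(name)
                lengths[name] = rec.query_length or rec.infer_query_length() or 0
            groups[name].append((Hit(rec.reference_name, fp, strand, cost), cost))
    out = []
    for name in order:
        hits = groups[name]
        best = min(c for _, c in hits)
        kept = sorted(
            {h for h, c in hits if c == best}, key=lambda h: (h.contig, h.five_prime, h.strand)
        )
        out.append(WeightedAlignment(read_id=name, length=lengths[name], best_hits=kept))
    return out, n_unmapped


def alignments_from_truth(truth: pd.DataFrame) -> list[WeightedAlignment]:
    """Treat a simulator truth table as a perfect aligner's output: one
    best hit per read at its true placement."""
    return [
        WeightedAlignment(
            read_id=row.read_id,
            length=int(row.length),
            best_hits=[Hit(row.contig, int(row.five_prime), row.strand, 0)],
        )
        for row in truth.itertuples()
    ]


# -------------------------------------------------------------- brute mapper


def map_reads_bruteforce(
    reads: Iterable[tuple[str, str]] | str | Path,
    genome: dict[str, str] | str | Path,
    max_mismatch: int = 0,
    sam_out: str | Path | None = None,
) -> list[WeightedAlignment]:
    """Exhaustive best-hit mapper for toy-scale verification.

    Scans every position of both strands, reporting all placements with
    Hamming distance both minimal and <= ``max_mismatch``, in deterministic
    (contig, position, strand) order.  Guarded against non-toy inputs;
    use a real aligner beyond that.  Optionally writes SAM via pysam.
    """
    if isinstance(reads, (str, Path)):
        reads = io.read_fastq(reads)
    else:
        reads = list(reads)
    if isinstance(genome, (str, Path)):
        genome = io.read_fasta(genome)
    total_len = sum(len(s) for s in genome.values())
    if total_len > 10_000_000 or total_len * max(len(reads), 1) > 2_000_000_000:
        raise ValueError(
            "brute-force mapper guard exceeded (genome x reads too large); "
            "use an external aligner"
        )
    contigs = {name: dna.encode(seq) for name, seq in sorted(genome.items())}

    out: list[WeightedAlignment] = []
    for read_id, seq in reads:
        query = dna.encode(seq)
        L = query.size
        rc = dna.revcomp_array(query)
        # a palindromic read's +/- placements share one genomic footprint;
        # report the plus-strand one only
        strands = (("+", query),) if np.array_equal(query, rc) else (("+", query), ("-", rc))
        found: list[tuple[Hit, int]] = []
        for contig, garr in contigs.items():
            if garr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(garr, L)
            for strand, q in strands:
                mism = (windows != q).sum(axis=1)
                for pos in np.nonzero(mism <= max_mismatch)[0]:
                    # 5'-most coordinate of the *read*: left end on plus,
                    # right end on minus
                    fp = int(pos) if strand == "+" else int(pos) + L - 1
                    found.append((Hit(contig, fp, strand, int(mism[pos])), int(pos)))
        if found:
            best = min(h.mismatches for h, _ in found)
            kept = [(h, p) for h, p in found if h.mismatches == best]
            kept.sort(key=lambda t: (t[0].contig, t[1], t[0].strand))
            out.append(
                WeightedAlignment(read_id=read_id, length=L, best_hits=[h for h, _ in kept])
            )
        else:
            out.append(WeightedAlignment(read_id=read_id, length=L, best_hits=[]))

    if sam_out is not None:
        _write_sam(out, reads, contigs, sam_out)
    return out


def _write_sam(
    alignments: list[WeightedAlignment],
    reads: list[tuple[str, str]],
    contigs: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(arr.size)} for name, arr in contigs.items()],
    }
    seqs = dict(reads)
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        refs = {name: i for i, name in enumerate(contigs)}
        for aln in alignments:
            seq = seqs[aln.read_id]
            if not aln.best_hits:
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = aln.read_id
                rec.query_sequence = seq
                rec.flag = 4
                sam.write(rec)
                continue
            for k, hit in enumerate(aln.best_hits):
                rec = pysam.AlignedSegment(sam.header)
                rec.query_name = aln.read_id
                rec.flag = (16 if hit.strand == "-" else 0) | (256 if k > 0 else 0)
                rec.reference_id = refs[hit.contig]
                leftmost = hit.five_prime if hit.strand == "+" else hit.five_prime - aln.length + 1
                rec.reference_start = leftmost
                rec.mapping_quality = 255
                rec.cigarstring = f"{aln.length}M"
                rec.query_sequence = dna.revcomp(seq) if hit.strand == "-" else seq
                rec.set_tag("NM", hit.mismatches)
                sam.write(rec)


# ---------------------------------------------------------------- assignment


def assign_multimappers(
    alignments: Iterable[WeightedAlignment],
    policy: str = "fractional",
    seed: int | None = None,
) -> list[WeightedAlignment]:
    """Resolve each read's best-hit set into weights under a policy.

    unique: weight 1 iff a single best hit, otherwise dropped (weight 0);
    random: one best hit gets weight 1, chosen uniformly from the seeded
    stream over hits in sorted order; fractional: 1/n each.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    rng = None
    if policy == "random":
        if seed is None:
            raise ValueError("random policy requires a seed")
        rng = stream(seed, "assign_multimappers")
    out = []
    for aln in alignments:
        if not aln.best_hits:
            continue
        if policy == "unique":
            aln.assigned = [(aln.best_hits[0], 1.0)] if aln.n_best == 1 else []
        elif policy == "fractional":
            w = 1.0 / aln.n_best
            aln.assigned = [(h, w) for h in aln.best_hits]
        else:
            aln.assigned = [(aln.best_hits[int(rng.integers(aln.n_best))], 1.0)]
        out.append(aln)
    return out


# ------------------------------------------------------------------ counting


class CountMatrix:
    """Features x samples counts plus per-sample normaliser totals.

    ``totals`` rows: total_mapped (all mapped reads), mirna_mapped, and
    flamenco_mapped (weight landing in miRNA-class features and in the
    flamenco-family uni-strand cluster).  ``units`` records whether the
    values are raw counts or normalised, and ``derived_rows`` lists rows
    (the combined 1.688-style family rows) that duplicate mass already
    present in other rows and are therefore excluded from conservation
    sums.
    """

    TOTAL_KEYS = ("total_mapped", "mirna_mapped", "flamenco_mapped")

    def __init__(
        self,
        counts: pd.DataFrame,
        totals: pd.DataFrame,
        units: str = "raw",
        meta: dict | None = None,
        derived_rows: list[str] | None = None,
    ):
        if (counts.to_numpy(float) < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.totals = totals
        self.units = units
        self.meta = dict(meta or {})
        self.derived_rows = list(derived_rows or [])

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def primary_rows(self) -> pd.DataFrame:
        """Rows excluding derived (combined-family) duplicates."""
        keep = [f for f in self.counts.index if f not in self.derived_rows]
        return self.counts.loc[keep]

    def join(self, other: "CountMatrix") -> "CountMatrix":
        if self.units != other.units:
            raise ValueError("cannot join matrices with different units")
        counts = self.counts.join(other.counts, how="outer").fillna(0.0)
        totals = self.totals.join(other.totals, how="outer").fillna(0.0)
        derived = sorted(set(self.derived_rows) | set(other.derived_rows))
        return CountMatrix(counts, totals, self.units, {**other.meta, **self.meta}, derived)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path) -> None:
        header = [
            f"units={self.units}",
            f"derived_rows={','.join(self.derived_rows)}",
        ] + [f"meta:{k}={v}" for k, v in sorted(self.meta.items())]
        frame = self.counts.reset_index().rename(columns={"index": "feature"})
        totals = self.totals.reset_index().rename(columns={"index": "feature"})
        totals["feature"] = "#total:" + totals["feature"]
        io.write_table(pd.concat([frame, totals], ignore_index=True), path, header)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        frame, raw_meta = io.read_table(path)
        frame = frame.set_index("feature")
        is_total = frame.index.str.startswith("#total:")
        totals = frame[is_total]
        totals.index = totals.index.str.removeprefix("#total:")
        meta = {
            k.removeprefix("meta:"): v for k, v in raw_meta.items() if k.startswith("meta:")
        }
        derived = [r for r in raw_meta.get("derived_rows", "").split(",") if r]
        counts = frame[~is_total].astype(float)
        counts.index.name = None
        totals = totals.astype(float)
        totals.index.name = None
        return cls(counts, totals, raw_meta.get("units", "raw"), meta, derived)


def _family_label(feature) -> str:
    return feature.family_label


def count_features(
    alignments: Iterable[WeightedAlignment],
    annotation: RepeatAnnotation,
    group_by: str = "locus",
    strand_mode: str = "both",
    sample: str = "sample",
) -> CountMatrix:
    """Count assigned weights per feature (by each hit's 5' coordinate).

    ``group_by`` is locus, family, or class.  Under family grouping,
    subfamilies are reported separately (e.g. ``1.688_359bp``) and a
    combined family row (``1.688``) is added and marked as derived.  Hits
    outside every feature accumulate in an ``unannotated`` row; features
    with no hits appear with count 0.
    """
    if group_by not in ("locus", "family", "class"):
        raise ValueError(f"unknown group_by {group_by!r}")
    if strand_mode not in ("both", "sense", "antisense"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    keys = {
        "locus": lambda f: f.locus_id,
        "family": _family_label,
        "class": lambda f: f.feature_class,
    }[group_by]
    rows = sorted({keys(f) for f in annotation}) + ["unannotated"]
    counts = dict.fromkeys(rows, 0.0)
    features = annotation.features

    # batch the hits so feature lookup is one vectorised search per contig
    contigs: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    weights: list[float] = []
    total_mapped = 0.0
    for aln in alignments:
        total_mapped += 1
        for hit, w in aln.assigned:
            contigs.append(hit.contig)
            positions.append(hit.five_prime)
            strands.append(hit.strand)
            weights.append(w)

    mirna = 0.0
    flamenco = 0.0
    if positions:
        contig_arr = np.array(contigs)
        pos_arr = np.array(positions, dtype=np.int64)
        strand_arr = np.array(strands)
        w_arr = np.array(weights, dtype=float)
        feat_idx = np.full(pos_arr.size, -1, dtype=np.int64)
        for contig in np.unique(contig_arr):
            sel = contig_arr == contig
            feat_idx[sel] = annotation.locate(str(contig), pos_arr[sel])
        counts["unannotated"] = float(w_arr[feat_idx < 0].sum())
        keep = feat_idx >= 0
        if strand_mode != "both":
            feat_strand = np.array([f.strand for f in features] + ["."])
            fs = feat_strand[feat_idx]
            sense = fs == strand_arr
            stranded = (fs == "+") | (fs == "-")
            if strand_mode == "sense":
                keep &= ~stranded | sense
            else:
                keep &= ~stranded | ~sense
        per_feature = np.zeros(len(features), dtype=float)
        np.add.at(per_feature, feat_idx[keep], w_arr[keep])
        for j, feat in enumerate(features):
            w = per_feature[j]
            if not w:
                continue
            counts[keys(feat)] += w
            if feat.feature_class == "miRNA":
                mirna += w
            if feat.family == "flamenco":
                flamenco += w

    series = pd.Series(counts, name=sample).loc[rows]
    frame = series.to_frame()
    derived: list[str] = []
    if group_by == "family":
        combined: dict[str, float] = {}
        for f in features:
            if f.subfamily is not None:
                combined.setdefault(f.family, 0.0)
        for fam in combined:
            members = sorted({_family_label(f) for f in features if f.family == fam})
            combined[fam] = float(frame.loc[members, sample].sum())
        for fam, value in sorted(combined.items()):
            if fam in frame.index:  # family also present without subfamily label
                frame.loc[fam] += value
            else:
                frame.loc[fam] = value
            derived.append(fam)
        frame = frame.sort_index()
        frame = pd.concat([frame.drop(index="unannotated"), frame.loc[["unannotated"]]])
    totals = pd.DataFrame(
        {sample: [total_mapped, mirna, flamenco]}, index=list(CountMatrix.TOTAL_KEYS)
    )
    meta = {"group_by": group_by, "strand_mode": strand_mode}
    return CountMatrix(frame, totals, "raw", meta, derived)


def count_windows(
    alignments: Iterable[WeightedAlignment],
    feature,
    window_size: int,
) -> np.ndarray:
    """Tile a feature's interval into fixed windows and apportion weights
    by 5' coordinate; the last window may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    length = feature.end - feature.start
    if window_size > length:
        warnings.warn(
            f"window_size {window_size} exceeds locus length {length}; using a single window"
        )
    n_windows = max(1, -(-length // window_size))
    out = np.zeros(n_windows, dtype=float)
    for aln in alignments:
        for hit, w in aln.assigned:
            if hit.contig != feature.contig or not feature.start <= hit.five_prime < feature.end:
                continue
            out[(hit.five_prime - feature.start) // window_size] += w
    return out


# -------------------------------------------------------------- normalisation


def normalize(matrix: CountMatrix, mode: str = "rpm_total", reference: str | None = None) -> CountMatrix:
    """Scale counts to per-million units.

    ``rpm_total`` divides by total mapped reads (RPM);
    ``per_million_reference`` divides by the reads mapped to a reference
    class (``mirna`` or ``flamenco``), the normalisers unaffected by the
    regulatory pathway under study.
    """
    if matrix.units != "raw":
        raise ValueError("can only normalise raw counts")
    if mode == "rpm_total":
        key, units = "total_mapped", "rpm_total"
    elif mode == "per_million_reference":
        if reference not in ("mirna", "flamenco"):
            raise ValueError("reference must be 'mirna' or 'flamenco'")
        key, units = f"{reference}_mapped", f"per_million_{reference}"
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    denom = matrix.totals.loc[key]
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"zero normaliser ({key}) for sample(s): {', '.join(zero.index)}")
    counts = matrix.counts * 1e6 / denom
    return CountMatrix(counts, matrix.totals.copy(), units, {**matrix.meta, "normalized_by": key},
                       matrix.derived_rows)


# ------------------------------------------------------------------ summaries


@dataclass(frozen=True)
class StrandRatio:
    plus: float
    minus: float
    ratio: float  # inf when minus == 0 (flagged)
    infinite: bool


def strand_ratio(alignments: Iterable[WeightedAlignment], feature) -> StrandRatio:
    """Plus/minus weight inside a feature (5'-coordinate assignment)."""
    plus = minus = 0.0
    for aln in alignments:
        for hit, w in aln.assigned:
            if hit.contig != feature.contig or not feature.start <= hit.five_prime < feature.end:
                continue
            if hit.strand == "+":
                plus += w
            else:
                minus += w
    if minus == 0:
        return StrandRatio(plus, minus, float("inf"), True)
    return StrandRatio(plus, minus, plus / minus, False)


def fraction_of_mapped(matrix: CountMatrix, feature: str) -> pd.Series:
    """Percent of each sample's mapped reads attributed to a feature row."""
    if feature not in matrix.counts.index:
        raise KeyError(f"feature {feature!r} not in matrix")
    total = matrix.totals.loc["total_mapped"]
    if (total <= 0).any():
        raise ValueError("total_mapped must be > 0")
    return 100.0 * matrix.counts.loc[feature] / total
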