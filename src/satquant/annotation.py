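"""Genomic feature annotation: labelled intervals with GFF3 round-trip.

Internal coordinates are 0-based half-open; GFF3 I/O converts to and from
the format's 1-based inclusive convention.  Features carry the attributes
the counting and enrichment stages key on: family (e.g. ``Rsp``,
``1.688``), optional subfamily, locus id, compartment (heterochromatic or
euchromatic), and feature class (satDNA, uni-/dual-strand piRNA cluster,
gene, miRNA, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_CLASSES = (
    "satDNA",
    "piRNA_cluster_uni",
    "piRNA_cluster_dual",
    "gene",
    "miRNA",
    "other",
)
COMPARTMENTS = ("heterochromatic", "euchromatic")


@dataclass(frozen=True)
class Feature:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+", "-", "."
    family: str
    locus_id: str
    compartment: str
    feature_class: str
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.locus_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.locus_id}: invalid strand {self.strand!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.locus_id}: invalid compartment {self.compartment!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"{self.locus_id}: invalid class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def family_label(self) -> str:
        return self.family if self.subfamily is None else f"{self.family}_{self.subfamily}"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class RepeatAnnotation:
    """An ordered, validated collection of features over an assembly."""

    def __init__(self, features: list[Feature], contig_lengths: dict[str, int]):
        self.features = list(features)
        self.contig_lengths = dict(contig_lengths)
        seen: set[str] = set()
        for f in self.features:
            if f.locus_id in seen:
                raise ValueError(f"duplicate locus_id {f.locus_id!r}")
            seen.add(f.locus_id)
            clen = self.contig_lengths.get(f.contig)
            if clen is None:
                raise ValueError(f"{f.locus_id}: unknown contig {f.contig!r}")
            if f.end > clen:
                raise ValueError(f"{f.locus_id}: end {f.end} beyond contig length {clen}")
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._by_id = {f.locus_id: f for f in self.features}
        self._build_index()

    def _build_index(self) -> None:
        by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for i, f in enumerate(self.features):
            by_contig.setdefault(f.contig, []).append((f.start, f.end, i))
        for contig, triples in by_contig.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            idx = np.array([t[2] for t in triples], dtype=np.int64)
            if np.any(ends[:-1] > starts[1:]):
                j = int(np.nonzero(ends[:-1] > starts[1:])[0][0])
                a = self.features[int(idx[j])].locus_id
                b = self.features[int(idx[j + 1])].locus_id
                raise ValueError(f"overlapping features on {contig}: {a} and {b}")
            self._index[contig] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, locus_id: str) -> Feature:
        return self._by_id[locus_id]

    def locate(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Feature index containing each position, or -1 when unannotated."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, -1, dtype=np.int64)
        entry = self._index.get(contig)
        if entry is None:
            return out
        starts, ends, idx = entry
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = (j >= 0) & (positions < ends[np.clip(j, 0, len(ends) - 1)])
        out[ok] = idx[j[ok]]
        return out

    # ------------------------------------------------------------------ GFF3

    def to_gff(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig in sorted(self.contig_lengths):
                fh.write(f"##sequence-region {contig} 1 {self.contig_lengths[contig]}\n")
            for f in self.features:
                attrs = [f"ID={f.locus_id}", f"family={f.family}"]
                if f.subfamily is not None:
                    attrs.append(f"subfamily={f.subfamily}")
                attrs += [f"compartment={f.compartment}", f"class={f.feature_class}"]
                fh.write(
                    "\t".join(
                        [
                            f.contig,
                            "satquant",
                            f.feature_class,
                            str(f.start + 1),  # GFF3 is 1-based inclusive
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_gff(cls, path: str | Path) -> "RepeatAnnotation":
        contig_lengths: dict[str, int] = {}
        features: list[Feature] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("##sequence-region"):
                    _, contig, _one, length = line.split()
                    contig_lengths[contig] = int(length)
                    continue
                if line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
                features.append(
                    Feature(
                        contig=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        strand=cols[6],
                        family=attrs["family"],
                        locus_id=attrs["ID"],
                        compartment=attrs["compartment"],
                        feature_class=attrs["class"],
                        subfamily=attrs.get("subfamily"),
                    )
                )
        if not contig_lengths:
            # tolerate GFFs without sequence-region pragmas
            for f in features:
                contig_lengths[f.contig] = max(contig_lengths.get(f.contig, 0), f.end)
        return cls(features, contig_lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [f.locus_id for f in self.features],
                "contig": [f.contig for f in self.features],
                "start": [f.start for f in self.features],
                "end": [f.end for f in self.features],
                "strand": [f.strand for f in self.features],
                "family": [f.family for f in self.features],
                "subfamily": [f.subfamily for f in self.features],
                "compartment": [f.compartment for f in self.features],
                "class": [f.feature_class for f in self.features],
            }
        )
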