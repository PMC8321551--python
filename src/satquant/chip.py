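"""ChIP/input enrichment scoring over repeats and piRNA clusters.

The enrichment score of a feature is E = RPM_chip / RPM_input, the ratio
of library-size-normalised read abundance in the antibody ChIP sample to
its no-antibody input control.  At heterochromatic satellite loci only
uniquely mapping reads are scored (satellite multimappers cannot be
confidently placed, and the unique subset suffices at discrete assembled
loci); the euchromatic baseline is the median enrichment of
protein-coding genes at least 5 Mb from any heterochromatin boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diff
from .annotation import RepeatAnnotation
from .counting import CountMatrix

#: feature class -> enrichment summary class
CLASS_LABELS = {
    "satDNA": "satDNA",
    "piRNA_cluster_uni": "uni",
    "piRNA_cluster_dual": "dual",
    "gene": "eu",
}


@dataclass(frozen=True)
class EnrichmentRecord:
    feature: str
    rpm_chip: float
    rpm_input: float
    enrichment: float | None  # None = undefined (input RPM is 0)
    read_policy: str
    compartment: str
    feature_class: str
    contig: str | None = None
    midpoint: float | None = None

    @property
    def summary_class(self) -> str | None:
        return CLASS_LABELS.get(self.feature_class)


def enrichment_score(
    chip: CountMatrix,
    input_: CountMatrix,
    feature: str,
    policy: str,
    annotation: RepeatAnnotation | None = None,
) -> EnrichmentRecord:
    """E = RPM_chip / RPM_input for one feature (single-sample matrices).

    Both matrices must already be RPM-normalised from the same
    annotation.  When the annotation is supplied and the feature is a
    heterochromatic satellite locus, the unique-read policy is enforced.
    """
    for name, m in (("chip", chip), ("input", input_)):
        if m.units != "rpm_total":
            raise ValueError(f"{name} matrix must be RPM-normalised (units rpm_total)")
        if feature not in m.counts.index:
            raise KeyError(f"feature {feature!r} absent from {name} matrix")
    compartment = "euchromatic"
    feature_class = "other"
    contig = midpoint = None
    if annotation is not None and feature in {f.locus_id for f in annotation}:
        feat = annotation[feature]
        compartment, feature_class = feat.compartment, feat.feature_class
        contig, midpoint = feat.contig, feat.midpoint
        if feature_class == "satDNA" and compartment == "heterochromatic" and policy != "unique":
            raise ValueError(
                f"{feature}: heterochromatic satellite loci must be scored with the "
                f"unique-read policy, not {policy!r}"
            )
    rpm_chip = float(chip.counts[chip.samples[0]].at[feature])
    rpm_input = float(input_.counts[input_.samples[0]].at[feature])
    enr = rpm_chip / rpm_input if rpm_input > 0 else None
    return EnrichmentRecord(
        feature, rpm_chip, rpm_input, enr, policy, compartment, feature_class, contig, midpoint
    )


def enrichment_table(
    chip: CountMatrix,
    input_: CountMatrix,
    annotation: RepeatAnnotation,
    policy: str,
) -> list[EnrichmentRecord]:
    """Enrichment records for every annotated locus present in both
    matrices."""
    present = set(chip.counts.index) & set(input_.counts.index)
    return [
        enrichment_score(chip, input_, f.locus_id, policy, annotation)
        for f in annotation
        if f.locus_id in present
    ]


def euchromatic_control(
    gene_records: list[EnrichmentRecord],
    heterochromatin_boundaries: dict[str, list[int]],
    min_distance: int = 5_000_000,
) -> tuple[float | None, int]:
    """Median enrichment over genes whose midpoint is at least
    ``min_distance`` from every heterochromatin boundary on their contig.
    Returns (median or None when no gene qualifies, qualifying count)."""
    values = []
    for rec in gene_records:
        if rec.enrichment is None or rec.midpoint is None:
            continue
        boundaries = heterochromatin_boundaries.get(rec.contig, [])
        dist = min((abs(rec.midpoint - b) for b in boundaries), default=np.inf)
        if dist >= min_distance:
            values.append(rec.enrichment)
    if not values:
        return None, 0
    return float(np.median(values)), len(values)


def class_summary(records: list[EnrichmentRecord]) -> tuple[pd.DataFrame, list[diff.TestResult]]:
    """Per-class mean enrichment (satDNA / uni / dual / eu) with pairwise
    Welch t-tests, BH-adjusted across the comparisons."""
    groups: dict[str, list[float]] = {}
    for rec in records:
        cls = rec.summary_class
        if cls is None or rec.enrichment is None:
            continue
        if cls == "satDNA" and rec.compartment != "heterochromatic":
            continue  # euchromatic satellite insertions are excluded
        groups.setdefault(cls, []).append(rec.enrichment)
    summary = pd.DataFrame(
        {
            "class": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean_enrichment": [float(np.mean(v)) for v in groups.values()],
        }
    )
    tests = diff.group_ttests(groups, mode="pairwise") if len(groups) > 1 else []
    return summary, tests


def enrichment_change(
    control: list[EnrichmentRecord],
    knockdown: list[EnrichmentRecord],
) -> tuple[pd.DataFrame, list[diff.TestResult]]:
    """log2(E_knockdown / E_control) per matched feature, with per-class
    one-sample t-tests against zero (BH-adjusted).

    An undefined or zero enrichment on either side propagates as an
    undefined (NaN) change."""
    by_feature = {r.feature: r for r in control}
    rows = []
    for kd in knockdown:
        ctrl = by_feature.get(kd.feature)
        if ctrl is None:
            continue
        defined = (
            ctrl.enrichment is not None and kd.enrichment is not None
            and ctrl.enrichment > 0 and kd.enrichment > 0
        )
        rows.append(
            {
                "feature": kd.feature,
                "class": kd.summary_class,
                "enrichment_control": ctrl.enrichment,
                "enrichment_knockdown": kd.enrichment,
                "log2_change": float(np.log2(kd.enrichment / ctrl.enrichment))
                if defined
                else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    groups = {
        cls: grp["log2_change"].dropna().to_numpy()
        for cls, grp in frame.dropna(subset=["class"]).groupby("class")
    }
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    tests = diff.group_ttests(groups, mode="one_sample", mu=0.0) if groups else []
    return frame, tests
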