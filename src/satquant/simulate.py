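"""Synthetic genomes, reads, and ground truth for satellite-DNA analysis.

The generator emulates the statistical structure the downstream analysis
assumes: tandem satellite arrays whose transcript abundance is
proportional to genomic copy number, dual-strand non-polyadenylated
transcription, small-RNA pools with piRNA-like lengths (truncated normal,
peak 24-26 nt), 5' uridine bias, ping-pong responder pairs whose 5' ends
overlap by exactly 10 nt, ChIP libraries with per-feature enrichment over
a uniform input, regulatory knockdowns that deplete RDC-dependent loci
only, and qPCR Ct tables.  Every emitted read carries a truth record, so
each downstream stage can be verified against configured ground truth.

All randomness flows through :func:`satquant._rng.stream`: one generator
per operation, seeded from (global seed, operation name), so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dna
from ._rng import stream
from .annotation import Feature, RepeatAnnotation
from .repeats import ConsensusRepeat, default_consensus

#: regulatory class -> feature classes whose transcription it licenses
REGULATORY_CLASSES = {
    "rdc": ("satDNA", "piRNA_cluster_dual"),
}

READ_CATEGORIES = ("primary", "responder", "chip", "input", "transcript")


# --------------------------------------------------------------------- config


@dataclass(frozen=True)
class PirnaModel:
    """Small-RNA pool parameters.

    pingpong_fraction
        Fraction of reads that are ping-pong responders (5' end on the
        opposite strand exactly 10 nt into a primary read).
    u1_bias
        Probability that a primary read starts with uridine (T in DNA
        space).
    length_*
        Truncated-normal read-length model; defaults (mean 25, sd 1.5,
        bounds 23-28) reproduce the canonical piRNA size peak at 24-26 nt.
    """

    pingpong_fraction: float = 0.3
    u1_bias: float = 0.75
    length_mean: float = 25.0
    length_sd: float = 1.5
    length_min: int = 23
    length_max: int = 28

    def __post_init__(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise ValueError("; ".join(errs))

    def validation_errors(self) -> list[str]:
        errs = []
        if not 0.0 <= self.pingpong_fraction <= 1.0:
            errs.append(f"pingpong_fraction {self.pingpong_fraction} outside [0, 1]")
        if not 0.0 <= self.u1_bias <= 1.0:
            errs.append(f"u1_bias {self.u1_bias} outside [0, 1]")
        if not 18 <= self.length_min <= self.length_max <= 35:
            errs.append(
                f"length bounds [{self.length_min}, {self.length_max}] must be within [18, 35]"
            )
        if self.length_sd <= 0:
            errs.append("length_sd must be > 0")
        return errs


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus.

    For ``satDNA`` loci, ``family`` names a consensus in the config's
    consensus set and ``copies`` full repeat units are laid down in
    tandem.  For other classes, ``length`` bases of unique (background)
    sequence are annotated.  ``abundance`` is the locus's transcript
    abundance coefficient (relative sampling weight for expression-derived
    reads); ``chip_enrichment`` is the per-feature ChIP enrichment factor
    over a uniform input.
    """

    name: str
    family: str
    feature_class: str
    compartment: str
    copies: int = 0
    length: int = 0
    substitution_rate: float = 0.0
    abundance: float = 0.0
    chip_enrichment: float = 1.0
    strand_model: str = "dual"  # dual | plus | minus
    offset: int | None = None  # explicit placement; auto-placed when None

    def validation_errors(self) -> list[str]:
        errs = []
        if self.copies < 0:
            errs.append(f"{self.name}: copies must be >= 0")
        if not 0.0 <= self.substitution_rate < 1.0:
            errs.append(f"{self.name}: substitution_rate outside [0, 1)")
        if self.abundance < 0:
            errs.append(f"{self.name}: abundance must be >= 0")
        if self.chip_enrichment <= 0:
            errs.append(f"{self.name}: chip_enrichment must be > 0")
        if self.strand_model not in ("dual", "plus", "minus"):
            errs.append(f"{self.name}: unknown strand_model {self.strand_model!r}")
        if self.feature_class != "satDNA" and self.length <= 0:
            errs.append(f"{self.name}: non-satellite locus needs length > 0")
        return errs


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    background_length: int = 100_000
    loci: tuple[LocusSpec, ...] = ()
    consensus: dict[str, ConsensusRepeat] = field(default_factory=default_consensus)
    pirna: PirnaModel = field(default_factory=PirnaModel)
    chip_read_length: int = 50
    contig_name: str = "sim1"
    knockdown_applied: dict[str, float] = field(default_factory=dict)

    def validation_errors(self) -> list[str]:
        errs = []
        if self.background_length <= 0:
            errs.append("background_length must be > 0")
        if self.chip_read_length <= 0:
            errs.append("chip_read_length must be > 0")
        seen = set()
        for locus in self.loci:
            errs.extend(locus.validation_errors())
            if locus.name in seen:
                errs.append(f"duplicate locus name {locus.name!r}")
            seen.add(locus.name)
            if locus.feature_class == "satDNA" and locus.family not in self.consensus:
                errs.append(f"{locus.name}: no consensus for family {locus.family!r}")
        errs.extend(self.pirna.validation_errors())
        return errs

    def validate(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errs))


# ----------------------------------------------------------------- generators


def simulate_satellite_array(
    consensus: ConsensusRepeat,
    copies: int,
    substitution_rate: float,
    seed: int,
    stream_name: str = "satellite_array",
) -> tuple[str, list[tuple[int, int, str]]]:
    """Tandem array of ``copies`` mutated repeat units.

    Dimer families lay down Left then Right within each copy.  Mutations
    are substitutions only (always to a different base), so the per-copy
    truth intervals tile the array exactly.  Returns the array sequence
    and ``(start, end, copy_label)`` intervals, one per copy.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    unit = np.concatenate([dna.encode(seq) for _, seq in consensus.units])
    rng = stream(seed, stream_name)
    arr = np.tile(unit, copies)
    hit = np.nonzero(rng.random(arr.size) < substitution_rate)[0]
    if hit.size:
        idx = np.searchsorted(dna.BASES, arr[hit])
        arr[hit] = dna.BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    step = unit.size
    intervals = [(i * step, (i + 1) * step, f"copy{i}") for i in range(copies)]
    return dna.decode(arr), intervals


@dataclass
class SimulatedGenome:
    """A built genome: sequences, annotation, and per-locus truth."""

    config: SimulationConfig
    sequences: dict[str, str]
    annotation: RepeatAnnotation
    locus_truth: pd.DataFrame  # one row per locus: abundance, enrichment, coords

    @property
    def contig(self) -> str:
        return self.config.contig_name

    def genome_array(self) -> np.ndarray:
        return dna.encode(self.sequences[self.contig])


def build_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out background, satellite arrays, genes, miRNA loci, and piRNA
    clusters along one contig, and return sequences + GFF-ready annotation
    + a per-locus truth table.

    Auto-placed loci are separated by background gaps that split
    ``background_length`` evenly; loci with explicit offsets are placed
    there, and any overlap among them is reported as an error listing the
    collisions.
    """
    config.validate()
    seed = config.seed

    # realised length of every locus
    lengths: dict[str, int] = {}
    arrays: dict[str, str] = {}
    for locus in config.loci:
        if locus.feature_class == "satDNA":
            cons = config.consensus[locus.family]
            seq, _ = simulate_satellite_array(
                cons,
                locus.copies,
                locus.substitution_rate,
                seed,
                stream_name=f"satellite_array:{locus.name}",
            )
            arrays[locus.name] = seq
            lengths[locus.name] = len(seq)
        else:
            lengths[locus.name] = locus.length

    explicit = [l for l in config.loci if l.offset is not None]
    auto = [l for l in config.loci if l.offset is None]
    placed: dict[str, tuple[int, int]] = {}

    collisions = []
    spans = sorted(
        ((l.offset, l.offset + lengths[l.name], l.name) for l in explicit), key=lambda t: t[0]
    )
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if e1 > s2:
            collisions.append(f"{n1} [{s1}, {e1}) overlaps {n2} [{s2}, {e2})")
    if collisions:
        raise ValueError("unresolvable feature placements: " + "; ".join(collisions))
    for s, e, name in spans:
        placed[name] = (s, e)

    gap = config.background_length // (len(auto) + 1)
    remainder = config.background_length - gap * (len(auto) + 1)
    cursor = gap
    span_list = list(spans)
    for locus in auto:
        length = lengths[locus.name]
        moved = True
        while moved:
            moved = False
            for s, e, name in span_list:
                if cursor < e and s < cursor + length:
                    cursor = e + gap
                    moved = True
        placed[locus.name] = (cursor, cursor + length)
        cursor += length + gap
    cursor += remainder
    total = max([cursor] + [e for _, e in placed.values()])

    rng = stream(seed, "build_genome")
    genome = dna.random_bases(rng, total)
    for name, seq in arrays.items():
        s, e = placed[name]
        genome[s:e] = dna.encode(seq)

    features = []
    rows = []
    for locus in config.loci:
        s, e = placed[locus.name]
        cons = config.consensus.get(locus.family) if locus.feature_class == "satDNA" else None
        family = cons.family_name if cons else locus.family
        subfamily = cons.subfamily if cons else None
        strand = {"dual": ".", "plus": "+", "minus": "-"}[locus.strand_model]
        features.append(
            Feature(
                contig=config.contig_name,
                start=s,
                end=e,
                strand=strand,
                family=family,
                locus_id=locus.name,
                compartment=locus.compartment,
                feature_class=locus.feature_class,
                subfamily=subfamily,
            )
        )
        rows.append(
            {
                "locus_id": locus.name,
                "family": family,
                "subfamily": subfamily,
                "class": locus.feature_class,
                "compartment": locus.compartment,
                "contig": config.contig_name,
                "start": s,
                "end": e,
                "length": e - s,
                "copies": locus.copies,
                "abundance": locus.abundance,
                "chip_enrichment": locus.chip_enrichment,
                "strand_model": locus.strand_model,
            }
        )
    annotation = RepeatAnnotation(features, {config.contig_name: total})
    truth = pd.DataFrame(rows)
    return SimulatedGenome(config, {config.contig_name: dna.decode(genome)}, annotation, truth)


# ------------------------------------------------------------------ small RNA


def _sample_lengths(rng: np.random.Generator, n: int, model: PirnaModel) -> np.ndarray:
    """Integer lengths from the truncated normal, by rejection."""
    out = np.empty(n, dtype=np.int64)
    need = np.arange(n)
    while need.size:
        draw = np.rint(rng.normal(model.length_mean, model.length_sd, need.size)).astype(np.int64)
        ok = (draw >= model.length_min) & (draw <= model.length_max)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _extract(
    genome: np.ndarray, five_prime: np.ndarray, lengths: np.ndarray, minus: np.ndarray
) -> list[np.ndarray]:
    """Vectorised sequence extraction; reads are returned 5'->3'."""
    n = five_prime.size
    seqs: list[np.ndarray | None] = [None] * n
    lmax = int(lengths.max()) if n else 0
    for is_minus in (False, True):
        sel = np.nonzero(minus == is_minus)[0]
        if not sel.size:
            continue
        if is_minus:
            idx = five_prime[sel, None] - np.arange(lmax)
            mat = dna.complement_array(genome[np.clip(idx, 0, genome.size - 1)])
        else:
            idx = five_prime[sel, None] + np.arange(lmax)
            mat = genome[np.clip(idx, 0, genome.size - 1)]
        for k, i in enumerate(sel):
            seqs[i] = mat[k, : lengths[i]].copy()
    return seqs  # type: ignore[return-value]


def simulate_small_rna_reads(
    sim: SimulatedGenome,
    pirna: PirnaModel | None = None,
    n_reads: int = 10_000,
    seed: int | None = None,
    stream_name: str = "small_rna",
) -> pd.DataFrame:
    """Simulate a small-RNA library; returns the truth table (one row per
    read) including sequences.

    Every read first samples its source locus with probability
    proportional to transcript abundance, so per-locus read counts track
    configured abundance exactly (knockdowns scale them multiplicatively).
    Reads at single-strand loci, and a fraction ``1 - pingpong_fraction``
    of reads at dual-strand loci, are primaries: strand from the locus
    strand model, 5' position uniform within the locus, 5' base uridine
    with probability ``u1_bias``.  The remaining dual-strand reads are
    ping-pong responders: each is paired to a primary template drawn from
    the same model at the same locus, placed on the opposite strand so the
    pair's 5' ends overlap by exactly 10 nt, with position 10 complementary
    to the template's first base.  The template's coordinates are recorded
    in the truth table.
    """
    pirna = pirna or sim.config.pirna
    seed = sim.config.seed if seed is None else seed
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    cols = [
        "read_id",
        "locus_id",
        "contig",
        "strand",
        "five_prime",
        "start",
        "end",
        "length",
        "category",
        "template_five_prime",
        "template_strand",
        "sequence",
    ]
    if n_reads == 0:
        return pd.DataFrame(columns=cols)

    rng = stream(seed, stream_name)
    truth = sim.locus_truth
    expressed = truth[(truth["abundance"] > 0) & (truth["length"] >= pirna.length_max + 12)]
    if expressed.empty:
        raise ValueError("no expressed locus is long enough to emit reads")
    weights = expressed["abundance"].to_numpy(float)
    weights = weights / weights.sum()
    starts = expressed["start"].to_numpy(np.int64)
    ends = expressed["end"].to_numpy(np.int64)
    strand_models = expressed["strand_model"].to_numpy()
    locus_ids = expressed["locus_id"].to_numpy()
    genome = sim.genome_array()

    if pirna.pingpong_fraction > 0 and not (strand_models == "dual").any():
        raise ValueError(
            "pingpong_fraction > 0 but no dual-strand locus can provide primary templates"
        )

    n = n_reads
    li = rng.choice(weights.size, size=n, p=weights)
    is_dual = strand_models[li] == "dual"
    resp = is_dual & (rng.random(n) < pirna.pingpong_fraction)

    read_len = _sample_lengths(rng, n, pirna)
    tpl_len = _sample_lengths(rng, n, pirna)  # responders' template length
    anchor_len = np.where(resp, tpl_len, read_len)

    # place the anchor (the read itself for primaries; the template for
    # responders) fully inside the locus, capping the plus-strand 5' so a
    # paired responder 5' (p + 9) also lands inside the locus
    tpl_minus = np.where(is_dual, rng.random(n) < 0.5, strand_models[li] == "minus")
    lo = np.where(tpl_minus, starts[li] + anchor_len - 1, starts[li])
    hi = np.where(tpl_minus, ends[li] - 1, ends[li] - np.maximum(anchor_len, 10))
    tpl_fp = lo + (rng.random(n) * (hi - lo + 1)).astype(np.int64)

    # 5' base of every primary/template: U (T) with probability u1_bias,
    # otherwise uniform over the other three bases
    u1 = rng.random(n) < pirna.u1_bias
    alt = dna.BASES[[0, 1, 2]][rng.integers(0, 3, size=n)]
    first = np.where(u1, np.uint8(ord("T")), alt).astype(np.uint8)

    # responders pair with a primary actually emitted at their locus, so
    # the 10-nt-overlap partner exists in the library; the independent
    # virtual draw above remains only when the locus emitted no primary
    # (e.g. pingpong_fraction = 1)
    resp_idx = np.nonzero(resp)[0]
    for locus in np.unique(li[resp_idx]) if resp_idx.size else []:
        r_sel = resp_idx[li[resp_idx] == locus]
        p_sel = np.nonzero(~resp & (li == locus))[0]
        if p_sel.size:
            j = p_sel[rng.integers(0, p_sel.size, size=r_sel.size)]
            tpl_fp[r_sel] = tpl_fp[j]
            tpl_minus[r_sel] = tpl_minus[j]
            first[r_sel] = first[j]
    comp_first = dna.complement_array(first)

    # ping-pong geometry: plus template 5' at p -> minus responder 5' at
    # p + 9 (overlap q - p + 1 = 10); mirrored for minus templates
    read_minus = np.where(resp, ~tpl_minus, tpl_minus)
    read_fp = np.where(resp, np.where(tpl_minus, tpl_fp - 9, tpl_fp + 9), tpl_fp)
    seqs = _extract(genome, read_fp, read_len, read_minus)
    for i in range(n):
        if resp[i]:
            seqs[i][9] = comp_first[i]
        else:
            seqs[i][0] = first[i]

    read_start = np.where(read_minus, read_fp - read_len + 1, read_fp)
    records = [
        {
            "read_id": f"sr{i:07d}",
            "locus_id": locus_ids[li[i]],
            "contig": sim.contig,
            "strand": "-" if read_minus[i] else "+",
            "five_prime": int(read_fp[i]),
            "start": int(read_start[i]),
            "end": int(read_start[i] + read_len[i]),
            "length": int(read_len[i]),
            "category": "responder" if resp[i] else "primary",
            "template_five_prime": int(tpl_fp[i]) if resp[i] else None,
            "template_strand": ("-" if tpl_minus[i] else "+") if resp[i] else None,
            "sequence": dna.decode(seqs[i]),
        }
        for i in range(n)
    ]
    frame = pd.DataFrame.from_records(records, columns=cols)
    frame["template_five_prime"] = frame["template_five_prime"].astype("Float64")
    return frame


# ----------------------------------------------------------------------- ChIP


def simulate_chip_reads(
    sim: SimulatedGenome,
    n_reads: int = 100_000,
    seed: int | None = None,
    read_length: int | None = None,
    stream_name: str = "chip",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a ChIP library and its matched no-antibody input.

    Input read 5' positions are uniform over the contig; ChIP 5' positions
    are drawn with per-segment probability proportional to length times
    the feature's enrichment factor (background segments have factor 1).
    Returns (chip, input) truth tables.
    """
    seed = sim.config.seed if seed is None else seed
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = read_length or sim.config.chip_read_length
    genome = sim.genome_array()
    G = genome.size
    truth = sim.locus_truth.sort_values("start")
    if (truth["chip_enrichment"] <= 0).any():
        raise ValueError("all chip enrichment factors must be > 0")

    # segments tile the contig: alternating background and features
    seg_start, seg_end, seg_e, seg_name = [], [], [], []
    cursor = 0
    for row in truth.itertuples():
        if row.start > cursor:
            seg_start.append(cursor)
            seg_end.append(row.start)
            seg_e.append(1.0)
            seg_name.append("background")
        seg_start.append(row.start)
        seg_end.append(row.end)
        seg_e.append(float(row.chip_enrichment))
        seg_name.append(row.locus_id)
        cursor = row.end
    if cursor < G:
        seg_start.append(cursor)
        seg_end.append(G)
        seg_e.append(1.0)
        seg_name.append("background")
    seg_start = np.array(seg_start)
    seg_end = np.array(seg_end)
    seg_len = seg_end - seg_start
    weights = seg_len * np.array(seg_e)
    weights = weights / weights.sum()

    rng = stream(seed, stream_name)

    def library(category: str, fp: np.ndarray, feature: np.ndarray) -> pd.DataFrame:
        n = fp.size
        minus = rng.random(n) < 0.5
        # clamp so the read body stays on the contig (5' position unchanged)
        fp = np.where(minus, np.maximum(fp, L - 1), np.minimum(fp, G - L))
        start = np.where(minus, fp - L + 1, fp)
        seqs = _extract(genome, fp, np.full(n, L, dtype=np.int64), minus)
        return pd.DataFrame(
            {
                "read_id": [f"{category[:2]}{i:07d}" for i in range(n)],
                "locus_id": feature,
                "contig": sim.contig,
                "strand": np.where(minus, "-", "+"),
                "five_prime": fp.astype(np.int64),
                "start": start.astype(np.int64),
                "end": (start + L).astype(np.int64),
                "length": L,
                "category": category,
                "sequence": [dna.decode(s) for s in seqs],
            }
        )

    si = rng.choice(weights.size, size=n_reads, p=weights)
    chip_fp = seg_start[si] + (rng.random(n_reads) * seg_len[si]).astype(np.int64)
    chip = library("chip", chip_fp, np.array(seg_name, dtype=object)[si])

    input_fp = rng.integers(0, G, size=n_reads)
    seg_of = np.searchsorted(seg_start, input_fp, side="right") - 1
    inp = library("input", input_fp, np.array(seg_name, dtype=object)[seg_of])
    return chip, inp


# ------------------------------------------------------------------ knockdown


def simulate_knockdown(
    config: SimulationConfig, class_factors: dict[str, float]
) -> SimulationConfig:
    """Apply regulatory knockdowns: multiply the abundance of loci in each
    regulatory class (``rdc`` covers satDNA and dual-strand clusters) by
    its factor; miRNA, uni-strand cluster, and gene abundances are
    untouched."""
    affected: dict[str, float] = {}
    for cls, factor in class_factors.items():
        if cls not in REGULATORY_CLASSES:
            raise ValueError(
                f"unknown regulatory class {cls!r}; known: {sorted(REGULATORY_CLASSES)}"
            )
        if not 0.0 < factor <= 1.0:
            raise ValueError(f"knockdown factor for {cls!r} must be in (0, 1]")
        for fclass in REGULATORY_CLASSES[cls]:
            affected[fclass] = affected.get(fclass, 1.0) * factor
    loci = tuple(
        replace(l, abundance=l.abundance * affected[l.feature_class])
        if l.feature_class in affected
        else l
        for l in config.loci
    )
    return replace(
        config, loci=loci, knockdown_applied={**config.knockdown_applied, **class_factors}
    )


# ----------------------------------------------------------------------- qPCR


def simulate_qpcr(
    quantities: dict[str, dict[str, float]],
    efficiency: float = 1.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
    intercept: float = 30.0,
    stream_name: str = "qpcr",
) -> pd.DataFrame:
    """Simulate Ct values for a {sample: {target: quantity}} table.

    Ct = intercept - log2(quantity) / log2(1 + efficiency) + N(0, noise_sd),
    with ``replicates`` technical replicates per (sample, target).
    Reference loci (e.g. a tRNA for genomic DNA, RPS3 for expression) are
    simply targets whose quantity is constant across samples.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    rng = stream(seed, stream_name)
    rows = []
    base = np.log2(1.0 + efficiency)
    for sample, targets in quantities.items():
        for target, quantity in targets.items():
            if quantity <= 0:
                raise ValueError(f"{sample}/{target}: quantity must be > 0")
            for rep in range(1, replicates + 1):
                ct = intercept - np.log2(quantity) / base
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append({"sample": sample, "target": target, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- presets


def demo_config(
    seed: int,
    rsp_copies: int = 25,
    s260_copies: int = 23,
    s359_copies: int = 17,
    background_length: int = 4_000_000,
    abundance_per_copy: float = 10.0,
) -> SimulationConfig:
    """A compact study-shaped configuration: heterochromatic Rsp and 1.688
    arrays, a small euchromatic Rsp insertion (the intronic-copies analog),
    one dual- and one uni-strand (flamenco-like) piRNA cluster, miRNA loci
    (normalizer), and euchromatic genes.  Satellite transcript abundance is
    proportional to copy number; per-class ChIP enrichment factors follow
    the dual > satDNA > uni ~ euchromatin regime.  The background dwarfs
    the annotated features, as in a real assembly, so that plain ChIP/input
    RPM ratios recover the configured enrichment factors."""
    loci = [
        LocusSpec(
            name="Rsp_het",
            family="Rsp",
            feature_class="satDNA",
            compartment="heterochromatic",
            copies=rsp_copies,
            substitution_rate=0.02,
            abundance=rsp_copies * abundance_per_copy,
            chip_enrichment=4.7,
            strand_model="dual",
        ),
        LocusSpec(
            name="260bp_het",
            family="1.688_260bp",
            feature_class="satDNA",
            compartment="heterochromatic",
            copies=s260_copies,
            substitution_rate=0.02,
            abundance=s260_copies * abundance_per_copy,
            chip_enrichment=4.7,
            strand_model="dual",
        ),
        LocusSpec(
            name="359bp_het",
            family="1.688_359bp",
            feature_class="satDNA",
            compartment="heterochromatic",
            copies=s359_copies,
            substitution_rate=0.02,
            abundance=s359_copies * abundance_per_copy,
            chip_enrichment=4.7,
            strand_model="dual",
        ),
        LocusSpec(
            name="Rsp_eu",
            family="Rsp",
            feature_class="satDNA",
            compartment="euchromatic",
            copies=12,
            substitution_rate=0.02,
            abundance=12 * abundance_per_copy,
            chip_enrichment=1.0,
            strand_model="dual",
        ),
        LocusSpec(
            name="cluster_42AB",
            family="cluster_42AB",
            feature_class="piRNA_cluster_dual",
            compartment="heterochromatic",
            length=10_000,
            abundance=100.0,
            chip_enrichment=9.0,
            strand_model="dual",
        ),
        LocusSpec(
            name="cluster_80F",
            family="cluster_80F",
            feature_class="piRNA_cluster_dual",
            compartment="heterochromatic",
            length=10_000,
            abundance=100.0,
            chip_enrichment=9.0,
            strand_model="dual",
        ),
        LocusSpec(
            name="flamenco",
            family="flamenco",
            feature_class="piRNA_cluster_uni",
            compartment="heterochromatic",
            length=12_000,
            abundance=150.0,
            chip_enrichment=1.7,
            strand_model="plus",
        ),
        LocusSpec(
            name="cluster_20A",
            family="cluster_20A",
            feature_class="piRNA_cluster_uni",
            compartment="euchromatic",
            length=8_000,
            abundance=50.0,
            chip_enrichment=1.7,
            strand_model="plus",
        ),
    ]
    for i in range(3):
        loci.append(
            LocusSpec(
                name=f"mir{i + 1}",
                family="miRNA",
                feature_class="miRNA",
                compartment="euchromatic",
                length=200,
                abundance=100.0,
                chip_enrichment=1.0,
                strand_model="plus",
            )
        )
    for i in range(8):
        loci.append(
            LocusSpec(
                name=f"gene{i + 1}",
                family="gene",
                feature_class="gene",
                compartment="euchromatic",
                length=2_500,
                abundance=5.0,
                chip_enrichment=1.55,
                strand_model="plus",
            )
        )
    return SimulationConfig(seed=seed, background_length=background_length, loci=tuple(loci))


def single_locus_config(
    seed: int,
    family: str = "Rsp",
    copies: int = 25,
    pingpong_fraction: float = 0.6,
    background_length: int = 20_000,
) -> SimulationConfig:
    """One dual-strand heterochromatic satellite array and nothing else:
    the minimal setting for studying the ping-pong signature on a single
    locus."""
    locus = LocusSpec(
        name=f"{family}_locus",
        family=family,
        feature_class="satDNA",
        compartment="heterochromatic",
        copies=copies,
        substitution_rate=0.02,
        abundance=1.0,
        chip_enrichment=4.7,
        strand_model="dual",
    )
    return SimulationConfig(
        seed=seed,
        background_length=background_length,
        loci=(locus,),
        pirna=PirnaModel(pingpong_fraction=pingpong_fraction),
    )
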