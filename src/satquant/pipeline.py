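"""End-to-end orchestration: simulate -> count -> signatures -> profile ->
differential abundance -> ChIP enrichment, from a single YAML config.

Every stage writes plain TSV/FASTA/FASTQ/GFF with deterministic
formatting, and a JSON manifest records the config hash, seed, stage
outputs, and timestamps.  Re-running with the same config reproduces
every stage output byte for byte (the manifest's timestamps differ).
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, chip, counting, diff, io, profile, signatures, simulate

log = logging.getLogger("satquant")

_SCHEMA: dict[str, dict] = {
    "seed": {"required": True, "type": int},
    "simulation": {
        "background_length": {"type": int, "default": 4_000_000, "min": 1},
        "rsp_copies": {"type": int, "default": 25, "min": 0},
        "s260_copies": {"type": int, "default": 23, "min": 0},
        "s359_copies": {"type": int, "default": 17, "min": 0},
    },
    "reads": {
        "small_rna": {"type": int, "default": 20_000, "min": 0},
        "chip": {"type": int, "default": 50_000, "min": 0},
    },
    "knockdown": {
        "rdc": {"type": float, "default": 0.05, "min": 1e-9, "max": 1.0},
    },
    "pirna": {
        "pingpong_fraction": {"type": float, "default": 0.3, "min": 0.0, "max": 1.0},
        "u1_bias": {"type": float, "default": 0.75, "min": 0.0, "max": 1.0},
    },
    "counting": {
        "policy": {"type": str, "default": "fractional", "choices": counting.POLICIES},
    },
    "signatures": {
        "o_max": {"type": int, "default": 30, "min": 11},
        "weighting": {"type": str, "default": "reads", "choices": ("reads", "species")},
    },
    "profile": {
        "family": {"type": str, "default": "Rsp"},
        "min_identity": {"type": float, "default": 0.8, "min": 0.0, "max": 1.0},
        "max_reads": {"type": int, "default": 500, "min": 1},
    },
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("invalid pipeline config: " + "; ".join(errors))
        self.errors = errors


def validate_config(source: str | Path | dict | None) -> dict:
    """Validate and normalise a pipeline config (YAML path or dict).

    Defaults are filled in and recorded in the returned mapping; unknown
    keys, missing required keys, and out-of-range values are all
    collected and reported together.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    raw = copy.deepcopy(dict(raw or {}))  # never mutate the caller's config
    errors: list[str] = []
    out: dict = {}

    def check_value(path: str, spec: dict, value):
        if value is None:
            value = spec.get("default")
        want = spec["type"]
        if want is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if not isinstance(value, want):
            errors.append(f"{path}: expected {want.__name__}, got {value!r}")
            return value
        if "min" in spec and value < spec["min"]:
            errors.append(f"{path}: {value} below minimum {spec['min']}")
        if "max" in spec and value > spec["max"]:
            errors.append(f"{path}: {value} above maximum {spec['max']}")
        if "choices" in spec and value not in spec["choices"]:
            errors.append(f"{path}: {value!r} not one of {spec['choices']}")
        return value

    for key, spec in _SCHEMA.items():
        if "type" in spec:  # scalar
            if spec.get("required") and key not in raw:
                errors.append(f"{key}: required key missing")
                continue
            out[key] = check_value(key, spec, raw.pop(key, None))
        else:  # section
            section = raw.pop(key, {}) or {}
            if not isinstance(section, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            out[key] = {}
            for sub, subspec in spec.items():
                out[key][sub] = check_value(f"{key}.{sub}", subspec, section.pop(sub, None))
            for unknown in sorted(section):
                errors.append(f"{key}.{unknown}: unknown key")
    for unknown in sorted(raw):
        errors.append(f"{unknown}: unknown key")
    if errors:
        raise ConfigError(errors)
    return out


# ----------------------------------------------------------------------- run


def _write_counts(
    truth: pd.DataFrame, sim, policy: str, seed: int, sample: str, outdir: Path
) -> dict[str, counting.CountMatrix]:
    alignments = counting.alignments_from_truth(truth)
    alignments = counting.assign_multimappers(alignments, policy, seed=seed)
    out = {}
    for group_by in ("locus", "family"):
        matrix = counting.count_features(
            alignments, sim.annotation, group_by=group_by, sample=sample
        )
        matrix.meta["policy"] = policy
        matrix.to_tsv(outdir / f"counts_{sample}_{group_by}.tsv")
        out[group_by] = matrix
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    started = time.time()
    stages: list[dict] = []
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()

    def stage(name: str, outputs: list[str]):
        log.info("stage %-12s done (%.1fs elapsed)", name, time.time() - started)
        stages.append({"name": name, "outputs": sorted(outputs)})

    # ---- simulate
    sim_cfg = simulate.demo_config(
        seed,
        rsp_copies=cfg["simulation"]["rsp_copies"],
        s260_copies=cfg["simulation"]["s260_copies"],
        s359_copies=cfg["simulation"]["s359_copies"],
        background_length=cfg["simulation"]["background_length"],
    )
    pirna = simulate.PirnaModel(
        pingpong_fraction=cfg["pirna"]["pingpong_fraction"], u1_bias=cfg["pirna"]["u1_bias"]
    )
    sim_cfg = dataclasses.replace(sim_cfg, pirna=pirna)
    sim = simulate.build_genome(sim_cfg)
    io.write_fasta(sim.sequences, outdir / "genome.fasta")
    sim.annotation.to_gff(outdir / "annotation.gff3")
    io.write_table(sim.locus_truth, outdir / "locus_truth.tsv")

    kd_cfg = simulate.simulate_knockdown(sim_cfg, {"rdc": cfg["knockdown"]["rdc"]})
    kd_sim = simulate.build_genome(kd_cfg)  # same sequences; knocked-down abundances

    n_small = cfg["reads"]["small_rna"]
    libraries: dict[str, pd.DataFrame] = {
        "smallrna_control": simulate.simulate_small_rna_reads(
            sim, pirna, n_small, seed, stream_name="small_rna:control"
        ),
        "smallrna_mutant": simulate.simulate_small_rna_reads(
            kd_sim, pirna, n_small, seed, stream_name="small_rna:mutant"
        ),
    }
    chip_truth, input_truth = simulate.simulate_chip_reads(sim, cfg["reads"]["chip"], seed)
    libraries["chip"] = chip_truth
    libraries["chip_input"] = input_truth
    sim_outputs = ["genome.fasta", "annotation.gff3", "locus_truth.tsv"]
    for name, truth in libraries.items():
        io.write_fastq(zip(truth["read_id"], truth["sequence"]), outdir / f"{name}.fastq")
        io.write_truth(truth.drop(columns=["sequence"]), outdir / f"{name}.truth.tsv")
        sim_outputs += [f"{name}.fastq", f"{name}.truth.tsv"]
    stage("simulate", sim_outputs)

    # ---- count (alignments ingested from the truth placements)
    policy = cfg["counting"]["policy"]
    matrices = {
        name: _write_counts(truth, sim, policy, seed, name, outdir)
        for name, truth in libraries.items()
    }
    stage("count", [f"counts_{name}_{g}.tsv" for name in libraries for g in ("locus", "family")])

    # ---- signatures, per satellite family on the control library
    control = libraries["smallrna_control"]
    sat_loci = sim.locus_truth[sim.locus_truth["class"] == "satDNA"]
    sig_rows = []
    for family, group in sat_loci.groupby("family"):
        reads = signatures.SmallRNASet.from_truth(
            control[control["locus_id"].isin(group["locus_id"])]
        )
        if not len(reads):
            continue
        lengths = signatures.length_histogram(reads)
        bias = signatures.nucleotide_bias(reads)
        hist = signatures.pingpong_histogram(
            reads, o_max=cfg["signatures"]["o_max"], weighting=cfg["signatures"]["weighting"]
        )
        sig_rows.append(
            {
                "family": family,
                "n_reads": len(reads),
                "fraction_23_28": lengths.fraction_in_range,
                "modal_length": lengths.modal_length,
                "u1_fraction": bias.u1_fraction,
                "a10_fraction": bias.a10_fraction,
                "u1_or_a10_fraction": bias.u1_or_a10_fraction,
                "pingpong_z10": signatures.pingpong_zscore(hist),
            }
        )
    io.write_table(pd.DataFrame(sig_rows), outdir / "signatures.tsv")
    stage("signatures", ["signatures.tsv"])

    # ---- consensus profile for the configured family
    fam = cfg["profile"]["family"]
    cons_key = next(
        (k for k, c in sim_cfg.consensus.items() if c.family_name == fam or k == fam), None
    )
    prof_outputs = []
    if cons_key is not None:
        multimer = profile.build_multimer(sim_cfg.consensus[cons_key])
        fam_loci = sat_loci[sat_loci["family"] == sim_cfg.consensus[cons_key].family_name]
        reads = control[control["locus_id"].isin(fam_loci["locus_id"])]
        reads = reads.head(cfg["profile"]["max_reads"])
        hits = profile.align_to_consensus(
            list(zip(reads["read_id"], reads["sequence"])),
            multimer,
            min_identity=cfg["profile"]["min_identity"],
        )
        track = profile.pileup_profile(hits, multimer.folded_length, reference=fam)
        io.write_table(track.to_frame(), outdir / f"profile_{fam}.tsv")
        prof_outputs.append(f"profile_{fam}.tsv")
    stage("profile", prof_outputs)

    # ---- differential abundance (mutant vs control, both normalisers)
    panels = [
        diff.knockdown_panel(
            matrices["smallrna_control"]["family"],
            matrices["smallrna_mutant"]["family"],
            normalizer=norm,
        )
        for norm in ("mirna", "flamenco")
    ]
    io.write_table(pd.concat(panels, ignore_index=True), outdir / "fold_changes.tsv")
    stage("diff", ["fold_changes.tsv"])

    # ---- ChIP enrichment
    chip_rpm = counting.normalize(matrices["chip"]["locus"], "rpm_total")
    input_rpm = counting.normalize(matrices["chip_input"]["locus"], "rpm_total")
    records = chip.enrichment_table(chip_rpm, input_rpm, sim.annotation, policy="unique")
    enr = pd.DataFrame(
        {
            "feature": [r.feature for r in records],
            "rpm_chip": [r.rpm_chip for r in records],
            "rpm_input": [r.rpm_input for r in records],
            "enrichment": [r.enrichment for r in records],
            "class": [r.summary_class for r in records],
            "compartment": [r.compartment for r in records],
            "policy": [r.read_policy for r in records],
        }
    )
    io.write_table(enr, outdir / "enrichment.tsv")
    summary, tests = chip.class_summary(records)
    io.write_table(summary, outdir / "chip_class_means.tsv")
    io.write_table(
        pd.DataFrame([asdict(t) for t in tests]), outdir / "chip_class_tests.tsv"
    )
    stage("chip", ["enrichment.tsv", "chip_class_means.tsv", "chip_class_tests.tsv"])

    manifest = {
        "tool": "satquant",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": config_hash,
        "stages": stages,
        "started": started,
        "finished": time.time(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
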