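"""Consensus repeat units for complex satellite families.

A complex satellite is described by its consensus repeat unit(s): one
monomer for 1.688-type families (named after unit sizes, e.g. the 260-bp
subfamily on 2L or the 359-bp subfamily on the X), or a Left/Right pair of
closely related ~120-bp units for Responder (Rsp)-type dimers.

The shipped default consensus sequences are synthetic: they are generated
once from a fixed internal stream with the unit lengths and Left/Right
divergence of the real families, so downstream geometry (array tiling,
multimer construction, coordinate folding) is exercised realistically
without bundling genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna


@dataclass(frozen=True)
class ConsensusRepeat:
    """A satellite family's consensus unit(s).

    ``units`` is an ordered tuple of ``(unit_name, sequence)`` pairs: one
    unit for monomer families, exactly two (Left, Right) for dimer
    families.
    """

    family_name: str
    units: tuple[tuple[str, str], ...]
    unit_structure: str  # "monomer" | "dimer"
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if self.unit_structure not in ("monomer", "dimer"):
            raise ValueError(f"unknown unit_structure {self.unit_structure!r}")
        want = 2 if self.unit_structure == "dimer" else 1
        if len(self.units) != want:
            raise ValueError(
                f"{self.unit_structure} family {self.family_name!r} must have "
                f"{want} unit(s), got {len(self.units)}"
            )
        for name, seq in self.units:
            dna.validate_acgt(seq, what=f"unit {name!r} of {self.family_name!r}")

    @property
    def label(self) -> str:
        """Family label, with the subfamily suffixed when present."""
        return self.family_name if self.subfamily is None else f"{self.family_name}_{self.subfamily}"

    @property
    def unit_length(self) -> int:
        """Length of one full copy (both units for a dimer)."""
        return sum(len(seq) for _, seq in self.units)


def _mutated(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(out.size) < rate)[0]
    if hit.size:
        idx = np.searchsorted(dna.BASES, out[hit])
        out[hit] = dna.BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return out


def default_consensus(internal_seed: int = 62375) -> dict[str, ConsensusRepeat]:
    """Synthetic consensus set: an Rsp-like dimer and four 1.688-like monomers.

    Unit lengths follow the field's naming (120+120 for the dimer;
    260/353/356/359 for the monomer subfamilies).  The Right dimer unit is
    the Left unit diverged by ~10% substitutions, mirroring the two closely
    related halves of a real dimer.
    """
    rng = np.random.default_rng(internal_seed)
    left = dna.random_bases(rng, 120)
    right = _mutated(left, 0.10, rng)
    out: dict[str, ConsensusRepeat] = {
        "Rsp": ConsensusRepeat(
            family_name="Rsp",
            units=(("Left", dna.decode(left)), ("Right", dna.decode(right))),
            unit_structure="dimer",
        )
    }
    base359 = dna.random_bases(rng, 359)
    for size in (260, 353, 356, 359):
        seq = _mutated(base359[:size], 0.15, rng)
        name = f"{size}bp"
        out[f"1.688_{name}"] = ConsensusRepeat(
            family_name="1.688",
            units=((name, dna.decode(seq)),),
            unit_structure="monomer",
            subfamily=name,
        )
    return out
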