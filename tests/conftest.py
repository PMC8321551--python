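import numpy as np
import pytest

from satquant import counting, simulate
from satquant.annotation import Feature, RepeatAnnotation


@pytest.fixture(scope="session")
def demo_sim():
    """One study-shaped simulated genome shared across tests."""
    return simulate.build_genome(simulate.demo_config(123))


@pytest.fixture(scope="session")
def rsp_consensus():
    return simulate.default_consensus()["Rsp"]


@pytest.fixture(scope="session")
def mono_consensus():
    return simulate.default_consensus()["1.688_359bp"]


@pytest.fixture
def toy_annotation():
    """Two loci on a 10 kb contig, with a gap between and around them."""
    features = [
        Feature("chrT", 1000, 4000, ".", "Rsp", "locusA", "heterochromatic", "satDNA"),
        Feature("chrT", 5000, 7500, "+", "gene", "locusB", "euchromatic", "gene"),
    ]
    return RepeatAnnotation(features, {"chrT": 10_000})


def make_alignment(read_id, hits, length=25):
    """Shorthand for a WeightedAlignment from (contig, five_prime, strand,
    mismatches) tuples."""
    return counting.WeightedAlignment(
        read_id=read_id,
        length=length,
        best_hits=[counting.Hit(*h) for h in hits],
    )


@pytest.fixture
def random_toy_case():
    """Factory for randomized toy annotations + alignment sets used by the
    conservation checks."""

    def build(seed):
        rng = np.random.default_rng(seed)
        contig_len = int(rng.integers(2_000, 10_000))
        n_feat = int(rng.integers(1, 6))
        bounds = np.sort(rng.choice(contig_len, size=2 * n_feat, replace=False))
        features = [
            Feature(
                "chrR",
                int(bounds[2 * i]),
                int(bounds[2 * i + 1]),
                ".",
                f"fam{i}",
                f"locus{i}",
                "heterochromatic",
                "satDNA",
            )
            for i in range(n_feat)
            if bounds[2 * i] < bounds[2 * i + 1]
        ]
        annotation = RepeatAnnotation(features, {"chrR": contig_len})
        alignments = []
        for r in range(int(rng.integers(20, 200))):
            n_best = int(rng.integers(1, 5))
            hits = [
                (
                    "chrR",
                    int(rng.integers(0, contig_len)),
                    "+" if rng.random() < 0.5 else "-",
                    0,
                )
                for _ in range(n_best)
            ]
            alignments.append(make_alignment(f"r{r}", hits))
        return annotation, alignments

    return build
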