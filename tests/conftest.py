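"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from clipsplice import crosslink, synthetic_data


@pytest.fixture(scope="session")
def u6_reference() -> tuple[str, str]:
    """A 106-nt synthetic snRNA-like reference (stand-in for U6)."""
    rng = np.random.default_rng(106)
    return "U6", "".join(rng.choice(list("ACGT"), size=106))


@pytest.fixture(scope="session")
def peaked_profile() -> np.ndarray:
    """Binding profile with a strong peak around the internal stem-loop
    region and background elsewhere; zero mass on the final nucleotide."""
    prof = np.ones(106)
    prof[40:48] += 30.0
    prof[60:68] += 15.0
    prof[-1] = 0.0
    return prof / prof.sum()


@pytest.fixture(scope="session")
def u6_truth(u6_reference, peaked_profile) -> synthetic_data.SimulationTruth:
    name, seq = u6_reference
    return synthetic_data.SimulationTruth(
        seed=421,
        references=[(name, seq)],
        binding_profile={name: peaked_profile},
        deletion_sites={name: [63, 64]},
        deletion_prob=0.043,
        read_length=30,
        n_reads_per_sample=50_000,
        samples=[("rep1", "case"), ("rep2", "control")],
    )


@pytest.fixture(scope="session")
def u6_clip(u6_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("u6clip")
    return synthetic_data.simulate_clip_reads(u6_truth, out)


@pytest.fixture(scope="session")
def u6_library(u6_clip) -> crosslink.SamLibrary:
    return crosslink.load_sam(u6_clip.sam_paths["rep1"])


@pytest.fixture(scope="session")
def toy_annotation():
    return synthetic_data.simulate_annotation(
        n_genes=6, exons_per_gene=4, planted_cryptic=3, seed=77
    )


@pytest.fixture(scope="session")
def donor_sets():
    """Consensus-like donor training signal (fixed GT at the intron start)
    plus uniform decoys."""
    info = [0.5, 0.5, 1.0, 2.0, 2.0, 1.2, 1.0, 0.8, 0.5]
    return synthetic_data.simulate_splice_site_sets(
        info, n_signal=800, n_decoy=800, seed=9, consensus="CAGGTAAGT"
    )
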