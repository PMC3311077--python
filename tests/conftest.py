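"""Shared fixtures: small seeded simulations reused across test modules."""
import pytest

import wgpmap as w
from wgpmap.assembly import AssemblyParams, Fingerprint


@pytest.fixture(scope="session")
def unique_genome():
    """Repeat-free 1 Mb genome: tags are unique, provenance is unambiguous."""
    return w.simulate_genome(1_000_000, 0.0, seed=101)


@pytest.fixture(scope="session")
def tiling_library(unique_genome):
    """~6x tiling of the unique genome with 30-kb clones, plus digests."""
    clones = w.simulate_bac_library(
        unique_genome, 200, mean_insert=30_000, sd_insert=3_000, seed=102
    )
    tags = w.clone_tags(clones)
    return clones, tags


@pytest.fixture(scope="session")
def tiling_fingerprints(tiling_library):
    clones, tags = tiling_library
    return [
        Fingerprint.wgp(cid, {t.tag_sequence for t in tags[cid]})
        for cid in sorted(tags)
    ]


@pytest.fixture()
def wgp_params():
    return AssemblyParams()
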