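"""Shared fixtures: tiny hand-built reference sets and a simulated database."""

import pytest

from wildmeat.seq_io import Alignment, ReferenceDB, Sequence
from wildmeat.synthetic_data import SimConfig, simulate_reference_db


def make_db(marker: str, species_seqs: dict[str, list[str]]) -> ReferenceDB:
    """ReferenceDB from {species: [residue strings]} for one marker."""
    seqs = [
        Sequence(id=f"{sp.replace(' ', '_')}_{i}", residues=r, species=sp,
                 marker=marker)
        for sp, rs in species_seqs.items()
        for i, r in enumerate(rs)
    ]
    return ReferenceDB({marker: Alignment(seqs)})


def _mutate(base: str, positions: list[int]) -> str:
    """Apply A->G transitions at the given positions of ``base``."""
    chars = list(base)
    for j in positions:
        assert chars[j] == "A"
        chars[j] = "G"
    return "".join(chars)


@pytest.fixture
def two_species_db() -> ReferenceDB:
    """Two species 12% apart with ~1% within-species diversity, 100 columns."""
    base = "ACGT" * 25
    beta_base = _mutate(base, [4 * k for k in range(1, 13)])
    return make_db("cytb", {
        "Alpha ferox": [base, _mutate(base, [0])],
        "Beta mitis": [beta_base, _mutate(beta_base, [52])],
    })


@pytest.fixture(scope="session")
def deep_split_db():
    """Simulated 5-species reference set in the deep-barcode-gap regime."""
    cfg = SimConfig(
        n_species=5, n_refs_per_species=4, within_theta=0.004,
        species_tree_depth=0.15, seed=11,
    )
    db, tree, pops = simulate_reference_db(cfg)
    return cfg, db, tree, pops
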