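"""Shared fixtures: a small synthetic dikaryon and the 15-family pairing
fixture (allele pairs + decoys + one planted within-haplotype duplicate)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dikarase import simulate as S

from .helpers import mutate_protein, random_protein


@dataclass
class Dikaryon:
    config: S.SimConfig
    contigs1: dict
    models1: list
    contigs2: dict
    models2: list
    truth: S.TruthSet


def make_dikaryon(config: S.SimConfig) -> Dikaryon:
    contigs1, models1 = S.build_gene_models(config)
    contigs2, models2, truth = S.diverge_haplotypes(contigs1, models1, config)
    return Dikaryon(config, contigs1, models1, contigs2, models2, truth)


@pytest.fixture(scope="session")
def small_config() -> S.SimConfig:
    return S.SimConfig(
        n_families=3,
        n_conditions=4,
        depth_per_gene=80.0,
        seed=11,
        cds_len_range=(600, 900),
        n_introns_range=(0, 4),
        promoter_len=600,
    )


@pytest.fixture(scope="session")
def dikaryon(small_config) -> Dikaryon:
    return make_dikaryon(small_config)


@pytest.fixture(scope="session")
def pairing_fixture():
    """15 allelic protein pairs (97-99.9% identity) + 5 decoys (<90%) +
    one within-haplotype duplicate at similarity >= 92%, coverage >= 80%."""
    cfg = S.SimConfig(
        n_families=15,
        seed=23,
        cds_len_range=(900, 1500),
        n_introns_range=(0, 3),
        promoter_len=300,
        snp_rate_coding=0.005,
    )
    d = make_dikaryon(cfg)
    prot1 = S.proteins_from_models(d.contigs1, d.models1, "H1_")
    prot2 = S.proteins_from_models(d.contigs2, d.models2, "H2_")
    rng = np.random.default_rng(99)
    decoys = {
        f"H2_decoy{i}": random_protein(int(rng.integers(300, 500)), rng)
        for i in range(5)
    }
    prot2_with_decoys = {**prot2, **decoys}
    # duplicate of family 1 inside haplotype 1, ~5% diverged, full length
    dup = mutate_protein(prot1["H1_lac01"], 0.05, rng)
    prot1_with_dup = {**prot1, "H1_lac01d": dup}
    return {
        "prot1": prot1,
        "prot2": prot2,
        "prot1_dup": prot1_with_dup,
        "prot2_decoys": prot2_with_decoys,
        "dikaryon": d,
    }
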