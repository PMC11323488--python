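"""Shared fixtures: small deterministic genomes and populations."""

from __future__ import annotations

import numpy as np
import pytest

import anigap as ag

BASES = np.array(list("ACGT"))


def random_genome(rng: np.random.Generator, length: int, gid: str = "g") -> ag.GenomeSeq:
    return ag.GenomeSeq(id=gid, seq="".join(rng.choice(BASES, size=length)))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n_subs substitutions at distinct uniform sites."""
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_subs, replace=False):
        old = arr[pos]
        arr[pos] = rng.choice([b for b in "ACGT" if b != old])
    return "".join(arr)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240722)


@pytest.fixture(scope="session")
def small_population():
    """Mutation-only single-cluster population used across modules."""
    params = ag.SimParams(
        n_genomes=6, n_genes=8, gene_len_mean=600, gene_len_sd=80,
        core_ratio=100, mu=30, sd=5, seed=7,
    )
    return ag.simulate_population(params)


@pytest.fixture(scope="session")
def two_cluster_population():
    params = ag.planted_gap_params(seed=77, target_between_ani=98.8)
    return ag.simulate_population(params)
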