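import numpy as np
import pandas as pd
import pytest

from replichore.simulate import EvolutionParams, evolve_pair, generate_genome

ANCESTOR_N = 2000
ANCESTOR_LEN = 2_000_000


@pytest.fixture(scope="session")
def ancestor():
    """One shared 2000-gene ancestor genome (no sequences, fast to evolve)."""
    genome, _ = generate_genome(n_genes=ANCESTOR_N, genome_length=ANCESTOR_LEN,
                                seed=101, with_sequences=False)
    return genome


@pytest.fixture(scope="session")
def longitudinal_pair(ancestor):
    """A synthetic pair in the high-translocation (longitudinal) regime."""
    params = EvolutionParams(n_genes=ANCESTOR_N, genome_length=ANCESTOR_LEN,
                             crossing_fraction=0.45, symmetry_sd=0.02,
                             ortholog_loss=0.28, seed=202)
    return evolve_pair(ancestor, params)


@pytest.fixture(scope="session")
def small_sequenced_pair():
    """A small pair with protein sequences, for BBH-path tests."""
    genome, proteome = generate_genome(n_genes=40, genome_length=40_000, seed=7)
    params = EvolutionParams(n_genes=40, genome_length=40_000,
                             crossing_fraction=0.3, ortholog_loss=0.2, seed=8)
    pair = evolve_pair(genome, params, proteome=proteome)
    return genome, proteome, pair


def make_pair_frame(d_a, d_b, repl_a, repl_b, lead_a=None, lead_b=None):
    """Assemble an annotated ortholog-pair table directly from arrays.

    Bins are derived from (d, replichore) the same way an oriC-anchored
    genome with antipodal ter would assign them: d < 0.25 is O, d > 0.75 is
    T, and the middle half belongs to the gene's replichore bin.
    """
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    n = len(d_a)
    repl_a = np.asarray(repl_a)
    repl_b = np.asarray(repl_b)
    lead_a = np.ones(n, dtype=bool) if lead_a is None else np.asarray(lead_a, dtype=bool)
    lead_b = np.ones(n, dtype=bool) if lead_b is None else np.asarray(lead_b, dtype=bool)

    def bins(d, repl):
        return np.where(d < 0.25, "O", np.where(d > 0.75, "T", repl))

    return pd.DataFrame({
        "gene_a": [f"a{i}" for i in range(n)],
        "gene_b": [f"b{i}" for i in range(n)],
        "mid_a": d_a, "mid_b": d_b,
        "d_a": d_a, "d_b": d_b,
        "repl_a": repl_a, "repl_b": repl_b,
        "bin_a": bins(d_a, repl_a), "bin_b": bins(d_b, repl_b),
        "strand_a": np.where(lead_a == (repl_a == "R"), "+", "-"),
        "strand_b": np.where(lead_b == (repl_b == "R"), "+", "-"),
        "lead_a": lead_a, "lead_b": lead_b,
    })
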