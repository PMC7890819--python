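import numpy as np
import pandas as pd
import pytest

from marshcaz import synthgen


@pytest.fixture(scope="session")
def design() -> synthgen.StudyDesign:
    return synthgen.StudyDesign()


@pytest.fixture(scope="session")
def truth(design) -> synthgen.GroundTruth:
    return synthgen.make_ground_truth(design, n_families=12, seed=7)


@pytest.fixture(scope="session")
def proteome(design, truth) -> synthgen.ProteomeTables:
    return synthgen.generate_proteome(design, truth, n_proteins=80, seed=11)


@pytest.fixture(scope="session")
def community_tables(design, truth) -> synthgen.CommunityTables:
    return synthgen.generate_community(design, truth=truth, seed=13)


def random_proteins(rng: np.random.Generator, n: int, n_pep=(3, 8), pep_len=(5, 12)):
    """Toy protein database of concatenated tryptic peptides, unique sequences."""
    proteins, seen = [], set()
    i = 0
    while len(proteins) < n:
        n_p = int(rng.integers(*n_pep))
        peps = [
            "".join(rng.choice(list(synthgen.AMINO_POOL), size=int(rng.integers(*pep_len))))
            + ("K" if rng.random() < 0.5 else "R")
            for _ in range(n_p)
        ]
        seq = "".join(peps)
        if seq not in seen:
            seen.add(seq)
            proteins.append((f"p{i}", seq))
            i += 1
    return proteins
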