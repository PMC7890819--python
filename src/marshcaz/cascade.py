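"""Two-pass partitioned protein database search.

Searching many MS datasets against a multi-million-sequence ORF database
is intractable for a single search, so the database is split into
subsets and every dataset is first searched against every subset at high
stringency.  All proteins hit anywhere are pooled and dereplicated into
a compact "true hit" database, which each dataset is then searched
against once more at relaxed stringency; peptide-spectrum matches (PSMs)
are finally filtered on their expect score.  The trade-off is
sensitivity: a protein whose every peptide only reaches the relaxed
threshold never enters the true-hit database and is lost.

The search engine is pluggable; :func:`naive_engine` is a deterministic
digest-and-exact-match engine used for testing and synthetic runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from . import quant
from .errors import ParameterError, PipelineError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds for the partitioned two-pass search.

    ``first_pass_p``/``final_pass_p`` are applied to the engine's per-PSM
    significance value (with the naive engine, the surrogate expect
    score); ``psm_expect_max`` filters final-pass PSMs.
    """

    n_subsets: int = 21
    first_pass_p: float = 0.05
    final_pass_p: float = 0.1
    psm_expect_max: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.first_pass_p <= self.final_pass_p <= 1):
            raise ParameterError(
                "need 0 < first_pass_p <= final_pass_p <= 1, got "
                f"{self.first_pass_p}, {self.final_pass_p}"
            )
        if self.n_subsets < 1:
            raise ParameterError("n_subsets must be >= 1")
        if self.psm_expect_max <= 0:
            raise ParameterError("psm_expect_max must be > 0")


@dataclass(frozen=True)
class PsmRecord:
    dataset_id: str
    peptide: str
    protein_id: str
    expect: float
    charge: int = 2

    def __post_init__(self) -> None:
        if self.expect <= 0:
            raise ParameterError("expect must be > 0")
        if not self.peptide:
            raise ParameterError("peptide must be non-empty")


@dataclass(frozen=True)
class Dataset:
    """One MS acquisition: an id plus its observed peptide sequences."""

    id: str
    peptides: tuple[str, ...]


#: Engine contract: (datasets, database, p_threshold) -> PSM list, where
#: database is a list of (protein_id, sequence).  Output protein ids must
#: come from the database and relaxing p_threshold must never remove a PSM.
SearchEngine = Callable[[Sequence[Dataset], Sequence[tuple[str, str]], float], list[PsmRecord]]


def surrogate_expect(peptide: str) -> float:
    """Length-based surrogate expect score: min(1, 10**(3 - L))."""
    return min(1.0, 10.0 ** (3 - len(peptide)))


def naive_engine(
    datasets: Sequence[Dataset],
    database: Sequence[tuple[str, str]],
    p_threshold: float,
    *,
    digest_min_len: int = 1,
    digest_max_len: int = 100,
) -> list[PsmRecord]:
    """Digest-and-exact-match test engine.

    Each database protein is digested in silico (trypsin rule); a dataset
    peptide matches a protein when it equals one of its digest peptides
    (leucine and isoleucine distinct).  The PSM's expect is the length
    surrogate; a PSM is emitted when expect <= p_threshold.  Shared
    peptides match every containing protein.
    """
    pep_index: dict[str, list[str]] = {}
    for prot_id, seq in database:
        for pep in quant.digest(seq, min_len=digest_min_len, max_len=digest_max_len):
            pep_index.setdefault(pep, []).append(prot_id)
    psms: list[PsmRecord] = []
    for ds in datasets:
        for pep in ds.peptides:
            e = surrogate_expect(pep)
            if e > p_threshold:
                continue
            for prot_id in pep_index.get(pep, ()):
                psms.append(PsmRecord(ds.id, pep, prot_id, e))
    return psms


def partition_database(
    proteins: Sequence[tuple[str, str]], n_subsets: int, seed: int
) -> list[list[tuple[str, str]]]:
    """Split a protein database into near-equal disjoint subsets.

    Seeded shuffle then round-robin assignment: subsets are disjoint,
    their union is the input, and sizes differ by at most one.
    """
    if n_subsets > len(proteins):
        raise ParameterError(
            f"cannot split {len(proteins)} proteins into {n_subsets} subsets"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    subsets: list[list[tuple[str, str]]] = [[] for _ in range(n_subsets)]
    for rank, idx in enumerate(order):
        subsets[rank % n_subsets].append(proteins[idx])
    return subsets


@dataclass
class FirstPassResult:
    truehit_db: list[tuple[str, str]]
    n_searches: int


def first_pass(
    engine: SearchEngine,
    datasets: Sequence[Dataset],
    subsets: Sequence[Sequence[tuple[str, str]]],
    config: SearchConfig,
) -> FirstPassResult:
    """High-stringency search of every dataset against every subset.

    The true-hit database is the exact-sequence-dereplicated union of all
    proteins hit at ``first_pass_p``.
    """
    hit_ids: set[str] = set()
    n_searches = 0
    for ds in datasets:
        for k, subset in enumerate(subsets):
            try:
                psms = engine([ds], subset, config.first_pass_p)
            except Exception as exc:  # noqa: BLE001 - engine is third-party code
                raise PipelineError(
                    f"first pass: engine failed on dataset {ds.id!r}, subset {k}: {exc}"
                ) from exc
            n_searches += 1
            hit_ids.update(p.protein_id for p in psms)
    pool = [(pid, seq) for subset in subsets for pid, seq in subset if pid in hit_ids]
    # minimal redundancy: exact-sequence dereplication of the hit pool
    seen: set[str] = set()
    truehit: list[tuple[str, str]] = []
    for pid, seq in pool:
        if seq not in seen:
            seen.add(seq)
            truehit.append((pid, seq))
    if not truehit:
        warnings.warn("first pass found no hits; true-hit database is empty", stacklevel=2)
    return FirstPassResult(truehit_db=truehit, n_searches=n_searches)


@dataclass
class FinalPassResult:
    identified_proteins: list[str]
    psms: list[PsmRecord]


def final_pass(
    engine: SearchEngine,
    datasets: Sequence[Dataset],
    truehit_db: Sequence[tuple[str, str]],
    config: SearchConfig,
) -> FinalPassResult:
    """Relaxed search against the true-hit database plus PSM filtering.

    One engine run per dataset at ``final_pass_p``; PSMs with expect
    above ``psm_expect_max`` are discarded and a protein is identified
    when it retains at least one PSM.
    """
    if not truehit_db:
        raise ParameterError("true-hit database is empty")
    kept: list[PsmRecord] = []
    for ds in datasets:
        try:
            psms = engine([ds], truehit_db, config.final_pass_p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"final pass: engine failed on dataset {ds.id!r}: {exc}"
            ) from exc
        kept.extend(p for p in psms if p.expect <= config.psm_expect_max)
    identified = sorted({p.protein_id for p in kept})
    return FinalPassResult(identified_proteins=identified, psms=kept)


def run_cascade(
    engine: SearchEngine,
    datasets: Sequence[Dataset],
    database: Sequence[tuple[str, str]],
    config: SearchConfig,
) -> tuple[FirstPassResult, FinalPassResult]:
    """Partition -> first pass -> final pass, end to end."""
    subsets = partition_database(database, config.n_subsets, config.seed)
    fp = first_pass(engine, datasets, subsets, config)
    if not fp.truehit_db:
        return fp, FinalPassResult(identified_proteins=[], psms=[])
    return fp, final_pass(engine, datasets, fp.truehit_db, config)
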