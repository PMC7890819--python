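"""Partitioned two-pass search: partition algebra, search-count
arithmetic, PSM filtering boundaries, engine monotonicity, and the
cascade's sensitivity trade-off versus a single relaxed search."""

import numpy as np
import pytest

from marshcaz import cascade
from marshcaz.cascade import (
    Dataset,
    FinalPassResult,
    SearchConfig,
    final_pass,
    first_pass,
    naive_engine,
    partition_database,
    run_cascade,
    surrogate_expect,
)
from marshcaz.errors import ParameterError, PipelineError
from marshcaz.quant import digest
from tests.conftest import random_proteins


def single_pass(datasets, database, config):
    """Oracle: one relaxed search of the whole database plus PSM filter."""
    psms = [p for p in naive_engine(datasets, database, config.final_pass_p)
            if p.expect <= config.psm_expect_max]
    return sorted({p.protein_id for p in psms})


def make_datasets(rng, proteins, n_datasets=3, frac=0.5, min_pep_len=5):
    """Sample dataset peptides from protein digests (>= min_pep_len only,
    so every matched PSM also clears first-pass stringency)."""
    out = []
    for d in range(n_datasets):
        peps = []
        for _, seq in proteins:
            for pep in digest(seq, min_len=min_pep_len, max_len=100):
                if rng.random() < frac:
                    peps.append(pep)
        out.append(Dataset(f"d{d}", tuple(sorted(set(peps)))))
    return out


class TestSearchConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ParameterError):
            SearchConfig(first_pass_p=0.2, final_pass_p=0.1)
        with pytest.raises(ParameterError):
            SearchConfig(n_subsets=0)


class TestPartitionDatabase:
    def test_exact_division(self):
        subsets = partition_database([(f"p{i}", "AK") for i in range(42)], 21, seed=0)
        assert len(subsets) == 21 and all(len(s) == 2 for s in subsets)

    def test_remainder_spread(self):
        subsets = partition_database([(f"p{i}", "AK") for i in range(43)], 21, seed=0)
        sizes = sorted(len(s) for s in subsets)
        assert sizes == [2] * 20 + [3]

    def test_union_and_disjointness(self):
        rng = np.random.default_rng(1)
        proteins = [(f"p{i}", f"s{i}") for i in range(1000)]
        subsets = partition_database(proteins, 7, seed=5)
        ids = [pid for s in subsets for pid, _ in s]
        assert len(ids) == 1000 and set(ids) == {p for p, _ in proteins}

    def test_deterministic_given_seed(self):
        proteins = [(f"p{i}", f"s{i}") for i in range(50)]
        a = partition_database(proteins, 6, seed=3)
        b = partition_database(proteins, 6, seed=3)
        assert a == b

    def test_too_many_subsets_rejected(self):
        with pytest.raises(ParameterError):
            partition_database([("p", "AK")], 2, seed=0)


class TestNaiveEngine:
    def test_surrogate_expect_by_length(self):
        assert surrogate_expect("AAA") == 1.0           # never significant
        assert surrogate_expect("AAAAA") == pytest.approx(0.01)
        assert surrogate_expect("AAAA") == pytest.approx(0.1)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            proteins = random_proteins(rng, 8)
            datasets = make_datasets(rng, proteins, n_datasets=2, min_pep_len=4)
            strict = naive_engine(datasets, proteins, 0.05)
            relaxed = naive_engine(datasets, proteins, 0.1)
            assert set(map(str, strict)) <= set(map(str, relaxed))

    def test_hits_only_database_proteins(self):
        rng = np.random.default_rng(2)
        proteins = random_proteins(rng, 5)
        datasets = make_datasets(rng, proteins)
        psms = naive_engine(datasets, proteins, 0.1)
        assert {p.protein_id for p in psms} <= {pid for pid, _ in proteins}


class TestFirstPass:
    def test_search_count_is_datasets_times_subsets(self):
        rng = np.random.default_rng(4)
        proteins = random_proteins(rng, 42)
        datasets = make_datasets(rng, proteins, n_datasets=12)
        subsets = partition_database(proteins, 21, seed=0)
        res = first_pass(naive_engine, datasets, subsets, SearchConfig())
        assert res.n_searches == 12 * 21 == 252

    def test_no_hits_warns_and_returns_empty(self):
        proteins = [("p0", "AAAK" * 10)]
        datasets = [Dataset("d0", ("NOMATCHPEPK",))]
        with pytest.warns(UserWarning, match="no hits"):
            res = first_pass(naive_engine, datasets, [proteins], SearchConfig())
        assert res.truehit_db == []

    def test_duplicate_sequences_collapse_in_truehit(self):
        seq = "AAAAAGK" + "CCCCCDR"
        proteins = [("p0", seq), ("p1", seq), ("p2", seq)]
        subsets = [[proteins[0]], [proteins[1]], [proteins[2]]]
        datasets = [Dataset("d0", ("AAAAAGK",))]
        res = first_pass(naive_engine, datasets, subsets,
                         SearchConfig(n_subsets=3))
        assert len(res.truehit_db) == 1

    def test_engine_failure_names_dataset_and_subset(self):
        def broken(datasets, database, p):
            raise RuntimeError("boom")

        with pytest.raises(PipelineError, match=r"dataset 'd0', subset 0"):
            first_pass(broken, [Dataset("d0", ())], [[("p", "AK")]], SearchConfig())


class TestFinalPass:
    def test_expect_filter_boundary_inclusive(self):
        # expect 0.1 ("0.1 or better") retained; anything above discarded
        prot = [("p0", "AAAACGK")]  # peptide AAAACGK (len 7, expect 1e-4)
        boundary = [("p1", "TTTR")]  # len-4 peptide, expect exactly 0.1
        db = prot + boundary
        datasets = [Dataset("d0", ("AAAACGK", "TTTR"))]
        res = final_pass(naive_engine, datasets, db, SearchConfig())
        assert set(res.identified_proteins) == {"p0", "p1"}
        res2 = final_pass(naive_engine, datasets, db,
                          SearchConfig(psm_expect_max=0.0999999))
        assert set(res2.identified_proteins) == {"p0"}

    def test_no_datasets_empty_result(self):
        res = final_pass(naive_engine, [], [("p", "AAAACGK")], SearchConfig())
        assert res.identified_proteins == [] and res.psms == []

    def test_empty_truehit_rejected(self):
        with pytest.raises(ParameterError):
            final_pass(naive_engine, [], [], SearchConfig())

    def test_toy_database_identifies_exactly_matching_proteins(self):
        rng = np.random.default_rng(7)
        proteins = random_proteins(rng, 10)
        matched = proteins[:4]
        datasets = [Dataset("d0", tuple(
            sorted({pep for _, s in matched for pep in digest(s, min_len=5, max_len=100)})))]
        res = final_pass(naive_engine, datasets, proteins, SearchConfig())
        assert set(res.identified_proteins) == {pid for pid, _ in matched}


class TestCascadeEquivalence:
    def test_agrees_with_single_pass_under_sufficiency(self):
        # Whenever every identifiable protein has >= 1 first-pass-strength
        # PSM, the partitioned cascade and a single relaxed search agree.
        for seed in range(25):
            rng = np.random.default_rng(seed)
            proteins = random_proteins(rng, int(rng.integers(10, 60)))
            datasets = make_datasets(rng, proteins, n_datasets=3,
                                     frac=0.4, min_pep_len=5)
            config = SearchConfig(n_subsets=min(5, len(proteins)), seed=seed)
            _, final = run_cascade(naive_engine, datasets, proteins, config)
            assert final.identified_proteins == single_pass(datasets, proteins, config)

    def test_counterexample_protein_is_missed_by_cascade(self):
        # A protein whose every matched peptide sits between the two
        # thresholds (expect 0.1: length 4) is identified by the single
        # relaxed search but never enters the true-hit database.
        weak = ("weak", "AAAR" + "CCCK")          # only length-4 peptides
        strong = ("strong", "DDDDDFK" + "EEEEEGR")  # length-7 peptides
        db = [weak, strong]
        datasets = [Dataset("d0", ("AAAR", "CCCK", "DDDDDFK"))]
        config = SearchConfig(n_subsets=2, seed=0)
        _, final = run_cascade(naive_engine, datasets, db, config)
        assert "weak" not in final.identified_proteins
        assert "strong" in final.identified_proteins
        assert "weak" in single_pass(datasets, db, config)

    def test_identified_subset_chain(self):
        rng = np.random.default_rng(11)
        proteins = random_proteins(rng, 30)
        datasets = make_datasets(rng, proteins, frac=0.3)
        fp, final = run_cascade(naive_engine, datasets, proteins,
                                SearchConfig(n_subsets=5, seed=1))
        truehit_ids = {pid for pid, _ in fp.truehit_db}
        db_ids = {pid for pid, _ in proteins}
        assert truehit_ids <= db_ids
        assert set(final.identified_proteins) <= truehit_ids
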