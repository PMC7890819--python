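"""Generator structure: design arithmetic, determinism, ground-truth
invariants and closed-form biomass behaviour."""

import hashlib
import io

import numpy as np
import pandas as pd
import pytest

from marshcaz import synthgen
from marshcaz.errors import ParameterError


class TestStudyDesign:
    def test_default_design_arithmetic(self, design):
        # 5 cages x 9 weeks + day-0 outgroup; 4 proteome weeks x 3 replicates
        assert design.n_samples == 46
        assert design.n_proteome_datasets == 12
        assert len(design.sample_ids()) == 46
        assert len(design.dataset_weeks()) == 12

    def test_sample_count_formula(self):
        d = synthgen.StudyDesign(cages=3, sample_weeks=(1, 2), proteome_weeks=(1,),
                                 proteome_replicates=2, include_day0_outgroup=False)
        assert d.n_samples == 3 * 2
        assert d.n_proteome_datasets == 2

    def test_proteome_weeks_must_be_subset(self):
        with pytest.raises(ParameterError):
            synthgen.StudyDesign(sample_weeks=(1, 2), proteome_weeks=(3,))

    def test_counts_must_be_positive(self):
        with pytest.raises(ParameterError):
            synthgen.StudyDesign(cages=0)


class TestGroundTruth:
    def test_fractions_sum_to_one_each_week(self, truth):
        assert np.allclose(truth.expected_fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_propensities_nonnegative_and_planted_boosted(self, truth):
        assert (truth.secretion_propensity >= 0).all()
        planted = sorted(truth.planted_productive_families)
        others = truth.secretion_propensity.drop(planted)
        assert truth.secretion_propensity[planted].min() > 3 * others.median()

    def test_planted_abundance_pinned(self, design):
        t = synthgen.make_ground_truth(design, n_families=10, n_planted=2,
                                       planted_abundance=0.004, seed=1)
        for fam in t.planted_productive_families:
            assert np.allclose(t.expected_fractions[fam], 0.004, atol=5e-4)

    def test_producer_share_pinning(self, design):
        t = synthgen.make_ground_truth(
            design, n_families=20, nonproducer_fraction=0.5,
            producer_share_day0=0.139, producer_share_colonised=0.52, seed=3)
        prod = sorted(t.producer_families)
        shares = t.expected_fractions[prod].sum(axis=1)
        assert shares.loc[0] == pytest.approx(0.139, abs=1e-9)
        assert (shares.loc[1:] - 0.52).abs().max() < 1e-9

    def test_covered_secretion_share_near_target(self, design):
        t = synthgen.make_ground_truth(design, n_families=30,
                                       covered_secretion_share=0.75, seed=5)
        share = t.expected_secretion_share(design.proteome_weeks)
        covered = share[share.index.isin(t.community_families)].sum()
        assert 0.73 <= covered <= 0.85  # greedy exclusion leaves a small gap
        assert t.planted_productive_families <= t.community_families

    def test_parameter_validation(self, design):
        with pytest.raises(ParameterError):
            synthgen.make_ground_truth(design, n_families=3)
        with pytest.raises(ParameterError):
            synthgen.make_ground_truth(design, n_families=10, turnover=1.5)


class TestGenerateCommunity:
    def test_sample_count_matches_design(self, community_tables, design):
        assert community_tables.otu_table.shape[1] == design.n_samples == 46

    def test_counts_are_nonnegative_integers(self, community_tables):
        table = community_tables.otu_table
        assert (table.to_numpy() >= 0).all()
        assert table.dtypes.map(lambda d: np.issubdtype(d, np.integer)).all()

    def test_lineages_rank_complete(self, community_tables):
        for lin in community_tables.lineage_table["lineage"]:
            prefixes = [part.split("__")[0] for part in lin.split(";")]
            assert prefixes == ["d", "p", "c", "o", "f", "g"]

    def test_determinism_same_seed_identical_tables(self, design, truth):
        out = []
        for _ in range(2):
            c = synthgen.generate_community(design, truth=truth, seed=99)
            buf = io.StringIO()
            c.otu_table.to_csv(buf, sep="\t")
            out.append(hashlib.sha256(buf.getvalue().encode()).hexdigest())
        assert out[0] == out[1]

    def test_zero_turnover_mean_fractions_match_truth(self):
        # Monte-Carlo: with turnover 0 the expected fractions are constant
        # over weeks; sample means must sit within 3 SE of the configured
        # truth for every family.
        design = synthgen.StudyDesign(cages=2, sample_weeks=(1, 8, 16),
                                      proteome_weeks=(1,), proteome_replicates=1)
        truth = synthgen.make_ground_truth(design, n_families=6, turnover=0.0,
                                           n_planted=0, seed=21)
        assert np.allclose(
            truth.expected_fractions.std(axis=0), 0.0, atol=1e-12
        ), "turnover 0 must freeze the expected profile"
        fams = truth.families
        means = []
        for seed in range(50):
            c = synthgen.generate_community(design, truth=truth, seed=1000 + seed)
            frac = c.otu_table.div(c.otu_table.sum(axis=0), axis=1)
            fam_frac = frac.groupby(
                c.lineage_table.set_index("otu_id")["lineage"]
                .str.extract(r"f__([^;]+)")[0]
                .reindex(frac.index).values
            ).sum()
            means.append(fam_frac.mean(axis=1).reindex(fams))
        means = pd.DataFrame(means)
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        expected = truth.expected_fractions.iloc[0]
        assert ((grand - expected).abs() <= 3 * se + 1e-12).all()

    def test_invalid_parameters_rejected(self, design, truth):
        with pytest.raises(ParameterError):
            synthgen.generate_community(design, truth=truth, depth_mean=0)


class TestGenerateProteome:
    def test_each_family_gets_a_protein(self, design):
        truth = synthgen.make_ground_truth(design, n_families=12, n_planted=0, seed=2)
        prot = synthgen.generate_proteome(design, truth, n_proteins=12, seed=2)
        assert set(prot.protein_family.values()) == set(truth.families)

    def test_determinism_identical_fasta_checksum(self, design, truth):
        sums = []
        for _ in range(2):
            p = synthgen.generate_proteome(design, truth, n_proteins=40, seed=4)
            blob = "".join(f">{i}\n{s}\n" for i, s in p.proteins)
            sums.append(hashlib.sha256(blob.encode()).hexdigest())
        assert sums[0] == sums[1]

    def test_psms_reference_generated_proteins_and_datasets(self, proteome, design):
        assert set(proteome.psms["protein_id"]) <= {p for p, _ in proteome.proteins}
        assert set(proteome.psms["dataset_id"]) <= set(design.dataset_weeks())

    def test_evalues_span_domain_threshold(self, proteome):
        ev = proteome.domains["evalue"]
        assert (ev <= 1e-10).any() and (ev > 1e-10).any()

    def test_too_few_proteins_rejected(self, design, truth):
        with pytest.raises(ParameterError):
            synthgen.generate_proteome(design, truth, n_proteins=3)


class TestGenerateBiomass:
    def test_noise_free_closed_form(self, design):
        truth = synthgen.make_ground_truth(
            design, n_families=6,
            decay_constants={k: 0.0074 for k in synthgen.DEFAULT_DECAY_CONSTANTS},
            seed=0)
        bm = synthgen.generate_biomass(truth, weeks=[0, 16], noise_sd=0.0,
                                       seed=0, cages=1, m0_mg=100.0)
        m0 = bm.loc[bm["week"] == 0, "total_mg"].iloc[0]
        m16 = bm.loc[bm["week"] == 16, "total_mg"].iloc[0]
        # 112 days at k = 0.0074/day leaves exp(-0.8288) of the mass
        assert m16 / m0 == pytest.approx(np.exp(-0.0074 * 112), rel=1e-12)

    def test_zero_decay_constant_series(self, design):
        truth = synthgen.make_ground_truth(
            design, n_families=6,
            decay_constants={k: 0.0 for k in synthgen.DEFAULT_DECAY_CONSTANTS},
            seed=0)
        bm = synthgen.generate_biomass(truth, weeks=[0, 4, 8], noise_sd=0.0, seed=0)
        assert bm.groupby("cage")["total_mg"].nunique().eq(1).all()

    def test_fraction_columns_sum_to_one(self, truth):
        bm = synthgen.generate_biomass(truth, weeks=[0, 2, 8], noise_sd=0.05, seed=8)
        frac_sum = bm[list(synthgen.DEFAULT_DECAY_CONSTANTS)].sum(axis=1)
        assert np.allclose(frac_sum, 1.0, atol=1e-9)

    def test_negative_noise_rejected(self, truth):
        with pytest.raises(ParameterError):
            synthgen.generate_biomass(truth, weeks=[1], noise_sd=-0.1)
        with pytest.raises(ParameterError):
            synthgen.generate_biomass(truth, weeks=[])
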