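"""Parameter-recovery experiments on synthetic studies.

Each experiment regenerates a synthetic study from a seed, pushes it
through the real analysis chain (PSMs -> emPAI/mol% -> annotation ->
community profile -> statistic) and scores the result against the
generator's ground truth.  These are the package's calibration
experiments: they quantify how well the productivity-index flag, the
group-contribution aggregation, the amplicon cross-reference and the
decay fits recover what was configured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotax, community, ecology, quant, synthgen
from .decay import fit_first_order


def analyse_study(
    design: synthgen.StudyDesign,
    truth: synthgen.GroundTruth,
    n_proteins: int,
    seed: int,
) -> dict:
    """One synthetic study through the quantification/annotation chain.

    Returns the per-(taxon family, week) CAZyme contributions, the
    community family profile, the productivity table and the flagged
    taxon set.
    """
    comm = synthgen.generate_community(design, truth=truth, seed=seed)
    prot = synthgen.generate_proteome(design, truth, n_proteins=n_proteins, seed=seed)

    observable = {pid: quant.digest(seq) for pid, seq in prot.proteins}
    covs = quant.coverage_from_psms(prot.psms, observable)
    quant_df = quant.normalize_mol_pct(covs)
    mean_q = quant.mean_mol_pct(quant_df, prot.dataset_weeks)

    config = annotax.AnnotationConfig()
    domains = annotax.filter_domains(prot.domains, config)
    assignments = annotax.assign_taxon(prot.blast_hits, prot.lineage_table, config)
    tax = annotax.assignments_to_frame(assignments)
    labels = tax.merge(
        domains[["protein_id", "family", "cazy_class"]].rename(
            columns={"family": "cazyme_family"}),
        on="protein_id", how="inner",
    )
    caz_q = mean_q[mean_q["protein_id"].isin(set(domains["protein_id"]))]
    fam_contrib = quant.aggregate(caz_q, labels, ["family"]).rename(
        columns={"family": "taxon"})

    profile = community.family_profile(comm.otu_table, comm.lineage_table).merge(
        comm.sample_meta, on="sample_id")
    week_ab = (
        profile.groupby(["week", "family"])["rel_abundance"].mean().reset_index()
        .rename(columns={"family": "taxon", "rel_abundance": "abundance"})
    )
    pi = ecology.productivity_table(
        fam_contrib[fam_contrib["taxon"] != "NA"], week_ab)
    return {
        "community": comm,
        "proteome": prot,
        "fam_contrib": fam_contrib,
        "profile": profile,
        "pi": pi,
        "flagged": ecology.flag_productive(pi),
    }


def pi_flag_recovery(
    n_seeds: int = 20,
    n_proteins: int = 500,
    n_families: int = 30,
    base_seed: int = 0,
) -> dict:
    """Recall and false-flag rate of the PI > 0.3 flag on planted
    10x-propensity families at 0.5% abundance."""
    design = synthgen.StudyDesign()
    tp = fn = fp = tn = 0
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i) % (2**31)
        truth = synthgen.make_ground_truth(design, n_families=n_families, seed=seed)
        res = analyse_study(design, truth, n_proteins, seed)
        planted = truth.planted_productive_families
        others = set(truth.families) - planted
        tp += len(res["flagged"] & planted)
        fn += len(planted - res["flagged"])
        fp += len(res["flagged"] & others)
        tn += len(others - res["flagged"])
    return {
        "recall_pct": 100.0 * tp / (tp + fn),
        "false_flag_pct": 100.0 * fp / (fp + tn),
        "n_seeds": n_seeds,
    }


def _split_truth(design: synthgen.StudyDesign, shares=(0.4, 0.3, 0.3)) -> synthgen.GroundTruth:
    """Three equally abundant families with a configured secretion split."""
    fams = [f"Split_{i}" for i in range(len(shares))]
    weeks = [0, *design.sample_weeks]
    fractions = pd.DataFrame(
        1.0 / len(fams), index=pd.Index(weeks, name="week"), columns=fams)
    return synthgen.GroundTruth(
        families=fams,
        lineages={
            f: f"d__Bacteria;p__P;c__C_{i};o__O_{i};f__{f};g__G_{i}"
            for i, f in enumerate(fams)
        },
        taxon_class={f: f"C_{i}" for i, f in enumerate(fams)},
        expected_fractions=fractions,
        secretion_propensity=pd.Series(shares, index=fams, dtype=float),
        planted_productive_families=set(),
        community_families=set(fams),
        decay_constants=dict(synthgen.DEFAULT_DECAY_CONSTANTS),
    )


def secretion_split_recovery(
    n_seeds: int = 20,
    n_proteins: int = 90,
    shares=(0.4, 0.3, 0.3),
    base_seed: int = 0,
) -> dict:
    """Recovered sigma x-bar mol% of a configured 40/30/30 secretion split.

    Returns the mean recovered share per family (percent) and the largest
    absolute deviation from the configured split.
    """
    design = synthgen.StudyDesign()
    truth = _split_truth(design, shares)
    recovered = []
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i + 1) % (2**31)
        res = analyse_study(design, truth, n_proteins, seed)
        fam = res["fam_contrib"]
        per_week = fam.pivot_table(index="week", columns="taxon",
                                   values="sum_mean_mol_pct", fill_value=0.0)
        per_week = per_week.div(per_week.sum(axis=1), axis=0) * 100.0
        recovered.append(per_week.mean(axis=0))
    mean_rec = pd.DataFrame(recovered).mean(axis=0)
    target = pd.Series(
        [s * 100 for s in shares], index=[f"Split_{i}" for i in range(len(shares))])
    err = (mean_rec - target).abs().max()
    return {
        "recovered_pct": mean_rec.to_dict(),
        "configured_pct": target.to_dict(),
        "max_abs_error_pct": float(err),
        "n_seeds": n_seeds,
    }


def crossref_recovery(
    n_seeds: int = 20,
    n_proteins: int = 500,
    n_families: int = 30,
    covered_share: float = 0.75,
    base_seed: int = 0,
) -> dict:
    """Recovered amplicon-cross-referenced CAZyme mol% versus the planted
    coverage of expected secretion."""
    design = synthgen.StudyDesign()
    diffs, recovered_means = [], []
    for i in range(n_seeds):
        seed = (base_seed + 1000 * i + 2) % (2**31)
        truth = synthgen.make_ground_truth(
            design, n_families=n_families, covered_secretion_share=covered_share,
            seed=seed)
        res = analyse_study(design, truth, n_proteins, seed)
        share = truth.expected_secretion_share(design.proteome_weeks)
        expected = float(share[share.index.isin(truth.community_families)].sum() * 100)
        xref = annotax.crossref(
            res["fam_contrib"].rename(columns={"taxon": "family"}),
            set(res["profile"]["family"]),
        )
        recovered = float(xref.mean())
        diffs.append(recovered - expected)
        recovered_means.append(recovered)
    return {
        "mean_recovered_pct": float(np.mean(recovered_means)),
        "mean_abs_error_pct": float(np.mean(np.abs(diffs))),
        "n_seeds": n_seeds,
    }


def decay_recovery(n_noisy_seeds: int = 50, base_seed: int = 0) -> dict:
    """Decay-constant recovery: exact at zero noise, within tolerance at
    5% multiplicative noise."""
    design = synthgen.StudyDesign()
    truth = synthgen.make_ground_truth(design, n_families=6, seed=base_seed % (2**31))
    weeks = [0, *design.sample_weeks]

    bm0 = synthgen.generate_biomass(truth, weeks=weeks, noise_sd=0.0,
                                    seed=base_seed % (2**31), cages=1)
    rel_errs_nf = []
    for comp, k_true in truth.decay_constants.items():
        if k_true == 0:
            continue
        k_fit = fit_first_order(bm0["week"], bm0["total_mg"] * bm0[comp]).k
        rel_errs_nf.append(abs(k_fit - k_true) / k_true)

    k_true = truth.decay_constants["cellulose_frac"]
    fits = []
    for i in range(n_noisy_seeds):
        seed = (base_seed + 1000 * i + 3) % (2**31)
        bm = synthgen.generate_biomass(truth, weeks=weeks, noise_sd=0.05,
                                       seed=seed, cages=1)
        fits.append(fit_first_order(bm["week"], bm["total_mg"] * bm["cellulose_frac"]).k)
    return {
        "noise_free_max_rel_error": float(max(rel_errs_nf)),
        "noisy_k_mean_per_day": float(np.mean(fits)),
        "noisy_k_true_per_day": float(k_true),
        "noisy_rel_error": float(abs(np.mean(fits) - k_true) / k_true),
        "n_noisy_seeds": n_noisy_seeds,
    }
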