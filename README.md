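# marshcaz

A tested, reusable reimplementation of a meta-exo-proteome-to-ecology
analysis of lignocellulose degradation in salt-marsh sediments: who in a
colonising microbial community secretes the carbohydrate-active enzymes
(CAZymes) that break down plant biomass, which taxa secrete
disproportionately for their abundance, and how fast the biomass itself
decays.

The package is aimed at microbial-ecology and metaproteomics researchers
who want the full computational chain — from ORF database preparation
and a two-pass partitioned protein search, through emPAI/mol%
quantification, CAZyme and taxonomic annotation, to the
productivity-index statistic, the taxon↔CAZyme bipartite network,
amplicon cross-referencing and litterbag decay kinetics — exercisable
end-to-end on synthetic data that emulates the study design (5 caged
litterbags sampled at weeks 1–6, 8, 10 and 16 plus a day-0 sediment
outgroup; triplicate proteomes at weeks 1, 3, 5 and 10).

## The statistics at the core

**emPAI and mol%.** A protein's exponentially modified protein abundance
index is

    emPAI = 10^(N_observed / N_observable) − 1

where `N_observed` counts distinct peptides seen for the protein in a
dataset and `N_observable` counts distinct tryptic peptides of 6–35
residues from its in-silico digest. Normalising emPAI within a dataset
gives the molar percentage (mol%); the replicate mean is x̄ mol% and the
sum over a group's proteins is Σx̄ mol%.

**Productivity index.** For a taxon with CAZyme output Σx̄ mol% and
community relative abundance *a* (both in percent),

    PI = log10(Σx̄ mol% / a)

PI = 0 means output exactly proportional to abundance; taxa with
PI > 0.3 (≈ two-fold) at one or more time points are flagged as
disproportionately productive.

**Two-pass partitioned search.** Each MS dataset is searched at high
stringency (p = 0.05) against 21 database subsets; all hits are pooled
and dereplicated into a "true hit" database; a single relaxed search
(p = 0.1) per dataset against that database, followed by a PSM expect
filter (≤ 0.1), yields the identified proteins. The test suite proves
both the equivalence with a single relaxed search under a sufficiency
condition and the sensitivity cost (a constructed protein whose every
peptide sits between the two thresholds is lost).

**Decay kinetics.** Biomass components follow first-order decay
M(t) = M₀·e^(−kt), fitted by least squares on log mass; interval loss
rates below 0.4 %/day mark the refractory phase.

## Worked example

The analysis is organised as numbered drivers that write their tables
under `results/`:

```
python analysis/01_simulate_study.py      # synthetic inputs + ground truth
python analysis/02_search_cascade.py      # two-pass partitioned search
python analysis/03_quantify_empai.py      # emPAI -> mol% -> x-bar mol%
python analysis/04_annotate.py            # CAZyme filter + best-hit taxonomy
python analysis/05_community_profile.py   # family profiles, producer enrichment
python analysis/06_productivity_network.py# PI flags, crossref, bipartite network
python analysis/07_biomass_decay.py       # decay fits and loss rates
```

With the default seed (42) the drivers print, among other things:

```
community samples : 46 (design says 46)
first-pass searches : 252 (12 datasets x 21 subsets)
mol% sum per dataset: min 100.000000000, max 100.000000000 (conserved at 100)
flagged productive taxa : ['Fam_002', 'Fam_019', 'Fam_022']
planted ground truth    : ['Fam_002', 'Fam_019', 'Fam_022'] -> recall 100%
crossref CAZyme mol% in amplicon profile, per week:
  {1: 77.6, 3: 77.7, 5: 76.9, 10: 74.5} (configured 76.9%)
recovered day-0 13.3%, week-1 52.3% -> 3.94-fold (configured 3.77-fold)
component decay constants (true vs fitted, day^-1):
  cellulose 0.013 -> 0.01299, hemicellulose 0.011 -> 0.01088, lignin 0.004 -> 0.00403
```

That is: the simulated design reproduces the study's sample and search
arithmetic exactly; the three families planted as low-abundance,
ten-fold over-productive CAZyme secretors are recovered by the PI > 0.3
flag; the fraction of CAZyme output cross-referenced to the amplicon
profile matches the configured coverage; a community configured with
producers at 13.9% of the day-0 sediment enriching to ~52% on the
biomass recovers the expected ~3.8-fold enrichment; and the decay
constants come back from the noisy mass series.

The same stages are available programmatically
(`marshcaz.iohub.run_pipeline`) and through the thin `marshcaz` CLI
(`simulate`, `cascade`, `run`, `decay`).

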