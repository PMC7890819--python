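"""emPAI quantification and molar-percentage aggregation.

The exponentially modified protein abundance index (emPAI) estimates a
protein's molar amount from peptide-level evidence:

    emPAI = 10**(n_observed / n_observable) - 1

where ``n_observed`` counts distinct peptides seen for the protein in a
dataset and ``n_observable`` counts distinct peptides an in-silico tryptic
digest could produce within the detectable length window.  Normalising
emPAI across a dataset yields the molar percentage (mol%); averaging mol%
over replicate datasets of a time point gives x-bar mol%, and summing
x-bar mol% over the proteins of a group (a taxon, a CAZyme family, ...)
gives the sigma x-bar mol% quantity every downstream statistic consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, QuantificationError

logger = logging.getLogger(__name__)

#: Default detectable peptide-length window for the "observable" digest.
OBSERVABLE_MIN_LEN = 6
OBSERVABLE_MAX_LEN = 35


def digest(
    protein_seq: str,
    *,
    min_len: int = OBSERVABLE_MIN_LEN,
    max_len: int = OBSERVABLE_MAX_LEN,
    missed_cleavages: int = 0,
) -> set[str]:
    """In-silico tryptic digest: distinct peptides within a length window.

    Trypsin cleaves C-terminal to K or R except when the next residue is
    proline.  ``missed_cleavages`` joins up to that many adjacent fragments.
    An empty sequence yields an empty set.
    """
    if min_len > max_len:
        raise ParameterError(f"min_len {min_len} > max_len {max_len}")
    if missed_cleavages < 0:
        raise ParameterError("missed_cleavages must be >= 0")
    if not protein_seq:
        return set()

    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(protein_seq):
        at_cut = aa in "KR" and (i + 1 == len(protein_seq) or protein_seq[i + 1] != "P")
        if at_cut:
            fragments.append(protein_seq[start : i + 1])
            start = i + 1
    if start < len(protein_seq):
        fragments.append(protein_seq[start:])

    peptides: set[str] = set()
    for i in range(len(fragments)):
        pep = ""
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            pep += fragments[j]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return peptides


@dataclass(frozen=True)
class PeptideCoverage:
    """Observed vs observable distinct-peptide counts for one protein/dataset."""

    protein_id: str
    dataset_id: str
    n_observed: int
    n_observable: int

    def __post_init__(self) -> None:
        if self.n_observable < 0 or self.n_observed < 0:
            raise ParameterError("peptide counts must be non-negative")
        if self.n_observed > self.n_observable:
            raise ParameterError(
                f"{self.protein_id}/{self.dataset_id}: observed "
                f"{self.n_observed} exceeds observable {self.n_observable}"
            )


def compute_empai(cov: PeptideCoverage) -> float:
    """emPAI = 10**(n_observed/n_observable) - 1, in [0, 9]."""
    if cov.n_observable == 0:
        raise QuantificationError(
            f"protein {cov.protein_id} has no observable peptides; unquantifiable"
        )
    return 10.0 ** (cov.n_observed / cov.n_observable) - 1.0


def coverage_from_psms(
    psms: pd.DataFrame,
    observable: dict[str, set[str]],
    *,
    count_unexpected: bool = False,
) -> list[PeptideCoverage]:
    """Build per-(protein, dataset) coverage from a PSM table.

    ``psms`` needs columns dataset_id, protein_id, peptide.  Observed
    peptides absent from the protein's observable set (missed-cleavage
    artefacts, in-source fragments) are logged and excluded from
    n_observed unless ``count_unexpected`` — exclusion keeps the emPAI
    exponent <= 1 and the index within [0, 9].
    """
    out: list[PeptideCoverage] = []
    for (ds, prot), grp in psms.groupby(["dataset_id", "protein_id"], sort=True):
        obs_set = observable.get(prot, set())
        seen = set(grp["peptide"])
        unexpected = seen - obs_set
        if unexpected and not count_unexpected:
            logger.info(
                "%s/%s: %d observed peptide(s) outside the observable set; excluded",
                ds, prot, len(unexpected),
            )
            seen &= obs_set
        out.append(
            PeptideCoverage(
                protein_id=prot,
                dataset_id=ds,
                n_observed=len(seen),
                n_observable=max(len(obs_set), len(seen)),
            )
        )
    return out


def normalize_mol_pct(coverages: list[PeptideCoverage]) -> pd.DataFrame:
    """emPAI per protein and mol% per dataset.

    Returns a frame with columns protein_id, dataset_id, empai, mol_pct
    where mol_pct_i = empai_i / sum(empai over the dataset) * 100.
    """
    if not coverages:
        raise QuantificationError("no coverage records to quantify")
    rows = [
        (c.protein_id, c.dataset_id, compute_empai(c)) for c in coverages
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "dataset_id", "empai"])
    totals = df.groupby("dataset_id")["empai"].transform("sum")
    if (totals == 0).any():
        bad = df.loc[totals == 0, "dataset_id"].unique().tolist()
        raise QuantificationError(f"all-zero emPAI in dataset(s) {bad}")
    df["mol_pct"] = df["empai"] / totals * 100.0
    return df


def mean_mol_pct(
    quant: pd.DataFrame, dataset_weeks: dict[str, int]
) -> pd.DataFrame:
    """x-bar mol% per (protein, week): mean over the week's replicate datasets.

    A protein absent from a replicate contributes 0 to the mean, so the
    divisor is always the full replicate count of the week.
    """
    df = quant.copy()
    df["week"] = df["dataset_id"].map(dataset_weeks)
    if df["week"].isna().any():
        missing = df.loc[df["week"].isna(), "dataset_id"].unique().tolist()
        raise ParameterError(f"dataset(s) with no week assignment: {missing}")
    n_reps = (
        pd.Series(dataset_weeks).rename("week").reset_index()
        .groupby("week")["index"].nunique()
    )
    summed = (
        df.groupby(["protein_id", "week"], sort=True)["mol_pct"].sum().reset_index()
    )
    summed["mean_mol_pct"] = summed["mol_pct"] / summed["week"].map(n_reps)
    return summed[["protein_id", "week", "mean_mol_pct"]]


def aggregate(
    mean_quant: pd.DataFrame,
    labels: pd.DataFrame,
    group_cols: list[str],
) -> pd.DataFrame:
    """Sigma x-bar mol% of label groups per week.

    ``mean_quant`` is the output of :func:`mean_mol_pct`; ``labels`` maps
    protein_id to the grouping columns (taxon rank, CAZyme family, ...).
    Proteins without a label row fall into an explicit "NA" group, which is
    retained and reported.  Returns columns group_cols + [week,
    sum_mean_mol_pct].
    """
    for col in group_cols:
        if col not in labels.columns:
            raise ParameterError(f"unknown grouping column {col!r}")
    merged = mean_quant.merge(
        labels[["protein_id", *group_cols]].drop_duplicates(), on="protein_id", how="left"
    )
    for col in group_cols:
        merged[col] = merged[col].fillna("NA")
    out = (
        merged.groupby([*group_cols, "week"], sort=True)["mean_mol_pct"]
        .sum()
        .reset_index()
        .rename(columns={"mean_mol_pct": "sum_mean_mol_pct"})
    )
    return out
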