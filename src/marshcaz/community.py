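"""Amplicon community-profile computations.

Family-level relative abundance from an OTU count table plus lineage
strings, OTU richness, the summed abundance of CAZyme-productive
lineages, and fold enrichment relative to the day-0 sediment outgroup.
Abundances are relative (percent of sample reads) because amplicon
profiles carry no absolute scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotax import _parse_lineage
from .errors import ParameterError


def family_profile(otu_table: pd.DataFrame, lineages: pd.DataFrame) -> pd.DataFrame:
    """Family-level relative abundance (percent) per sample.

    ``otu_table`` is OTU ids x sample ids (integer counts); ``lineages``
    maps otu_id to a semicolon-delimited lineage string.  Counts are
    summed by family name; OTUs unresolved at family level fall into the
    retained "NA" bucket.  Zero-read samples are excluded with a warning.
    Returns a long frame: sample_id, family, rel_abundance.
    """
    fam_of = {
        row["otu_id"]: _parse_lineage(row["lineage"])["family"]
        for _, row in lineages.iterrows()
    }
    missing = set(otu_table.index) - set(fam_of)
    if missing:
        raise ParameterError(f"OTUs without lineage rows: {sorted(missing)[:5]} ...")
    fam = pd.Series({otu: fam_of[otu] for otu in otu_table.index}, name="family")
    by_family = otu_table.groupby(fam).sum()
    totals = by_family.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"samples with zero reads excluded: {empty}", stacklevel=2)
        by_family = by_family.drop(columns=empty)
        totals = totals.drop(empty)
    rel = by_family.div(totals, axis=1) * 100.0
    long = (
        rel.reset_index()
        .melt(id_vars="family", var_name="sample_id", value_name="rel_abundance")
    )
    return long[["sample_id", "family", "rel_abundance"]]


def otu_richness(otu_table: pd.DataFrame, sample: str) -> int:
    """Number of OTUs with a nonzero count in ``sample``."""
    return int((otu_table[sample] > 0).sum())


def producer_fraction(profile: pd.DataFrame, producer_families: set[str]) -> pd.Series:
    """Summed relative abundance (percent) of producer families per sample."""
    if not producer_families:
        raise ParameterError("producer family set is empty")
    sub = profile[profile["family"].isin(producer_families)]
    out = sub.groupby("sample_id")["rel_abundance"].sum()
    return out.reindex(profile["sample_id"].unique(), fill_value=0.0)


def fold_enrichment(value_t: float, value_day0: float) -> float:
    """value_t / value_day0; NA when the day-0 reference is zero."""
    if value_day0 < 0 or value_t < 0:
        raise ParameterError("abundances must be non-negative")
    if value_day0 == 0:
        return float("nan")
    return value_t / value_day0
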