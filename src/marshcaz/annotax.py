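"""CAZyme domain filtering, family->class mapping, best-hit taxonomy and
proteome/amplicon cross-referencing.

Carbohydrate-active enzyme (CAZyme) annotations arrive as tabular domain
hits (protein, family, e-value).  Proteome-derived hits are kept at
e-value <= 1e-10; transcriptome-derived hits at e-value <= 1e-5 when the
parent ORF is expressed at TPM >= 1.  Glycosyl transferases (GT) are
synthesis-side and excluded by default.  Taxonomic origin is assigned by
the best homology hit (highest bitscore), with the lineage resolved from
a rank table; proteins without an acceptable hit stay in an explicit
"NA" group rather than being dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")
_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_\S+)?$", re.IGNORECASE)

LINEAGE_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class AnnotationConfig:
    proteome_evalue_max: float = 1e-10
    transcriptome_evalue_max: float = 1e-5
    transcriptome_tpm_min: float = 1.0
    blast_evalue_max: float = 1e-5
    exclude_gt: bool = True

    def __post_init__(self) -> None:
        for name in ("proteome_evalue_max", "transcriptome_evalue_max",
                     "transcriptome_tpm_min", "blast_evalue_max"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


def normalize_family(family: str) -> str:
    """Canonical family name: upper-case, whitespace stripped, subfamily
    suffix after '_' removed (GH5_2 -> GH5)."""
    fam = family.strip().upper()
    m = _FAMILY_RE.match(fam)
    if not m:
        raise FormatError(f"unparseable CAZyme family: {family!r}")
    return f"{m.group(1).upper()}{m.group(2)}"


def family_to_class(family: str) -> str:
    """CAZyme class (GH/GT/PL/CE/AA/CBM) from a family name prefix."""
    m = _FAMILY_RE.match(family.strip().upper())
    if not m:
        raise FormatError(f"unparseable CAZyme family: {family!r}")
    return m.group(1).upper()


def filter_domains(annotations: pd.DataFrame, config: AnnotationConfig | None = None) -> pd.DataFrame:
    """Apply the per-source e-value (and TPM) thresholds, inclusively.

    ``annotations`` needs columns protein_id, family, evalue, source
    (proteome|transcriptome); transcriptome rows also need ``tpm``.
    Family names are normalised; GT families dropped when configured.
    """
    config = config or AnnotationConfig()
    df = annotations.copy()
    if "source" not in df.columns or df["source"].isna().any():
        raise FormatError("every annotation row needs a 'source'")
    bad_source = set(df["source"]) - {"proteome", "transcriptome"}
    if bad_source:
        raise FormatError(f"unknown annotation source(s): {sorted(bad_source)}")
    df["family"] = df["family"].map(normalize_family)
    df["cazy_class"] = df["family"].map(family_to_class)

    is_prot = df["source"] == "proteome"
    keep = pd.Series(False, index=df.index)
    keep[is_prot] = df.loc[is_prot, "evalue"] <= config.proteome_evalue_max
    is_tx = ~is_prot
    if is_tx.any():
        if "tpm" not in df.columns or df.loc[is_tx, "tpm"].isna().any():
            raise FormatError("transcriptome annotations require a 'tpm' column")
        keep[is_tx] = (df.loc[is_tx, "evalue"] <= config.transcriptome_evalue_max) & (
            df.loc[is_tx, "tpm"] >= config.transcriptome_tpm_min
        )
    if config.exclude_gt:
        keep &= df["cazy_class"] != "GT"
    return df[keep].reset_index(drop=True)


@dataclass(frozen=True)
class TaxAssignment:
    protein_id: str
    best_hit: str | None
    bitscore: float
    evalue: float
    lineage: dict[str, str]  # rank -> name, "NA" where unresolved


def _parse_lineage(s: str) -> dict[str, str]:
    parts = [p.strip() for p in str(s).split(";")]
    out = {}
    for rank, part in zip(LINEAGE_RANKS, parts):
        # tolerate rank-prefixed convention d__/p__/c__/o__/f__/g__
        name = re.sub(r"^[a-z]__", "", part)
        out[rank] = name if name else "NA"
    for rank in LINEAGE_RANKS[len(parts):]:
        out[rank] = "NA"
    return out


def assign_taxon(
    hits: pd.DataFrame,
    lineage_table: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> list[TaxAssignment]:
    """Best-hit taxonomy per protein.

    ``hits`` has columns qseqid, sseqid, bitscore, evalue; rows above
    ``blast_evalue_max`` are ignored.  The best hit maximises bitscore,
    ties broken by minimal e-value then lexicographically smallest
    subject id — so assignment is independent of input order.  Proteins
    with no acceptable hit (and proteins whose subject is missing from
    the lineage table, which is logged) get an all-NA lineage.
    """
    config = config or AnnotationConfig()
    lineages = {
        row["subject_id"]: _parse_lineage(row["lineage"])
        for _, row in lineage_table.iterrows()
    }
    na_lineage = {rank: "NA" for rank in LINEAGE_RANKS}
    out: list[TaxAssignment] = []
    usable = hits[hits["evalue"] <= config.blast_evalue_max]
    for prot, grp in usable.groupby("qseqid", sort=True):
        ranked = grp.sort_values(
            ["bitscore", "evalue", "sseqid"], ascending=[False, True, True]
        )
        best = ranked.iloc[0]
        lin = lineages.get(best["sseqid"])
        if lin is None:
            logger.warning(
                "subject %s absent from lineage table; protein %s -> NA",
                best["sseqid"], prot,
            )
            lin = na_lineage
        out.append(
            TaxAssignment(
                protein_id=str(prot),
                best_hit=str(best["sseqid"]),
                bitscore=float(best["bitscore"]),
                evalue=float(best["evalue"]),
                lineage=dict(lin),
            )
        )
    assigned = {a.protein_id for a in out}
    for prot in sorted(set(hits["qseqid"]) - assigned):
        out.append(TaxAssignment(str(prot), None, np.nan, np.nan, dict(na_lineage)))
    return out


def assignments_to_frame(assignments: list[TaxAssignment]) -> pd.DataFrame:
    """Flatten TaxAssignments into a protein_id x ranks frame."""
    rows = [
        {"protein_id": a.protein_id, **a.lineage} for a in assignments
    ]
    return pd.DataFrame(rows, columns=["protein_id", *LINEAGE_RANKS])


def crossref(
    contributions: pd.DataFrame,
    amplicon_families: set[str],
) -> pd.Series:
    """Fraction of CAZyme mol% whose producing taxon family is seen in the
    amplicon community profile, per week (percent).

    ``contributions`` has columns family (taxon family name), week,
    sum_mean_mol_pct.  Weeks with zero total contribution report NA.
    """
    df = contributions.copy()
    totals = df.groupby("week")["sum_mean_mol_pct"].sum()
    matched = (
        df[df["family"].isin(amplicon_families)]
        .groupby("week")["sum_mean_mol_pct"]
        .sum()
        .reindex(totals.index, fill_value=0.0)
    )
    frac = matched / totals * 100.0
    frac[totals == 0] = np.nan
    return frac
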