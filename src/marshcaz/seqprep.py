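"""Transcriptome-side sequence preparation.

Contig length filtering, six-frame ORF extraction with alternative
initiation codons, exact-sequence dereplication and TPM (transcripts per
million) computation.  These steps mirror a metatranscriptome assembly
being turned into a protein search database: short contigs are dropped,
every open reading frame of at least ``min_orf_len`` nucleotides is
extracted from all six frames, and duplicate ORFs are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Common bacterial initiation codons; the alternative-start set is
#: configurable because annotation pipelines differ on TTG/GTG usage.
DEFAULT_ALT_STARTS = frozenset({"ATG", "GTG", "TTG"})
STRICT_STARTS = frozenset({"ATG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_NT
        if bad:
            raise FormatError(
                f"contig {self.id}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class OrfRecord:
    """An ORF on a parent contig.

    ``frame`` is +1..+3 (forward) or -1..-3 (reverse); ``start``/``end``
    are 1-based inclusive coordinates on the FORWARD strand regardless of
    frame, with start <= end.  ``sequence`` excludes the stop codon; a
    segment that runs off the contig end without a stop is ``partial``.
    """

    id: str
    parent_contig: str
    frame: int
    start: int
    end: int
    sequence: str
    partial: bool = False

    @property
    def header(self) -> str:
        return f"{self.parent_contig}|{self.frame:+d}|{self.start}-{self.end}"


def filter_contigs(contigs: list[Contig], min_keep_len: int = 501) -> list[Contig]:
    """Keep contigs of length >= ``min_keep_len`` (default drops <= 500 bp)."""
    if min_keep_len < 1:
        raise ParameterError("min_keep_len must be >= 1")
    return [c for c in contigs if len(c.sequence) >= min_keep_len]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_stop(codon: str) -> bool:
    # A codon containing N is never a start or a stop.
    return codon in STOP_CODONS


def _scan_strand(seq: str, frame_offset: int, starts: frozenset[str], min_len: int):
    """Yield (start0, end0, seq, partial) ORFs in one reading frame.

    Within each stop-delimited segment the ORF runs from the first allowed
    start codon to the next in-frame stop (stop excluded); coordinates are
    0-based on the given strand.
    """
    n = len(seq)
    pos = frame_offset
    orf_start: int | None = None
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if orf_start is None and codon in starts:
            orf_start = pos
        if _is_stop(codon):
            if orf_start is not None and pos - orf_start >= min_len:
                yield orf_start, pos, seq[orf_start:pos], False
            orf_start = None
        pos += 3
    if orf_start is not None and pos - orf_start >= min_len:
        yield orf_start, pos, seq[orf_start:pos], True


def extract_orfs(
    contig: Contig,
    min_orf_len: int = 300,
    alt_starts: bool = True,
) -> list[OrfRecord]:
    """Six-frame ORF extraction.

    ORF length excludes the stop codon; reverse-strand hits are reported
    with forward-strand coordinates.  With ``alt_starts`` the start set is
    {ATG, GTG, TTG}, otherwise {ATG}.
    """
    starts = DEFAULT_ALT_STARTS if alt_starts else STRICT_STARTS
    seq = contig.sequence.upper()
    n = len(seq)
    records: list[OrfRecord] = []
    counter = 0
    for offset in range(3):
        for s0, e0, orf_seq, partial in _scan_strand(seq, offset, starts, min_orf_len):
            counter += 1
            records.append(
                OrfRecord(
                    id=f"{contig.id}_orf{counter}",
                    parent_contig=contig.id,
                    frame=offset + 1,
                    start=s0 + 1,
                    end=e0,
                    sequence=orf_seq,
                    partial=partial,
                )
            )
    rc = reverse_complement(seq)
    for offset in range(3):
        for s0, e0, orf_seq, partial in _scan_strand(rc, offset, starts, min_orf_len):
            counter += 1
            records.append(
                OrfRecord(
                    id=f"{contig.id}_orf{counter}",
                    parent_contig=contig.id,
                    frame=-(offset + 1),
                    start=n - e0 + 1,
                    end=n - s0,
                    sequence=orf_seq,
                    partial=partial,
                )
            )
    return records


def dereplicate(seqs: list[tuple[str, str]]) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Exact-sequence deduplication.

    ``seqs`` is a list of (id, sequence).  The first occurrence's id is
    retained; returns (unique records, sequence -> occurrence count).
    """
    unique: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    for rec_id, seq in seqs:
        if seq not in counts:
            unique.append((rec_id, seq))
            counts[seq] = 0
        counts[seq] += 1
    return unique, counts


def compute_tpm(read_counts, lengths) -> pd.DataFrame:
    """Transcripts per million from read counts and feature lengths.

    tpm_i = (count_i / length_i) / sum_j(count_j / length_j) * 1e6; an
    all-zero count vector yields all-zero TPM.  ``read_counts`` may be a
    dict or a pandas Series indexed by ORF id.
    """
    counts = pd.Series(read_counts, dtype=float)
    lens = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lens.isna().any():
        raise ParameterError("length missing for some ids")
    if (lens <= 0).any():
        raise ParameterError("lengths must be positive")
    if (counts < 0).any():
        raise ParameterError("read counts must be non-negative")
    rate = counts / lens
    total = rate.sum()
    tpm = rate / total * 1e6 if total > 0 else rate * 0.0
    return pd.DataFrame(
        {
            "orf_id": counts.index,
            "read_count": counts.values,
            "length_nt": lens.values,
            "tpm": tpm.values,
        }
    )
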