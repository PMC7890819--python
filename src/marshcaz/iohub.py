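"""Format readers/writers, configuration, seed control and the end-to-end
pipeline driver.

All tabular interchange uses one TSV dialect: tab-separated, UTF-8,
mandatory header row, '#' comment lines carrying provenance (config
hash, seed, tool version).  FASTA I/O wraps Biopython.  One global seed
fans out to per-module seeds as ``seed + module index`` so every stage
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__, annotax, cascade, community, decay, ecology, quant, seqprep, synthgen
from .errors import FormatError, ParameterError, PipelineError

logger = logging.getLogger(__name__)

#: Stable module indices for seed fan-out.
MODULE_INDEX = {
    "synthgen": 0, "seqprep": 1, "cascade": 2, "quant": 3,
    "annotax": 4, "community": 5, "ecology": 6, "decay": 7,
}


def module_seed(global_seed: int, module: str) -> int:
    """Per-module seed: global seed plus the module's stable index."""
    if module not in MODULE_INDEX:
        raise ParameterError(f"unknown module {module!r}")
    return (int(global_seed) + MODULE_INDEX[module]) % (2**31)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; id is the header token before any whitespace.

    Tolerates lower-case sequence and CRLF line endings.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        with open(path, newline=None) as fh:
            text = fh.read()
        if text and not text.lstrip().startswith(">"):
            first_bad = text.splitlines()[0][:30]
            raise FormatError(f"{path}:1: expected '>' header, got {first_bad!r}")
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    except FormatError:
        raise
    except Exception as exc:  # malformed FASTA from Biopython
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    return records


def write_fasta(records, path, width: int = 80) -> None:
    """Write (id, sequence) pairs, wrapping sequence lines at ``width``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tables

#: Declared schemas: column name -> pandas dtype.
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "otu": {},  # otu_id index + arbitrary integer sample columns, validated ad hoc
    "lineage": {"otu_id": "string", "lineage": "string"},
    "subject_lineage": {"subject_id": "string", "lineage": "string"},
    "domain": {"protein_id": "string", "family": "string", "evalue": "float64",
               "coverage": "float64"},
    "blast": {"qseqid": "string", "sseqid": "string", "bitscore": "float64",
              "evalue": "float64"},
    "psm": {"dataset_id": "string", "protein_id": "string", "peptide": "string",
            "expect": "float64"},
    "biomass": {"cage": "int64", "week": "int64", "total_mg": "float64",
                "cellulose_frac": "float64", "hemicellulose_frac": "float64",
                "lignin_frac": "float64", "ash_frac": "float64"},
    "quant": {"protein_id": "string", "dataset_id": "string", "empai": "float64",
              "mol_pct": "float64"},
}


def read_table(path, schema: str, strict: bool = True) -> pd.DataFrame:
    """Read a TSV against a declared schema.

    Scientific-notation e-values parse as floats; a missing declared
    column (other than optional lineage ranks) or a type failure raises
    FormatError naming the column; under ``strict`` an undeclared extra
    column is also an error.
    """
    if schema not in TABLE_SCHEMAS:
        raise ParameterError(f"unknown table schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype="string")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TSV: {exc}") from exc
    if schema == "otu":
        if df.columns[0] != "otu_id":
            raise FormatError(f"{path}: OTU table must lead with 'otu_id'")
        df = df.set_index("otu_id")
        try:
            return df.astype("int64")
        except Exception as exc:
            raise FormatError(f"{path}: non-integer OTU counts: {exc}") from exc
    missing = set(spec) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    extra = set(df.columns) - set(spec)
    if extra and strict:
        raise FormatError(f"{path}: undeclared column(s) {sorted(extra)}")
    for col, dtype in spec.items():
        try:
            df[col] = df[col].astype(dtype)
        except Exception as exc:
            raise FormatError(f"{path}: column {col!r} not {dtype}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False) -> None:
    """Write a TSV with '#' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class PipelineConfig:
    """Everything one synthetic end-to-end run needs."""

    seed: int = 0
    outdir: str = "results/pipeline"
    n_families: int = 30
    n_proteins: int = 500
    turnover: float = 0.8
    n_planted: int = 3
    covered_secretion_share: float = 1.0
    biomass_noise_sd: float = 0.05
    n_subsets: int = 21
    design: synthgen.StudyDesign = field(default_factory=synthgen.StudyDesign)
    search: cascade.SearchConfig = field(default_factory=cascade.SearchConfig)
    annotation: annotax.AnnotationConfig = field(default_factory=annotax.AnnotationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub in (("design", synthgen.StudyDesign),
                         ("search", cascade.SearchConfig),
                         ("annotation", annotax.AnnotationConfig)):
            if key in data and isinstance(data[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(data[key]) - sub_known
                if sub_unknown:
                    raise ParameterError(f"unknown {key} key(s): {sorted(sub_unknown)}")
                if key == "design":
                    for tup in ("sample_weeks", "proteome_weeks"):
                        if tup in data[key]:
                            data[key][tup] = tuple(data[key][tup])
                data[key] = sub(**data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance(config: PipelineConfig) -> dict:
    return {"tool": f"marshcaz {__version__}", "seed": config.seed,
            "config_sha": config.digest()}


# ---------------------------------------------------------------------------
# End-to-end pipeline

_CODON_OF = {  # one codon per residue, for reverse-translating demo contigs
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> seqprep -> cascade -> quant -> annotax -> community ->
    ecology -> decay, writing every table plus a machine-readable summary.

    Returns the summary dict (also written as summary.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    prov = provenance(config)
    summary: dict = {"seed": config.seed, "config_sha": config.digest(),
                     "version": __version__}

    with _stage("simulate"):
        design = config.design
        truth = synthgen.make_ground_truth(
            design, n_families=config.n_families, turnover=config.turnover,
            n_planted=config.n_planted,
            covered_secretion_share=config.covered_secretion_share,
            seed=module_seed(config.seed, "synthgen"),
        )
        comm = synthgen.generate_community(
            design, truth=truth, seed=module_seed(config.seed, "synthgen"))
        prot = synthgen.generate_proteome(
            design, truth, n_proteins=config.n_proteins,
            seed=module_seed(config.seed, "synthgen"))
        biomass = synthgen.generate_biomass(
            truth, weeks=[0, *design.sample_weeks], noise_sd=config.biomass_noise_sd,
            seed=module_seed(config.seed, "synthgen"))
        write_table(comm.otu_table, out / "otu_table.tsv", prov, index=True)
        write_table(comm.lineage_table, out / "otu_lineages.tsv", prov)
        write_table(prot.domains, out / "domains.tsv", prov)
        write_table(prot.blast_hits, out / "blast_hits.tsv", prov)
        write_table(prot.lineage_table, out / "subject_lineages.tsv", prov)
        write_table(prot.psms, out / "psms.tsv", prov)
        write_table(biomass, out / "biomass.tsv", prov)
        write_fasta(prot.proteins, out / "proteins.faa")
        summary["n_community_samples"] = int(comm.otu_table.shape[1])
        summary["n_proteome_datasets"] = design.n_proteome_datasets

    with _stage("seqprep"):
        # exercise the transcriptome path on reverse-translated demo contigs
        rng = np.random.default_rng(module_seed(config.seed, "seqprep"))
        contigs = []
        for pid, seq in prot.proteins[:20]:
            nt = "ATG" + "".join(_CODON_OF[aa] for aa in seq) + "TAA"
            contigs.append(seqprep.Contig(id=f"contig_{pid}", sequence=nt))
        kept = seqprep.filter_contigs(contigs, 501)
        orfs = [o for c in kept for o in seqprep.extract_orfs(c)]
        uniq, _counts = seqprep.dereplicate([(o.id, o.sequence) for o in orfs])
        tpm = seqprep.compute_tpm(
            {oid: int(rng.integers(1, 1000)) for oid, _ in uniq},
            {oid: len(s) for oid, s in uniq},
        )
        write_table(tpm, out / "transcript_tpm.tsv", prov)
        summary["n_demo_orfs"] = len(uniq)

    with _stage("cascade"):
        datasets = [
            cascade.Dataset(ds, tuple(sorted(set(grp["peptide"]))))
            for ds, grp in prot.psms.groupby("dataset_id")
        ]
        search = dataclasses.replace(
            config.search,
            n_subsets=min(config.n_subsets, len(prot.proteins)),
            seed=module_seed(config.seed, "cascade"),
        )
        fp, final = cascade.run_cascade(cascade.naive_engine, datasets, prot.proteins, search)
        summary["n_first_pass_searches"] = fp.n_searches
        summary["n_truehit_proteins"] = len(fp.truehit_db)
        summary["n_identified_proteins"] = len(final.identified_proteins)

    with _stage("quant"):
        psm_df = pd.DataFrame(
            [(p.dataset_id, p.protein_id, p.peptide, p.expect) for p in final.psms],
            columns=["dataset_id", "protein_id", "peptide", "expect"],
        )
        observable = {pid: quant.digest(seq) for pid, seq in prot.proteins}
        covs = quant.coverage_from_psms(psm_df, observable)
        quant_df = quant.normalize_mol_pct(covs)
        mean_q = quant.mean_mol_pct(quant_df, prot.dataset_weeks)
        write_table(quant_df, out / "quant.tsv", prov)
        summary["mol_pct_sum_per_dataset"] = {
            ds: float(g["mol_pct"].sum()) for ds, g in quant_df.groupby("dataset_id")
        }

    with _stage("annotax"):
        domains = annotax.filter_domains(prot.domains, config.annotation)
        assignments = annotax.assign_taxon(prot.blast_hits, prot.lineage_table,
                                           config.annotation)
        tax = annotax.assignments_to_frame(assignments)
        labels = tax.merge(
            domains[["protein_id", "family", "cazy_class"]].rename(
                columns={"family": "cazyme_family"}),
            on="protein_id", how="inner",
        )
        # downstream ecology statistics run on the CAZyme fraction only
        mean_q_caz = mean_q[mean_q["protein_id"].isin(set(domains["protein_id"]))]
        fam_contrib = quant.aggregate(mean_q_caz, labels, ["family"]).rename(
            columns={"family": "taxon"})
        class_contrib = quant.aggregate(mean_q_caz, labels, ["class", "cazyme_family"])
        write_table(fam_contrib, out / "contrib_taxon_family.tsv", prov)
        write_table(class_contrib, out / "contrib_class_cazyfamily.tsv", prov)

    with _stage("community"):
        profile = community.family_profile(comm.otu_table, comm.lineage_table)
        profile = profile.merge(comm.sample_meta, on="sample_id")
        producers = set(labels["family"]) - {"NA"}
        day0 = comm.sample_meta.loc[comm.sample_meta["week"] == 0, "sample_id"]
        week_means = (
            profile.assign(prod=profile["family"].isin(producers))
            .groupby(["week", "sample_id"])
            .apply(lambda g: g.loc[g["prod"], "rel_abundance"].sum(), include_groups=False)
            .groupby("week").mean()
        )
        write_table(profile, out / "family_profile.tsv", prov)
        summary["producer_fraction_by_week"] = {int(w): float(v) for w, v in week_means.items()}
        if len(day0) and week_means.get(0, 0) > 0:
            summary["producer_fold_enrichment_wk1"] = community.fold_enrichment(
                float(week_means.loc[1]), float(week_means.loc[0]))
        summary["otu_richness_day0"] = (
            community.otu_richness(comm.otu_table, day0.iloc[0]) if len(day0) else None
        )

    with _stage("ecology"):
        # abundance at taxon-family rank: per-week mean over cage samples
        week_ab = (
            profile.groupby(["week", "family"])["rel_abundance"].mean().reset_index()
            .rename(columns={"family": "taxon", "rel_abundance": "abundance"})
        )
        pi_input = fam_contrib[fam_contrib["taxon"] != "NA"]
        pi = ecology.productivity_table(pi_input, week_ab)
        flagged = ecology.flag_productive(pi)
        xref = annotax.crossref(
            fam_contrib.rename(columns={"taxon": "family"}),
            set(profile["family"]),
        )
        net_in = class_contrib.rename(columns={"class": "taxon"})
        net = ecology.build_network(net_in)
        net_f = ecology.filter_network(net)
        nodes, edges = ecology.network_tables(net_f)
        write_table(pi, out / "productivity_index.tsv", prov)
        write_table(nodes, out / "network_nodes.tsv", prov)
        write_table(edges, out / "network_edges.tsv", prov)
        try:
            nx.write_graphml(
                nx.relabel_nodes(net_f, {n: f"{n[0]}:{n[1]}" for n in net_f.nodes}),
                out / "network.graphml",
            )
        except Exception:  # GraphML export is best-effort presentation output
            logger.exception("GraphML export failed")
        summary["flagged_productive_taxa"] = sorted(flagged)
        summary["crossref_pct_by_week"] = {int(w): float(v) for w, v in xref.items()}

    with _stage("decay"):
        fits = decay.decay_summary(biomass)
        rates = decay.interval_rates(biomass)
        write_table(fits, out / "decay_fits.tsv", prov)
        write_table(rates, out / "interval_rates.tsv", prov)
        summary["total_mass_k_per_day_mean"] = float(fits["k_per_day"].mean())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
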