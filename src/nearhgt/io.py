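"""Readers and writers for gene orders, alignments, roles and reports.

External coordinates (GFF3, GenBank) are 1-based inclusive; everything
internal is 0-based half-open.  Strand is ignored for gene ordering: the
synteny index concerns order, not orientation.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .crm import HGTReport
from .distances import OrthologAlignment
from .synteny import CandidateSet, Genome, SIProfile

__all__ = [
    "read_gene_order",
    "write_gene_order",
    "read_alignment_dir",
    "read_roles",
    "write_si_table",
    "write_histogram",
    "write_candidates",
    "write_report",
]


def read_gene_order(path, fmt: str = "tsv", organism_id: str | None = None,
                    topology: str = "circular") -> Genome:
    """Read an ordered gene list from TSV, GFF3 or GenBank.

    TSV: two columns, 1-based rank and gene identifier, no header.
    GFF3: CDS features ordered by (start, end, id); identifier taken from the
    locus_tag, gene or ID attribute (first available).
    GenBank: CDS features ordered by start; identifier from locus_tag/gene.
    """
    path = Path(path)
    if organism_id is None:
        organism_id = path.stem
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", header=None, names=["rank", "gene"],
                             dtype={"rank": int, "gene": str})
        except Exception as exc:
            raise ValueError(f"{path}: malformed gene-order TSV: {exc}") from exc
        if df.empty:
            raise ValueError(f"{path}: empty gene-order file")
        genes = tuple(df.sort_values("rank")["gene"])
    elif fmt == "gff3":
        genes = _genes_from_gff3(path)
    elif fmt == "genbank":
        genes = _genes_from_genbank(path)
    else:
        raise ValueError(f"unknown gene-order format {fmt!r}")
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return Genome(organism_id=organism_id, genes=genes, topology=topology)


def _gff3_attr(attrs: str, keys=("locus_tag", "gene", "ID", "Name")) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def _genes_from_gff3(path: Path) -> tuple[str, ...]:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            row = dict(zip(cols, parts))
            if row["type"] != "CDS":
                continue
            name = _gff3_attr(row["attributes"])
            if name is None:
                raise ValueError(f"{path}:{lineno}: CDS without an identifier attribute")
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            records.append((start, end, name))
    records.sort()  # deterministic (start, end, id) tie-break
    return tuple(name for _, _, name in records)


def _genes_from_genbank(path: Path) -> tuple[str, ...]:
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = (feat.qualifiers.get("locus_tag") or feat.qualifiers.get("gene")
                    or [None])[0]
            if name is None:
                continue
            records.append((int(feat.location.start), int(feat.location.end), name))
    records.sort()
    return tuple(name for _, _, name in records)


def write_gene_order(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for i, gene in enumerate(genome.genes, 1):
            fh.write(f"{i}\t{gene}\n")


def read_alignment_dir(directory) -> dict[str, OrthologAlignment]:
    """Load every per-gene aligned FASTA (*.fa / *.fasta) in a directory."""
    directory = Path(directory)
    alignments = {}
    for path in sorted(directory.glob("*.fa")) + sorted(directory.glob("*.fasta")):
        aln = OrthologAlignment.from_fasta(path)
        alignments[aln.gene_id] = aln
    if not alignments:
        raise ValueError(f"no alignment FASTA files in {directory}")
    return alignments


def read_roles(path) -> tuple[list[str], list[str]]:
    """Organism role file: TSV of (organism_id, strain|reference)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["organism", "role"])
    strains = list(df[df["role"] == "strain"]["organism"])
    references = list(df[df["role"] == "reference"]["organism"])
    bad = set(df["role"]) - {"strain", "reference"}
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return strains, references


def write_si_table(profile: SIProfile, path) -> None:
    rows = sorted(profile.si.items())
    pd.DataFrame(rows, columns=["gene", "si"]).to_csv(path, sep="\t", index=False)


def write_histogram(hist: Mapping[int, int], path) -> None:
    pd.DataFrame(sorted(hist.items()), columns=["si", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_candidates(cand: CandidateSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pair={cand.genome_pair[0]},{cand.genome_pair[1]}"
                 f" delta_si={cand.threshold_fraction} cutoff={cand.cutoff}\n")
        fh.write("gene\n")
        for gene in cand.candidates:
            fh.write(f"{gene}\n")


def write_report(report: HGTReport, out_dir) -> None:
    """TSV summary + JSON with full per-test records + skip log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(s) for s in report.summaries]).to_csv(
        out_dir / "report.tsv", sep="\t", index=False
    )
    payload = {
        "k": report.k,
        "delta_si": report.delta_si,
        "delta_rho": report.delta_rho,
        "records": [asdict(r) for r in report.records],
        "pairs_without_shared_genes": report.pairs_without_shared_genes,
    }
    (out_dir / "records.json").write_text(json.dumps(payload, indent=1))
    with open(out_dir / "skips.log", "w") as fh:
        for context, reason in report.skips:
            fh.write(f"{context}\t{reason}\n")
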