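"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; GFF3 handling is restricted to CDS features
with ``locus_tag``/``product``/COG attributes, which is all the mapping
stage consumes. Tables are plain TSV via pandas. The Roary
``gene_presence_absence`` dialect is accepted for pangenome matrices.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import CdsRecord
from .kmers import GenomePanel

_ROARY_META_COLS = {
    "Gene", "Non-unique Gene name", "Annotation", "No. isolates",
    "No. sequences", "Avg sequences per isolate", "Genome Fragment",
    "Order within Fragment", "Accessory Fragment",
    "Accessory Order with Fragment", "QC", "Min group size nuc",
    "Max group size nuc", "Avg group size nuc",
}


def read_fasta_scaffolds(path) -> list:
    """[(scaffold_id, uppercase sequence), ...] from one FASTA file."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, scaffolds) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in scaffolds]
    SeqIO.write(records, str(path), "fasta")


def read_genome_manifest(path) -> GenomePanel:
    """Panel from a manifest TSV with columns (strain_id, fasta_path);
    relative paths resolve against the manifest's directory."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t")
    if not {"strain_id", "fasta_path"}.issubset(df.columns):
        raise ValueError("manifest needs columns strain_id, fasta_path")
    entries = []
    for _, row in df.iterrows():
        p = Path(row["fasta_path"])
        if not p.is_absolute():
            p = base / p
        entries.append((str(row["strain_id"]), read_fasta_scaffolds(p)))
    return GenomePanel(entries)


def write_genome_panel(panel: GenomePanel, out_dir) -> Path:
    """One FASTA per strain plus a manifest TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for strain, scaffolds in panel.entries:
        fname = f"{strain}.fasta"
        write_fasta(out_dir / fname, scaffolds)
        rows.append({"strain_id": strain, "fasta_path": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_phenotype(path) -> dict:
    """strain_id -> value from a two-column TSV (strain_id, value)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs columns strain_id, value")
    if df.empty:
        raise ValueError(f"phenotype file {path} is empty")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_phenotype(path, phenotype: dict) -> None:
    pd.DataFrame({"strain_id": sorted(phenotype),
                  "value": [phenotype[s] for s in sorted(phenotype)]}
                 ).to_csv(path, sep="\t", index=False)


def _gff_attr(attrs: str) -> dict:
    out = {}
    for field in attrs.strip().split(";"):
        if "=" in field:
            key, value = field.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3_cds(path) -> list:
    """CDS features from a GFF3 file as CdsRecord objects.

    Reads ``locus_tag`` (falling back to ``ID``), ``product``, and optional
    ``COG``/``cog_class`` attributes; non-CDS features are ignored.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = _gff_attr(parts[8])
            records.append(CdsRecord(
                scaffold_id=parts[0],
                start=int(parts[3]), end=int(parts[4]), strand=parts[6],
                locus_id=attrs.get("locus_tag", attrs.get("ID", "")),
                product=attrs.get("product", ""),
                cog_id=attrs.get("COG"),
                cog_class=attrs.get("cog_class"),
            ))
    return records


def write_gff3_cds(path, records) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(records, key=lambda r: (r.scaffold_id, r.start)):
            attrs = [f"ID={c.locus_id}", f"locus_tag={c.locus_id}"]
            if c.product:
                attrs.append(f"product={c.product}")
            if c.cog_id:
                attrs.append(f"COG={c.cog_id}")
            if c.cog_class:
                attrs.append(f"cog_class={c.cog_class}")
            fh.write("\t".join([c.scaffold_id, "halogwas", "CDS",
                                str(c.start), str(c.end), ".", c.strand,
                                "0", ";".join(attrs)]) + "\n")


def read_gff_manifest(path) -> dict:
    """strain_id -> list of CdsRecord from a manifest TSV
    (strain_id, gff_path)."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t")
    if not {"strain_id", "gff_path"}.issubset(df.columns):
        raise ValueError("manifest needs columns strain_id, gff_path")
    out = {}
    for _, row in df.iterrows():
        p = Path(row["gff_path"])
        if not p.is_absolute():
            p = base / p
        out[str(row["strain_id"])] = read_gff3_cds(p)
    return out


def read_roary_matrix(path) -> pd.DataFrame:
    """Pangenome presence/absence matrix: clusters x strains.

    Accepts Roary's ``gene_presence_absence.csv`` (metadata columns are
    dropped, the ``Gene`` column becomes the index) or a plain TSV whose
    first column is the cluster id and remaining columns are strains.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    first = df.columns[0]
    if "Gene" in df.columns:
        df = df.set_index("Gene")
        df = df.drop(columns=[c for c in _ROARY_META_COLS if c in df.columns],
                     errors="ignore")
    else:
        df = df.set_index(first)
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
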