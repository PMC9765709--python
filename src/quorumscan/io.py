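"""File I/O and the in-memory genome bundle shared across pipeline stages.

All genomic coordinates in this package are 0-based half-open with strand
'+'/'-'. GFF3 output converts to the 1-based inclusive convention of the
format; the GFF3 reader converts back.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["replicon_id", "start", "end", "strand", "locus_tag", "product"]
MGE_COLUMNS = ["replicon_id", "type", "start", "end"]


@dataclasses.dataclass
class GenomeBundle:
    """Replicon sequences plus the annotation tables the pipeline consumes.

    Attributes
    ----------
    replicons : mapping of replicon id to nucleotide sequence
    genes : DataFrame with GENE_COLUMNS
    proteome : mapping of protein/locus id to protein sequence
    mge : DataFrame with MGE_COLUMNS; rows of type ``plasmid`` or
        ``phage_plasmid`` label whole replicons, rows of type ``prophage``
        are [start, end) intervals on chromosomal replicons
    known_peptides : DataFrame (family, peptide) of described mature peptides
    circular : set of replicon ids treated as circular
    """

    replicons: dict[str, str]
    genes: pd.DataFrame
    proteome: dict[str, str]
    mge: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=MGE_COLUMNS)
    )
    known_peptides: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["family", "peptide"])
    )
    circular: set[str] = dataclasses.field(default_factory=set)

    def replicon_type(self, replicon_id: str) -> str:
        """'plasmid', 'phage_plasmid' or 'chromosome' for a replicon id."""
        if replicon_id not in self.replicons:
            raise KeyError(f"unknown replicon: {replicon_id}")
        rows = self.mge[
            (self.mge["replicon_id"] == replicon_id)
            & (self.mge["type"].isin(["plasmid", "phage_plasmid"]))
        ]
        if len(rows):
            return str(rows.iloc[0]["type"])
        return "chromosome"

    def gene_row(self, locus_tag: str) -> pd.Series:
        rows = self.genes[self.genes["locus_tag"] == locus_tag]
        if not len(rows):
            raise KeyError(f"unknown locus tag: {locus_tag}")
        return rows.iloc[0]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "quorumscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            attrs = f"ID={row.locus_tag};locus_tag={row.locus_tag}"
            if "product" in row and pd.notna(row["product"]):
                attrs += f";product={row['product']}"
            fh.write(
                "\t".join(
                    [
                        str(row.replicon_id),
                        source,
                        "CDS",
                        str(int(row.start) + 1),
                        str(int(row.end)),
                        ".",
                        str(row.strand),
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "replicon_id": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "locus_tag": attrs.get("locus_tag", attrs.get("ID", "")),
                    "product": attrs.get("product", ""),
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bundle(bundle: GenomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialise a bundle to plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "replicons": outdir / "replicons.fna",
        "genes": outdir / "genes.gff3",
        "proteome": outdir / "proteome.faa",
        "mge": outdir / "mge.tsv",
        "known_peptides": outdir / "known_peptides.tsv",
        "meta": outdir / "meta.json",
    }
    write_fasta(bundle.replicons, paths["replicons"])
    write_gff3(bundle.genes, paths["genes"])
    write_fasta(bundle.proteome, paths["proteome"])
    write_tsv(bundle.mge, paths["mge"])
    write_tsv(bundle.known_peptides, paths["known_peptides"])
    paths["meta"].write_text(json.dumps({"circular": sorted(bundle.circular)}))
    return paths


def read_bundle(indir: str | Path) -> GenomeBundle:
    indir = Path(indir)
    meta_path = indir / "meta.json"
    circular: set[str] = set()
    if meta_path.exists():
        circular = set(json.loads(meta_path.read_text()).get("circular", []))
    known = indir / "known_peptides.tsv"
    return GenomeBundle(
        replicons=read_fasta(indir / "replicons.fna"),
        genes=read_gff3(indir / "genes.gff3"),
        proteome=read_fasta(indir / "proteome.faa"),
        mge=read_tsv(indir / "mge.tsv"),
        known_peptides=read_tsv(known)
        if known.exists()
        else pd.DataFrame(columns=["family", "peptide"]),
        circular=circular,
    )
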