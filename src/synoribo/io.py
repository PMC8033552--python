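"""Readers and writers for the tab-separated tables the pipeline consumes.

All tables are plain TSV with a header row; lines starting with ``#`` are
comments.  Transcript coordinates are 0-based half-open everywhere in memory;
the VCF-like known-SNP panel is the one 1-based interface, converted on the
way in and out.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
SAMPLES = ("normal", "tumor")
ASSAYS = ("rna", "rpf")

#: per-site nucleotide-count columns, e.g. ``rna_tumor_G``
COUNT_COLUMNS = tuple(
    f"{assay}_{sample}_{base}" for assay in ASSAYS for sample in SAMPLES for base in BASES
)

SITE_KEY = ["gene", "pos"]


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally with a leading ``#`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    path.write_text(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_site_counts(paths: Iterable[str | Path] | str | Path) -> pd.DataFrame:
    """Read and concatenate per-patient site-count tables.

    Each table has columns ``gene, pos, ref, outgroup, patient`` plus the 16
    nucleotide-count columns (:data:`COUNT_COLUMNS`).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [read_tsv(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    missing = [c for c in ("gene", "pos", "ref", "outgroup", *COUNT_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"site-count table missing columns: {missing}")
    return df


def read_cds_models(path: str | Path) -> pd.DataFrame:
    """CDS model table: gene, transcript_len, cds_start, cds_end (0-based half-open)."""
    df = read_tsv(path)
    bad = df[(df["cds_end"] - df["cds_start"]) % 3 != 0]
    if len(bad):
        raise ValueError(f"CDS length not divisible by 3 for genes: {sorted(bad['gene'])}")
    return df


def write_cds_models(df: pd.DataFrame, path: str | Path) -> None:
    write_tsv(df, path, comment="gene models, transcript coordinates, 0-based half-open")


def read_transcripts(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_transcripts(seqs: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_panel(path: str | Path) -> set[tuple[str, int]]:
    """Known-SNP panel, VCF-like TSV (CHROM=transcript, POS 1-based, REF, ALT).

    Returns the set of 0-based (gene, pos) keys; panel exclusion is by site.
    """
    df = read_tsv(path)
    return set(zip(df["CHROM"], df["POS"].astype(int) - 1))


def write_panel(entries: pd.DataFrame, path: str | Path) -> None:
    """``entries`` has 0-based columns gene, pos, ref, alt; written 1-based."""
    out = pd.DataFrame(
        {
            "CHROM": entries["gene"],
            "POS": entries["pos"].astype(int) + 1,
            "REF": entries["ref"],
            "ALT": entries["alt"],
        }
    )
    write_tsv(out, path, comment="known-SNP panel, POS is 1-based (VCF convention)")
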