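"""Annotation triage for de novo transcriptome assemblies.

Three small, strict filters used when building a reference transcriptome
from assembled contigs:

* peptide length gate — keep predicted peptides strictly longer than 100
  amino acids (equivalently, ORFs longer than 300 bp, stop codon excluded);
* BLAST tabular hit filter — keep ortholog hits with query coverage strictly
  above 70% and percent identity strictly above 50%, optionally reduced to
  the best surviving hit per query;
* two-source ortholog merge — union two query-to-gene annotation maps (for
  example Swiss-Prot and a congeneric proteome), tagging provenance and
  reporting conflicts instead of dropping them.

All filters are idempotent, and loosening a threshold never removes a
previously kept record.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

#: Standard 12 columns of BLAST tabular output (-outfmt 6).
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

REQUIRED_HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "evalue",
                        "bitscore", "qlen")


def peptide_lengths_from_fasta(path) -> pd.Series:
    """Peptide lengths (aa) per record id from a FASTA file.

    Trailing stop-codon asterisks are not counted as residues.
    """
    lengths = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        lengths[rec.id] = len(str(rec.seq).rstrip("*"))
    return pd.Series(lengths, name="length_aa", dtype=int)


def filter_peptides(peptide_lengths, min_aa: int = 100) -> list:
    """Ids of peptides strictly longer than ``min_aa`` amino acids."""
    series = pd.Series(peptide_lengths)
    if len(series) and (series <= 0).any():
        bad = series.index[series <= 0].tolist()
        raise ValueError(f"non-positive peptide length(s) for: {bad}")
    return series.index[series > min_aa].tolist()


def read_blast_tabular(path, qlen_path=None) -> pd.DataFrame:
    """Read BLAST -outfmt 6 hits (12 columns, or 13 with a trailing qlen).

    Query lengths may instead come from a two-column sidecar TSV
    (``qseqid<TAB>qlen``, no header).  The result always carries a ``qlen``
    column; an error names whichever required column cannot be filled.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(OUTFMT6_COLUMNS):
        df.columns = list(OUTFMT6_COLUMNS)
    elif df.shape[1] == len(OUTFMT6_COLUMNS) + 1:
        df.columns = list(OUTFMT6_COLUMNS) + ["qlen"]
    else:
        raise ValueError(
            f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}"
        )
    if qlen_path is not None:
        qlen = pd.read_csv(qlen_path, sep="\t", header=None,
                           names=["qseqid", "qlen"]).set_index("qseqid")["qlen"]
        df["qlen"] = df["qseqid"].map(qlen)
        unknown = df.loc[df["qlen"].isna(), "qseqid"].unique().tolist()
        if unknown:
            raise ValueError(f"no query length for: {unknown}")
    missing = [c for c in REQUIRED_HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def filter_blast_hits(hits: pd.DataFrame, min_coverage: float = 0.70,
                      min_identity: float = 50.0,
                      best_per_query: bool = True) -> pd.DataFrame:
    """High-quality ortholog hits: coverage > 70% and identity > 50% (strict).

    Query coverage is alignment length / query length; a ``qcov`` column
    (capped at 1 for reporting) is added.  With ``best_per_query`` only the
    highest-bitscore survivor per query is kept (ties broken by lowest
    e-value, then lexicographic subject id).
    """
    missing = [c for c in REQUIRED_HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing required column(s): {missing}")
    if (hits["qlen"] <= 0).any() or (hits["length"] <= 0).any():
        raise ValueError("alignment and query lengths must be positive")
    cov = hits["length"] / hits["qlen"]
    kept = hits.loc[(cov > min_coverage) & (hits["pident"] > min_identity)].copy()
    kept["qcov"] = (kept["length"] / kept["qlen"]).clip(upper=1.0)
    if best_per_query and len(kept):
        kept = (
            kept.sort_values(
                ["qseqid", "bitscore", "evalue", "sseqid"],
                ascending=[True, False, True, True],
                kind="mergesort",
            )
            .groupby("qseqid", sort=False)
            .head(1)
        )
    return kept.reset_index(drop=True)


def merge_annotations(source_a: dict, source_b: dict,
                      source_names: tuple[str, str] = ("swissprot", "sterlet"),
                      ) -> pd.DataFrame:
    """Union two query-to-gene annotation maps with provenance tags.

    Every query in either source appears once; per-source gene labels are
    kept side by side (missing source = NA), ``sources`` lists the providing
    sources, and ``conflict`` marks queries the two sources annotate with
    different genes — reported, never dropped.
    """
    name_a, name_b = source_names
    queries = sorted(set(source_a) | set(source_b))
    rows = []
    for q in queries:
        in_a, in_b = q in source_a, q in source_b
        gene_a = source_a.get(q)
        gene_b = source_b.get(q)
        sources = [n for n, present in ((name_a, in_a), (name_b, in_b)) if present]
        rows.append(
            {
                "query": q,
                name_a: gene_a,
                name_b: gene_b,
                "sources": ",".join(sources),
                "conflict": bool(in_a and in_b and gene_a != gene_b),
            }
        )
    return pd.DataFrame(
        rows, columns=["query", name_a, name_b, "sources", "conflict"]
    ).set_index("query")
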