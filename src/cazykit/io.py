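"""Readers and writers for the pipeline's tabular interchange formats.

Three TSV formats are understood:

``annotations.tsv``
    One row per CAZyme domain hit: ``species_id, gene_id, family`` and
    optional ``start, end, evalue``.  Rows with the same (species, gene)
    aggregate into one gene annotation, preserving file order (the
    domain architecture).

``genome_summary.tsv``
    ``species_id, total_genes, lineage_group``.

``expression.tsv``
    Long format: ``gene_id, tissue, replicate, fpkm``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    AnnotationsBySpecies,
    DomainHit,
    FamilyParseError,
    GeneAnnotation,
    GenomeSummary,
    parse_family,
)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = ["species_id", "gene_id", "family", "start", "end", "evalue"]


class AnnotationParseError(ValueError):
    """A malformed annotation row, reported with its line number."""


def _opt_int(value: str) -> Optional[int]:
    return int(value) if value not in ("", None) else None


def _opt_float(value: str) -> Optional[float]:
    return float(value) if value not in ("", None) else None


def read_annotations(
    path: PathLike,
    max_evalue: Optional[float] = None,
) -> AnnotationsBySpecies:
    """Read a dbCAN-style annotation table into genes grouped by species.

    Every row becomes one :class:`~cazykit.model.DomainHit`; rows sharing
    (species, gene) aggregate into one :class:`~cazykit.model.GeneAnnotation`
    in file order.  Duplicate identical rows are kept with a warning
    (tandem repeat domains are legitimate annotations).

    Parameters
    ----------
    path
        TSV file with header ``species_id, gene_id, family`` and optional
        ``start, end, evalue`` columns.
    max_evalue
        If given, hits with an e-value above this threshold are dropped.
        Off by default: upstream annotations are taken as given.
    """
    genes: dict[tuple[str, str], GeneAnnotation] = {}
    seen_rows: set[tuple] = set()
    duplicates: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"species_id", "gene_id", "family"} <= set(
            reader.fieldnames
        ):
            raise AnnotationParseError(
                f"{path}: header must contain species_id, gene_id, family"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                family = parse_family(row["family"])
                hit = DomainHit(
                    family=family,
                    start=_opt_int(row.get("start")),
                    end=_opt_int(row.get("end")),
                    evalue=_opt_float(row.get("evalue")),
                )
            except (FamilyParseError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if max_evalue is not None and hit.evalue is not None and hit.evalue > max_evalue:
                continue
            key = (row["species_id"], row["gene_id"], family.raw, hit.start, hit.end)
            if key in seen_rows:
                duplicates.append(lineno)
            seen_rows.add(key)
            gkey = (row["species_id"], row["gene_id"])
            if gkey not in genes:
                genes[gkey] = GeneAnnotation(
                    species_id=row["species_id"], gene_id=row["gene_id"], hits=[]
                )
            genes[gkey].hits.append(hit)

    if duplicates:
        warnings.warn(
            f"{path}: {len(duplicates)} duplicate identical annotation rows kept "
            f"(first at line {duplicates[0]}); repeat domains are legitimate",
            stacklevel=2,
        )
    out: AnnotationsBySpecies = {}
    for (species, _), gene in genes.items():
        out.setdefault(species, []).append(gene)
    return out


def write_annotations(annotations: AnnotationsBySpecies, path: PathLike) -> None:
    """Write annotations back to the TSV interchange format (round-trippable)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for species in annotations:
            for gene in annotations[species]:
                for hit in gene.hits:
                    writer.writerow(
                        [
                            species,
                            gene.gene_id,
                            hit.family.raw,
                            "" if hit.start is None else hit.start,
                            "" if hit.end is None else hit.end,
                            "" if hit.evalue is None else repr(hit.evalue),
                        ]
                    )


def read_genome_summary(path: PathLike) -> dict[str, GenomeSummary]:
    """Read per-species genome summaries keyed by species id."""
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    required = {"species_id", "total_genes", "lineage_group"}
    if not required <= set(df.columns):
        raise AnnotationParseError(f"{path}: header must contain {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.species_id] = GenomeSummary(
            species_id=row.species_id,
            total_genes=int(row.total_genes),
            lineage_group=str(row.lineage_group),
        )
    return out


def write_genome_summary(summaries: dict[str, GenomeSummary], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "total_genes": s.total_genes,
                "lineage_group": s.lineage_group,
            }
            for s in summaries.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression(
    path: PathLike,
    replicates_expected: int = 3,
    known_genes: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Read a long-format expression table of per-replicate FPKM values.

    Expression tables cover the whole transcriptome; genes absent from the
    annotation set are retained (CAZyme filtering happens downstream) but
    flagged in the ``annotated`` column when ``known_genes`` is given.

    Returns a DataFrame with columns ``gene_id, tissue, replicate, fpkm``
    (and ``annotated`` if requested).  Negative FPKM raises; a (gene,
    tissue) with fewer than ``replicates_expected`` replicates warns --
    downstream averaging uses the replicates available.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "tissue": str}
    )
    required = {"gene_id", "tissue", "replicate", "fpkm"}
    if not required <= set(df.columns):
        raise AnnotationParseError(f"{path}: header must contain {sorted(required)}")
    if len(df) == 0:
        return df
    if (df["fpkm"] < 0).any():
        bad = df.index[df["fpkm"] < 0][0]
        raise ValueError(f"{path}: negative fpkm at row {bad + 2}")
    dup = df.duplicated(subset=["gene_id", "tissue", "replicate"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (gene, tissue, replicate) rows")
    counts = df.groupby(["gene_id", "tissue"], sort=False)["replicate"].size()
    short = counts[counts < replicates_expected]
    if len(short) > 0:
        warnings.warn(
            f"{path}: {len(short)} (gene, tissue) pairs have fewer than "
            f"{replicates_expected} replicates; averaging over those available",
            stacklevel=2,
        )
    if known_genes is not None:
        df = df.assign(annotated=df["gene_id"].isin(known_genes))
    return df
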