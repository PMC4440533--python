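"""Frequency profiling of CAZyme domain repertoires.

"Frequency" here is the per-genome census: how many CAZyme domains of
each family and class a genome carries, how many genes carry them, and
what fraction of the annotated gene space is CAZyme-coding.  Domain
counts include tandem repeats within a gene -- a gene with seven GT41
domains contributes seven GT41 domain occurrences but one CAZyme gene.

Class relative frequencies (percent of a genome's CAZyme domain total in
each of GT/GH/PL/CE/CBM) are the quantity that is strikingly conserved
across land plants; the coefficient of variation across species within a
lineage group quantifies that conservation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CLASS_LABELS,
    GeneAnnotation,
    GenomeSummary,
    class_of,
    sorted_families,
)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GenomeProfile:
    """Per-species CAZyme domain and gene counts.

    Invariants: ``total_domain_count`` is the sum of the per-family domain
    counts; for every family the gene count never exceeds the domain
    count; ``cazyme_gene_count`` never exceeds ``total_genes``.
    """

    species_id: str
    domain_count_by_family: Counter = field(default_factory=Counter)
    gene_count_by_family: Counter = field(default_factory=Counter)
    cazyme_gene_count: int = 0
    total_genes: int = 0
    lineage_group: Optional[str] = None

    @property
    def total_domain_count(self) -> int:
        return sum(self.domain_count_by_family.values())

    def class_counts(self) -> dict[str, int]:
        """Absolute domain counts aggregated to the five classes."""
        out = {c: 0 for c in CLASS_LABELS}
        for fam, n in self.domain_count_by_family.items():
            out[class_of(fam)] += n
        return out

    @property
    def families(self) -> list[str]:
        return sorted_families(self.domain_count_by_family)


def build_profile(
    annotations: Sequence[GeneAnnotation], summary: GenomeSummary
) -> GenomeProfile:
    """Count domains and genes per family for one genome.

    Every domain hit contributes 1 to its family's domain count (repeats
    included); a gene contributes 1 to ``cazyme_gene_count`` and 1 to each
    distinct family's gene count, regardless of its number of domains.
    """
    profile = GenomeProfile(
        species_id=summary.species_id,
        total_genes=summary.total_genes,
        lineage_group=summary.lineage_group,
    )
    for gene in annotations:
        if gene.species_id != summary.species_id:
            raise ValueError(
                f"gene {gene.gene_id} belongs to {gene.species_id}, "
                f"not {summary.species_id}"
            )
        profile.cazyme_gene_count += 1
        for hit in gene.hits:
            profile.domain_count_by_family[hit.family.name] += 1
        for fam in gene.distinct_families:
            profile.gene_count_by_family[fam] += 1
    if profile.cazyme_gene_count > summary.total_genes:
        raise ValueError(
            f"{summary.species_id}: {profile.cazyme_gene_count} CAZyme genes "
            f"exceed genome total of {summary.total_genes}"
        )
    return profile


def class_table_from_counts(
    class_counts: pd.DataFrame,
    cazyme_genes: pd.Series,
    total_genes: pd.Series,
) -> pd.DataFrame:
    """Class frequency table from per-class domain counts.

    Parameters are indexed by species: ``class_counts`` has the five class
    columns; ``cazyme_genes`` and ``total_genes`` give genome gene counts.
    Relative frequencies are percentages of each species' domain total and
    are reported as missing (not zero) when that total is zero.
    ``pct_cazyme_genes`` is rounded half-up to two decimals, the precision
    at which such tables are conventionally printed.
    """
    classes = list(CLASS_LABELS)
    table = class_counts[classes].copy()
    cazyme_genes = cazyme_genes.reindex(table.index)
    total_genes = total_genes.reindex(table.index)
    total = table.sum(axis=1).astype(float)
    for c in classes:
        table[f"rel_{c}"] = np.where(total > 0, table[c] / total * 100.0, np.nan)
    table["cazyme_domains"] = total.astype(int)
    table["cazyme_genes"] = cazyme_genes
    table["total_genes"] = total_genes
    table["pct_cazyme_genes"] = [
        round_half_up(g / t * 100.0) if t > 0 else np.nan
        for g, t in zip(cazyme_genes, total_genes)
    ]
    return table


def class_table(profiles: Iterable[GenomeProfile]) -> pd.DataFrame:
    """Absolute and relative class frequencies plus %CAZyme genes per species."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("class_table requires at least one profile")
    idx = [p.species_id for p in profiles]
    counts = pd.DataFrame([p.class_counts() for p in profiles], index=idx)
    return class_table_from_counts(
        counts,
        pd.Series([p.cazyme_gene_count for p in profiles], index=idx),
        pd.Series([p.total_genes for p in profiles], index=idx),
    )


def profile_table(profiles: Iterable[GenomeProfile]) -> pd.DataFrame:
    """Census-style summary row per species (gene/domain totals and classes)."""
    rows = []
    for p in profiles:
        row = {
            "species_id": p.species_id,
            "lineage_group": p.lineage_group,
            "total_genes": p.total_genes,
            "cazyme_genes": p.cazyme_gene_count,
            "pct_cazyme_genes": round_half_up(
                p.cazyme_gene_count / p.total_genes * 100.0
            )
            if p.total_genes
            else np.nan,
            "cazyme_domains": p.total_domain_count,
        }
        row.update(p.class_counts())
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id")


def class_cv(
    table: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Coefficient of variation of class relative frequencies per lineage group.

    CV = sample (n-1) standard deviation / mean of a class's relative
    frequencies across the species of a group.  Groups of size one, and
    cells with zero mean, are reported as missing.

    ``grouping`` maps every species in ``table`` to its lineage group.
    """
    missing = [s for s in table.index if s not in grouping]
    if missing:
        raise ValueError(f"species without lineage group: {missing}")
    rel = table[[f"rel_{c}" for c in CLASS_LABELS]].copy()
    rel.columns = list(CLASS_LABELS)
    rel["group"] = [grouping[s] for s in table.index]

    def _cv(x: pd.Series) -> float:
        if len(x) < 2:
            return np.nan
        m = x.mean()
        if m == 0:
            return np.nan
        return x.std(ddof=1) / m

    return rel.groupby("group", sort=True).agg(_cv)
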