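"""Expression investment of CAZyme domain families.

The expression investment of a family in a tissue is the summed
replicate-averaged FPKM of all genes containing that family, under an
explicit repeat-collapse accounting rule: a gene's FPKM is added exactly
once to each *distinct* family it contains.  A gene annotated X-X-Y
therefore adds its FPKM once to family X and once to family Y -- repeats
of one family are ignored, but a mixed gene invests in every family it
combines.  Consequently the family totals in a tissue sum to

    sum_genes meanFPKM(gene) * n_distinct_families(gene),

which exceeds the plain FPKM sum whenever mixed genes are expressed (the
same holds for class totals: a mixed GT/GH gene contributes to both
classes).

FPKM is treated as an opaque nonnegative abundance.  Because its
normalization is experiment-specific, cross-species comparisons use only
the *direction* of tissue contrasts, never magnitudes.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnnotationsBySpecies, GeneAnnotation, class_of, sorted_families

CONCORDANCE_LABELS = (
    "same_xylem_up",
    "same_leaf_up",
    "discordant",
    "absent_in_one",
    "absent_in_both",
    "tied",
)


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue matrix of replicate-averaged FPKM.

    Arithmetic mean over the replicates present for each (gene, tissue);
    missing replicates have already been warned about by the reader.
    """
    if len(records) == 0:
        return pd.DataFrame()
    return records.pivot_table(
        index="gene_id", columns="tissue", values="fpkm", aggfunc="mean"
    )


def _gene_map(annotations: AnnotationsBySpecies | Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    if isinstance(annotations, Mapping):
        genes: Iterable[GeneAnnotation] = (
            g for gs in annotations.values() for g in gs
        )
    else:
        genes = annotations
    return {g.gene_id: g for g in genes}


def expressed_genes(
    matrix: pd.DataFrame,
    annotations: AnnotationsBySpecies | Sequence[GeneAnnotation],
    threshold: float = 0.0,
) -> dict:
    """CAZyme genes expressed above ``threshold`` in at least one tissue.

    Only annotated (CAZyme) genes are considered; the expression matrix
    may cover the whole transcriptome.  Returns the gene set, its count,
    and its percentage of all annotated CAZyme genes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    genes = _gene_map(annotations)
    present = [g for g in genes if g in matrix.index]
    expressed = {
        g for g in present if (matrix.loc[g].fillna(0.0) > threshold).any()
    }
    n_cazyme = len(genes)
    return {
        "genes": expressed,
        "n_expressed": len(expressed),
        "n_cazyme_genes": n_cazyme,
        "pct_expressed": len(expressed) / n_cazyme * 100.0 if n_cazyme else math.nan,
    }


def family_investment(
    matrix: pd.DataFrame,
    annotations: AnnotationsBySpecies | Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Family x tissue expression-investment table.

    For each gene and tissue, the gene's mean FPKM is added once to every
    distinct family the gene contains.  Genes in the matrix without
    annotation are ignored; annotated genes without expression rows
    contribute nothing.
    """
    genes = _gene_map(annotations)
    tissues = list(matrix.columns)
    families = sorted_families(f for g in genes.values() for f in g.distinct_families)
    table = pd.DataFrame(0.0, index=pd.Index(families, name="family"), columns=tissues)
    common = [g for g in matrix.index if g in genes]
    for gene_id in common:
        fpkm = matrix.loc[gene_id].fillna(0.0)
        for fam in genes[gene_id].distinct_families:
            table.loc[fam] += fpkm
    return table


def class_investment(table: pd.DataFrame) -> pd.DataFrame:
    """Class x tissue marginals of a family investment table.

    Families partition into classes, so class totals sum to the family
    totals; note a mixed GT/GH gene contributes to both class totals via
    its two family entries (a consequence of the distinct-family rule).
    """
    classes = pd.Series([class_of(f) for f in table.index], index=table.index)
    return table.groupby(classes, sort=False).sum()


def proportional_investment(table: pd.DataFrame, by_class: bool = False) -> pd.DataFrame:
    """Share (%) of each family's (or class's) investment per tissue.

    Shares are computed against the column sum of the investment table
    itself, so printed shares are internally consistent and sum to 100
    within each tissue.  Tissues with zero total report missing.
    """
    t = class_investment(table) if by_class else table
    totals = t.sum(axis=0)
    out = t.divide(totals.where(totals > 0), axis=1) * 100.0
    return out


def tissue_ratio(
    table: pd.DataFrame, family: str, tissue_a: str, tissue_b: str
) -> float:
    """Investment ratio of ``tissue_a`` over ``tissue_b`` for one family.

    Full precision is returned (round for reporting).  A zero denominator
    yields ``inf`` with a warning.
    """
    a = float(table.loc[family, tissue_a])
    b = float(table.loc[family, tissue_b])
    if b == 0:
        warnings.warn(
            f"{family}: zero investment in {tissue_b}; ratio is infinite",
            stacklevel=2,
        )
        return math.inf
    return a / b


def concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    tissue_pair_a: tuple[str, str],
    tissue_pair_b: Optional[tuple[str, str]] = None,
) -> pd.DataFrame:
    """Direction concordance of xylem-vs-leaf investment between two species.

    Only the sign of (xylem - leaf) is compared within each species;
    FPKM magnitudes are never compared across species because their
    normalization is experiment-specific.  ``tissue_pair_*`` name the
    (xylem-like, leaf-like) columns in each table.

    Labels per family: ``same_xylem_up`` / ``same_leaf_up`` when both
    species agree on direction; ``discordant`` when they disagree;
    ``absent_in_one`` / ``absent_in_both`` when a family has zero
    investment in both tissues of a species; ``tied`` when a species
    shows exactly equal investment in the two tissues (a degenerate case
    arising only in noise-free synthetic data).
    """
    if tissue_pair_b is None:
        tissue_pair_b = tissue_pair_a
    for table, pair in ((table_a, tissue_pair_a), (table_b, tissue_pair_b)):
        missing = [t for t in pair if t not in table.columns]
        if missing:
            raise KeyError(f"tissues not in table: {missing}")
    families = sorted_families(set(table_a.index) | set(table_b.index))
    rows = []
    for fam in families:
        d = {}
        for side, (table, pair) in zip(
            "ab", ((table_a, tissue_pair_a), (table_b, tissue_pair_b))
        ):
            if fam in table.index:
                x = float(table.loc[fam, pair[0]])
                l = float(table.loc[fam, pair[1]])
                d[side] = None if x == l == 0 else np.sign(x - l)
            else:
                d[side] = None
        absent = sum(v is None for v in d.values())
        if absent == 2:
            label = "absent_in_both"
        elif absent == 1:
            label = "absent_in_one"
        elif d["a"] == 0 or d["b"] == 0:
            label = "tied"
        elif d["a"] == d["b"]:
            label = "same_xylem_up" if d["a"] > 0 else "same_leaf_up"
        else:
            label = "discordant"
        rows.append({"family": fam, "label": label})
    return pd.DataFrame(rows).set_index("family")
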