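"""Bundled reference data.

The package ships a small census of CAZyme gene and domain content for
twenty-two sequenced plant genomes spanning green algae, a moss, a
lycophyte, monocots and eudicots, as published for dbCAN annotations of
Phytozome v8.0 gene models.  It records, per species: genome size, total
annotated genes, CAZyme gene count, the percentage of CAZyme genes, the
reported CAZyme domain total, and per-class domain counts (GT, GH, PL,
CE, CBM).

A handful of published rows are internally inconsistent: their per-class
counts do not sum to the reported domain total.  ``load_plant_census``
exposes this as a ``class_sum_consistent`` column rather than silently
reconciling the numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import CLASS_LABELS, GenomeSummary


def load_plant_census() -> pd.DataFrame:
    """Load the 22-genome plant CAZyme census.

    Returns a DataFrame indexed by ``species_id`` with columns
    ``organism, lineage_group, genome_mbp, total_genes, cazyme_genes,
    pct_cazyme_genes, cazyme_domains, GT, GH, PL, CE, CBM,
    class_sum_consistent``.
    """
    ref = resources.files("cazykit.data").joinpath("plant_cazyme_census.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="species_id")
    df["class_sum_consistent"] = df[list(CLASS_LABELS)].sum(axis=1) == df["cazyme_domains"]
    return df


def census_summaries(census: pd.DataFrame | None = None) -> dict[str, GenomeSummary]:
    """Genome summaries (species, gene total, lineage group) from the census."""
    if census is None:
        census = load_plant_census()
    return {
        sp: GenomeSummary(
            species_id=sp,
            total_genes=int(row.total_genes),
            lineage_group=str(row.lineage_group),
        )
        for sp, row in census.iterrows()
    }
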