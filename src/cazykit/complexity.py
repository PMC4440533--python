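"""Gene-level complexity of CAZyme domain content.

Complexity looks *within* genes: how many CAZyme domains a gene carries,
whether multi-domain genes are repeats of one family (``repeat_only``)
or combine distinct families (``mixed``), the distribution of per-gene
domain multiplicity (heavy-tailed, approximately power-law), and the
catalog of distinct-family combinations compared across species.

A combination's identity is the unordered set of distinct families in a
mixed gene; domain order and within-gene repeats are ignored, matching
how such combinations are conventionally reported (e.g. CBM43+GH17).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnnotationsBySpecies, GeneAnnotation, combo_label

CATEGORIES = ("single", "repeat_only", "mixed")


def classify_genes(annotations: AnnotationsBySpecies) -> pd.DataFrame:
    """Per-gene complexity records.

    Columns: ``species_id, gene_id, n_domains, n_distinct_families,
    category`` where category is ``single`` (one domain), ``repeat_only``
    (>= 2 domains, one family) or ``mixed`` (>= 2 distinct families) --
    a partition of all CAZyme genes.
    """
    rows = [
        {
            "species_id": species,
            "gene_id": g.gene_id,
            "n_domains": g.n_domains,
            "n_distinct_families": len(g.distinct_families),
            "category": g.category,
        }
        for species, genes in annotations.items()
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=["species_id", "gene_id", "n_domains", "n_distinct_families", "category"],
    )


def category_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species fraction of genes in each complexity category.

    Also reports ``multidomain_fraction`` (genes with >= 2 domains) and
    ``repeat_given_multidomain`` (share of multi-domain genes that are
    repeats of a single family) -- the two headline repeat statistics.
    """
    out = []
    for species, grp in records.groupby("species_id", sort=False):
        n = len(grp)
        counts = grp["category"].value_counts()
        multi = n - counts.get("single", 0)
        row = {"species_id": species, "n_genes": n}
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = counts.get(cat, 0) / n if n else np.nan
        row["multidomain_fraction"] = multi / n if n else np.nan
        row["repeat_given_multidomain"] = (
            counts.get("repeat_only", 0) / multi if multi else np.nan
        )
        out.append(row)
    return pd.DataFrame(out).set_index("species_id")


def multiplicity_distribution(records: pd.DataFrame) -> pd.Series:
    """Counts of genes having k CAZyme domains, k = 1, 2, ...

    The counts sum to the number of CAZyme genes.  Empty input yields an
    empty histogram.
    """
    if len(records) == 0:
        return pd.Series(dtype=int, name="genes")
    dist = records["n_domains"].value_counts().sort_index()
    dist.index.name = "n_domains"
    return dist.rename("genes")


def families_in_high_multiplicity_genes(
    annotations: AnnotationsBySpecies, min_domains: int = 5
) -> dict[str, set[str]]:
    """Distinct families of every gene with at least ``min_domains`` domains.

    Keyed ``"species/gene"``.  Used to flag observations of the form
    "every gene with five or more domains contains family X" (in plant
    genomes that family is GT41, the O-GlcNAc transferase repeat).
    """
    return {
        f"{species}/{g.gene_id}": set(g.distinct_families)
        for species, genes in annotations.items()
        for g in genes
        if g.n_domains >= min_domains
    }


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float  # log10 of the k = 1 level
    r_squared: float


def fit_power_law(distribution: Mapping[int, int] | pd.Series) -> PowerLawFit:
    """Least-squares power-law fit of a multiplicity histogram.

    Ordinary least squares of log10(count) on log10(k) over the nonzero
    bins; zero-count bins are excluded rather than imputed.  The slope is
    the power-law exponent (expected negative for heavy-tailed gene
    complexity).  R-squared is 1 - SS_res/SS_tot, with an exact fit
    (SS_res = 0) reported as 1 even when the counts are constant.
    """
    items = [(float(k), float(v)) for k, v in dict(distribution).items() if v > 0]
    if len(items) < 2:
        raise ValueError("insufficient support: need >= 2 nonzero bins")
    k = np.log10([i[0] for i in items])
    y = np.log10([i[1] for i in items])
    slope, intercept = np.polyfit(k, y, 1)
    resid = y - (slope * k + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-18 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


@dataclass
class CombinationCatalog:
    """Multiset of distinct-family combinations found in one species' mixed genes."""

    species_id: str
    combos: Counter  # frozenset[str] -> number of genes bearing exactly that set

    @property
    def n_mixed_genes(self) -> int:
        return sum(self.combos.values())

    def labels(self) -> dict[str, int]:
        """Counts keyed by canonical combination label, deterministically ordered."""
        items = sorted(
            ((combo_label(c), n) for c, n in self.combos.items()), key=lambda x: x[0]
        )
        return dict(items)


def combinations(annotations: AnnotationsBySpecies) -> dict[str, CombinationCatalog]:
    """Catalog distinct-family combinations of mixed genes, per species.

    Each mixed gene contributes its set of distinct families exactly once;
    repeats within the gene do not alter the combination's identity.  A
    gene with >= 3 distinct families is one combination of that size, not
    decomposed into pairs (see :func:`pairwise_projection`).
    """
    out = {}
    for species, genes in annotations.items():
        combos: Counter = Counter()
        for g in genes:
            fams = g.distinct_families
            if len(fams) >= 2:
                combos[fams] += 1
        out[species] = CombinationCatalog(species_id=species, combos=combos)
    return out


def pairwise_projection(catalog: CombinationCatalog) -> Counter:
    """Project combinations onto unordered family pairs.

    A gene with families {A, B, C} contributes one count to each of
    {A,B}, {A,C}, {B,C}.  Useful when comparing against reports that
    list combinations as pairs.
    """
    pairs: Counter = Counter()
    for combo, n in catalog.combos.items():
        for pair in iter_combinations(sorted(combo), 2):
            pairs[frozenset(pair)] += n
    return pairs


def compare_combinations(
    catalogs: Mapping[str, CombinationCatalog],
    species_sets: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict:
    """Shared and species-unique combinations within species groupings.

    For each named grouping (default: one grouping ``"all"`` containing
    every cataloged species), reports the combinations present in every
    member and, per member, those present in no other member.  Labels are
    canonical and deterministically ordered; occurrence counts ride along.
    """
    if len(catalogs) < 2:
        raise ValueError("compare_combinations requires >= 2 catalogs")
    if species_sets is None:
        species_sets = {"all": list(catalogs)}
    result: dict = {}
    for group_name, members in species_sets.items():
        unknown = [s for s in members if s not in catalogs]
        if unknown:
            raise KeyError(f"unknown species in grouping {group_name!r}: {unknown}")
        sets = {s: set(catalogs[s].combos) for s in members}
        shared = set.intersection(*sets.values()) if members else set()
        entry = {
            "shared": sorted(combo_label(c) for c in shared),
            "n_shared": len(shared),
            "unique": {},
        }
        for s in members:
            others = set().union(*(sets[o] for o in members if o != s)) if len(members) > 1 else set()
            uniq = sets[s] - others
            entry["unique"][s] = {
                "combinations": sorted(combo_label(c) for c in uniq),
                "counts": {
                    combo_label(c): catalogs[s].combos[c] for c in sorted(uniq, key=combo_label)
                },
                "n_unique": len(uniq),
            }
        result[group_name] = entry
    return result
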