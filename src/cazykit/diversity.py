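"""Diversity of CAZyme family repertoires across species.

Diversity asks which families each genome carries, irrespective of copy
number: the family-by-species presence/absence matrix, the "core" set of
families shared by every species of interest, lineage-restricted sets
(present in one group, absent in another), the occurrence spectrum (in
how many species each family occurs -- bimodal across green plants), and
the share of each genome's domain content carried by the core set.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .frequency import GenomeProfile
from .model import class_of, family_sort_key


def presence_matrix(profiles: Iterable[GenomeProfile]) -> pd.DataFrame:
    """Family x species boolean presence matrix.

    A family is present in a species iff its domain count there is
    positive.  Rows are ordered by (class, family number); columns keep
    the input species order.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("presence_matrix requires at least one profile")
    species = [p.species_id for p in profiles]
    families = sorted(
        {f for p in profiles for f, n in p.domain_count_by_family.items() if n > 0},
        key=family_sort_key,
    )
    data = {
        p.species_id: [p.domain_count_by_family.get(f, 0) > 0 for f in families]
        for p in profiles
    }
    return pd.DataFrame(data, index=pd.Index(families, name="family"), columns=species)


def _check_species(matrix: pd.DataFrame, subset: Iterable[str]) -> list[str]:
    subset = list(subset)
    unknown = [s for s in subset if s not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown species: {unknown}")
    return subset


def core_families(
    matrix: pd.DataFrame,
    subset: Optional[Iterable[str]] = None,
    absent_in: Optional[Iterable[str]] = None,
) -> list[str]:
    """Families present in every species of ``subset`` (default: all).

    With ``absent_in``, restrict further to families absent from every
    species of that set -- e.g. land-plant-specific families are present
    in all land plants and absent in both green algae.
    """
    subset = _check_species(matrix, matrix.columns if subset is None else subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    mask = matrix[subset].all(axis=1)
    if absent_in is not None:
        absent_in = _check_species(matrix, absent_in)
        if absent_in:
            mask &= ~matrix[absent_in].any(axis=1)
    return list(matrix.index[mask])


def occurrence_spectrum(matrix: pd.DataFrame) -> pd.Series:
    """Histogram of families over the number of species they occur in.

    Bins run 1..N (N = number of species); the bin values sum to the
    number of families.
    """
    n = matrix.shape[1]
    occ = matrix.sum(axis=1)
    return occ.value_counts().reindex(range(1, n + 1), fill_value=0).rename("families")


def restricted_families(matrix: pd.DataFrame, max_species: int = 2) -> pd.DataFrame:
    """Families found in at most ``max_species`` species, with class labels.

    These are the lineage-restricted mode of the (bimodal) occurrence
    spectrum; the default of 2 matches the usual "one or two species"
    reading of "restricted".
    """
    occ = matrix.sum(axis=1)
    fams = matrix.index[occ <= max_species]
    return pd.DataFrame(
        {
            "family": fams,
            "n_species": occ[fams].to_numpy(),
            "class": [class_of(f) for f in fams],
        }
    ).set_index("family")


def spectrum_mode_fractions(matrix: pd.DataFrame, edge: int = 2) -> dict[str, float]:
    """Fractions of families in the two modes of the occurrence spectrum.

    Reported descriptively: the fraction of families present in at most
    ``edge`` species and the fraction present in at least N - edge + 1
    species (N = species count).  No functional form is fitted.
    """
    n = matrix.shape[1]
    occ = matrix.sum(axis=1)
    total = len(occ)
    return {
        "restricted_fraction": float((occ <= edge).sum()) / total if total else np.nan,
        "ubiquitous_fraction": float((occ >= n - edge + 1).sum()) / total
        if total
        else np.nan,
    }


def core_share(
    profiles: Iterable[GenomeProfile], core: Sequence[str]
) -> pd.DataFrame:
    """Percent of each genome's domain content contributed by ``core`` families.

    Returns per-species shares plus the across-species mean and sample
    standard deviation (the headline "core families carry X% +/- Y% of
    domain content" statistic).  Species with no domains report missing.
    """
    core = set(core)
    rows = {}
    for p in profiles:
        total = p.total_domain_count
        in_core = sum(n for f, n in p.domain_count_by_family.items() if f in core)
        rows[p.species_id] = in_core / total * 100.0 if total > 0 else np.nan
    shares = pd.Series(rows, name="core_share_pct")
    out = shares.to_frame()
    out.attrs["mean"] = float(shares.mean())
    out.attrs["sd"] = float(shares.std(ddof=1)) if shares.notna().sum() > 1 else np.nan
    return out
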