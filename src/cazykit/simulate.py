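"""Seeded synthetic data with known ground truth.

The generator emulates the three inputs the pipeline consumes -- a
dbCAN-style domain annotation table, a genome summary table, and a
long-format replicate-level FPKM expression table -- with structure the
analyses assume, so every downstream stage can be scored against planted
truth without any external download:

* family pools per class sized like the plant CAZyme family inventory
  (72 GT, 92 GH, 13 PL, 16 CE, 38 CBM);
* a planted *core* set present in every species, a planted *restricted*
  set present in only one or two species (yielding a bimodal occurrence
  spectrum), and accessory families in intermediate numbers of species;
* per-gene domain multiplicity 1 with probability ``1 - p_multidomain``,
  otherwise a power-law tail on k >= 2; multi-domain genes are
  same-family repeats with probability ``p_repeat_given_multidomain``,
  else mixed-family combinations;
* high-multiplicity genes (>= 5 domains) carry GT41, mirroring the
  O-GlcNAc-transferase repeat structure observed in plant genomes;
* gene abundance drawn lognormal (the standard heavy-tailed stand-in
  for RNA-seq abundance), multiplied per tissue by planted family bias
  factors, with lognormal replicate noise.

Presence of every planted family in its member species is guaranteed by
seeding one single-domain gene per (species, family) before the random
draws, so set-recovery checks are exact rather than probabilistic.

Every draw flows from a single integer seed; identical seeds give
byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CLASS_LABELS,
    DomainHit,
    GeneAnnotation,
    GenomeSummary,
    combo_label,
    parse_family,
)

#: Land-plant CAZyme class ratio GT:GH:PL:CE:CBM (percent scale).
LAND_PLANT_CLASS_RATIO = (40.0, 30.0, 2.0, 18.0, 10.0)
#: Green-algal class ratio, a markedly different repertoire composition.
GREEN_ALGAE_CLASS_RATIO = (57.0, 14.5, 0.6, 10.0, 17.0)

#: Family pool sizes per class, matching the plant family inventory.
DEFAULT_FAMILY_POOLS = {"GT": 72, "GH": 92, "PL": 13, "CE": 16, "CBM": 38}

DEFAULT_TISSUES = (
    "young_leaf",
    "mature_leaf",
    "shoot_tips",
    "flowers",
    "immature_xylem",
    "phloem",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the observed structure of plant CAZyme repertoires:
    2,000 CAZyme genes per genome of 30,000 genes, class ratio
    40:30:2:18:10 (GT:GH:PL:CE:CBM), 65 core and 74 restricted families
    out of a 231-family pool, 17% multi-domain genes of which 60% are
    same-family repeats, six tissues with three biological replicates, a
    fifth of genes silent in every tissue (roughly four fifths of CAZyme
    genes are captured by real tissue atlases), and xylem-biased
    secondary-cell-wall glycosyltransferase families (GT2, GT8, GT43,
    GT47) against a leaf-biased GT1.
    """

    seed: int = 0
    n_species: int = 5
    n_genes: int = 30_000
    n_cazyme_genes: int = 2_000
    class_ratio: tuple[float, ...] = LAND_PLANT_CLASS_RATIO
    family_pool_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_POOLS)
    )
    core_family_count: int = 65
    restricted_family_count: int = 74
    restricted_max_species: int = 2
    p_multidomain: float = 0.17
    p_repeat_given_multidomain: float = 0.60
    multiplicity_exponent: float = 2.5
    max_domains: int = 7
    gt41_rule: bool = True
    lineage_group: str = "eudicot"
    species_ids: Optional[tuple[str, ...]] = None
    # expression design
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 3
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    replicate_log_sd: float = 0.5
    p_silent: float = 0.2
    xylem_tissue: str = "immature_xylem"
    leaf_tissue: str = "young_leaf"
    xylem_biased_families: tuple[str, ...] = ("GT2", "GT8", "GT43", "GT47")
    leaf_biased_families: tuple[str, ...] = ("GT1",)
    bias_factor: float = 4.0

    def validate(self) -> None:
        if not 0 <= self.p_multidomain <= 1:
            raise ValueError("p_multidomain must be in [0, 1]")
        if not 0 <= self.p_repeat_given_multidomain <= 1:
            raise ValueError("p_repeat_given_multidomain must be in [0, 1]")
        if not 0 <= self.p_silent < 1:
            raise ValueError("p_silent must be in [0, 1)")
        if len(self.class_ratio) != len(CLASS_LABELS):
            raise ValueError("class_ratio needs five weights (GT, GH, PL, CE, CBM)")
        if min(self.class_ratio) < 0 or sum(self.class_ratio) == 0:
            raise ValueError("class weights must be nonnegative, not all zero")
        # classes with zero weight contribute no families at all
        pool_total = sum(
            n
            for c, n in self.family_pool_sizes.items()
            if self.class_ratio[CLASS_LABELS.index(c)] > 0
        )
        if self.core_family_count + self.restricted_family_count > pool_total:
            raise ValueError(
                f"core ({self.core_family_count}) + restricted "
                f"({self.restricted_family_count}) families exceed the usable pool "
                f"of {pool_total}"
            )
        if self.n_cazyme_genes > self.n_genes:
            raise ValueError("n_cazyme_genes cannot exceed n_genes")
        if self.max_domains < 2:
            raise ValueError("max_domains must be >= 2")

    def species_list(self) -> list[str]:
        if self.species_ids is not None:
            return list(self.species_ids)
        return [f"Sim{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream recovery check."""

    core: set[str]
    restricted: dict[str, list[str]]  # family -> member species
    accessory: dict[str, list[str]]
    gene_category: dict[str, str]  # "species/gene" -> single|repeat_only|mixed
    combinations: dict[str, dict[str, int]]  # species -> combo label -> count
    family_bias: dict[str, dict[str, float]]  # family -> tissue -> factor
    class_ratio: tuple[float, ...]
    multiplicity_exponent: float

    def families_of(self, species: str) -> set[str]:
        fams = set(self.core)
        fams |= {f for f, sps in self.restricted.items() if species in sps}
        fams |= {f for f, sps in self.accessory.items() if species in sps}
        return fams

    def to_json(self) -> str:
        d = asdict(self)
        d["core"] = sorted(self.core)
        return json.dumps(d, indent=1, sort_keys=True)


def power_law_consistent_p_multidomain(exponent: float, max_domains: int) -> float:
    """``p_multidomain`` making the full multiplicity histogram power-law.

    The generator draws k = 1 with probability ``1 - p_multidomain`` and
    the k >= 2 tail proportional to ``k**-exponent``.  With this value of
    ``p_multidomain`` the whole distribution over k = 1..max_domains is
    exactly proportional to ``k**-exponent``, which is the regime in
    which the fitted log-log slope estimates ``-exponent``.
    """
    k = np.arange(1, max_domains + 1, dtype=float)
    w = k ** (-exponent)
    return float(w[1:].sum() / w.sum())


def _allocate_core(
    config: SimulationConfig, pools: dict[str, int]
) -> dict[str, int]:
    """Largest-remainder allocation of core slots across classes (by pool size)."""
    total = sum(pools.values())
    exact = {c: config.core_family_count * pools[c] / total for c in CLASS_LABELS}
    alloc = {c: int(exact[c]) for c in CLASS_LABELS}
    remainder = config.core_family_count - sum(alloc.values())
    order = sorted(CLASS_LABELS, key=lambda c: exact[c] - alloc[c], reverse=True)
    for c in order[:remainder]:
        alloc[c] += 1
    for c in CLASS_LABELS:
        alloc[c] = min(alloc[c], pools[c])
    return alloc


def _compensated_class_probs(
    config: SimulationConfig,
    by_class: dict[str, list[str]],
    n_random: int,
    gt41_available: bool,
) -> np.ndarray:
    """Class-draw probabilities that realize the target ratio in expectation.

    Two parts of the design add domain mass outside the ratio-driven
    draws: the guaranteed-presence block (one single-domain gene per
    planted family, whose class mix follows the family pools) and, when
    the GT41 rule is active, the forced GT41 content of genes with five
    or more domains.  This solves for draw weights such that the
    *expected* realized class marginal equals the planted ratio; the
    weights are clipped at zero when a target is infeasible (e.g. more
    guaranteed mass in a class than its target share allows).
    """
    t = np.asarray(config.class_ratio, dtype=float)
    usable = np.array([len(by_class[c]) > 0 for c in CLASS_LABELS])
    t = np.where(usable, t, 0.0)
    t = t / t.sum()
    d_guar = np.array([len(by_class[c]) for c in CLASS_LABELS], dtype=float)

    pm = config.p_multidomain
    pr = config.p_repeat_given_multidomain
    k = np.arange(2, config.max_domains + 1, dtype=float)
    pk = k ** (-config.multiplicity_exponent)
    pk = pk / pk.sum()
    # E[1/n_distinct] for mixed genes: 2 distinct when k = 2, else 2 or 3
    e_inv_m = np.where(k == 2, 0.5, 5.0 / 12.0)
    high = k >= 5
    if gt41_available and high.any():
        forced = pm * float(
            np.sum(pk[high] * k[high] * (pr + (1 - pr) * e_inv_m[high]))
        )
        ratio_mass = (1 - pm) + pm * float(
            np.sum(pk[~high] * k[~high])
            + np.sum(pk[high] * k[high] * (1 - pr) * (1 - e_inv_m[high]))
        )
    else:
        forced = 0.0
        ratio_mass = (1 - pm) + pm * float(np.sum(pk * k))

    total = d_guar.sum() + n_random * (forced + ratio_mass)
    w = t * total - d_guar
    w[CLASS_LABELS.index("GT")] -= n_random * forced
    w = np.clip(w, 0.0, None)
    w = np.where(usable, w, 0.0)
    if w.sum() == 0:
        w = t
    return w / w.sum()


def _draw_multiplicity(config: SimulationConfig, rng: np.random.Generator) -> int:
    if rng.random() >= config.p_multidomain:
        return 1
    k = np.arange(2, config.max_domains + 1, dtype=float)
    w = k ** (-config.multiplicity_exponent)
    return int(rng.choice(k, p=w / w.sum()))


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[dict[str, list[GeneAnnotation]], dict[str, GenomeSummary], GroundTruth]:
    """Generate annotations, genome summaries and planted ground truth."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    species = config.species_list()
    n_sp = len(species)

    ratio = np.asarray(config.class_ratio, dtype=float)
    pool_sizes = {
        c: (config.family_pool_sizes.get(c, 0) if ratio[i] > 0 else 0)
        for i, c in enumerate(CLASS_LABELS)
    }
    pools = {c: [f"{c}{i + 1}" for i in range(n)] for c, n in pool_sizes.items()}
    all_families = [f for c in CLASS_LABELS for f in pools[c]]

    # families that downstream checks rely on being everywhere
    forced_core = set()
    if config.gt41_rule and "GT41" in all_families:
        forced_core.add("GT41")
    for fam in (*config.xylem_biased_families, *config.leaf_biased_families):
        if fam in all_families:
            forced_core.add(fam)

    if len(forced_core) > config.core_family_count:
        raise ValueError(
            f"core_family_count={config.core_family_count} is smaller than the "
            f"{len(forced_core)} families the design forces into the core"
        )
    alloc = _allocate_core(config, pool_sizes)
    core: set[str] = set(forced_core)
    for c in CLASS_LABELS:
        candidates = [f for f in pools[c] if f not in core]
        want = alloc[c] - sum(1 for f in core if f in pools[c])
        want = max(0, min(want, len(candidates)))
        core |= {str(f) for f in rng.choice(candidates, size=want, replace=False)}
    # top up to the exact requested count
    rest = [f for f in all_families if f not in core]
    while len(core) < config.core_family_count:
        core.add(rest.pop(int(rng.integers(len(rest)))))
    rest = [f for f in all_families if f not in core]

    restricted_fams = [
        str(f) for f in rng.choice(rest, size=config.restricted_family_count, replace=False)
    ]
    restricted: dict[str, list[str]] = {}
    for fam in restricted_fams:
        k = int(rng.integers(1, min(config.restricted_max_species, n_sp) + 1))
        restricted[fam] = sorted(str(s) for s in rng.choice(species, size=k, replace=False))

    accessory: dict[str, list[str]] = {}
    acc_lo = min(config.restricted_max_species + 1, n_sp)
    acc_hi = max(acc_lo, n_sp - 1)
    for fam in rest:
        if fam in restricted:
            continue
        k = int(rng.integers(acc_lo, acc_hi + 1))
        accessory[fam] = sorted(str(s) for s in rng.choice(species, size=k, replace=False))

    membership: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        fams = sorted(core)
        fams += [f for f, sps in accessory.items() if sp in sps]
        fams += [f for f, sps in restricted.items() if sp in sps]
        by_class = {c: [f for f in fams if parse_family(f).class_label == c] for c in CLASS_LABELS}
        membership[sp] = by_class

    annotations: dict[str, list[GeneAnnotation]] = {}
    gene_category: dict[str, str] = {}
    combos: dict[str, dict[str, int]] = {}

    for sp in species:
        by_class = membership[sp]
        available = [f for c in CLASS_LABELS for f in by_class[c]]
        if len(available) > config.n_cazyme_genes:
            raise ValueError(
                f"{sp}: {len(available)} planted families exceed "
                f"{config.n_cazyme_genes} CAZyme genes"
            )
        n_random = config.n_cazyme_genes - len(available)
        class_p = _compensated_class_probs(
            config, by_class, n_random, config.gt41_rule and "GT41" in available
        )

        def draw_family() -> str:
            c = CLASS_LABELS[int(rng.choice(len(CLASS_LABELS), p=class_p))]
            fams = by_class[c]
            return fams[int(rng.integers(len(fams)))]

        genes: list[GeneAnnotation] = []
        sp_combos: dict[frozenset, int] = {}

        def add_gene(families_in_order: list[str]) -> None:
            gid = f"{sp}_g{len(genes) + 1:05d}"
            hits = [DomainHit(family=parse_family(f)) for f in families_in_order]
            gene = GeneAnnotation(species_id=sp, gene_id=gid, hits=hits)
            genes.append(gene)
            gene_category[f"{sp}/{gid}"] = gene.category
            if gene.category == "mixed":
                key = frozenset(gene.distinct_families)
                sp_combos[key] = sp_combos.get(key, 0) + 1

        # guaranteed presence of every planted family
        for fam in available:
            add_gene([fam])

        for _ in range(config.n_cazyme_genes - len(available)):
            k = _draw_multiplicity(config, rng)
            if k == 1:
                add_gene([draw_family()])
                continue
            is_repeat = (
                rng.random() < config.p_repeat_given_multidomain
                or len(available) < 2
            )
            force_gt41 = config.gt41_rule and k >= 5 and "GT41" in available
            if is_repeat:
                fam = "GT41" if force_gt41 else draw_family()
                add_gene([fam] * k)
            else:
                n_distinct = 2 if k == 2 else int(rng.integers(2, min(k, 3) + 1))
                n_distinct = min(n_distinct, len(available))
                fams: list[str] = []
                while len(fams) < n_distinct:
                    f = draw_family()
                    if f not in fams:
                        fams.append(f)
                if force_gt41 and "GT41" not in fams:
                    fams[0] = "GT41"
                    fams = list(dict.fromkeys(fams))
                arch = list(fams)
                for _ in range(k - len(fams)):
                    arch.append(fams[int(rng.integers(len(fams)))])
                arch = [arch[i] for i in rng.permutation(len(arch))]
                add_gene(arch)

        annotations[sp] = genes
        combos[sp] = {
            combo_label(c): n
            for c, n in sorted(sp_combos.items(), key=lambda kv: combo_label(kv[0]))
        }

    summaries = {
        sp: GenomeSummary(
            species_id=sp, total_genes=config.n_genes, lineage_group=config.lineage_group
        )
        for sp in species
    }

    bias: dict[str, dict[str, float]] = {}
    for fam in config.xylem_biased_families:
        bias[fam] = {config.xylem_tissue: config.bias_factor}
    for fam in config.leaf_biased_families:
        bias.setdefault(fam, {})[config.leaf_tissue] = config.bias_factor

    truth = GroundTruth(
        core=core,
        restricted=restricted,
        accessory=accessory,
        gene_category=gene_category,
        combinations=combos,
        family_bias=bias,
        class_ratio=tuple(float(x) for x in ratio / ratio.sum() * 100.0),
        multiplicity_exponent=config.multiplicity_exponent,
    )
    return annotations, summaries, truth


def simulate_expression(
    config: SimulationConfig,
    annotations: dict[str, list[GeneAnnotation]],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Generate a replicate-level FPKM table for every annotated gene.

    Mean FPKM per gene and tissue is a lognormal baseline times the
    product of the gene's distinct families' planted tissue-bias factors;
    each replicate multiplies the mean by lognormal noise of log-sd
    ``replicate_log_sd`` (0 gives noise-free replicates).  A fraction
    ``p_silent`` of genes is silent in every tissue, emulating genes a
    tissue atlas never captures.
    """
    rng = np.random.default_rng([int(config.seed), 2])
    rows = []
    for sp in annotations:
        for gene in annotations[sp]:
            silent = rng.random() < config.p_silent
            base = float(
                rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
            )
            if silent:
                base = 0.0
            for tissue in config.tissues:
                factor = 1.0
                for fam in gene.distinct_families:
                    factor *= truth.family_bias.get(fam, {}).get(tissue, 1.0)
                mean = base * factor
                for rep in range(1, config.n_replicates + 1):
                    noise = (
                        float(rng.lognormal(0.0, config.replicate_log_sd))
                        if config.replicate_log_sd > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "gene_id": gene.gene_id,
                            "tissue": tissue,
                            "replicate": rep,
                            "fpkm": mean * noise,
                        }
                    )
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate", "fpkm"])
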