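"""Recurrent mass-selection programs: genomic selection (two cycles per year,
annual model updating, selection after pollination in cycle 1 and before
pollination in cycle 2) and phenotypic selection (one cycle per year,
female-side selection only).

Population sizes default to the experimental scheme: 192 plants in cycle 1,
48 in cycle 2, 12 selected, a 40-plant bottleneck to create the initial
population, and 36-plant seed-stock samples for common-garden evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import GBLUPModel, expected_index, fit_gblup
from .index import SelectionIndexModel, IndexValue, index_scores
from .simulate import (
    GeneticMap,
    GenotypeMatrix,
    Population,
    TraitArchitecture,
    bottleneck_then_expand,
    observe_markers,
    phenotype,
    random_mate,
    simulate_founders,
)

__all__ = [
    "SchemeConfig",
    "CycleRecord",
    "ProgramResult",
    "rank_individuals",
    "apply_mortality",
    "update_marker_panel",
    "selection_overlap",
    "run_gs_cycle1",
    "run_gs_cycle2",
    "run_ps_cycle",
    "run_program",
    "true_index",
]


@dataclass
class SchemeConfig:
    scheme: str = "GS"              # "GS" | "PS"
    years: int = 3
    gs_cycle1_size: int = 192
    gs_cycle2_size: int = 48
    ps_size: int = 192
    n_selected: int = 12
    update_policy: str = "annual"   # annual | never | every_cycle
    bottleneck_k: int = 40
    seed: int = 0
    mortality_rate: float = 0.0
    founder_size: int = 200
    eval_sample_size: int = 36
    dominant_fraction: float | None = None  # None: use map modes
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.scheme not in {"GS", "PS"}:
            raise ValueError("scheme must be 'GS' or 'PS'")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        sizes = [self.gs_cycle1_size, self.gs_cycle2_size, self.ps_size]
        if any(self.n_selected > s for s in sizes):
            raise ValueError("n_selected must not exceed any cycle size")
        if self.update_policy not in {"annual", "never", "every_cycle"}:
            raise ValueError("unknown update policy")
        if not 0.0 <= self.mortality_rate < 1.0:
            raise ValueError("mortality_rate must be in [0, 1)")


@dataclass
class CycleRecord:
    cycle_label: str
    selected_ids: list
    selection_source: str           # observed | expected | predicted
    seed_parent_ids: list
    pollen_parent_ids: list
    model_version: str
    panel_size: int


@dataclass
class ProgramResult:
    config: SchemeConfig
    populations: dict               # label -> Population ("initial", "post_gs1", ...)
    records: list
    models_by_version: dict         # version label -> {trait: GBLUPModel}
    genotypes: dict                 # cycle label -> GenotypeMatrix (panel-restricted)
    phenotypes: dict                # cycle label -> DataFrame (cycle-1 phenotyping)
    panel_sizes: dict               # cycle label -> panel size used
    eval_phenotypes: dict           # label -> DataFrame, common-garden samples
    eval_populations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# selection primitives
# ---------------------------------------------------------------------------


def rank_individuals(values: list[IndexValue] | pd.Series) -> list:
    """Ids ordered best-first; ties broken by individual id (stable, documented)."""
    if isinstance(values, pd.Series):
        items = list(values.items())
    else:
        items = [(v.individual_id, v.value) for v in values]
    return [i for i, _ in sorted(items, key=lambda kv: (-kv[1], str(kv[0])))]


def apply_mortality(ranked_ids: list, n_selected: int, deaths=frozenset()) -> list:
    """Fill the selected set in rank order, skipping dead plants."""
    if len(set(ranked_ids)) != len(ranked_ids):
        raise ValueError("duplicate ids in ranking")
    survivors = [i for i in ranked_ids if i not in set(deaths)]
    if len(survivors) < n_selected:
        raise ValueError("fewer survivors than the number to select")
    return survivors[:n_selected]


def update_marker_panel(panel: list, geno: GenotypeMatrix) -> list:
    """Drop markers monomorphic in the current population (panel order kept)."""
    frame = geno.to_frame()
    keep = []
    for m in panel:
        if m not in frame.columns:
            continue
        col = frame[m].dropna()
        if col.nunique() > 1:
            keep.append(m)
    if not keep:
        raise ValueError("marker panel became empty")
    return keep


def selection_overlap(rank_a: list, rank_b: list, k: int) -> int:
    """Size of the intersection of the top-k sets of two rankings."""
    if len(set(rank_a)) != len(rank_a) or len(set(rank_b)) != len(rank_b):
        raise ValueError("duplicate ids within a ranking")
    if k > len(rank_a) or k > len(rank_b):
        raise ValueError("k exceeds ranking length")
    return len(set(rank_a[:k]) & set(rank_b[:k]))


def _draw_deaths(ids, rate, rng):
    if rate <= 0:
        return frozenset()
    return frozenset(np.asarray(ids, dtype=object)[rng.random(len(ids)) < rate])


def true_index(pop: Population, arch: TraitArchitecture,
               index_model: SelectionIndexModel) -> pd.Series:
    """Index applied to true genetic values (simulation ground truth)."""
    return index_scores(arch.genetic_values(pop), index_model)


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------


def run_gs_cycle1(
    pop: Population,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    index_model: SelectionIndexModel,
    config: SchemeConfig,
    panel: list,
    prior_models: dict | None,
    cycle_label: str,
    seed: int,
    train: bool = True,
):
    """Genotype + phenotype the full population, train/update models, select
    the top plants AFTER pollination (dams = selected, sires = everyone)."""
    if pop.n != config.gs_cycle1_size:
        raise ValueError("population size does not match gs_cycle1_size")
    rng = np.random.default_rng(seed)
    geno = observe_markers(pop, gmap, config.dominant_fraction,
                           config.missing_rate, seed=int(rng.integers(2**31 - 1)))
    panel = update_marker_panel(panel, geno)
    geno_p = geno.subset_markers(panel)
    phenos = phenotype(pop, arch, seed=int(rng.integers(2**31 - 1)))
    if train or prior_models is None:
        models = {
            t: fit_gblup(geno_p, phenos[t].to_numpy(), t, panel_version=cycle_label)
            for t in index_model.trait_names
        }
        version = cycle_label
    else:
        models = prior_models
        version = next(iter(prior_models.values())).panel_version
    exp_idx = expected_index(models, geno_p, index_model, source="expected")
    ranked = rank_individuals(exp_idx)
    deaths = _draw_deaths(pop.ids, config.mortality_rate, rng)
    selected = apply_mortality(ranked, config.n_selected, deaths)
    offspring = random_mate(
        pop, config.gs_cycle2_size, gmap, self_incompatible=True,
        dams=selected, sires=None, seed=int(rng.integers(2**31 - 1)),
        generation=f"post_{cycle_label.lower()}",
    )
    record = CycleRecord(cycle_label, selected, "expected", selected,
                         list(pop.ids), version, len(panel))
    return offspring, models, panel, geno_p, phenos, record


def run_gs_cycle2(
    pop: Population,
    gmap: GeneticMap,
    models: dict,
    index_model: SelectionIndexModel,
    config: SchemeConfig,
    panel: list,
    cycle_label: str,
    seed: int,
):
    """Genotype only; select the top plants BEFORE pollination and mate among
    the selected set only (both parent sexes selected)."""
    if pop.n != config.gs_cycle2_size:
        raise ValueError("population size does not match gs_cycle2_size")
    rng = np.random.default_rng(seed)
    geno = observe_markers(pop, gmap, config.dominant_fraction,
                           config.missing_rate, seed=int(rng.integers(2**31 - 1)))
    geno_p = geno.subset_markers(panel)
    pred_idx = expected_index(models, geno_p, index_model, source="predicted")
    ranked = rank_individuals(pred_idx)
    deaths = _draw_deaths(pop.ids, config.mortality_rate, rng)
    selected = apply_mortality(ranked, config.n_selected, deaths)
    offspring = random_mate(
        pop, config.gs_cycle1_size, gmap, self_incompatible=True,
        dams=selected, sires=selected, seed=int(rng.integers(2**31 - 1)),
        generation=f"post_{cycle_label.lower()}",
    )
    version = next(iter(models.values())).panel_version
    record = CycleRecord(cycle_label, selected, "predicted", selected,
                         selected, version, len(panel))
    return offspring, geno_p, record


def run_ps_cycle(
    pop: Population,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    index_model: SelectionIndexModel,
    config: SchemeConfig,
    cycle_label: str,
    seed: int,
):
    """Observed-index selection after pollination (female side only)."""
    if pop.n != config.ps_size:
        raise ValueError("population size does not match ps_size")
    rng = np.random.default_rng(seed)
    phenos = phenotype(pop, arch, seed=int(rng.integers(2**31 - 1)))
    obs_idx = index_scores(phenos, index_model)
    ranked = rank_individuals(obs_idx)
    deaths = _draw_deaths(pop.ids, config.mortality_rate, rng)
    selected = apply_mortality(ranked, config.n_selected, deaths)
    offspring = random_mate(
        pop, config.ps_size, gmap, self_incompatible=True,
        dams=selected, sires=None, seed=int(rng.integers(2**31 - 1)),
        generation=f"post_{cycle_label.lower()}",
    )
    record = CycleRecord(cycle_label, selected, "observed", selected,
                         list(pop.ids), "", 0)
    return offspring, phenos, record


# ---------------------------------------------------------------------------
# whole program
# ---------------------------------------------------------------------------


def run_program(
    config: SchemeConfig,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    index_model: SelectionIndexModel,
    founders: Population | None = None,
) -> ProgramResult:
    """Bottleneck, then ``years`` of GS (two cycles/year) or PS (one cycle/year),
    with seed-stock samples of the initial and every post-cycle population
    phenotyped in one shared environment at the end."""
    rng = np.random.default_rng(config.seed)

    def next_seed():
        return int(rng.integers(2**31 - 1))

    if founders is None:
        founders = simulate_founders(config.founder_size, gmap, seed=next_seed(),
                                     generation="founder")
    first_size = config.gs_cycle1_size if config.scheme == "GS" else config.ps_size
    pop = bottleneck_then_expand(founders, config.bottleneck_k, first_size,
                                 gmap, seed=next_seed(), generation="initial")

    populations = {"initial": pop}
    records: list[CycleRecord] = []
    models_by_version: dict[str, dict] = {}
    genotypes: dict[str, GenotypeMatrix] = {}
    phenotypes_by_cycle: dict[str, pd.DataFrame] = {}
    panel_sizes: dict[str, int] = {}
    panel = list(gmap.marker_id)
    models: dict | None = None

    if config.scheme == "GS":
        for year in range(1, config.years + 1):
            c1 = f"GS{2 * year - 1}"
            # "every_cycle" aliases annual: phenotypes exist only in cycle 1
            train = config.update_policy in {"annual", "every_cycle"} or year == 1
            pop, models, panel, geno, phenos, rec = run_gs_cycle1(
                pop, gmap, arch, index_model, config, panel, models, c1,
                seed=next_seed(), train=train,
            )
            if rec.model_version not in models_by_version:
                models_by_version[rec.model_version] = models
            genotypes[c1] = geno
            phenotypes_by_cycle[c1] = phenos
            panel_sizes[c1] = rec.panel_size
            records.append(rec)
            populations[f"post_{c1.lower()}"] = pop

            c2 = f"GS{2 * year}"
            pop, geno2, rec2 = run_gs_cycle2(
                pop, gmap, models, index_model, config, panel, c2, seed=next_seed()
            )
            genotypes[c2] = geno2
            panel_sizes[c2] = rec2.panel_size
            records.append(rec2)
            populations[f"post_{c2.lower()}"] = pop
    else:
        for year in range(1, config.years + 1):
            c = f"PS{year}"
            pop, phenos, rec = run_ps_cycle(
                pop, gmap, arch, index_model, config, c, seed=next_seed()
            )
            phenotypes_by_cycle[c] = phenos
            records.append(rec)
            populations[f"post_{c.lower()}"] = pop

    # common-garden seed stock: one extra round of within-population random
    # mating per population, all samples phenotyped with one environment seed
    eval_pops = {}
    for label, p in populations.items():
        eval_pops[label] = random_mate(
            p, config.eval_sample_size, gmap, self_incompatible=True,
            seed=next_seed(), generation=f"eval_{label}",
        )
    env_rng = np.random.default_rng(next_seed())
    eval_phenos = {}
    for label, p in eval_pops.items():
        eval_phenos[label] = phenotype(p, arch, seed=int(env_rng.integers(2**31 - 1)))

    return ProgramResult(
        config, populations, records, models_by_version, genotypes,
        phenotypes_by_cycle, panel_sizes, eval_phenos, eval_pops,
    )
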