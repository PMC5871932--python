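"""Forward-in-time simulation of a self-incompatible allogamous diploid population.

Provides the genetic map, population (phased haplotypes + pedigree),
meiosis/random-mating machinery, a correlated multi-trait architecture,
phenotyping, and marker observation (codominant dosage or dominant
presence/absence, with optional missingness).  Everything is seeded
explicitly and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CODOMINANT = "codominant"
DOMINANT = "dominant"

__all__ = [
    "GeneticMap",
    "Population",
    "TraitArchitecture",
    "GenotypeMatrix",
    "make_map",
    "simulate_founders",
    "random_mate",
    "bottleneck_then_expand",
    "build_trait_architecture",
    "phenotype",
    "observe_markers",
    "r2_phased",
    "expected_heterozygosity",
    "nearest_correlation",
]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: id, linkage group (1-based), position in cM, assay mode."""

    marker_id: np.ndarray
    linkage_group: np.ndarray
    position: np.ndarray
    marker_mode: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        lg = np.asarray(self.linkage_group, dtype=np.int64)
        pos = np.asarray(self.position, dtype=float)
        mode = np.asarray(self.marker_mode, dtype=object)
        if not (len(mid) == len(lg) == len(pos) == len(mode)):
            raise ValueError("map columns must have equal length")
        if len(mid) == 0:
            raise ValueError("empty genetic map")
        if len(set(mid)) != len(mid):
            raise ValueError("marker ids must be unique")
        if np.any(pos < 0):
            raise ValueError("map positions must be non-negative")
        for g in np.unique(lg):
            p = pos[lg == g]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions must be non-decreasing in linkage group {g}")
        bad = set(mode) - {CODOMINANT, DOMINANT}
        if bad:
            raise ValueError(f"unknown marker modes: {bad}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "linkage_group", lg)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "marker_mode", mode)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def group_slices(self) -> list[tuple[int, int]]:
        """(start, stop) index pairs per linkage group, in map order."""
        lg = self.linkage_group
        bounds = np.flatnonzero(np.diff(lg) != 0) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(lg)]])
        return list(zip(starts.tolist(), stops.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "linkage_group": self.linkage_group,
                "position_cM": self.position,
                "mode": self.marker_mode,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            df["marker_id"].to_numpy(dtype=object),
            df["linkage_group"].to_numpy(),
            df["position_cM"].to_numpy(dtype=float),
            df["mode"].to_numpy(dtype=object),
        )


def make_map(
    n_markers: int = 2000,
    n_linkage_groups: int = 8,
    length_cm: float = 100.0,
    dominant_fraction: float = 0.5,
    seed: int | None = None,
) -> GeneticMap:
    """Evenly spaced marker map over equal-length linkage groups.

    ``dominant_fraction`` of markers (chosen at random) are flagged as
    dominant assays; the rest are codominant.
    """
    if n_markers < 1 or n_linkage_groups < 1:
        raise ValueError("need at least one marker and one linkage group")
    if not 0.0 <= dominant_fraction <= 1.0:
        raise ValueError("dominant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    per = np.full(n_linkage_groups, n_markers // n_linkage_groups, dtype=int)
    per[: n_markers % n_linkage_groups] += 1
    ids, lgs, pos = [], [], []
    for g, k in enumerate(per, start=1):
        if k == 0:
            continue
        p = np.linspace(0.0, length_cm, k)
        for j in range(k):
            ids.append(f"m{g}_{j + 1}")
        lgs.append(np.full(k, g))
        pos.append(p)
    lgs = np.concatenate(lgs)
    pos = np.concatenate(pos)
    n_dom = int(round(dominant_fraction * n_markers))
    mode = np.array([CODOMINANT] * n_markers, dtype=object)
    dom_idx = rng.choice(n_markers, size=n_dom, replace=False)
    mode[dom_idx] = DOMINANT
    return GeneticMap(np.array(ids, dtype=object), lgs, pos, mode)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Diploid individuals with phased haplotypes over a map and pedigree links.

    ``haplotypes`` has shape (n, n_markers, 2), entries in {0, 1}.
    """

    ids: np.ndarray
    haplotypes: np.ndarray
    dam: np.ndarray
    sire: np.ndarray
    generation: str = "founder"

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.dam = np.asarray(self.dam, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        n = len(self.ids)
        if self.haplotypes.shape[0] != n or self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n, n_markers, 2)")
        if len(self.dam) != n or len(self.sire) != n:
            raise ValueError("pedigree arrays must match population size")
        for i, (d, s) in enumerate(zip(self.dam, self.sire)):
            if d is not None and d == self.ids[i]:
                raise ValueError("individual cannot be its own dam")
            if s is not None and s == self.ids[i]:
                raise ValueError("individual cannot be its own sire")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Allele-count matrix (n, n_markers) with entries in {0, 1, 2}."""
        return self.haplotypes.sum(axis=2, dtype=np.int8)

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 2))

    def subset(self, index: np.ndarray) -> "Population":
        return Population(
            self.ids[index],
            self.haplotypes[index],
            self.dam[index],
            self.sire[index],
            self.generation,
        )

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": [d if d is not None else "NA" for d in self.dam],
                "sire": [s if s is not None else "NA" for s in self.sire],
                "generation": self.generation,
            }
        )


def simulate_founders(
    n_individuals: int,
    gmap: GeneticMap,
    allele_freq=(0.1, 0.9),
    seed: int | None = None,
    generation: str = "founder",
) -> Population:
    """Founders in linkage equilibrium: alleles drawn independently per locus.

    ``allele_freq`` may be a (low, high) tuple (per-locus frequencies drawn
    uniformly from that interval), a scalar, or an array of per-locus
    frequencies.
    """
    if n_individuals < 2:
        raise ValueError("need at least two founder individuals")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    if isinstance(allele_freq, tuple) and len(allele_freq) == 2:
        lo, hi = allele_freq
        p = rng.uniform(lo, hi, size=m)
    else:
        p = np.broadcast_to(np.asarray(allele_freq, dtype=float), (m,)).copy()
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("allele frequencies must be in (0, 1)")
    haps = (rng.random((n_individuals, m, 2)) < p[None, :, None]).astype(np.int8)
    ids = np.array([f"{generation}_{i + 1}" for i in range(n_individuals)], dtype=object)
    none = np.array([None] * n_individuals, dtype=object)
    return Population(ids, haps, none.copy(), none.copy(), generation)


def _gametes(pop: Population, parent_idx: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """One recombinant gamete per entry of ``parent_idx`` (Haldane, no interference)."""
    slices = gmap.group_slices()
    pos = gmap.position
    out = np.empty((len(parent_idx), pop.n_markers), dtype=np.int8)
    for row, pi in enumerate(parent_idx):
        hap = pop.haplotypes[pi]
        for s, e in slices:
            p = pos[s:e]
            span = p[-1] - p[0]
            phase0 = rng.integers(2)
            n_x = rng.poisson(span / 100.0) if span > 0 else 0
            if n_x == 0:
                out[row, s:e] = hap[s:e, phase0]
            else:
                xpos = np.sort(rng.uniform(p[0], p[-1], n_x))
                phase = (phase0 + np.searchsorted(xpos, p, side="right")) % 2
                out[row, s:e] = hap[s:e][np.arange(e - s), phase]
    return out


def random_mate(
    pop: Population,
    n_offspring: int,
    gmap: GeneticMap,
    self_incompatible: bool = True,
    dams: Sequence | None = None,
    sires: Sequence | None = None,
    seed: int | None = None,
    generation: str = "offspring",
) -> Population:
    """Random union of gametes: each offspring draws a dam uniformly from
    ``dams`` and a sire uniformly from ``sires`` (defaults: whole population),
    excluding the dam itself when ``self_incompatible``.  Gametes are formed
    by Haldane recombination over the map.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be positive")
    if gmap.n_markers != pop.n_markers:
        raise ValueError("map does not match population haplotype length")
    rng = np.random.default_rng(seed)
    id_to_idx = {iid: i for i, iid in enumerate(pop.ids)}

    def _resolve(sel):
        if sel is None:
            return np.arange(pop.n)
        return np.array([id_to_idx[i] for i in sel], dtype=int)

    dam_pool = _resolve(dams)
    sire_pool = _resolve(sires)
    if len(dam_pool) == 0 or len(sire_pool) == 0:
        raise ValueError("empty parent pool")
    if self_incompatible and len(set(dam_pool) | set(sire_pool)) < 2:
        raise ValueError("self-incompatibility requires two distinct parents")
    if self_incompatible and len(set(sire_pool)) == 1:
        lone = sire_pool[0]
        if set(dam_pool) == {lone}:
            raise ValueError("self-incompatibility requires two distinct parents")

    dam_idx = dam_pool[rng.integers(len(dam_pool), size=n_offspring)]
    sire_idx = sire_pool[rng.integers(len(sire_pool), size=n_offspring)]
    if self_incompatible:
        clash = dam_idx == sire_idx
        guard = 0
        while np.any(clash):
            sire_idx[clash] = sire_pool[rng.integers(len(sire_pool), size=int(clash.sum()))]
            clash = dam_idx == sire_idx
            guard += 1
            if guard > 10_000:
                raise ValueError("cannot avoid selfing with the given parent pools")

    haps = np.empty((n_offspring, pop.n_markers, 2), dtype=np.int8)
    haps[:, :, 0] = _gametes(pop, dam_idx, gmap, rng)
    haps[:, :, 1] = _gametes(pop, sire_idx, gmap, rng)
    # deterministic batch tag keeps offspring ids distinct from parent ids
    # even when the same generation label is reused across matings
    tag = f"{rng.integers(1 << 30):08x}"
    ids = np.array(
        [f"{generation}.{tag}_{i + 1}" for i in range(n_offspring)], dtype=object
    )
    return Population(ids, haps, pop.ids[dam_idx].copy(), pop.ids[sire_idx].copy(), generation)


def bottleneck_then_expand(
    pop: Population,
    k: int,
    n_out: int,
    gmap: GeneticMap,
    seed: int | None = None,
    generation: str = "initial",
) -> Population:
    """Sample ``k`` individuals without replacement, then one round of
    self-incompatible random mating to ``n_out`` offspring."""
    if k > pop.n:
        raise ValueError("bottleneck size exceeds population size")
    if k < 2:
        raise ValueError("bottleneck needs at least two survivors")
    rng = np.random.default_rng(seed)
    keep = rng.choice(pop.n, size=k, replace=False)
    survivors = pop.subset(np.sort(keep))
    return random_mate(
        survivors,
        n_out,
        self_incompatible=True,
        gmap=gmap,
        seed=int(rng.integers(2**31 - 1)),
        generation=generation,
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def nearest_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest-PSD repair: clip eigenvalues at ``eps`` and restore unit diagonal."""
    a = np.asarray(mat, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(a)
    w = np.clip(w, eps, None)
    b = (v * w) @ v.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    np.fill_diagonal(b, 1.0)
    return b


@dataclass
class TraitArchitecture:
    """Pleiotropic additive QTL inducing a target genetic correlation matrix."""

    trait_names: list[str]
    qtl_indices: np.ndarray      # indices into the map
    qtl_effects: np.ndarray      # (n_qtl, n_traits), on the unit-genetic-variance scale
    error_sd: np.ndarray         # (n_traits,)
    target_genetic_corr: np.ndarray
    h2: np.ndarray

    def __post_init__(self):
        t = len(self.trait_names)
        if self.qtl_effects.shape[1] != t or len(self.error_sd) != t or len(self.h2) != t:
            raise ValueError("trait dimensions inconsistent")
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValueError("heritabilities must be in (0, 1]")

    def genetic_values(self, pop: Population) -> pd.DataFrame:
        g = pop.dosages()[:, self.qtl_indices].astype(float) @ self.qtl_effects
        return pd.DataFrame(g, index=pop.ids, columns=self.trait_names)


def build_trait_architecture(
    gmap: GeneticMap,
    target_corr: np.ndarray,
    h2,
    n_qtl: int = 100,
    seed: int | None = None,
    trait_names: list[str] | None = None,
    ref_pop: Population | None = None,
) -> TraitArchitecture:
    """Shared QTL with effect vectors ~ MVN(0, target_corr), rescaled per trait
    to unit genetic variance in a reference population (simulated founders if
    none is supplied); error_sd set from h² so phenotypic variance ≈ 1/h².
    """
    target = np.asarray(target_corr, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target correlation matrix must be square")
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    n_traits = target.shape[0]
    if trait_names is None:
        trait_names = [f"trait_{i + 1}" for i in range(n_traits)]
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_traits,)).copy()
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("heritabilities must be in (0, 1]")
    if n_qtl < 1:
        raise ValueError("need at least one QTL")
    rng = np.random.default_rng(seed)
    target = nearest_correlation(target)
    chol = np.linalg.cholesky(target + 1e-12 * np.eye(n_traits))
    qtl_idx = np.sort(rng.choice(gmap.n_markers, size=min(n_qtl, gmap.n_markers), replace=False))
    effects = rng.standard_normal((len(qtl_idx), n_traits)) @ chol.T

    if ref_pop is None:
        ref_pop = simulate_founders(2000, gmap, seed=int(rng.integers(2**31 - 1)))
    g = ref_pop.dosages()[:, qtl_idx].astype(float) @ effects
    cov_g = np.cov(g, rowvar=False).reshape(n_traits, n_traits)
    if np.any(np.diag(cov_g) <= 0):
        raise ValueError("degenerate genetic variance; increase n_qtl or reference size")
    # re-color so the realized genetic covariance in the reference population
    # equals the target exactly (unit variances, target correlations)
    l_emp = np.linalg.cholesky(cov_g + 1e-10 * np.eye(n_traits))
    transform = np.linalg.solve(l_emp.T, chol.T)
    effects = effects @ transform
    error_sd = np.sqrt((1.0 - h2) / h2)
    return TraitArchitecture(list(trait_names), qtl_idx, effects, error_sd, target, h2)


def phenotype(pop: Population, arch: TraitArchitecture, seed: int | None = None) -> pd.DataFrame:
    """Genetic value plus independent per-trait normal error."""
    if np.any(arch.qtl_indices >= pop.n_markers):
        raise ValueError("architecture QTL indices exceed the population's map")
    rng = np.random.default_rng(seed)
    g = arch.genetic_values(pop)
    noise = rng.standard_normal(g.shape) * arch.error_sd
    return g + noise


# ---------------------------------------------------------------------------
# marker observation
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Observed genotypes: codominant dosage {0,1,2} or dominant presence {0,1};
    NaN marks missing calls."""

    individuals: np.ndarray
    marker_ids: np.ndarray
    values: np.ndarray
    modes: np.ndarray

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.modes = np.asarray(self.modes, dtype=object)
        n, m = self.values.shape
        if len(self.individuals) != n or len(self.marker_ids) != m or len(self.modes) != m:
            raise ValueError("genotype matrix dimensions do not match id lists")
        dom = self.modes == DOMINANT
        vals = self.values[:, dom]
        if vals.size and np.nanmax(vals, initial=0) > 1:
            raise ValueError("dominant columns must contain only {0, 1, NaN}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def imputed(self) -> np.ndarray:
        """Column-mean imputation of missing entries (monomorphic NaN column → 0)."""
        v = self.values.copy()
        mask = np.isnan(v)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col = np.nanmean(v, axis=0)
            col = np.where(np.isnan(col), 0.0, col)
            v[mask] = np.broadcast_to(col, v.shape)[mask]
        return v

    def subset_markers(self, marker_ids: Sequence) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        idx = [pos[m] for m in marker_ids if m in pos]
        return GenotypeMatrix(
            self.individuals, self.marker_ids[idx], self.values[:, idx], self.modes[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.marker_ids)


def observe_markers(
    pop: Population,
    gmap: GeneticMap,
    dominant_fraction: float | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Assay the population: codominant markers report allele dosage, dominant
    markers report presence of the '1' allele (het and dominant homozygote are
    indistinguishable).  Modes come from the map unless ``dominant_fraction``
    overrides them.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    if dominant_fraction is None:
        modes = gmap.marker_mode.copy()
    else:
        if not 0.0 <= dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must be in [0, 1]")
        modes = np.array([CODOMINANT] * m, dtype=object)
        n_dom = int(round(dominant_fraction * m))
        modes[rng.choice(m, size=n_dom, replace=False)] = DOMINANT
    vals = pop.dosages().astype(float)
    dom = modes == DOMINANT
    vals[:, dom] = (vals[:, dom] > 0).astype(float)
    if missing_rate > 0:
        vals[rng.random(vals.shape) < missing_rate] = np.nan
    return GenotypeMatrix(pop.ids.copy(), gmap.marker_id.copy(), vals, modes)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def r2_phased(pop: Population, i: int, j: int) -> float:
    """Squared correlation of allelic states across the 2n phased haplotypes."""
    a = pop.haplotypes[:, i, :].ravel().astype(float)
    b = pop.haplotypes[:, j, :].ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic locus")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def expected_heterozygosity(pop: Population) -> float:
    p = pop.allele_freq()
    return float(np.mean(2 * p * (1 - p)))
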