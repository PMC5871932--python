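"""Pairwise linkage disequilibrium and LD-based effective population size.

r-squared is estimated from two-locus haplotype frequencies obtained by an
EM algorithm over unphased diploid genotypes.  The same engine covers
codominant x codominant pairs (the only latent variable is the phase of
double heterozygotes) and pairs involving dominant presence/absence markers
(where more genotype classes are pooled).  Effective population size is
fitted from the decay of r-squared with recombination distance using a
drift-expectation curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import CODOMINANT, DOMINANT, GeneticMap, GenotypeMatrix

__all__ = [
    "LDPair",
    "NeEstimate",
    "haldane_c",
    "em_haplotype_freqs",
    "r2_from_haplotype_freqs",
    "r2_from_haplotype_counts",
    "r2_direct",
    "r2_em_dominant",
    "ld_decay",
    "expected_r2",
    "fit_ne",
]


def haldane_c(d_cm) -> np.ndarray:
    """Map distance (cM) to recombination fraction via the inverse Haldane map."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# two-locus EM over unphased genotypes
# ---------------------------------------------------------------------------

# haplotypes h = 2*a + b, a = allele at locus 1, b = allele at locus 2
_H1 = np.array([h1 for h1 in range(4) for h2 in range(h1, 4)])
_H2 = np.array([h2 for h1 in range(4) for h2 in range(h1, 4)])
_MULT = np.where(_H1 == _H2, 1.0, 2.0)
_G1 = (_H1 >> 1) + (_H2 >> 1)       # dosage at locus 1 per haplotype pair
_G2 = (_H1 & 1) + (_H2 & 1)         # dosage at locus 2
# contribution of each unordered pair to each haplotype's count
_HCONTRIB = np.zeros((4, len(_H1)))
for _k, (_a, _b) in enumerate(zip(_H1, _H2)):
    _HCONTRIB[_a, _k] += 1
    _HCONTRIB[_b, _k] += 1


def _class_matrix(mode_i: str, mode_j: str) -> np.ndarray:
    """Boolean (9, 10) membership matrix: observed class (o1*3+o2) x pair."""
    o1 = _G1 if mode_i == CODOMINANT else np.minimum(_G1, 1)
    o2 = _G2 if mode_j == CODOMINANT else np.minimum(_G2, 1)
    code = o1 * 3 + o2
    A = np.zeros((9, len(_H1)), dtype=float)
    A[code, np.arange(len(_H1))] = 1.0
    return A


def _observed_class_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    code = (gi.astype(int) * 3 + gj.astype(int))
    return np.bincount(code, minlength=9).astype(float)


def _init_freqs(gi, gj, mode_i, mode_j) -> np.ndarray:
    def allele_freq(g, mode):
        if mode == CODOMINANT:
            p = g.mean() / 2.0
        else:
            f = g.mean()  # presence frequency; HWE: f = 1 - (1-p)^2
            p = 1.0 - np.sqrt(max(1.0 - f, 0.0))
        return float(np.clip(p, 1e-6, 1 - 1e-6))

    pa = allele_freq(gi, mode_i)
    pb = allele_freq(gj, mode_j)
    return np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])


def em_haplotype_freqs(
    gi,
    gj,
    mode_i: str = CODOMINANT,
    mode_j: str = CODOMINANT,
    tol: float = 1e-4,
    max_iter: int = 1000,
    track_loglik: bool = False,
):
    """EM estimate of the four two-locus haplotype frequencies.

    Iterates until the maximum absolute change of the estimated haplotype
    frequencies is below ``tol``.  Returns (freqs, n_iter, converged,
    loglik_trace) where the trace is populated when ``track_loglik``.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    if len(gi) == 0:
        raise ValueError("no complete observations")
    counts = _observed_class_counts(gi, gj)
    A = _class_matrix(mode_i, mode_j)
    n2 = 2.0 * counts.sum()
    p = _init_freqs(gi, gj, mode_i, mode_j)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = _MULT * p[_H1] * p[_H2]
        pc = A @ q
        if track_loglik:
            with np.errstate(divide="ignore"):
                trace.append(float(counts @ np.where(counts > 0, np.log(np.where(pc > 0, pc, 1.0)), 0.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pc > 0, counts / pc, 0.0)
        post = q * (A.T @ ratio)
        p_new = (_HCONTRIB @ post) / n2
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break
    return p, it, converged, trace


def em_loglik(p: np.ndarray, gi, gj, mode_i=CODOMINANT, mode_j=CODOMINANT) -> float:
    """Observed-data log-likelihood of haplotype frequencies ``p``."""
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = ~(np.isnan(gi) | np.isnan(gj))
    counts = _observed_class_counts(gi[ok], gj[ok])
    A = _class_matrix(mode_i, mode_j)
    pc = A @ (_MULT * p[_H1] * p[_H2])
    with np.errstate(divide="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.where(pc > 0, pc, np.nan)), 0.0)
    return float(np.nansum(terms)) if np.all(pc[counts > 0] > 0) else -np.inf


def r2_from_haplotype_freqs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    pa = p[2] + p[3]
    pb = p[1] + p[3]
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        raise ValueError("monomorphic locus in haplotype frequencies")
    d = p[3] - pa * pb
    return float(np.clip(d * d / denom, 0.0, 1.0))


def r2_from_haplotype_counts(counts) -> float:
    """r-squared from phased haplotype counts ordered (ab, aB, Ab, AB)."""
    c = np.asarray(counts, dtype=float)
    return r2_from_haplotype_freqs(c / c.sum())


@dataclass(frozen=True)
class LDPair:
    marker_i: object
    marker_j: object
    r2: float
    method: str                      # "direct" | "em"
    distance: float | None = None    # cM, same linkage group only
    em_iterations: int | None = None
    converged: bool = True
    maf: float | None = None         # min minor-allele frequency of the two markers

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0, 1]")
        if self.distance is not None and self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.method == "em" and self.em_iterations is None:
            raise ValueError("em method requires an iteration count")


def _check_polymorphic(g, name):
    vals = np.unique(g[~np.isnan(g)])
    if len(vals) < 2:
        raise ValueError(f"monomorphic column {name}")


def r2_direct(geno_i, geno_j, tol: float = 1e-6, max_iter: int = 10_000) -> float:
    """r-squared for a codominant pair from EM haplotype frequencies (the only
    phase-ambiguous class is the double heterozygote)."""
    gi = np.asarray(geno_i, dtype=float)
    gj = np.asarray(geno_j, dtype=float)
    _check_polymorphic(gi, "i")
    _check_polymorphic(gj, "j")
    p, _, _, _ = em_haplotype_freqs(gi, gj, CODOMINANT, CODOMINANT, tol=tol, max_iter=max_iter)
    return r2_from_haplotype_freqs(p)


def r2_em_dominant(
    geno_i,
    geno_j,
    mode_i: str = DOMINANT,
    mode_j: str = DOMINANT,
    tol: float = 1e-4,
    max_iter: int = 1000,
    marker_i: object = "i",
    marker_j: object = "j",
    distance: float | None = None,
) -> LDPair:
    """EM r-squared for pairs involving at least one dominant marker."""
    gi = np.asarray(geno_i, dtype=float)
    gj = np.asarray(geno_j, dtype=float)
    _check_polymorphic(gi, marker_i)
    _check_polymorphic(gj, marker_j)
    p, it, conv, _ = em_haplotype_freqs(gi, gj, mode_i, mode_j, tol=tol, max_iter=max_iter)
    return LDPair(
        marker_i, marker_j, r2_from_haplotype_freqs(p), "em",
        distance=distance, em_iterations=it, converged=conv, maf=_pair_maf(gi, gj, mode_i, mode_j),
    )


def _maf(g, mode) -> float:
    g = g[~np.isnan(g)]
    if mode == CODOMINANT:
        p = g.mean() / 2.0
    else:
        p = 1.0 - np.sqrt(max(1.0 - g.mean(), 0.0))
    return float(min(p, 1 - p))


def _pair_maf(gi, gj, mode_i, mode_j) -> float:
    return min(_maf(gi, mode_i), _maf(gj, mode_j))


def ld_decay(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    max_distance: float = 50.0,
    max_pairs: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int | None = None,
) -> list[LDPair]:
    """All polymorphic same-linkage-group pairs within ``max_distance`` cM.

    The estimator is chosen per pair from the marker modes ("direct" for
    codominant x codominant, "em" otherwise).  ``max_pairs`` subsamples the
    eligible pairs reproducibly (given ``seed``) for large panels.
    """
    frame = geno.to_frame()
    mode_of = dict(zip(geno.marker_ids, geno.modes))
    in_geno = set(geno.marker_ids)
    missing = in_geno - set(gmap.marker_id)
    if missing:
        raise ValueError(f"map does not cover genotype markers, e.g. {sorted(missing)[:3]}")

    candidates = []
    for s, e in gmap.group_slices():
        ids = gmap.marker_id[s:e]
        pos = gmap.position[s:e]
        keep = [(m, p) for m, p in zip(ids, pos) if m in in_geno]
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                d = keep[b][1] - keep[a][1]
                if d > max_distance:
                    break
                candidates.append((keep[a][0], keep[b][0], d))
    if not candidates:
        raise ValueError("no eligible marker pairs")
    if max_pairs is not None and len(candidates) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=max_pairs, replace=False)
        candidates = [candidates[i] for i in np.sort(idx)]

    pairs = []
    for mi, mj, d in candidates:
        gi = frame[mi].to_numpy(dtype=float)
        gj = frame[mj].to_numpy(dtype=float)
        try:
            _check_polymorphic(gi, mi)
            _check_polymorphic(gj, mj)
        except ValueError:
            continue
        modes = (mode_of[mi], mode_of[mj])
        if modes == (CODOMINANT, CODOMINANT):
            p, it, conv, _ = em_haplotype_freqs(gi, gj, *modes, tol=tol, max_iter=max_iter)
            pairs.append(LDPair(mi, mj, r2_from_haplotype_freqs(p), "direct",
                                distance=d, maf=_pair_maf(gi, gj, *modes)))
        else:
            pairs.append(
                r2_em_dominant(gi, gj, modes[0], modes[1], tol=tol, max_iter=max_iter,
                               marker_i=mi, marker_j=mj, distance=d)
            )
    return pairs


# ---------------------------------------------------------------------------
# effective population size from LD decay
# ---------------------------------------------------------------------------


def expected_r2(distance_cm, ne: float, sample_size: int,
                formula: str = "hill_weir_1988") -> np.ndarray:
    """Drift expectation of r-squared at a map distance, for Ne and sample n."""
    c = haldane_c(distance_cm)
    C = 4.0 * ne * c
    n = float(sample_size)
    if formula == "hill_weir_1988":
        base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
        corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
        return base * corr
    if formula == "drift_simple":
        return 1.0 / (2.0 + C) + 1.0 / n
    raise ValueError(f"unknown formula {formula!r}")


@dataclass
class NeEstimate:
    population_label: str
    ne: float
    sample_size: int
    n_pairs: int
    formula: str
    bound_hit: bool = False

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("Ne must be positive")

    def curve(self, distances) -> np.ndarray:
        return expected_r2(distances, self.ne, self.sample_size, self.formula)


def fit_ne(
    pairs: Sequence[LDPair],
    sample_size: int,
    population_label: str = "",
    formula: str = "hill_weir_1988",
    maf_threshold: float = 0.05,
    binned: bool = False,
    bin_width: float = 1.0,
    ne_bounds: tuple[float, float] = (1.0, 1e6),
) -> NeEstimate:
    """Nonlinear least-squares fit of Ne to observed r-squared vs distance.

    Pairs with min minor-allele frequency below ``maf_threshold`` (when known)
    are excluded.  ``binned=True`` fits bin means at bin midpoints instead of
    the raw pairs.
    """
    usable = [p for p in pairs
              if p.distance is not None
              and (p.maf is None or p.maf >= maf_threshold)]
    if len(usable) < 20:
        raise ValueError("need at least 20 usable pairs")
    d = np.array([p.distance for p in usable])
    r2 = np.array([p.r2 for p in usable])
    if len(np.unique(np.round(d, 9))) < 2:
        raise ValueError("need pairs at >= 2 distinct distances")

    if binned:
        edges = np.arange(0.0, d.max() + bin_width, bin_width)
        which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
        xs, ys = [], []
        for b in np.unique(which):
            xs.append(edges[b] + bin_width / 2.0)
            ys.append(r2[which == b].mean())
        d = np.array(xs)
        r2 = np.array(ys)

    lo, hi = ne_bounds

    def resid(log_ne):
        return expected_r2(d, np.exp(log_ne[0]), sample_size, formula) - r2

    fit = least_squares(resid, x0=[np.log(100.0)],
                        bounds=([np.log(lo)], [np.log(hi)]))
    ne = float(np.exp(fit.x[0]))
    bound_hit = bool(np.isclose(ne, lo, rtol=1e-3) or np.isclose(ne, hi, rtol=1e-3))
    return NeEstimate(population_label, ne, sample_size, len(usable), formula, bound_hit)


def decay_table(pairs: Sequence[LDPair], ne_est: NeEstimate | None = None,
                bin_width: float = 1.0) -> pd.DataFrame:
    """Binned LD-decay summary (bin midpoint, mean observed r2, fitted r2)."""
    usable = [p for p in pairs if p.distance is not None]
    d = np.array([p.distance for p in usable])
    r2 = np.array([p.r2 for p in usable])
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in np.unique(which):
        mid = edges[b] + bin_width / 2.0
        row = {"bin_mid_cM": mid, "mean_r2": r2[which == b].mean(),
               "n_pairs": int((which == b).sum())}
        if ne_est is not None:
            row["expected_r2"] = float(ne_est.curve(mid))
        rows.append(row)
    return pd.DataFrame(rows)
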