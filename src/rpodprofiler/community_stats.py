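"""Mock-community benchmarking and community-ecology statistics.

Covers the statistics used to validate and apply an amplicon profiling
method: observed/expected recovery ratios for a defined mock community,
Bray-Curtis dissimilarity, principal-coordinates analysis (PCoA),
beta dispersion (within-group multivariate variability, compared between
methods with a Mann-Whitney U test), non-metric multidimensional scaling
(NMDS, Kruskal stress-1), Chao1 richness, analytic rarefaction, and the
qPCR anchoring that converts relative abundances into absolute CFU/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.special import gammaln
from skbio.diversity.alpha import chao1 as _skbio_chao1
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof


# ---------------------------------------------------------------------------
# mock-community recovery


@dataclass(frozen=True)
class MockSpec:
    """A defined community: species and their expected relative abundances
    (percent, summing to 100)."""

    species: tuple[str, ...]
    expected_percent: tuple[float, ...]
    replicates: int = 1

    def __post_init__(self) -> None:
        if len(self.species) != len(self.expected_percent):
            raise ValueError("species/abundance length mismatch")
        if not math.isclose(sum(self.expected_percent), 100.0,
                            rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("expected abundances must sum to 100%")


def observed_expected_ratio(observed: Sequence[float] | float,
                            expected: float) -> dict[str, float] | float:
    """Recovery ratio in percent: 100 * observed / expected.

    ``observed`` may be a single relative abundance (%) or one value per
    replicate; with replicates the per-replicate ratios plus their mean
    and sample standard deviation are returned.
    """
    if expected <= 0:
        raise ValueError("expected abundance must be > 0")
    if np.isscalar(observed):
        return 100.0 * float(observed) / expected
    ratios = 100.0 * np.asarray(observed, dtype=float) / expected
    return {"ratios": ratios,
            "mean": float(ratios.mean()),
            "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0}


# ---------------------------------------------------------------------------
# distances and ordination


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(table: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis distances between the rows of ``table``."""
    table = np.asarray(table, dtype=float)
    n = table.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = bray_curtis(table[i], table[j])
    return dm


def _validate_distance_matrix(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return dm


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n, k) for positive eigenvalues
    eigenvalues: np.ndarray
    correction_constant: float = 0.0  # Cailliez constant applied, 0 if none


def pcoa(dm: np.ndarray, negative_tol: float = 1e-8) -> PCoAResult:
    """Principal-coordinates analysis by double-centred eigendecomposition.

    Non-Euclidean input (negative eigenvalues beyond tolerance) is handled
    by the Cailliez correction — the smallest constant added to every
    off-diagonal distance that makes the matrix embeddable — and the
    constant used is recorded in the result.
    """
    dm = _validate_distance_matrix(dm)
    n = dm.shape[0]

    def decompose(d: np.ndarray):
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(dm)
    constant = 0.0
    scale = max(abs(vals[0]), 1.0)
    if vals[-1] < -negative_tol * scale:
        constant = _cailliez_constant(dm)
        d2 = dm + constant
        np.fill_diagonal(d2, 0.0)
        vals, vecs = decompose(d2)
    pos = vals > negative_tol * max(abs(vals[0]), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if coords.shape[1] == 0:  # all points coincide
        coords = np.zeros((n, 1))
    return PCoAResult(coords, vals, constant)


def _cailliez_constant(dm: np.ndarray) -> float:
    """Smallest c such that d_ij + c (i != j) is Euclidean-embeddable."""
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * j @ (dm ** 2) @ j
    d2 = -0.5 * j @ dm @ j
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    sp = np.vstack([upper, lower])
    eigs = np.linalg.eigvals(sp)
    return float(np.max(eigs.real))


# ---------------------------------------------------------------------------
# beta dispersion


@dataclass
class DispersionResult:
    dispersions: dict[str, float]            # group -> mean distance
    sample_distances: dict[str, np.ndarray]  # group -> per-sample distances
    u_statistic: float | None = None
    p_value: float | None = None


def _spatial_median(points: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 1000) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration."""
    x = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - x, axis=1)
        if (d < tol).any():
            return points[d.argmin()]
        w = 1.0 / d
        x_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def beta_dispersion(dm: np.ndarray, groups: Sequence[str],
                    center: str = "median") -> DispersionResult:
    """Within-group multivariate dispersion in PCoA space.

    Each sample's distance to its own group's spatial median (``center=
    "median"``, the conventional default; ``"centroid"`` available) is
    computed in the PCoA embedding of the distance matrix; a group's
    dispersion is the mean of those distances.  With exactly two groups
    the per-sample distances are compared by a two-sided Mann-Whitney U
    test.
    """
    dm = _validate_distance_matrix(dm)
    groups = list(groups)
    if len(groups) != dm.shape[0]:
        raise ValueError("one group label required per sample")
    labels = sorted(set(groups))
    sizes = {g: groups.count(g) for g in labels}
    singletons = [g for g in labels if sizes[g] < 2]
    if singletons:
        raise ValueError(f"singleton group(s) not comparable: {singletons}")
    coords = pcoa(dm).coordinates
    dispersions: dict[str, float] = {}
    sample_distances: dict[str, np.ndarray] = {}
    for g in labels:
        idx = [i for i, lab in enumerate(groups) if lab == g]
        pts = coords[idx]
        ctr = (_spatial_median(pts) if center == "median"
               else pts.mean(axis=0))
        d = np.linalg.norm(pts - ctr, axis=1)
        sample_distances[g] = d
        dispersions[g] = float(d.mean())
    u = p = None
    if len(labels) == 2:
        u, p = mann_whitney_u(sample_distances[labels[0]],
                              sample_distances[labels[1]])
    return DispersionResult(dispersions, sample_distances, u, p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (rank-sum) test.

    Exact enumeration of the U null distribution when n*m <= 400,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(a) * len(b) <= 400 else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float  # Kruskal stress-1 of the best restart
    best_restart: int = 0


def _kruskal_stress1(dm: np.ndarray, coords: np.ndarray) -> float:
    n = dm.shape[0]
    iu = np.triu_indices(n, 1)
    diss = dm[iu]
    d = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    dhat = IsotonicRegression().fit_transform(diss, d)
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(dm: np.ndarray, k: int = 2, restarts: int = 20,
         seed: int = 0, max_iter: int = 300) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1 by iterative majorization
    (SMACOF with isotonic disparities) from multiple seeded random starts.

    Deterministic given ``seed``; the restart with the lowest stress wins.
    """
    dm = _validate_distance_matrix(dm)
    n = dm.shape[0]
    if k >= n:
        raise ValueError("embedding dimension must be below sample count")
    if dm[np.triu_indices(n, 1)].max(initial=0.0) == 0:
        return NMDSResult(np.zeros((n, k)), 0.0, 0)
    rng = np.random.RandomState(seed)
    best: NMDSResult | None = None
    for r in range(restarts):
        init = rng.normal(size=(n, k))
        coords, _ = smacof(dm, metric=False, n_components=k, init=init,
                           n_init=1, max_iter=max_iter,
                           normalized_stress=True,
                           random_state=rng.randint(2 ** 31 - 1))
        stress = _kruskal_stress1(dm, coords)
        if best is None or stress < best.stress:
            best = NMDSResult(coords, stress, r)
    return best


# ---------------------------------------------------------------------------
# alpha diversity


def chao1(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return float(_skbio_chao1(arr.astype(int), bias_corrected=True))


def rarefaction_curve(counts: Sequence[float],
                      depths: Sequence[int]) -> np.ndarray:
    """Analytic expected richness at each subsampling depth.

    E[S(d)] = sum_i (1 - C(N - n_i, d) / C(N, d)) under hypergeometric
    subsampling without replacement; computed with log-gamma for
    stability.
    """
    arr = np.asarray(counts)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(int)
    arr = arr[arr > 0]
    total = int(arr.sum())
    out = []
    for d in depths:
        if d > total:
            raise ValueError(f"depth {d} exceeds total count {total}")
        if d == 0:
            out.append(0.0)
            continue
        # log C(N - n_i, d) - log C(N, d); impossible draws contribute 0
        keep = (total - arr) >= d
        logp = np.full(arr.shape, -np.inf)
        logp[keep] = (_log_comb(total - arr[keep], d) - _log_comb(total, d))
        out.append(float(np.sum(1.0 - np.exp(logp))))
    return np.asarray(out)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# qPCR anchoring and correlation


@dataclass
class QpcrCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        """Amplification efficiency (10^(-1/slope) - 1) * 100; 100% means
        perfect doubling per cycle."""
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0


def qpcr_standard_curve(points: Sequence[tuple[float, float]]) -> QpcrCurve:
    """Least-squares dilution curve CT = slope * log10(CFU) + intercept.

    Requires >= 3 points spanning >= 2 log units and a negative slope
    (CT decreases as template increases).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (log10 CFU, CT) points")
    x, y = pts[:, 0], pts[:, 1]
    if x.max() - x.min() < 2.0:
        raise ValueError("standard curve must span >= 2 log10 units")
    res = sps.linregress(x, y)
    if not np.isfinite(res.slope) or res.slope >= 0:
        raise ValueError("degenerate standard curve (slope must be < 0)")
    return QpcrCurve(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2))


def efficiency_to_slope(efficiency_percent: float) -> float:
    """Inverse of the efficiency formula: slope = -1 / log10(E/100 + 1)."""
    return -1.0 / math.log10(efficiency_percent / 100.0 + 1.0)


def absolute_abundance(total_cfu_per_g: float,
                       relative_percent: float) -> float:
    """Taxon load in CFU/g: total load times relative abundance / 100."""
    if total_cfu_per_g < 0:
        raise ValueError("total CFU/g must be >= 0")
    if not 0.0 <= relative_percent <= 100.0:
        raise ValueError("relative abundance must be within [0, 100]%")
    return total_cfu_per_g * relative_percent / 100.0


def correlate(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
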