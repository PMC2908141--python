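"""Per-electrode spike sorting: wavelet features + superparamagnetic clustering.

Each detected snippet is decomposed with a 4-level Haar discrete wavelet
transform; the ten coefficients whose distributions deviate most from
normality (Lilliefors statistic) are kept as features, on the rationale
that multimodal coefficients are the ones that separate units.  Feature
vectors are then clustered with superparamagnetic clustering (SPC): points
become q-state Potts spins coupled to their k nearest neighbours with
distance-decaying strength, Swendsen-Wang dynamics are run across a
temperature grid, and clusters are read off from the spin-spin correlation
(> 0.5) at a working temperature inside the superparamagnetic phase.

The working temperature is chosen by cluster-count stability: the number
of clusters holding at least ``min_cluster_size`` members is tracked along
the temperature scan, the multi-cluster count that persists over the most
temperatures is taken as the superparamagnetic-phase structure (persistence
ties resolve toward the count appearing at lower, more ordered
temperatures), and the working temperature is the one showing that count
with the largest fraction of spikes inside valid clusters (fragmented
high-temperature configurations can repeat a count, but only with much of
the data unassigned).  If no temperature ever shows two or more such clusters the data
are treated as a single cluster at the lowest temperature.  Clusters
smaller than ``min_cluster_size`` are left unassigned (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import norm

from .detect import WaveformMatrix


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SpcConfig:
    q: int = 20                      # Potts states
    k_neighbors: int = 11
    temperatures: tuple[float, ...] = tuple(round(0.01 * k, 3) for k in range(21))
    sweeps: int = 100                # Swendsen-Wang sweeps per temperature
    burn_in: int = 25                # sweeps discarded before measuring correlations
    min_cluster_size: int = 15
    correlation_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if list(self.temperatures) != sorted(self.temperatures):
            raise ValueError("temperature grid must be increasing")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass
class FeatureSet:
    coefficients: np.ndarray       # (n_spikes, n_selected)
    selected_indices: np.ndarray   # positions within the full DWT vector
    wavelet: str = "haar"
    levels: int = 4


@dataclass
class UnitAssignment:
    labels: np.ndarray        # per spike; 0 = unassigned, 1..n_units by size
    n_units: int
    temperature: float
    cluster_sizes: tuple[int, ...] = ()


def wavelet_coefficients(waves: np.ndarray, wavelet: str = "haar",
                         levels: int = 4) -> np.ndarray:
    """Full multi-level DWT coefficient matrix, one row per snippet."""
    coeffs = pywt.wavedec(np.asarray(waves, dtype=np.float64), wavelet,
                          level=levels, axis=1)
    return np.concatenate(coeffs, axis=1)


def normality_deviation(sample: np.ndarray) -> float:
    """Lilliefors-type statistic: sup |ECDF - Normal(mean, SD) CDF|.

    Degenerate (zero-variance) samples score 0 — a constant coefficient has
    no discriminative power.
    """
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        return 0.0
    z = norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - z)
    d_minus = np.max(z - (i - 1) / n)
    return float(max(d_plus, d_minus))


def realign_snippets(waves: np.ndarray) -> np.ndarray:
    """Subsample realignment of peak-aligned snippets.

    The detector aligns snippets to the integer extremum sample; noise can
    shift that extremum by a sample, and the residual sub-sample phase adds
    alignment scatter that would otherwise dominate the within-unit feature
    variance.  A parabola through the three samples around the center
    estimates the fractional peak offset, which is removed with a cubic
    interpolating shift.
    """
    from scipy.ndimage import shift as nd_shift

    w = np.asarray(waves, dtype=np.float64)
    c = w.shape[1] // 2
    out = np.empty_like(w)
    for i, row in enumerate(w):
        ym, y0, yp = row[c - 1], row[c], row[c + 1]
        denom = ym - 2 * y0 + yp
        frac = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
        frac = float(np.clip(frac, -1.0, 1.0))
        out[i] = nd_shift(row, -frac, order=3, mode="nearest") if frac else row
    return out


def extract_features(waves: WaveformMatrix | np.ndarray, n_select: int = 10,
                     wavelet: str = "haar", levels: int = 4,
                     min_cluster_size: int = 15, realign: bool = True) -> FeatureSet:
    """Wavelet-decompose snippets and keep the most non-normal coefficients."""
    if isinstance(waves, WaveformMatrix):
        raise TypeError("pass one electrode's snippet array, not the whole matrix")
    w = np.asarray(waves, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("expected an (n_spikes, window) snippet array")
    if w.shape[0] < 2 * min_cluster_size:
        raise InsufficientDataError(
            f"{w.shape[0]} spikes is too few to sort (need >= {2 * min_cluster_size})"
        )
    if realign:
        w = realign_snippets(w)
    full = wavelet_coefficients(w, wavelet, levels)
    scores = np.array([normality_deviation(full[:, j]) for j in range(full.shape[1])])
    n_select = min(n_select, full.shape[1])
    # highest scores first; stable tie-break on coefficient index
    order = np.lexsort((np.arange(len(scores)), -scores))
    sel = np.sort(order[:n_select])
    return FeatureSet(coefficients=full[:, sel], selected_indices=sel,
                      wavelet=wavelet, levels=levels)


def _knn_graph(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric k-nearest-neighbour edge list (i, j, distance), i < j."""
    n = x.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(x)
    dist, idx = tree.query(x, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    key = lo * n + hi
    _, first = np.unique(key, return_index=True)
    return lo[first], hi[first], d[first]


def _sw_correlations(
    n: int, ei: np.ndarray, ej: np.ndarray, p_freeze: np.ndarray,
    cfg: SpcConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Run Swendsen-Wang dynamics; return per-edge same-spin frequency."""
    spins = rng.integers(cfg.q, size=n)
    m = len(ei)
    agree = np.zeros(m)
    measured = 0
    for sweep in range(cfg.sweeps):
        same = spins[ei] == spins[ej]
        frozen = same & (rng.random(m) < p_freeze)
        graph = coo_matrix(
            (np.ones(frozen.sum()), (ei[frozen], ej[frozen])), shape=(n, n)
        )
        n_comp, comp = connected_components(graph, directed=False)
        spins = rng.integers(cfg.q, size=n_comp)[comp]
        if sweep >= cfg.burn_in:
            agree += spins[ei] == spins[ej]
            measured += 1
    return agree / max(measured, 1)


def _clusters_at(n: int, ei: np.ndarray, ej: np.ndarray,
                 corr: np.ndarray, threshold: float) -> np.ndarray:
    linked = corr > threshold
    graph = coo_matrix((np.ones(linked.sum()), (ei[linked], ej[linked])), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    return comp


def _select_temperature(n_valid: list[int], n_assigned: list[int]) -> int:
    """Cluster-count stability rule over the temperature scan.

    ``n_valid[k]`` is the number of clusters of at least min size at the
    k-th temperature and ``n_assigned[k]`` the number of points inside
    them.  Among multi-cluster counts (>= 2) the most persistent one wins,
    ties going to the count first seen at a lower temperature; the working
    temperature is the one with that count keeping the most points in
    valid clusters (higher temperature on ties).  Without any
    multi-cluster temperature the scan degenerates to a single cluster at
    the lowest temperature.
    """
    persistence: dict[int, int] = {}
    first_seen: dict[int, int] = {}
    for k, c in enumerate(n_valid):
        if c >= 2:
            persistence[c] = persistence.get(c, 0) + 1
            first_seen.setdefault(c, k)
    if not persistence:
        return 0
    best = max(persistence, key=lambda c: (persistence[c], -first_seen[c]))
    return max((k for k, c in enumerate(n_valid) if c == best),
               key=lambda k: (n_assigned[k], k))


def spc_cluster(features: FeatureSet | np.ndarray, cfg: SpcConfig | None = None) -> UnitAssignment:
    """Superparamagnetic clustering of feature vectors.

    Deterministic for identical (features, config including seed), and
    equivariant under permutation of the input rows: points are processed
    in a canonical (lexicographic) order internally, so reordering the
    spikes reorders the labels identically.
    """
    cfg = cfg or SpcConfig()
    x = features.coefficients if isinstance(features, FeatureSet) else np.asarray(features)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 * cfg.min_cluster_size:
        raise InsufficientDataError("too few points for superparamagnetic clustering")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    n = x.shape[0]

    order = np.lexsort(x.T[::-1])  # canonical point order (first column major)
    xs = x[order]

    if np.allclose(xs, xs[0]):
        labels_sorted = np.ones(n, dtype=int)
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        return UnitAssignment(labels=labels, n_units=1,
                              temperature=float(cfg.temperatures[0]),
                              cluster_sizes=(n,))

    ei, ej, d = _knn_graph(xs, cfg.k_neighbors)
    a = float(d.mean())
    k_hat = 2.0 * len(ei) / n
    if a > 0:
        coupling = np.exp(-(d**2) / (2.0 * a**2)) / k_hat
    else:
        coupling = np.full(len(ei), 1.0 / k_hat)

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5C]))
    per_temp: list[np.ndarray] = []
    for t in cfg.temperatures:
        if t <= 0:
            p_freeze = (coupling > 0).astype(np.float64)
        else:
            p_freeze = 1.0 - np.exp(-coupling / t)
        corr = _sw_correlations(n, ei, ej, p_freeze, cfg, rng)
        per_temp.append(_clusters_at(n, ei, ej, corr, cfg.correlation_threshold))

    n_valid, n_assigned = [], []
    for comp in per_temp:
        sizes = np.bincount(comp)
        big = sizes >= cfg.min_cluster_size
        n_valid.append(int(big.sum()))
        n_assigned.append(int(sizes[big].sum()))
    chosen = _select_temperature(n_valid, n_assigned)
    comp = per_temp[chosen]
    counts = np.bincount(comp)
    by_size = np.argsort(-counts, kind="stable")
    labels_sorted = np.zeros(n, dtype=int)
    next_label = 1
    sizes_out = []
    for c in by_size:
        if counts[c] >= cfg.min_cluster_size:
            labels_sorted[comp == c] = next_label
            sizes_out.append(int(counts[c]))
            next_label += 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return UnitAssignment(
        labels=labels,
        n_units=next_label - 1,
        temperature=float(cfg.temperatures[chosen]),
        cluster_sizes=tuple(sizes_out),
    )


def sort_electrode(snippets: np.ndarray, cfg: SpcConfig | None = None,
                   n_select: int = 10) -> UnitAssignment:
    """Feature extraction + SPC for one electrode's waveform block."""
    cfg = cfg or SpcConfig()
    feats = extract_features(snippets, n_select=n_select,
                             min_cluster_size=cfg.min_cluster_size)
    return spc_cluster(feats, cfg)


def sort_segment(
    waveforms: WaveformMatrix,
    active: np.ndarray,
    cfg: SpcConfig | None = None,
) -> dict[int, UnitAssignment]:
    """Sort every active electrode with enough spikes; returns per-electrode units."""
    cfg = cfg or SpcConfig()
    out: dict[int, UnitAssignment] = {}
    for e, snips in waveforms.snippets.items():
        if not active[e]:
            continue
        if snips.shape[0] < 2 * cfg.min_cluster_size:
            continue
        out[e] = sort_electrode(snips, cfg)
    return out


def count_units(assignments: dict[int, UnitAssignment]) -> float | None:
    """Mean sorted-unit count per active electrode (None when no electrodes)."""
    if not assignments:
        return None
    return float(np.mean([a.n_units for a in assignments.values()]))
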