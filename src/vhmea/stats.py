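"""Slice- and condition-level summaries and statistics.

Per slice: active-electrode count, mean firing frequency over the active
electrodes' 25-s observations, and total spikes per minute.  Across slices:
per-slice-normalized 0.5 Hz frequency histograms, three-component Gaussian
mixture fits by EM, Kruskal-Wallis comparisons of frequency distributions
(alpha = 0.01) and one-way ANOVA of slice summaries (alpha = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class InvalidDesignError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


class InconsistentInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class SliceSummary:
    slice_id: str
    genotype: str
    drug: str
    n_active: int
    mean_frequency_hz: float          # NaN when no active electrodes
    total_spikes_per_minute: float
    frequency_observations: np.ndarray = field(default_factory=lambda: np.empty(0))
    units_per_electrode: float | None = None

    @property
    def condition(self) -> str:
        return f"{self.genotype}:{self.drug}"


@dataclass(frozen=True)
class HistogramSpec:
    bin_width_hz: float = 0.5

    def __post_init__(self):
        if self.bin_width_hz <= 0:
            raise InvalidInputError("bin width must be positive")


@dataclass
class GaussianMixtureFit:
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: np.ndarray   # per-iteration trace of the winning start
    n_iterations: int
    converged: bool

    @property
    def final_log_likelihood(self) -> float:
        return float(self.log_likelihood[-1])


@dataclass
class RankTestResult:
    H: float
    df: int
    p_value: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize_slice(
    event_table,
    active: np.ndarray,
    freq_series: dict[int, np.ndarray],
    assignments: dict | None = None,
    slice_id: str = "",
    genotype: str = "",
    drug: str = "",
) -> SliceSummary:
    """Fold one segment's detection (and optional sorting) output into a summary.

    Total spikes/minute totals events on active electrodes, scaled to one
    minute of recording.
    """
    active = np.asarray(active, dtype=bool)
    counts = event_table.counts()
    active_idx = [e for e in sorted(counts) if active[e]]
    missing = [e for e in active_idx if e not in freq_series]
    if missing:
        raise InconsistentInputError(f"no frequency series for active electrodes {missing}")
    obs = (
        np.concatenate([freq_series[e] for e in active_idx])
        if active_idx else np.empty(0)
    )
    total_active_spikes = sum(counts[e] for e in active_idx)
    per_minute = total_active_spikes / event_table.duration * 60.0
    units = None
    if assignments:
        from .sort import count_units

        units = count_units(assignments)
    return SliceSummary(
        slice_id=slice_id,
        genotype=genotype,
        drug=drug,
        n_active=int(len(active_idx)),
        mean_frequency_hz=float(obs.mean()) if obs.size else float("nan"),
        total_spikes_per_minute=float(per_minute),
        frequency_observations=obs,
        units_per_electrode=units,
    )


def build_histogram(
    observations_per_slice: list[np.ndarray],
    spec: HistogramSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-slice-normalized frequency histogram.

    Each slice contributes total weight 1 (every observation weighted by
    1/slice count); bins are [0, w), [w, 2w), ... so the pooled mass equals
    the number of slices.  Returns (bin_edges, weights).
    """
    spec = spec or HistogramSpec()
    slices = [np.asarray(o, dtype=np.float64) for o in observations_per_slice]
    if any(o.size == 0 for o in slices):
        raise InvalidInputError("every slice must contribute at least one observation")
    if any((o < 0).any() for o in slices):
        raise InvalidInputError("frequency observations cannot be negative")
    w = spec.bin_width_hz
    top = max(o.max() for o in slices)
    n_bins = int(math.floor(top / w)) + 1
    edges = np.arange(n_bins + 1) * w
    pooled = np.zeros(n_bins)
    for o in slices:
        hist, _ = np.histogram(o, bins=edges, weights=np.full(o.size, 1.0 / o.size))
        pooled += hist
    return edges, pooled


def fit_gmm(
    observations: np.ndarray,
    k: int = 3,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GaussianMixtureFit:
    """Univariate K-component Gaussian mixture by EM, best of ``n_starts``.

    Convergence when the log-likelihood gain per observation drops below
    ``tol``; component variances are floored at 1e-6 x data variance to
    avoid collapse.  The returned log-likelihood trace is non-decreasing.
    """
    x = np.asarray(observations, dtype=np.float64).ravel()
    if x.size < 10 * k:
        raise InsufficientDataError(f"need at least {10 * k} observations for K={k}")
    var_floor = max(1e-12, 1e-6 * float(x.var()))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E]))
    best = None
    for _ in range(max(1, n_starts)):
        fit = _em_run(x, k, rng, tol, max_iter, var_floor)
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    weights, means, variances, trace, converged = best
    order = np.argsort(means)
    return GaussianMixtureFit(
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        log_likelihood=trace,
        n_iterations=len(trace),
        converged=converged,
    )


def _em_run(x, k, rng, tol, max_iter, var_floor):
    from scipy.special import logsumexp

    n = x.size
    means = np.empty(k)
    means[0] = x[rng.integers(n)]
    for j in range(1, k):
        d2 = np.min((x[:, None] - means[None, :j]) ** 2, axis=1)
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        means[j] = x[rng.choice(n, p=p)]
    variances = np.full(k, max(float(x.var()), var_floor))
    weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_pdf = (
            -0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        joint = np.log(weights)[None, :] + log_pdf
        log_norm = logsumexp(joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(joint - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if trace and ll - trace[-1] < tol * n:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    return weights, means, variances, np.asarray(trace), converged


def kruskal_wallis(*groups: np.ndarray, alpha: float = 0.01) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(gs) < 2:
        raise InvalidDesignError("Kruskal-Wallis needs at least two groups")
    if any(g.size == 0 for g in gs):
        raise InvalidDesignError("every group needs at least one observation")
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        # all observations identical: zero statistic after tie correction
        return RankTestResult(H=0.0, df=df, p_value=1.0, alpha=alpha)
    H, p = sps.kruskal(*gs)
    return RankTestResult(H=float(H), df=df, p_value=float(p), alpha=alpha)


def anova_oneway(*groups: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA (between/within F test)."""
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise InvalidDesignError("one-way ANOVA needs >= 2 groups of >= 2 observations")
    df_between = len(gs) - 1
    df_within = sum(g.size for g in gs) - len(gs)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return AnovaResult(F=0.0, df_between=df_between, df_within=df_within,
                           p_value=1.0, alpha=alpha)
    with np.errstate(all="ignore"):
        F, p = sps.f_oneway(*gs)
    if not np.isfinite(F):
        # zero within-group variance: infinitely strong separation if the
        # means differ, no effect at all if they do not
        grand = pooled.mean()
        between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
        F, p = (float("inf"), 0.0) if between > 0 else (0.0, 1.0)
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within,
                       p_value=float(p), alpha=alpha)


def _sem(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def compare_conditions(summaries: list[SliceSummary]) -> dict:
    """Condition-level report: mean +/- SEM table plus group comparisons.

    The table gives per-condition means and SEMs of active-electrode count,
    firing frequency, and spikes/minute.  Within each genotype, one-way
    ANOVA compares slice-level active counts and frequencies across drug
    states; Kruskal-Wallis compares the pooled raw 25-s frequency
    observations between conditions (per-slice-normalized weights are a
    histogram display choice, not used for the test).
    """
    if not summaries:
        raise InvalidDesignError("no summaries given")
    rows = []
    by_condition: dict[tuple[str, str], list[SliceSummary]] = {}
    for s in summaries:
        by_condition.setdefault((s.genotype, s.drug), []).append(s)
    for (gt, drug), group in sorted(by_condition.items()):
        n_active = np.array([s.n_active for s in group], dtype=float)
        freq = np.array([s.mean_frequency_hz for s in group], dtype=float)
        spm = np.array([s.total_spikes_per_minute for s in group], dtype=float)
        rows.append({
            "genotype": gt, "drug": drug, "n_slices": len(group),
            "n_active_mean": float(n_active.mean()), "n_active_sem": _sem(n_active),
            "frequency_mean_hz": float(np.nanmean(freq)), "frequency_sem_hz": _sem(freq[~np.isnan(freq)]),
            "spikes_per_min_mean": float(spm.mean()), "spikes_per_min_sem": _sem(spm),
        })
    table = pd.DataFrame(rows)

    anova: dict[str, dict] = {}
    kruskal: dict[str, dict] = {}
    genotypes = sorted({gt for gt, _ in by_condition})
    for gt in genotypes:
        conds = sorted(drug for g, drug in by_condition if g == gt)
        if len(conds) < 2:
            continue
        active_groups = [[s.n_active for s in by_condition[(gt, d)]] for d in conds]
        if all(len(g) >= 2 for g in active_groups):
            res = anova_oneway(*active_groups)
            anova[gt] = {"conditions": conds, "F": res.F, "p_value": res.p_value,
                         "significant": res.significant}
        obs_groups = [
            np.concatenate([s.frequency_observations for s in by_condition[(gt, d)]])
            for d in conds
        ]
        if all(g.size > 0 for g in obs_groups):
            kres = kruskal_wallis(*obs_groups)
            kruskal[gt] = {"conditions": conds, "H": kres.H, "p_value": kres.p_value,
                           "significant": kres.significant}
    return {"table": table, "anova": anova, "kruskal_wallis": kruskal}
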