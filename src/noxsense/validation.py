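"""Evoked-vs-background validation of the template: cluster-based permutation
testing, data-driven analysis-window selection, and PCA with paired testing of
component weights.

The cluster test compares per-subject average evoked and background waveforms
with a paired t-statistic at every timepoint; contiguous supra-threshold runs
form clusters whose mass (summed |t|) is referred to a permutation null of
maximum cluster masses obtained by within-subject condition sign-flips. The
threshold for cluster significance is the 97.5th percentile of the permuted
maxima (a two-sided 5% family-wise level). The analysis window is the 300 ms
interval centred on the significant cluster's midpoint with both endpoints
rounded to the nearest 100 ms. PCA on the window-restricted, column-centred
stack of evoked and background averages identifies candidate components; the
component whose weights differ between conditions (paired t-test over the
first two components) is taken as the evoked response and correlated with the
template.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datagen import TemplateWaveform, as_rng

__all__ = ["ClusterResult", "PCAResult", "background_events",
           "cluster_permutation", "select_window", "pca_validate"]


def background_events(events, duration_s: float, n_epochs: int,
                      pre_ms: float = 500.0, post_ms: float = 1000.0,
                      min_gap_s: float = 5.0, seed=None):
    """Stimulus-free pseudo-event times for cutting background epochs.

    Draws ``n_epochs`` times uniformly over the record that keep a full
    epoch inside the recording and stay at least ``min_gap_s`` away from
    every real event, so background activity is sampled with the same
    epoch length and baseline rule as evoked activity.
    """
    import pandas as pd

    rng = as_rng(seed)
    stim = np.asarray(events["time_s"], float)
    lo = pre_ms / 1000.0
    hi = duration_s - post_ms / 1000.0
    if hi <= lo:
        raise ValueError("recording too short for a background epoch")
    times = []
    for _ in range(200 * n_epochs):
        t = rng.uniform(lo, hi)
        if np.abs(stim - t).min() >= min_gap_s:
            times.append(t)
            if len(times) == n_epochs:
                break
    if len(times) < n_epochs:
        raise ValueError("could not place enough stimulus-free epochs "
                         f"({len(times)} of {n_epochs})")
    return pd.DataFrame({"time_s": sorted(times),
                         "label": ["background"] * n_epochs})


@dataclass
class ClusterResult:
    clusters: list                       # dicts: start_ms, end_ms, mass, p, significant
    n_perm: int
    significance_percentile: float
    mass_threshold: float                # percentile of the null max masses
    t_threshold: float                   # cluster-forming |t| threshold
    search_window_ms: tuple | None
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["significant"]]


def _find_runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(idx[::2], idx[1::2]))


def _cluster_masses(t_series: np.ndarray, thr: float):
    runs = _find_runs(np.abs(t_series) > thr)
    return runs, [float(np.abs(t_series[a:b]).sum()) for a, b in runs]


def cluster_permutation(evoked: np.ndarray,
                        background: np.ndarray,
                        times_ms: np.ndarray,
                        search_window_ms: tuple[float, float] | None = None,
                        n_perm: int = 1000,
                        cluster_forming_alpha: float = 0.05,
                        significance_percentile: float = 97.5,
                        seed=None) -> ClusterResult:
    """Nonparametric cluster test of evoked vs background activity.

    ``evoked`` and ``background`` are paired subject x time matrices on the
    same time axis. The null distribution flips each subject's condition
    labels at random (equivalently the sign of the paired difference),
    enumerated exhaustively when ``2**n_subjects <= n_perm``.
    """
    evoked = np.asarray(evoked, float)
    background = np.asarray(background, float)
    if evoked.shape != background.shape:
        raise ValueError("evoked and background must be paired (same shape)")
    n_sub = evoked.shape[0]
    if n_sub < 3:
        raise ValueError("need >= 3 subjects for a paired cluster test")

    times_ms = np.asarray(times_ms, float)
    sel = slice(None)
    if search_window_ms is not None:
        lo, hi = search_window_ms
        sel = (times_ms >= lo) & (times_ms <= hi)
    d = (evoked - background)[:, sel]
    t_times = times_ms[sel]

    def paired_t(diffs):
        m = diffs.mean(0)
        sd = diffs.std(0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, m / (sd / math.sqrt(n_sub)), 0.0)

    thr = float(stats.t.ppf(1.0 - cluster_forming_alpha / 2.0, n_sub - 1))
    t_obs = paired_t(d)
    runs, masses = _cluster_masses(t_obs, thr)

    if 2 ** n_sub <= n_perm:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n_sub)]
             for i in range(2 ** n_sub)], float)
    else:
        rng = as_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.empty(len(signs))
    for i, s in enumerate(signs):
        t_p = paired_t(d * s[:, None])
        _, m = _cluster_masses(t_p, thr)
        null_max[i] = max(m) if m else 0.0

    mass_thr = float(np.percentile(null_max, significance_percentile))
    n_eff = len(signs)
    clusters = []
    for (a, b), mass in zip(runs, masses):
        p = (1 + int((null_max >= mass).sum())) / (1 + n_eff)
        clusters.append({
            "start_ms": float(t_times[a]),
            "end_ms": float(t_times[b - 1]),
            "mass": mass,
            "p": p,
            "significant": mass > mass_thr,
        })
    clusters.sort(key=lambda c: c["start_ms"])
    return ClusterResult(clusters, n_eff, significance_percentile, mass_thr,
                         thr, search_window_ms, null_max)


def _round_nearest_100(v: float) -> float:
    # round-half-up on the 100 ms grid
    return math.floor(v / 100.0 + 0.5) * 100.0


def select_window(cluster: tuple[float, float]) -> tuple[float, float]:
    """300 ms analysis window about the cluster midpoint, endpoints rounded
    to the nearest 100 ms (half-up)."""
    start, end = cluster
    mid = 0.5 * (start + end)
    return (_round_nearest_100(mid - 150.0), _round_nearest_100(mid + 150.0))


@dataclass
class PCAResult:
    components: np.ndarray              # (n_components, n_times) orthonormal rows
    variance_explained: np.ndarray      # percent, non-increasing
    weights: np.ndarray                 # (2 * n_subjects, n_components)
    paired_t: np.ndarray                # per tested component
    paired_p: np.ndarray
    template_correlation: np.ndarray    # Pearson r per tested component
    selected_component: int | None
    window_ms: tuple
    n_components_tested: int
    mean_: np.ndarray = field(repr=False, default=None)


def pca_validate(evoked: np.ndarray,
                 background: np.ndarray,
                 times_ms: np.ndarray,
                 window_ms: tuple[float, float],
                 template: TemplateWaveform | np.ndarray,
                 n_components_tested: int = 2,
                 alpha: float = 0.05) -> PCAResult:
    """PCA of evoked and background averages with paired weight testing.

    Evoked and background per-subject averages are stacked (two rows per
    subject), restricted to the analysis window, column-centred and
    decomposed by SVD. For each of the first ``n_components_tested``
    components the subject weights are compared between conditions with a
    paired t-test; the significant component (the larger |t| if both) is
    selected as the evoked response and its waveform correlated with the
    template resampled onto the window grid.
    """
    evoked = np.asarray(evoked, float)
    background = np.asarray(background, float)
    if evoked.shape != background.shape:
        raise ValueError("evoked and background must be paired (same shape)")
    n_sub = evoked.shape[0]
    times_ms = np.asarray(times_ms, float)
    lo, hi = window_ms
    sel = (times_ms >= lo) & (times_ms < hi)
    if not sel.any():
        raise ValueError("analysis window outside the data span")

    X = np.vstack([evoked[:, sel], background[:, sel]])
    mu = X.mean(0)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    weights = U * S                    # observation scores; X ≈ weights @ Vt + mu
    with np.errstate(invalid="ignore", divide="ignore"):
        var = 100.0 * S ** 2 / (S ** 2).sum() if S.sum() > 0 else S * 0.0

    k = min(n_components_tested, Vt.shape[0], n_sub - 1)
    if k < n_components_tested:
        warnings.warn(f"only {k} components testable with {n_sub} subjects",
                      stacklevel=2)
    t_vals = np.zeros(k)
    p_vals = np.ones(k)
    for j in range(k):
        dw = weights[:n_sub, j] - weights[n_sub:, j]
        sd = dw.std(ddof=1)
        if sd > 0:
            t_vals[j] = dw.mean() / (sd / math.sqrt(n_sub))
            p_vals[j] = 2.0 * stats.t.sf(abs(t_vals[j]), n_sub - 1)
        elif dw.mean() != 0:
            # constant non-zero paired difference: infinitely significant
            t_vals[j] = math.copysign(math.inf, dw.mean())
            p_vals[j] = 0.0

    if isinstance(template, TemplateWaveform):
        tpl = template.resampled(int(sel.sum()))
    else:
        tpl = np.asarray(template, float)
        if tpl.size != sel.sum():
            old = np.linspace(0, 1, tpl.size)
            new = np.linspace(0, 1, int(sel.sum()))
            tpl = np.interp(new, old, tpl)
    corr = np.array([float(np.corrcoef(Vt[j], tpl)[0, 1]) for j in range(k)])

    sig = [j for j in range(k) if p_vals[j] < alpha]
    selected = None
    if sig:
        # larger |t| wins; near-ties go to the higher-variance component
        best = max(abs(t_vals[j]) for j in sig)
        tol = 0.0 if math.isinf(best) else 1e-6 * max(best, 1.0)
        selected = int(min(j for j in sig if abs(t_vals[j]) >= best - tol))
    return PCAResult(Vt[:k], var, weights, t_vals, p_vals, corr, selected,
                     tuple(window_ms), k, mu)
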