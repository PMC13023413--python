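"""ERP component quantification and nonparametric statistics.

Covers the evoked-response branch of the pipeline: ROI-averaged waveforms
per subject and condition, N1/P2 window amplitudes, pointwise t tests,
cluster-based permutation correction over time (and over time-frequency
grids), one-way repeated-measures ANOVA on window amplitudes, and the
topographic ANOVA (TANOVA) on global dissimilarity between GFP-normalized
scalp maps.

Permutation machinery follows the standard cluster-mass recipe: pointwise
two-tailed t tests at the cluster-forming threshold, clusters of adjacent
suprathreshold samples (4-connectivity on 2-D grids), cluster mass = sum of
t values, and a maximum-statistic null distribution built by within-subject
condition-label exchange (sign flips for paired designs).  Positive and
negative clusters are tracked separately.  Cluster p-values use the >=
convention including the observed labeling, so p >= 1/(n_permutations + 1);
when the design admits at most ``n_perm`` distinct relabelings the null is
enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .containers import EpochSet
from .montage import ROI_CHANNELS

logger = logging.getLogger(__name__)

__all__ = [
    "ERPWaveform",
    "Cluster",
    "ClusterTestResult",
    "TANOVAResult",
    "roi_average",
    "cohort_waveforms",
    "window_amplitude",
    "pointwise_test",
    "cluster_permutation_1d",
    "cluster_permutation_2d",
    "rm_anova_window",
    "condition_topographies",
    "tanova",
]

N1_WINDOW_MS = (100.0, 150.0)
P2_WINDOW_MS = (150.0, 250.0)


# --------------------------------------------------------------------- #
# waveforms and window amplitudes
# --------------------------------------------------------------------- #

@dataclass
class ERPWaveform:
    """Per-subject ROI-averaged waveforms for one condition."""

    values: np.ndarray  # (n_subjects, n_times), microvolts
    time_ms: np.ndarray
    condition: str
    subjects: list[str]
    roi: tuple[str, ...] = ROI_CHANNELS

    @property
    def grand_average(self) -> np.ndarray:
        return self.values.mean(axis=0)


def roi_average(ep: EpochSet,
                roi: tuple[str, ...] = ROI_CHANNELS) -> dict[str, ERPWaveform]:
    """Average epochs within (subject, condition), then over ROI channels.

    Returns one :class:`ERPWaveform` per condition with one row per subject.
    The two averaging steps commute by linearity; epochs first is the
    conventional order.
    """
    idx = ep.channel_indices(roi)  # raises naming the missing channel
    out: dict[str, ERPWaveform] = {}
    subjects = sorted(set(ep.subject_id))
    for cond in ep.conditions_present():
        rows, kept = [], []
        for subj in subjects:
            mask = (ep.condition == cond) & (ep.subject_id == subj)
            if not mask.any():
                continue
            rows.append(ep.data[mask][:, idx, :].mean(axis=(0, 1)))
            kept.append(subj)
        out[cond] = ERPWaveform(
            values=np.stack(rows, axis=0), time_ms=ep.time_ms.copy(),
            condition=cond, subjects=kept, roi=tuple(roi),
        )
    return out


def cohort_waveforms(epoch_sets: list[EpochSet],
                     roi: tuple[str, ...] = ROI_CHANNELS,
                     ) -> dict[str, ERPWaveform]:
    """ROI waveforms for a cohort given one :class:`EpochSet` per subject."""
    per_subject = [roi_average(ep, roi) for ep in epoch_sets]
    conditions = list(per_subject[0])
    out = {}
    for cond in conditions:
        values = np.concatenate([d[cond].values for d in per_subject], axis=0)
        subjects = [s for d in per_subject for s in d[cond].subjects]
        out[cond] = ERPWaveform(values=values,
                                time_ms=per_subject[0][cond].time_ms,
                                condition=cond, subjects=subjects,
                                roi=tuple(roi))
    return out


def window_amplitude(w: ERPWaveform | np.ndarray,
                     window_ms: tuple[float, float],
                     time_ms: np.ndarray | None = None) -> np.ndarray | float:
    """Mean amplitude over samples whose time lies in the closed window.

    For an :class:`ERPWaveform` returns one value per subject; for a bare
    1-D array (with ``time_ms``) a scalar.
    """
    if isinstance(w, ERPWaveform):
        values, time_ms = w.values, w.time_ms
    else:
        values = np.asarray(w, dtype=float)
        if time_ms is None:
            raise ValueError("time_ms required for array input")
    lo, hi = window_ms
    mask = (time_ms >= lo) & (time_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    out = values[..., mask].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------------- #
# pointwise tests
# --------------------------------------------------------------------- #

def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, ERPWaveform) else np.asarray(x, dtype=float)


def pointwise_test(group_a, group_b, paired: bool = True,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed t statistic and p value at every time point.

    ``paired=True`` (the default for within-subject condition contrasts)
    tests the per-subject difference; ``paired=False`` reproduces an
    independent-samples comparison.  Time points with zero variance yield
    NaN statistics and are excluded from clustering downstream.
    """
    a, b = _as_values(group_a), _as_values(group_b)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal shapes")
        if a.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        d = a - b
        n = d.shape[0]
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
        df = n - 1
    else:
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need at least 2 subjects per group")
        na, nb = a.shape[0], b.shape[0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(pooled > 0,
                         (a.mean(axis=0) - b.mean(axis=0))
                         / np.sqrt(pooled * (1.0 / na + 1.0 / nb)), np.nan)
        df = na + nb - 2
    p = 2.0 * sstats.t.sf(np.abs(t), df)
    return t, p


# --------------------------------------------------------------------- #
# cluster permutation
# --------------------------------------------------------------------- #

@dataclass
class Cluster:
    """A suprathreshold cluster with its mass statistic and permutation p."""

    indices: np.ndarray          # flat sample indices (1-D) or (k, 2) grid indices
    mass: float                  # sum of t values over the cluster
    p_value: float
    tail: str                    # "positive" | "negative"
    time_ms: tuple[float, float] | None = None
    freq_hz: tuple[float, float] | None = None


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    forming_alpha: float
    tail: str = "both"
    t_observed: np.ndarray | None = None
    enumerated: bool = False

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a 1-D boolean mask, as index arrays."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [np.arange(s, e) for s, e in zip(starts, stops)]


def _clusters_1d(t: np.ndarray, thresh: float) -> list[tuple[np.ndarray, float, str]]:
    finite = np.isfinite(t)
    out = []
    for idx in _runs(finite & (t > thresh)):
        out.append((idx, float(t[idx].sum()), "positive"))
    for idx in _runs(finite & (t < -thresh)):
        out.append((idx, float(t[idx].sum()), "negative"))
    return out


def _max_masses_1d(tmat: np.ndarray, thresh: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-permutation maximal positive and |negative| cluster masses."""
    n_perm = tmat.shape[0]
    pos = np.zeros(n_perm)
    neg = np.zeros(n_perm)
    for i in range(n_perm):
        row = tmat[i]
        for idx in _runs(np.isfinite(row) & (row > thresh)):
            pos[i] = max(pos[i], row[idx].sum())
        for idx in _runs(np.isfinite(row) & (row < -thresh)):
            neg[i] = max(neg[i], -row[idx].sum())
    return pos, neg


def _paired_t_matrix(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for sign-flipped paired differences, vectorized.

    ``d`` is (n_subjects, n_points); ``signs`` is (n_perm, n_subjects).
    Squared values are flip-invariant, so only the mean changes.
    """
    n = d.shape[0]
    ssq = (d ** 2).sum(axis=0)
    mean = signs @ d / n
    var = (ssq[None, :] - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, mean / np.sqrt(var / n), np.nan)
    return t


def _sign_matrix(n: int, n_perm: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Sign-flip design: exhaustive when feasible, sampled otherwise."""
    if 2 ** n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return signs, True
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    signs[0] = 1.0  # observed labeling included in the null
    return signs, False


def _perm_pvalues(observed: list[tuple[np.ndarray, float, str]],
                  pos_null: np.ndarray, neg_null: np.ndarray) -> list[float]:
    # two-tailed max-statistic null: the familywise reference is the larger
    # of the maximal positive and maximal |negative| cluster mass of each
    # permutation, so reporting both tails stays calibrated at alpha
    null = np.maximum(pos_null, neg_null)
    n_null = null.size
    ps = []
    for _, mass, tail in observed:
        count = int(np.sum(null >= abs(mass) - 1e-12))
        ps.append(min(count / n_null, 1.0))
    return ps


def cluster_permutation_1d(group_a, group_b, n_perm: int = 1000,
                           forming_alpha: float = 0.05, paired: bool = True,
                           seed: int | None = 0) -> ClusterTestResult:
    """Cluster-based permutation test over a 1-D (time) axis.

    Within-subject contrasts permute condition labels per subject, i.e.
    sign-flip the paired differences.  Cluster mass is the sum of t values;
    each observed cluster is compared against the null distribution of the
    maximal cluster mass of its tail.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse",
                       n_perm)
    a, b = _as_values(group_a), _as_values(group_b)
    rng = np.random.default_rng(seed)
    if paired:
        d = a - b
        n = d.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        thresh = sstats.t.ppf(1.0 - forming_alpha / 2.0, n - 1)
        t_obs, _ = pointwise_test(a, b, paired=True)
        observed = _clusters_1d(t_obs, thresh)
        signs, enumerated = _sign_matrix(n, n_perm, rng)
        tmat = _paired_t_matrix(d, signs)
    else:
        na, nb = a.shape[0], b.shape[0]
        thresh = sstats.t.ppf(1.0 - forming_alpha / 2.0, na + nb - 2)
        t_obs, _ = pointwise_test(a, b, paired=False)
        observed = _clusters_1d(t_obs, thresh)
        x = np.concatenate([a, b], axis=0)
        enumerated = False
        tmat = np.empty((n_perm, x.shape[1]))
        for i in range(n_perm):
            idx = (np.arange(na + nb) if i == 0
                   else rng.permutation(na + nb))
            t_i, _ = pointwise_test(x[idx[:na]], x[idx[na:]], paired=False)
            tmat[i] = t_i
    pos_null, neg_null = _max_masses_1d(tmat, thresh)
    pvals = _perm_pvalues(observed, pos_null, neg_null)
    # report for group_a's time axis when available
    time_ms = group_a.time_ms if isinstance(group_a, ERPWaveform) else None
    clusters = []
    for (idx, mass, tail), p in zip(observed, pvals):
        extent = None
        if time_ms is not None:
            extent = (float(time_ms[idx[0]]), float(time_ms[idx[-1]]))
        clusters.append(Cluster(indices=idx, mass=mass, p_value=p, tail=tail,
                                time_ms=extent))
    return ClusterTestResult(clusters=clusters, n_permutations=tmat.shape[0],
                             forming_alpha=forming_alpha, tail="both",
                             t_observed=t_obs, enumerated=enumerated)


def _clusters_2d(t: np.ndarray, thresh: float) -> list[tuple[np.ndarray, float, str]]:
    finite = np.isfinite(t)
    out = []
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    for tail, mask in (("positive", finite & (t > thresh)),
                       ("negative", finite & (t < -thresh))):
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labels == lab)
            out.append((idx, float(t[labels == lab].sum()), tail))
    return out


def cluster_permutation_2d(tf_a: np.ndarray, tf_b: np.ndarray,
                           n_perm: int = 1000, forming_alpha: float = 0.05,
                           seed: int | None = 0,
                           freqs_hz: np.ndarray | None = None,
                           time_ms: np.ndarray | None = None,
                           ) -> ClusterTestResult:
    """Paired cluster permutation over a 2-D time-frequency grid.

    ``tf_a``/``tf_b`` are (n_subjects, n_freqs, n_times).  Clusters are
    4-connected over the grid; everything else matches the 1-D test.
    """
    a = np.asarray(tf_a, dtype=float)
    b = np.asarray(tf_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("expect matching (n_subjects, n_freqs, n_times) arrays")
    n, nf, nt = a.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse",
                       n_perm)
    rng = np.random.default_rng(seed)
    thresh = sstats.t.ppf(1.0 - forming_alpha / 2.0, n - 1)
    d = (a - b).reshape(n, nf * nt)
    t_obs, _ = pointwise_test(a.reshape(n, -1), b.reshape(n, -1), paired=True)
    t_obs = t_obs.reshape(nf, nt)
    observed = _clusters_2d(t_obs, thresh)
    signs, enumerated = _sign_matrix(n, n_perm, rng)
    tmat = _paired_t_matrix(d, signs)
    pos_null = np.zeros(tmat.shape[0])
    neg_null = np.zeros(tmat.shape[0])
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for i in range(tmat.shape[0]):
        grid = tmat[i].reshape(nf, nt)
        finite = np.isfinite(grid)
        labels, n_lab = ndimage.label(finite & (grid > thresh), structure=structure)
        if n_lab:
            pos_null[i] = ndimage.sum_labels(grid, labels,
                                             np.arange(1, n_lab + 1)).max()
        labels, n_lab = ndimage.label(finite & (grid < -thresh),
                                      structure=structure)
        if n_lab:
            neg_null[i] = -ndimage.sum_labels(grid, labels,
                                              np.arange(1, n_lab + 1)).min()
    pvals = _perm_pvalues(observed, pos_null, neg_null)
    clusters = []
    for (idx, mass, tail), p in zip(observed, pvals):
        t_extent = f_extent = None
        if time_ms is not None:
            t_extent = (float(time_ms[idx[:, 1].min()]),
                        float(time_ms[idx[:, 1].max()]))
        if freqs_hz is not None:
            f_extent = (float(freqs_hz[idx[:, 0].min()]),
                        float(freqs_hz[idx[:, 0].max()]))
        clusters.append(Cluster(indices=idx, mass=mass, p_value=p, tail=tail,
                                time_ms=t_extent, freq_hz=f_extent))
    return ClusterTestResult(clusters=clusters, n_permutations=tmat.shape[0],
                             forming_alpha=forming_alpha, tail="both",
                             t_observed=t_obs, enumerated=enumerated)


# --------------------------------------------------------------------- #
# repeated-measures ANOVA
# --------------------------------------------------------------------- #

def rm_anova_window(amplitudes: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Returns F with (k-1, (k-1)(n-1)) degrees of freedom via the explicit
    sums-of-squares decomposition (condition + subject + residual).
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.ndim != 2:
        raise ValueError("expect subjects x conditions table")
    if np.isnan(x).any():
        raise ValueError("table must be complete (no missing cells)")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    gm = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_total = np.sum((x - gm) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    f = (ss_cond / df1) / ms_err if ms_err > 0 else (
        0.0 if ss_cond == 0 else np.inf)
    p = float(sstats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return {"F": float(f), "df": (df1, df2), "p": p,
            "ss_cond": float(ss_cond), "ss_err": float(ss_err)}


# --------------------------------------------------------------------- #
# TANOVA
# --------------------------------------------------------------------- #

@dataclass
class TANOVAResult:
    diss: np.ndarray        # global dissimilarity per time point
    p: np.ndarray           # permutation p value per time point
    n_permutations: int
    window_ms: tuple[float, float] | None = None
    time_ms: np.ndarray | None = None
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def condition_topographies(epoch_sets: list[EpochSet],
                           conditions: list[str] | None = None,
                           window_ms: tuple[float, float] | None = None,
                           ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack per-subject condition-average scalp maps.

    Returns ``(maps, conditions, time_ms)`` with maps shaped
    (n_subjects, n_conditions, n_channels, n_times), optionally restricted
    to ``window_ms``.
    """
    first = epoch_sets[0]
    conditions = conditions or first.conditions_present()
    time_ms = first.time_ms
    mask = np.ones(time_ms.size, dtype=bool)
    if window_ms is not None:
        mask = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
        if not mask.any():
            raise ValueError(f"window {window_ms} contains no samples")
    maps = []
    for ep in epoch_sets:
        per_cond = []
        for cond in conditions:
            sel = ep.condition == cond
            if not sel.any():
                raise ValueError(f"{ep.subject_id[0]} lacks condition {cond!r}")
            per_cond.append(ep.data[sel][:, :, mask].mean(axis=0))
        maps.append(np.stack(per_cond, axis=0))
    return np.stack(maps, axis=0), list(conditions), time_ms[mask]


def _diss(grand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise DISS between GFP-normalized condition maps.

    ``grand`` is (n_conditions, n_channels, n_times).  Returns the DISS
    series and a boolean mask of time points excluded for zero GFP.
    """
    gfp = np.sqrt(np.mean(grand ** 2, axis=1, keepdims=True))
    excluded = (gfp[:, 0, :] == 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        normed = np.where(gfp > 0, grand / gfp, 0.0)
    c = grand.shape[0]
    pairs = list(itertools.combinations(range(c), 2))
    diss = np.zeros(grand.shape[2])
    for i, j in pairs:
        diss += np.sqrt(np.mean((normed[i] - normed[j]) ** 2, axis=0))
    diss /= len(pairs)
    diss[excluded] = np.nan
    return diss, excluded


def tanova(maps: np.ndarray, n_perm: int = 1000,
           window_ms: tuple[float, float] | None = None,
           time_ms: np.ndarray | None = None,
           seed: int | None = 0, chunk: int = 64) -> TANOVAResult:
    """Topographic ANOVA: permutation test on global map dissimilarity.

    ``maps`` is (n_subjects, n_conditions, n_channels, n_times).  Per time
    point each condition's grand-average map is normalized by its global
    field power; DISS is the mean pairwise RMS difference between the
    normalized maps.  The null shuffles condition labels within subject.
    Time points where any condition has zero GFP are excluded (NaN) and
    flagged.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[..., None]
    s, c, _, n_t = maps.shape
    if c < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    obs, excluded = _diss(maps.mean(axis=0))
    if excluded.any():
        logger.info("tanova: %d time point(s) excluded for zero GFP",
                    int(excluded.sum()))
    exceed = np.zeros(n_t)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # independent within-subject shuffles per permutation
        idx = np.stack([np.stack([rng.permutation(c) for _ in range(s)])
                        for _ in range(m)])  # (m, s, c)
        shuffled = np.take_along_axis(maps[None], idx[..., None, None], axis=2)
        grand = shuffled.mean(axis=1)  # (m, c, ch, t)
        for g in grand:
            null, _ = _diss(g)
            exceed += (null >= obs - 1e-12)
        done += m
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[excluded] = np.nan
    return TANOVAResult(diss=obs, p=p, n_permutations=n_perm,
                        window_ms=window_ms, time_ms=time_ms,
                        excluded=excluded)
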