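"""Trajectory summaries and the three-group statistical comparison.

Per-trajectory summaries: the beta ratio (mean beta-band envelope fraction in
the motor subregion over the pre-STN reference segment), the peak and area
under the curve of the normalized RMS on the normalized depth axis, and band
means.  Group comparison: Shapiro-Wilk normality gate, then one-way ANOVA
(all groups normal) or Kruskal-Wallis, with Bonferroni-corrected Welch
t-tests as post hocs when the omnibus test rejects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .borders import StnAnnotation, _best_changepoint


class DegenerateDataError(ValueError):
    """All values identical: no comparison is possible."""


def beta_ratio(beta_fractions: Sequence[float], depths: Sequence[float],
               annotation: StnAnnotation,
               motor_definition: str = "first_quarter") -> float:
    """Motor-subregion beta power over pre-STN beta power.

    Numerator: mean beta fraction over sites within the first quarter (or
    first half, ``motor_definition="first_half"``) of the STN below entry.
    Denominator: mean beta fraction over pre-STN sites within half an STN
    length above entry.  Returns nan when either segment is empty or the
    denominator is zero.
    """
    if motor_definition not in ("first_quarter", "first_half"):
        raise ValueError(f"unknown motor definition {motor_definition!r}")
    frac = 0.25 if motor_definition == "first_quarter" else 0.5
    beta = np.asarray(beta_fractions, dtype=float)
    d = np.asarray(depths, dtype=float)
    entry_d = annotation.entry_depth_mm
    length = annotation.entry_depth_mm - annotation.exit_depth_mm
    if length <= 0:
        return float("nan")
    offset = entry_d - d  # >= 0 inside the STN, < 0 above it
    motor = (offset >= 0) & (offset <= frac * length + 1e-9)
    pre = (offset < 0) & (-offset <= 0.5 * length + 1e-9)
    if not motor.any() or not pre.any():
        return float("nan")
    denom = beta[pre].mean()
    if denom <= 0:
        return float("nan")
    return float(beta[motor].mean() / denom)


def nrms_peak(grid: Sequence[float], nrms: Sequence[float]) -> float:
    """Maximum NRMS over the normalized STN extent [0, 1]."""
    g = np.asarray(grid, dtype=float)
    v = np.asarray(nrms, dtype=float)
    mask = (g >= 0.0) & (g <= 1.0)
    if not mask.any():
        raise ValueError("grid does not cover [0, 1]")
    return float(v[mask].max())


def nrms_auc(grid: Sequence[float], nrms: Sequence[float]) -> float:
    """Trapezoidal integral of NRMS over the normalized STN extent [0, 1]."""
    g = np.asarray(grid, dtype=float)
    v = np.asarray(nrms, dtype=float)
    mask = (g >= 0.0) & (g <= 1.0)
    if mask.sum() < 2:
        raise ValueError("grid does not cover [0, 1]")
    return float(np.trapezoid(v[mask], g[mask]))


def percent_motor(grid: Sequence[float], beta_profile: Sequence[float],
                  delta_profile: Sequence[float] | None = None,
                  contrast_floor: float = 0.2,
                  fallback_percent: float = 25.0) -> tuple[float, bool]:
    """Motor-subregion extent (percent of STN length) from group-averaged
    band profiles on the normalized axis.

    A single changepoint on the averaged beta profile over [0, 1] (delta
    fallback) marks the motor/non-motor border; indistinct profiles return
    the fallback percent, flagged.
    """
    g = np.asarray(grid, dtype=float)
    mask = (g >= 0.0) & (g <= 1.0)
    gg = g[mask]
    for prof in (beta_profile, delta_profile):
        if prof is None:
            continue
        vals = np.asarray(prof, dtype=float)[mask]
        if vals.size < 4:
            continue
        k, contrast = _best_changepoint(vals, min_side=2)
        mean_all = vals.mean()
        if mean_all > 0 and contrast / mean_all >= contrast_floor:
            return float(gg[k] * 100.0), False
    return fallback_percent, True


@dataclass
class TrajectorySummary:
    """Scalar statistics of one trajectory used in group comparisons."""

    trajectory_id: str
    group: str
    beta_ratio: float
    nrms_peak: float
    nrms_auc: float
    motor_band_means: dict[str, float] = field(default_factory=dict)
    pre_band_means: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def summarize_trajectory(tf, annotation: StnAnnotation,
                         motor_definition: str = "first_quarter",
                         n_grid: int = 100) -> TrajectorySummary:
    """Build the per-trajectory summary from extracted features."""
    from .features import normalize_depth_axis
    grid, nrms_g = normalize_depth_axis(tf.depths_mm, tf.nrms, annotation,
                                        n_grid=n_grid)
    d = tf.depths_mm
    length = annotation.entry_depth_mm - annotation.exit_depth_mm
    offset = annotation.entry_depth_mm - d
    motor = (offset >= 0) & (offset <= 0.25 * length + 1e-9)
    pre = (offset < 0) & (-offset <= 0.5 * length + 1e-9)
    motor_means = {c: float(tf.band_powers[c][motor].mean())
                   for c in tf.band_powers.columns} if motor.any() else {}
    pre_means = {c: float(tf.band_powers[c][pre].mean())
                 for c in tf.band_powers.columns} if pre.any() else {}
    return TrajectorySummary(
        trajectory_id=tf.trajectory_id, group=tf.group,
        beta_ratio=beta_ratio(tf.band_powers["beta"].to_numpy(), d,
                              annotation, motor_definition=motor_definition),
        nrms_peak=nrms_peak(grid, nrms_g),
        nrms_auc=nrms_auc(grid, nrms_g),
        motor_band_means=motor_means, pre_band_means=pre_means,
        flags=annotation.flags)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class PairResult:
    statistic: float
    p_raw: float
    p_corrected: float


@dataclass
class GroupComparison:
    """Omnibus test plus Bonferroni-corrected pairwise post hocs."""

    test_name: str
    statistic: float
    p_value: float
    normality: dict[str, bool]
    posthoc: dict[tuple[str, str], PairResult]
    alpha: float
    n_per_group: dict[str, int]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "normality": self.normality,
            "n_per_group": self.n_per_group,
            "posthoc": {f"{a}_vs_{b}": {"statistic": r.statistic,
                                        "p_raw": r.p_raw,
                                        "p_corrected": r.p_corrected}
                        for (a, b), r in self.posthoc.items()},
        }


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if values.size < 3 or np.ptp(values) == 0:
        return False
    try:
        return bool(sstats.shapiro(values).pvalue > alpha)
    except ValueError:
        return False


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    stat, p = sstats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both samples
        equal = np.isclose(a.mean(), b.mean())
        return (0.0, 1.0) if equal else (float("inf"), 0.0)
    return float(stat), float(p)


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> GroupComparison:
    """Shapiro-gated omnibus comparison with Bonferroni post hocs.

    All groups normal (Shapiro-Wilk at the same alpha) => one-way ANOVA,
    otherwise Kruskal-Wallis.  If the omnibus test rejects, pairwise Welch
    t-tests are run and corrected by the number of pairs (3 for 3 groups).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        if not np.isfinite(v).all():
            raise ValueError(f"group {g!r} contains non-finite values")
    allv = np.concatenate(list(groups.values()))
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all values identical across groups")
    normality = {g: _is_normal(v, alpha) for g, v in groups.items()}
    arrays = list(groups.values())
    if all(normality.values()):
        stat, p = sstats.f_oneway(*arrays)
        name = "anova"
    else:
        stat, p = sstats.kruskal(*arrays)
        name = "kruskal_wallis"
    posthoc: dict[tuple[str, str], PairResult] = {}
    if p < alpha:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        m = len(pairs)
        for a, b in pairs:
            t, praw = _welch_p(groups[a], groups[b])
            posthoc[(a, b)] = PairResult(t, praw, min(1.0, m * praw))
    return GroupComparison(
        test_name=name, statistic=float(stat), p_value=float(p),
        normality=normality, posthoc=posthoc, alpha=alpha,
        n_per_group={g: int(v.size) for g, v in groups.items()})


def group_average_curves(curves_by_group: Mapping[str, np.ndarray],
                         ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and SEM per group of trajectories on a common grid.

    Input arrays are (n_trajectories, n_grid[, n_freq]); SEM uses the sample
    SD over n (nan for a single trajectory).
    """
    out = {}
    for g, arr in curves_by_group.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim < 2:
            raise ValueError("expected (n_trajectories, n_grid) arrays")
        n = a.shape[0]
        mean = a.mean(axis=0)
        sem = a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
        out[g] = (mean, sem)
    return out
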