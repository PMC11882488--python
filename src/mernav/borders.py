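"""STN border and subdomain detection from per-site trajectory features.

Entry and exit are found as sustained elevations of the normalized RMS above
the pre-STN baseline; the motor/non-motor border as the single changepoint
that best separates the beta-band envelope power inside the nucleus (falling
back to the delta band, then to a fixed first-quarter heuristic when neither
band shows a distinct step — trajectories taking the fallback are flagged
"subdomain-indistinct").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StnAnnotation:
    """Entry/exit/motor-border delineation of one trajectory.

    ``method`` records provenance: "ground_truth" (from the generator),
    "detected" (this module) or "corrected" (expert override).
    """

    entry_index: int
    exit_index: int
    motor_border_index: int
    entry_depth_mm: float
    exit_depth_mm: float
    length_mm: float
    method: str = "detected"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "degenerate" in self.flags:
            return
        if not self.entry_index < self.motor_border_index <= self.exit_index:
            raise ValueError(
                f"require entry < motor_border <= exit, got "
                f"{self.entry_index}/{self.motor_border_index}/{self.exit_index}")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")


class MotorBorder(NamedTuple):
    index: int
    flagged: bool
    basis: str  # "beta", "delta" or "fallback"


def detect_entry_exit(nrms: Sequence[float], threshold: float = 1.25,
                      min_run: int = 3) -> Optional[tuple[int, int]]:
    """First and last site of sustained NRMS elevation, or None.

    Entry is the first site starting a run of at least ``min_run``
    consecutive sites with NRMS >= threshold; exit is the last site of the
    final such run.  Returns None when no qualifying run exists ("no STN
    detected") so cohort-level processing can flag rather than fail.
    """
    above = np.asarray(nrms, dtype=float) >= threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and above.size - start >= min_run:
        runs.append((start, int(above.size) - 1))
    if not runs:
        return None
    return runs[0][0], runs[-1][1]


def _best_changepoint(values: np.ndarray, min_side: int = 2) -> tuple[int, float]:
    """Split index (start of right segment) maximizing |mean_L - mean_R|.

    Ties break toward the earlier split (conservative motor extent).
    Returns (relative index, absolute contrast).
    """
    n = values.size
    if n < 2 * min_side:
        raise ValueError("too few sites for a changepoint")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    best_k, best_c = min_side, -1.0
    for k in range(min_side, n - min_side + 1):
        left = csum[k] / k
        right = (csum[n] - csum[k]) / (n - k)
        c = abs(left - right)
        if c > best_c + 1e-15:
            best_k, best_c = k, c
    return best_k, best_c


def delineate_motor_border(beta_power: Sequence[float], entry: int, exit: int,
                           delta_power: Sequence[float] | None = None,
                           contrast_floor: float = 0.2,
                           fallback_fraction: float = 0.25,
                           min_side: int = 2) -> MotorBorder:
    """Motor/non-motor border as a single changepoint inside (entry, exit].

    The changepoint statistic is evaluated on the beta-band power profile;
    if its relative contrast (|mean_L - mean_R| / overall mean) is below
    ``contrast_floor`` the delta band is tried; if both are indistinct the
    border falls back to entry + fallback_fraction * (exit - entry) and the
    trajectory is flagged.
    """
    if not entry < exit:
        raise ValueError("require entry < exit")
    n_inner = exit - entry  # sites in (entry, exit]
    fallback = entry + max(1, int(round(fallback_fraction * (exit - entry))))
    if n_inner < 2 * min_side:
        return MotorBorder(min(fallback, exit), True, "fallback")
    for basis, prof in (("beta", beta_power), ("delta", delta_power)):
        if prof is None:
            continue
        vals = np.asarray(prof, dtype=float)[entry + 1:exit + 1]
        k, contrast = _best_changepoint(vals, min_side=min_side)
        mean_all = vals.mean()
        rel = contrast / mean_all if mean_all > 0 else 0.0
        if rel >= contrast_floor:
            return MotorBorder(entry + 1 + k, False, basis)
    return MotorBorder(min(fallback, exit), True, "fallback")


def electrophysiological_length(annotation: StnAnnotation,
                                depths: Sequence[float] | None = None) -> float:
    """STN length in mm (entry depth minus exit depth)."""
    if depths is not None:
        d = np.asarray(depths, dtype=float)
        return float(d[annotation.entry_index] - d[annotation.exit_index])
    return float(annotation.entry_depth_mm - annotation.exit_depth_mm)


def annotate_trajectory(nrms: Sequence[float], depths: Sequence[float],
                        beta_power: Sequence[float] | None = None,
                        delta_power: Sequence[float] | None = None,
                        threshold: float = 1.25, min_run: int = 3,
                        contrast_floor: float = 0.2,
                        fallback_fraction: float = 0.25,
                        ) -> Optional[StnAnnotation]:
    """Full border detection for one trajectory; None if no STN is found."""
    hit = detect_entry_exit(nrms, threshold=threshold, min_run=min_run)
    if hit is None:
        return None
    entry, exit = hit
    depths = np.asarray(depths, dtype=float)
    flags: list[str] = []
    if exit <= entry:
        return StnAnnotation(entry, exit, exit, float(depths[entry]),
                             float(depths[exit]), 0.0, method="detected",
                             flags=("degenerate",))
    if beta_power is not None:
        mb = delineate_motor_border(beta_power, entry, exit,
                                    delta_power=delta_power,
                                    contrast_floor=contrast_floor,
                                    fallback_fraction=fallback_fraction)
        if mb.flagged:
            flags.append("subdomain-indistinct")
        motor = mb.index
    else:
        motor = entry + max(1, int(round(fallback_fraction * (exit - entry))))
        flags.append("subdomain-indistinct")
    length = float(depths[entry] - depths[exit])
    return StnAnnotation(entry, exit, motor, float(depths[entry]),
                         float(depths[exit]), length, method="detected",
                         flags=tuple(flags))


def apply_overrides(annotations: dict[str, Optional[StnAnnotation]],
                    overrides: pd.DataFrame,
                    depths_by_trajectory: dict[str, np.ndarray],
                    ) -> dict[str, Optional[StnAnnotation]]:
    """Expert correction: replace detected indices per trajectory.

    ``overrides`` needs columns trajectory_id, entry_index, exit_index,
    motor_border_index; corrected annotations get method="corrected".
    """
    required = {"trajectory_id", "entry_index", "exit_index", "motor_border_index"}
    missing = required - set(overrides.columns)
    if missing:
        raise ValueError(f"override table missing columns: {sorted(missing)}")
    out = dict(annotations)
    for row in overrides.itertuples():
        tid = row.trajectory_id
        if tid not in depths_by_trajectory:
            raise KeyError(f"unknown trajectory_id {tid!r} in overrides")
        d = np.asarray(depths_by_trajectory[tid], dtype=float)
        e, x, m = int(row.entry_index), int(row.exit_index), int(row.motor_border_index)
        out[tid] = StnAnnotation(e, x, m, float(d[e]), float(d[x]),
                                 float(d[e] - d[x]), method="corrected")
    return out
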