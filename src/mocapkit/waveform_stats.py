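"""Agreement statistics between joint-angle waveforms from two systems.

Implements vertical mean-shift alignment and the within-day Kadaba-form
coefficient of multiple correlation (CMC): the ratio of the between-curve
variance at each time point to the total variance, subtracted from one,
under a square root. A ratio above one (curves differ more than the
signal varies) yields an *undefined* CMC, reported as a flag rather than
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "JointAngleWaveform",
    "CMCReport",
    "CmcValue",
    "mean_shift_align",
    "cmc",
    "compare_systems",
    "time_normalize",
    "PLANES",
]

PLANES = ("flexion_extension", "abduction_adduction", "varus_valgus")


@dataclass
class JointAngleWaveform:
    """Time-normalized angle curves (degrees) for one joint/plane/system."""

    joint: str
    plane: str
    system: str
    trials: np.ndarray  # (T, N)

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[0] < 1 or self.trials.shape[1] < 2:
            raise ValueError("trials must be a (T >= 1, N >= 2) table")
        if not np.all(np.isfinite(self.trials)):
            raise ValueError("waveform contains non-finite angles")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")


class CmcValue(NamedTuple):
    """CMC outcome: value in [0, 1] when defined, else NaN plus a reason."""

    value: float
    defined: bool
    reason: str | None = None


@dataclass
class CMCReport:
    joint: str
    plane: str
    cmc: float
    defined: bool
    n_trials: int
    n_samples: int
    skipped: bool = False
    reason: str | None = None


def mean_shift_align(curveA: np.ndarray, curveB: np.ndarray) -> np.ndarray:
    """Translate curveA vertically so its mean equals curveB's mean.

    Works on 1-D curves or (T, N) trial tables (a single shift computed
    over all samples). Shape, and therefore variance, is untouched.
    """
    a = np.asarray(curveA, dtype=float)
    b = np.asarray(curveB, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"curve length mismatch: {a.shape[-1]} vs {b.shape[-1]} samples"
        )
    return a - a.mean() + b.mean()


def cmc(waveforms: np.ndarray) -> CmcValue:
    """Coefficient of multiple correlation over an (M, N) curve table.

    CMC = sqrt(1 - [within-time variance across curves] / [total variance
    about the grand mean]); identical curves give exactly 1. Undefined when
    the total variance vanishes or the variance ratio exceeds one.
    """
    y = np.atleast_2d(np.asarray(waveforms, dtype=float))
    M, N = y.shape
    if M < 2:
        raise ValueError("CMC needs at least 2 curves")
    if N < 2:
        raise ValueError("CMC needs at least 2 samples per curve")
    tmean = y.mean(axis=0)  # mean across curves at each sample
    gmean = y.mean()
    num = np.sum((y - tmean) ** 2) / (N * (M - 1))
    den = np.sum((y - gmean) ** 2) / (M * N - 1)
    if den <= 0.0:
        return CmcValue(float("nan"), False, "zero total variance")
    ratio = num / den
    if ratio > 1.0:
        return CmcValue(
            float("nan"), False, f"variance ratio {ratio:.4g} exceeds 1"
        )
    return CmcValue(float(np.sqrt(1.0 - ratio)), True, None)


def time_normalize(curve: np.ndarray, n_samples: int = 101) -> np.ndarray:
    """Resample a cycle to ``n_samples`` points by linear interpolation."""
    curve = np.asarray(curve, dtype=float)
    old = np.linspace(0.0, 1.0, curve.shape[-1])
    new = np.linspace(0.0, 1.0, n_samples)
    if curve.ndim == 1:
        return np.interp(new, old, curve)
    return np.stack([np.interp(new, old, row) for row in curve])


def compare_systems(
    systemA: list[JointAngleWaveform],
    systemB: list[JointAngleWaveform],
    align: bool = True,
) -> list[CMCReport]:
    """Per-(joint, plane) CMC between two measurement systems.

    Each system's trials are averaged into its mean curve (after optionally
    mean-shifting each of system A's trials to system B's grand mean) and
    the CMC is taken between the two mean curves, so identical systems
    score exactly 1 regardless of trial-to-trial noise. Joints present in
    only one system are reported as skipped.
    """
    index_b = {(w.joint, w.plane): w for w in systemB}
    seen: set[tuple[str, str]] = set()
    reports: list[CMCReport] = []
    for wa in systemA:
        key = (wa.joint, wa.plane)
        seen.add(key)
        wb = index_b.get(key)
        if wb is None:
            reports.append(
                CMCReport(
                    joint=wa.joint,
                    plane=wa.plane,
                    cmc=float("nan"),
                    defined=False,
                    n_trials=wa.trials.shape[0],
                    n_samples=wa.trials.shape[1],
                    skipped=True,
                    reason="missing from system B",
                )
            )
            continue
        if wa.trials.shape[1] != wb.trials.shape[1]:
            raise ValueError(
                f"{key}: sample-count mismatch "
                f"({wa.trials.shape[1]} vs {wb.trials.shape[1]})"
            )
        a_trials = wa.trials
        if align:
            target_mean = wb.trials.mean()
            a_trials = np.stack(
                [t - t.mean() + target_mean for t in a_trials]
            )
        stacked = np.vstack([a_trials.mean(axis=0), wb.trials.mean(axis=0)])
        result = cmc(stacked)
        reports.append(
            CMCReport(
                joint=wa.joint,
                plane=wa.plane,
                cmc=result.value,
                defined=result.defined,
                n_trials=a_trials.shape[0] + wb.trials.shape[0],
                n_samples=stacked.shape[1],
                reason=result.reason,
            )
        )
    for wb in systemB:
        key = (wb.joint, wb.plane)
        if key not in seen:
            reports.append(
                CMCReport(
                    joint=wb.joint,
                    plane=wb.plane,
                    cmc=float("nan"),
                    defined=False,
                    n_trials=wb.trials.shape[0],
                    n_samples=wb.trials.shape[1],
                    skipped=True,
                    reason="missing from system A",
                )
            )
    return reports
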