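"""Trace selection: photobleaching step detection, blinking detection,
and the intensity/quality criteria that define the analyzable molecule set.

A trace passes when its pre-bleach donor-excitation intensity I_DD lies
in 300–2000 counts and I_AA in 200–2000 counts, it shows at most one
donor and one acceptor photobleaching step, neither dye bleaches within
the first 50 frames, the trace lasts at least 50 frames, and neither dye
blinks.  Passing traces carry a truncation frame (first bleach event, or
trace end) that downstream statistics must respect.

Step detection replaces the manual trace inspection of the original
workflow with a parameterized change-point test: recursive binary
segmentation on a two-window mean-difference statistic measured in units
of the robust noise sigma, with a persistence (minimum segment length)
requirement.  A down-step later reversed by recovery to near the prior
level is a blink; unreversed down-steps to a background-consistent level
are bleaching candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QcCriteria",
    "StepEvent",
    "QcResult",
    "QcReport",
    "detect_bleach_steps",
    "detect_blinking",
    "apply_qc",
    "apply_qc_dataset",
]


@dataclass
class QcCriteria:
    idd_min: float = 300.0
    idd_max: float = 2000.0
    iaa_min: float = 200.0
    iaa_max: float = 2000.0
    early_bleach_window: int = 50  # frames 1-50, 1-based inclusive
    min_trace_frames: int = 50
    reject_multistep: bool = True
    reject_blinking: bool = True
    # step-detector parameters (noise-sigma units unless stated)
    step_threshold: float = 5.0  # z-threshold of the change-point statistic
    min_segment: int = 5  # persistence requirement, frames
    magnitude_sigma: float = 4.0  # minimum |step| in sigma units
    recovery_tol: float = 0.3  # relative recovery defining a blink
    background_fraction: float = 0.35  # post/pre level ratio calling "dark"

    def __post_init__(self) -> None:
        if self.idd_min >= self.idd_max or self.iaa_min >= self.iaa_max:
            raise ValueError("intensity windows must satisfy min < max")
        if self.early_bleach_window <= 0 or self.min_trace_frames <= 0:
            raise ValueError("frame counts must be positive")


@dataclass(frozen=True)
class StepEvent:
    """A persistent level change at ``frame`` (first frame of the new level)."""

    frame: int
    direction: int  # +1 up, -1 down
    magnitude: float
    pre_level: float
    post_level: float


@dataclass
class QcResult:
    molecule_id: int
    passed: bool
    first_fail: str  # "" when passed
    truncation_frame: int


@dataclass
class QcReport:
    table: pd.DataFrame  # molecule_id, verdict, first_fail_reason, truncation_frame
    counts: dict

    @property
    def n_pass(self) -> int:
        return int((self.table["verdict"] == "pass").sum())


def _robust_sigma(x: np.ndarray) -> float:
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _changepoints(x: np.ndarray, threshold: float, min_seg: int, sigma: float):
    """Recursive binary segmentation; returns sorted change frames."""
    cps: list[int] = []
    csum = np.concatenate([[0.0], np.cumsum(x)])

    def stat_max(lo: int, hi: int):
        # best split t in (lo+min_seg, hi-min_seg]
        ts = np.arange(lo + min_seg, hi - min_seg + 1)
        if len(ts) == 0:
            return None
        n1 = ts - lo
        n2 = hi - ts
        m1 = (csum[ts] - csum[lo]) / n1
        m2 = (csum[hi] - csum[ts]) / n2
        z = np.abs(m1 - m2) / (sigma * np.sqrt(1.0 / n1 + 1.0 / n2))
        i = int(np.argmax(z))
        return int(ts[i]), float(z[i])

    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_seg:
            continue
        best = stat_max(lo, hi)
        if best is None:
            continue
        t, z = best
        if z >= threshold:
            cps.append(t)
            stack.append((lo, t))
            stack.append((t, hi))
    return sorted(cps)


def detect_bleach_steps(
    channel,
    threshold: float = 5.0,
    min_segment: int = 5,
    magnitude_sigma: float = 4.0,
) -> list[StepEvent]:
    """Detect persistent intensity steps in one channel.

    Change-points come from recursive binary segmentation of the trace on
    a two-window mean-difference statistic in robust-noise-sigma units;
    adjacent-segment mean differences below ``magnitude_sigma`` noise
    units are discarded.  Noiseless traces use an internal sigma floor so
    that any genuine step registers.
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < 2 * min_segment:
        raise ValueError(
            f"trace of length {len(x)} shorter than twice the persistence "
            f"window ({min_segment})"
        )
    sigma = max(_robust_sigma(x), 1e-9)
    cps = _changepoints(x, threshold, min_segment, sigma)
    if not cps:
        return []
    bounds = [0, *cps, len(x)]
    levels = [float(np.mean(x[bounds[i]:bounds[i + 1]])) for i in range(len(bounds) - 1)]
    steps = []
    for i, cp in enumerate(cps):
        pre, post = levels[i], levels[i + 1]
        mag = post - pre
        if abs(mag) < magnitude_sigma * sigma:
            continue
        steps.append(
            StepEvent(
                frame=cp,
                direction=1 if mag > 0 else -1,
                magnitude=abs(mag),
                pre_level=pre,
                post_level=post,
            )
        )
    return steps


def _pair_blinks(steps: list[StepEvent], recovery_tol: float):
    """Split steps into blink pairs (down later recovered) and bleach
    candidates (unreversed down-steps)."""
    blinks = []
    bleaches = []
    used = [False] * len(steps)
    for i, s in enumerate(steps):
        if s.direction != -1 or used[i]:
            continue
        recovered = False
        for j in range(i + 1, len(steps)):
            u = steps[j]
            if used[j] or u.direction != 1:
                continue
            if abs(u.post_level - s.pre_level) <= recovery_tol * max(
                abs(s.pre_level), 1e-9
            ):
                used[i] = used[j] = True
                blinks.append((s, u))
                recovered = True
                break
        if not recovered:
            bleaches.append(s)
    return blinks, bleaches


def detect_blinking(
    channel,
    steps: list[StepEvent] | None = None,
    recovery_tol: float = 0.3,
) -> bool:
    """True when the channel shows a dark excursion followed by recovery
    to (within ``recovery_tol`` of) the prior level."""
    if steps is None:
        steps = detect_bleach_steps(channel)
    blinks, _ = _pair_blinks(steps, recovery_tol)
    return len(blinks) > 0


def _bleach_frame(bleaches: list[StepEvent], background_fraction: float):
    """First unreversed down-step landing at a background-consistent level."""
    for s in bleaches:
        if s.post_level <= background_fraction * max(s.pre_level, 1e-9):
            return s.frame
    return None


def apply_qc(trace, criteria: QcCriteria | None = None) -> QcResult:
    """Evaluate the selection criteria on one trace.

    Donor photophysics is read from the donor-excitation total
    I_DD + I_DA (donor bleach/blink drops it to background; acceptor
    bleach leaves it nearly unchanged because the donor dequenches), and
    acceptor photophysics from I_AA.  Intensity windows are evaluated on
    pre-first-bleach segment means.  Verdicts are deterministic and
    order-independent across molecules.
    """
    if criteria is None:
        criteria = QcCriteria()
    n = len(trace.i_dd)
    if n < criteria.min_trace_frames:
        return QcResult(trace.molecule_id, False, "too_short", 0)

    donor_sum = trace.i_dd + trace.i_da
    kw = dict(
        threshold=criteria.step_threshold,
        min_segment=criteria.min_segment,
        magnitude_sigma=criteria.magnitude_sigma,
    )
    donor_steps = detect_bleach_steps(donor_sum, **kw)
    acceptor_steps = detect_bleach_steps(trace.i_aa, **kw)
    donor_blinks, donor_bleaches = _pair_blinks(donor_steps, criteria.recovery_tol)
    acc_blinks, acc_bleaches = _pair_blinks(acceptor_steps, criteria.recovery_tol)

    d_frame = _bleach_frame(donor_bleaches, criteria.background_fraction)
    a_frame = _bleach_frame(acc_bleaches, criteria.background_fraction)
    candidates = [f for f in (d_frame, a_frame) if f is not None]
    truncation = min(candidates) if candidates else n

    pre = slice(0, truncation if truncation > 0 else n)
    mean_idd = float(np.mean(trace.i_dd[pre]))
    mean_iaa = float(np.mean(trace.i_aa[pre]))

    if not criteria.idd_min <= mean_idd <= criteria.idd_max:
        return QcResult(trace.molecule_id, False, "idd_window", truncation)
    if not criteria.iaa_min <= mean_iaa <= criteria.iaa_max:
        return QcResult(trace.molecule_id, False, "iaa_window", truncation)
    if criteria.reject_multistep and (len(donor_bleaches) >= 2 or len(acc_bleaches) >= 2):
        return QcResult(trace.molecule_id, False, "multistep_bleach", truncation)
    if candidates and min(candidates) < criteria.early_bleach_window:
        return QcResult(trace.molecule_id, False, "early_bleach", truncation)
    if criteria.reject_blinking and (donor_blinks or acc_blinks):
        return QcResult(trace.molecule_id, False, "blinking", truncation)
    return QcResult(trace.molecule_id, True, "", truncation)


def apply_qc_dataset(traces, criteria: QcCriteria | None = None) -> QcReport:
    """Run QC over a dataset and tabulate verdicts and per-criterion counts."""
    results = [apply_qc(tr, criteria) for tr in traces]
    table = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in results],
            "verdict": ["pass" if r.passed else "fail" for r in results],
            "first_fail_reason": [r.first_fail for r in results],
            "truncation_frame": [r.truncation_frame for r in results],
        }
    )
    counts = {"pass": 0}
    for r in results:
        key = "pass" if r.passed else r.first_fail
        counts[key] = counts.get(key, 0) + 1
    return QcReport(table=table, counts=counts)
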