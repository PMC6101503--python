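"""ALEX photometry: apparent FRET, stoichiometry, and the correction cascade.

Alternating-laser excitation (ALEX) yields three intensity channels per
frame — donor emission under donor excitation (I_DD), acceptor emission
under donor excitation (I_DA), and acceptor emission under acceptor
excitation (I_AA).  From these we compute the apparent FRET efficiency
E* = I_DA / (I_DD + I_DA) and the stoichiometry
S = (I_DD + I_DA) / (I_DD + I_DA + I_AA), then correct E* for donor
leakage into the acceptor channel (Lk), direct excitation of the acceptor
by the donor laser (Dir), and the detection-factor imbalance (gamma) to
obtain the accurate FRET efficiency E_a, from which the donor–acceptor
distance follows through the Förster relation.

Frames with undefined ratios (zero denominators) are marked NaN and
propagated; they are never clamped or silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionFactors",
    "EfficiencyTrace",
    "compute_estar",
    "compute_s",
    "leakage_from_donly",
    "direct_from_aonly",
    "proximity_ratio",
    "accurate_fret",
    "proximity_from_accurate",
    "distance_from_fret",
    "fret_from_distance",
    "trace_to_efficiency",
    "estimate_corrections",
    "gamma_from_bleach",
]

#: Förster radius of the Cy3B / Alexa647 pair, in Å.
DEFAULT_R0 = 60.1

#: Global detection factor used when none is estimated from bleaching steps.
DEFAULT_GAMMA = 0.95


@dataclass(frozen=True)
class CorrectionFactors:
    """Photometric calibration bundle: leakage, direct excitation, gamma, R0."""

    lk: float
    dir: float
    gamma: float = DEFAULT_GAMMA
    r0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        if self.lk < 0:
            raise ValueError(f"leakage must be >= 0, got {self.lk}")
        if self.dir < 0:
            raise ValueError(f"direct excitation must be >= 0, got {self.dir}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.r0 <= 0:
            raise ValueError(f"R0 must be > 0, got {self.r0}")


@dataclass
class EfficiencyTrace:
    """Per-frame E* and S for one molecule, with the pre-bleach inclusion mask.

    Frames at or beyond ``truncation_frame`` (the first donor or acceptor
    photobleaching event) are excluded from all downstream statistics, as
    are frames whose ratios are undefined.
    """

    molecule_id: int
    e_star: np.ndarray
    s: np.ndarray
    truncation_frame: int
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.e_star = np.asarray(self.e_star, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.e_star.shape != self.s.shape:
            raise ValueError("E* and S must have equal length")
        if self.included is None:
            idx = np.arange(len(self.e_star))
            self.included = (
                (idx < self.truncation_frame)
                & np.isfinite(self.e_star)
                & np.isfinite(self.s)
            )

    def __len__(self) -> int:
        return len(self.e_star)

    @property
    def e_star_included(self) -> np.ndarray:
        return self.e_star[self.included]


def compute_estar(i_dd, i_da):
    """Apparent FRET efficiency E* = I_DA / (I_DD + I_DA).

    Frames where the denominator vanishes are returned as NaN.
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    den = i_dd + i_da
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, i_da / den, np.nan)
    return out if out.ndim else float(out)


def compute_s(i_dd, i_da, i_aa):
    """Stoichiometry S = (I_DA + I_DD) / (I_DD + I_DA + I_AA).

    S near 1 flags donor-only molecules, S near 0 acceptor-only ones;
    doubly labelled molecules sit in between.  Zero total -> NaN.
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    i_aa = np.asarray(i_aa, dtype=float)
    den = i_dd + i_da + i_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, (i_da + i_dd) / den, np.nan)
    return out if out.ndim else float(out)


def leakage_from_donly(e_star_donly: float) -> float:
    """Leakage factor from the donor-only population: Lk = E*_D / (1 - E*_D)."""
    if not 0 <= e_star_donly < 1:
        raise ValueError(
            f"donor-only E* must lie in [0, 1), got {e_star_donly}"
        )
    return e_star_donly / (1.0 - e_star_donly)


def direct_from_aonly(s_aonly: float) -> float:
    """Direct-excitation factor from the acceptor-only population:
    Dir = S_A / (1 - S_A)."""
    if not 0 <= s_aonly < 1:
        raise ValueError(f"acceptor-only S must lie in [0, 1), got {s_aonly}")
    return s_aonly / (1.0 - s_aonly)


def proximity_ratio(e_star, s, lk: float, dir: float):
    """FRET proximity ratio E_PR: E* corrected for leakage and direct excitation.

    E_PR = [1 - Dir*(1-S)/S - Lk*(1-E*)/E*]
           / [(1-E*)/E* + 1 - Dir*(1-S)/S]

    The formula divides by E* and S, so frames with E* or S at 0 or 1 are
    returned as NaN (undefined-frame marker).  With Lk = Dir = 0 it reduces
    to E* exactly.
    """
    e_star = np.asarray(e_star, dtype=float)
    s = np.asarray(s, dtype=float)
    ok = (e_star > 0) & (e_star < 1) & (s > 0) & (s < 1)
    e_safe = np.where(ok, e_star, 0.5)
    s_safe = np.where(ok, s, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_e = (1.0 - e_safe) / e_safe
        dir_term = dir * (1.0 - s_safe) / s_safe
        num = 1.0 - dir_term - lk * inv_e
        den = inv_e + 1.0 - dir_term
        out = np.where(ok, num / den, np.nan)
    return out if out.ndim else float(out)


def accurate_fret(e_pr, gamma: float = DEFAULT_GAMMA):
    """Accurate FRET efficiency E_a = E_PR / [gamma - (gamma - 1) * E_PR]."""
    e_pr = np.asarray(e_pr, dtype=float)
    den = gamma - (gamma - 1.0) * e_pr
    if np.any(np.abs(den[np.isfinite(den)] if den.ndim else [den]) < 1e-12):
        raise ValueError("gamma correction denominator vanishes")
    out = e_pr / den
    return out if out.ndim else float(out)


def proximity_from_accurate(e_a, gamma: float = DEFAULT_GAMMA):
    """Invert the gamma correction: E_PR = gamma*E_a / [1 + (gamma-1)*E_a]."""
    e_a = np.asarray(e_a, dtype=float)
    out = gamma * e_a / (1.0 + (gamma - 1.0) * e_a)
    return out if out.ndim else float(out)


def distance_from_fret(e_a, r0: float = DEFAULT_R0):
    """Donor–acceptor distance R = R0 * [(1/E_a) - 1]^(1/6), in Å.

    Strictly decreasing in E_a; R(0.5) = R0; R(1) = 0.
    """
    e_a = np.asarray(e_a, dtype=float)
    if np.any(e_a <= 0) or np.any(e_a > 1):
        raise ValueError("E_a must lie in (0, 1] for distance conversion")
    out = r0 * ((1.0 / e_a) - 1.0) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def fret_from_distance(r, r0: float = DEFAULT_R0):
    """Förster curve E_a = 1 / [1 + (R/R0)^6]; inverse of distance_from_fret."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return out if out.ndim else float(out)


def trace_to_efficiency(trace, truncation_frame: int | None = None) -> EfficiencyTrace:
    """Compute per-frame E* and S for one trace, excluding post-bleach frames.

    Parameters
    ----------
    trace : AlexTrace
        Raw three-channel intensities.
    truncation_frame : int, optional
        Index of the first photobleaching event; frames at or beyond it are
        flagged excluded.  Defaults to the trace length (no truncation).
    """
    n = len(trace.i_dd)
    if truncation_frame is None:
        truncation_frame = n
    if truncation_frame > n:
        raise ValueError(
            f"truncation_frame {truncation_frame} exceeds trace length {n}"
        )
    e_star = compute_estar(trace.i_dd, trace.i_da)
    s = compute_s(trace.i_dd, trace.i_da, trace.i_aa)
    return EfficiencyTrace(
        molecule_id=trace.molecule_id,
        e_star=np.atleast_1d(e_star),
        s=np.atleast_1d(s),
        truncation_frame=int(truncation_frame),
    )


def estimate_corrections(
    e_star,
    s,
    s_donly_min: float = 0.8,
    s_aonly_max: float = 0.2,
    gamma: float = DEFAULT_GAMMA,
    r0: float = DEFAULT_R0,
) -> CorrectionFactors:
    """Estimate dataset-level Lk and Dir from the E*–S plane.

    The donor-only population (S >= ``s_donly_min``) yields Lk from its
    median E*; the acceptor-only population (S <= ``s_aonly_max``) yields
    Dir from its median S.  Single dataset-level factors are returned; the
    S-window boundaries delimiting the subpopulations are configurable.
    """
    e_star = np.asarray(e_star, dtype=float)
    s = np.asarray(s, dtype=float)
    ok = np.isfinite(e_star) & np.isfinite(s)
    donly = ok & (s >= s_donly_min)
    aonly = ok & (s <= s_aonly_max)
    if not donly.any():
        warnings.warn("no donor-only population found; Lk set to 0")
        lk = 0.0
    else:
        lk = leakage_from_donly(float(np.median(e_star[donly])))
    if not aonly.any():
        warnings.warn("no acceptor-only population found; Dir set to 0")
        dir_ = 0.0
    else:
        dir_ = direct_from_aonly(float(np.median(s[aonly])))
    return CorrectionFactors(lk=lk, dir=dir_, gamma=gamma, r0=r0)


def gamma_from_bleach(trace, bleach_frame: int, window: int = 20) -> float:
    """Per-molecule detection factor gamma = dI_AA / dI_DD across an
    acceptor-photobleaching step.

    dI_AA is the drop in I_AA and dI_DD the rise in I_DD between the
    ``window`` frames before and after ``bleach_frame``.  Optional route;
    the dataset default is the global gamma.
    """
    lo = max(0, bleach_frame - window)
    hi = min(len(trace.i_dd), bleach_frame + window)
    if bleach_frame - lo < 2 or hi - bleach_frame < 2:
        raise ValueError("bleach step too close to trace edge for gamma estimate")
    d_aa = np.mean(trace.i_aa[lo:bleach_frame]) - np.mean(trace.i_aa[bleach_frame:hi])
    d_dd = np.mean(trace.i_dd[bleach_frame:hi]) - np.mean(trace.i_dd[lo:bleach_frame])
    if d_dd <= 0:
        raise ValueError("no donor dequenching step found; cannot estimate gamma")
    return float(d_aa / d_dd)
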