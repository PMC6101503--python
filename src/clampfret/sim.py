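"""Synthetic ALEX trace generation with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
hidden continuous-time Markov chain over clamp conformational states,
frame-integrated EMCCD sampling (majority-occupancy discretization),
Gaussian camera noise, single-step donor/acceptor photobleaching, and
rare two-state (telegraph) dye blinking.

The per-frame photometric forward model is the exact algebraic inverse of
the correction cascade in :mod:`clampfret.alex`: state means are specified
on the accurate-FRET (E_a) scale, converted to the proximity ratio through
the gamma relation, and then to the apparent split fraction E_app by
inverting the leakage/direct-excitation formula, so that running the full
correction cascade on a noiseless rendered trace returns the state mean
exactly for any (Lk, Dir, gamma).  With the default identity photometrics
(Lk = Dir = 0, gamma = 1) the state means coincide with apparent E*.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alex import proximity_from_accurate

__all__ = [
    "SimConfig",
    "AlexTrace",
    "GroundTruth",
    "simulate_state_path",
    "render_intensities",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic ALEX dataset.

    Defaults describe the holoenzyme study conditions: 20 ms frames, 20 s
    observations, three clamp states with E* means 0.20 / 0.30 / 0.41,
    per-state lifetimes in the 150–350 ms range, and donor-excitation
    intensities inside the quality-control windows (I_DD 300–2000,
    I_AA 200–2000 counts).
    """

    n_molecules: int = 300
    n_frames: int = 1000
    exposure: float = 0.020  # seconds per frame (20 or 200 ms regimes)
    state_means_E: tuple = (0.20, 0.30, 0.41)  # accurate-FRET scale
    state_sigma_E: tuple = (0.05, 0.05, 0.05)  # std of E* per state
    # per-second transition rates; lifetimes ~303 / 200 / 250 ms
    rate_matrix_true: tuple = (
        (0.0, 2.0, 1.3),
        (2.5, 0.0, 2.5),
        (1.5, 2.5, 0.0),
    )
    total_intensity_mean: float = 1000.0  # I_DD + I_DA counts, donor excitation
    total_intensity_std: float = 80.0
    iaa_mean: float = 500.0
    iaa_std: float = 50.0
    donor_bleach_rate: float = 0.02  # per second
    acceptor_bleach_rate: float = 0.02
    blink_on_rate: float = 0.01  # rate of entering a dark interval, per dye
    blink_off_rate: float = 10.0  # recovery rate (mean dark time 100 ms)
    background_per_channel: float = 0.0  # traces arrive background-corrected
    channel_noise_std: float = 25.0  # additive camera noise per channel
    leakage_true: float = 0.0
    direct_true: float = 0.0
    gamma_true: float = 1.0
    # fraction of molecules whose clamp never interconverts during the
    # observation (static subpopulation, ~68% in the holoenzyme study)
    static_fraction: float = 0.68
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means_E, dtype=float)
        if means.ndim != 1 or len(means) < 1:
            raise ValueError("state_means_E must be a nonempty 1-D sequence")
        if np.any(np.diff(means) <= 0):
            raise ValueError("state_means_E must be strictly increasing")
        if np.any((means < 0) | (means > 1)):
            raise ValueError("state_means_E must lie in [0, 1]")
        q = np.asarray(self.rate_matrix_true, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("rate_matrix_true must be square")
        if q.shape[0] != len(means):
            raise ValueError("rate matrix size must match number of states")
        off = q[~np.eye(len(q), dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be nonnegative")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        for name in (
            "donor_bleach_rate",
            "acceptor_bleach_rate",
            "blink_on_rate",
            "blink_off_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if not 0 <= self.static_fraction <= 1:
            raise ValueError("static_fraction must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.state_means_E)


@dataclass
class AlexTrace:
    """Raw per-frame three-channel intensities for one molecule."""

    molecule_id: int
    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    exposure: float

    def __post_init__(self) -> None:
        self.i_dd = np.asarray(self.i_dd, dtype=float)
        self.i_da = np.asarray(self.i_da, dtype=float)
        self.i_aa = np.asarray(self.i_aa, dtype=float)
        if not (len(self.i_dd) == len(self.i_da) == len(self.i_aa)):
            raise ValueError("channel arrays must have equal length")

    def __len__(self) -> int:
        return len(self.i_dd)


@dataclass
class GroundTruth:
    """True hidden trajectory and photophysics for one simulated molecule.

    The state path is physically meaningful only up to the first bleach
    frame; later entries record what the hidden chain did but no signal
    reports on it.
    """

    molecule_id: int
    states: np.ndarray
    donor_bleach_frame: int
    acceptor_bleach_frame: int
    donor_dark: np.ndarray
    acceptor_dark: np.ndarray

    @property
    def truncation_frame(self) -> int:
        return min(self.donor_bleach_frame, self.acceptor_bleach_frame)

    @property
    def donor_alive(self) -> np.ndarray:
        idx = np.arange(len(self.states))
        return (idx < self.donor_bleach_frame) & ~self.donor_dark

    @property
    def acceptor_alive(self) -> np.ndarray:
        idx = np.arange(len(self.states))
        return (idx < self.acceptor_bleach_frame) & ~self.acceptor_dark


def stationary_distribution(rate_matrix) -> np.ndarray:
    """Stationary distribution of a continuous-time Markov chain.

    Solves pi Q = 0 with Q the generator (off-diagonal rates, diagonal
    minus row sums), normalized to sum 1.
    """
    q = np.asarray(rate_matrix, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    k = q.shape[0]
    # append normalization row; least squares handles the rank deficiency
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _sample_ctmc(rate_matrix, t_end: float, rng: np.random.Generator,
                 initial_state: int | None = None):
    """Jump-chain sampling of a CTMC on [0, t_end).

    Returns (times, states): piecewise-constant path with change times,
    times[0] = 0.
    """
    q = np.asarray(rate_matrix, dtype=float)
    k = q.shape[0]
    exit_rates = np.array([q[i].sum() - q[i, i] for i in range(k)])
    if initial_state is None:
        state = int(rng.choice(k, p=stationary_distribution(q)))
    else:
        state = int(initial_state)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(k, p=probs / probs.sum()))
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int)


def simulate_state_path(
    rate_matrix,
    n_frames: int,
    exposure: float,
    seed=None,
    initial_state: int | None = None,
) -> np.ndarray:
    """Sample a hidden state path, discretized to camera frames.

    The chain is simulated in continuous time and each frame is labelled
    by the state occupying the largest fraction of the frame interval
    (majority occupancy), mirroring camera integration: events faster than
    the frame time are partially averaged away rather than resolved.
    Ties go to the lowest state index.
    """
    q = np.asarray(rate_matrix, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = q[~np.eye(len(q), dtype=bool)]
    if np.any(off < 0):
        raise ValueError("transition rates must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = n_frames * exposure
    times, states = _sample_ctmc(q, t_end, rng, initial_state)
    k = q.shape[0]
    occupancy = np.zeros((n_frames, k))
    edges = np.arange(n_frames + 1) * exposure
    seg_starts = times
    seg_ends = np.append(times[1:], t_end)
    for start, end, st in zip(seg_starts, seg_ends, states):
        # only frames overlapping [start, end) are touched
        f0 = min(max(int(start / exposure), 0), n_frames - 1)
        f1 = min(int(np.ceil(end / exposure)), n_frames)
        overlap = (
            np.minimum(end, edges[f0 + 1:f1 + 1]) - np.maximum(start, edges[f0:f1])
        )
        np.maximum(overlap, 0.0, out=overlap)
        occupancy[f0:f1, st] += overlap
    return occupancy.argmax(axis=1)


def _dark_frames(on_rate, off_rate, n_frames, exposure, rng) -> np.ndarray:
    """Telegraph blinking: frames whose midpoint falls in a dark interval."""
    dark = np.zeros(n_frames, dtype=bool)
    if on_rate <= 0:
        return dark
    t_end = n_frames * exposure
    mids = (np.arange(n_frames) + 0.5) * exposure
    t = 0.0
    while True:
        t += rng.exponential(1.0 / on_rate)
        if t >= t_end:
            break
        dur = rng.exponential(1.0 / off_rate) if off_rate > 0 else t_end
        dark |= (mids >= t) & (mids < t + dur)
        t += dur
    return dark


def apparent_split_fraction(e_a, i_aa, total, config: SimConfig):
    """Apparent acceptor split fraction E_app for given accurate FRET E_a.

    Inverts the correction cascade: E_PR from the gamma relation, then
    E_app = (E_PR + Lk) / (1 + Lk - c (1 - E_PR)) with c = Dir * I_AA / T,
    the exact algebraic inverse of the leakage/direct-excitation formula.
    """
    e_pr = proximity_from_accurate(e_a, config.gamma_true)
    c = config.direct_true * np.asarray(i_aa, dtype=float) / np.asarray(total, dtype=float)
    return (e_pr + config.leakage_true) / (
        1.0 + config.leakage_true - c * (1.0 - e_pr)
    )


def render_intensities(
    path: np.ndarray,
    config: SimConfig,
    seed=None,
    molecule_id: int = 0,
) -> tuple[AlexTrace, GroundTruth]:
    """Render three-channel intensities for a hidden state path.

    Per live frame the donor-excitation total T is split into I_DA and
    I_DD according to the apparent fraction derived from the state's
    accurate-FRET mean; I_AA is drawn independently.  After donor bleach
    both donor-excitation channels fall to background; after acceptor
    bleach I_DA and I_AA fall to background and the donor dequenches
    (its lost FRET fraction returns scaled by 1/gamma).  Blinking applies
    the same signatures transiently.  E*-scale Gaussian noise, additive
    channel noise and background are applied afterwards; counts are
    clipped at zero.
    """
    path = np.asarray(path, dtype=int)
    n = len(path)
    if path.min() < 0 or path.max() >= config.n_states:
        raise ValueError("state path indexes outside state_means_E")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _bleach_frame(rate):
        if rate <= 0:
            return n
        t = rng.exponential(1.0 / rate)
        return min(n, int(t / config.exposure))

    donor_bleach = _bleach_frame(config.donor_bleach_rate)
    acceptor_bleach = _bleach_frame(config.acceptor_bleach_rate)
    donor_dark = _dark_frames(
        config.blink_on_rate, config.blink_off_rate, n, config.exposure, rng
    )
    acceptor_dark = _dark_frames(
        config.blink_on_rate, config.blink_off_rate, n, config.exposure, rng
    )

    means = np.asarray(config.state_means_E, dtype=float)
    sigmas = np.asarray(config.state_sigma_E, dtype=float)
    total = rng.normal(config.total_intensity_mean, config.total_intensity_std, n)
    total = np.clip(total, 1.0, None)
    iaa_clean = rng.normal(config.iaa_mean, config.iaa_std, n)
    iaa_clean = np.clip(iaa_clean, 0.0, None)

    e_app = apparent_split_fraction(means[path], iaa_clean, total, config)
    e_noisy = e_app + rng.normal(0.0, 1.0, n) * sigmas[path]

    idx = np.arange(n)
    donor_on = (idx < donor_bleach) & ~donor_dark
    acceptor_on = (idx < acceptor_bleach) & ~acceptor_dark

    i_da = np.where(donor_on & acceptor_on, e_noisy * total, 0.0)
    # donor dequenching when the acceptor is off: the FRET fraction returns
    # to the donor channel scaled by 1/gamma (gamma = dI_AA/dI_DD convention)
    dd_live = np.where(
        acceptor_on,
        (1.0 - e_noisy) * total,
        (1.0 - e_app + e_app / config.gamma_true) * total,
    )
    i_dd = np.where(donor_on, dd_live, 0.0)
    i_aa = np.where(acceptor_on, iaa_clean, 0.0)

    noise = lambda: rng.normal(0.0, config.channel_noise_std, n)
    bg = config.background_per_channel
    i_dd = np.clip(i_dd + bg + noise(), 0.0, None)
    i_da = np.clip(i_da + bg + noise(), 0.0, None)
    i_aa = np.clip(i_aa + bg + noise(), 0.0, None)

    trace = AlexTrace(molecule_id, i_dd, i_da, i_aa, config.exposure)
    truth = GroundTruth(
        molecule_id=molecule_id,
        states=path,
        donor_bleach_frame=donor_bleach,
        acceptor_bleach_frame=acceptor_bleach,
        donor_dark=donor_dark,
        acceptor_dark=acceptor_dark,
    )
    return trace, truth


def simulate_dataset(config: SimConfig):
    """Simulate a full dataset: one (AlexTrace, GroundTruth) per molecule.

    A fixed config (including seed) reproduces the dataset bitwise; each
    molecule gets an independent child stream of the dataset seed.
    """
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_molecules)
    pi_stat = stationary_distribution(config.rate_matrix_true)
    traces, truths = [], []
    for mol, child in enumerate(children):
        rng = np.random.default_rng(child)
        if rng.random() < config.static_fraction:
            # static molecule: the clamp stays in one state throughout
            state = int(rng.choice(config.n_states, p=pi_stat))
            path = np.full(config.n_frames, state, dtype=int)
        else:
            path = simulate_state_path(
                config.rate_matrix_true, config.n_frames, config.exposure, rng
            )
        trace, truth = render_intensities(path, config, rng, molecule_id=mol)
        traces.append(trace)
        truths.append(truth)
    return traces, truths


def write_dataset(traces, ground_truths, config: SimConfig, directory) -> Path:
    """Write a trace dataset: traces.csv, ground-truth sidecars, metadata.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(len(tr)),
                    "I_DD": tr.i_dd,
                    "I_DA": tr.i_da,
                    "I_AA": tr.i_aa,
                }
            )
        )
    cols = ["molecule_id", "frame", "I_DD", "I_DA", "I_AA"]
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    # %.17g guarantees a lossless float round trip through the text table
    table.to_csv(directory / "traces.csv", index=False, float_format="%.17g")

    gt_rows = []
    mol_rows = []
    for gt in ground_truths:
        gt_rows.append(
            pd.DataFrame(
                {
                    "molecule_id": gt.molecule_id,
                    "frame": np.arange(len(gt.states)),
                    "true_state": gt.states,
                    "donor_alive": gt.donor_alive.astype(int),
                    "acceptor_alive": gt.acceptor_alive.astype(int),
                }
            )
        )
        mol_rows.append(
            {
                "molecule_id": gt.molecule_id,
                "donor_bleach_frame": gt.donor_bleach_frame,
                "acceptor_bleach_frame": gt.acceptor_bleach_frame,
            }
        )
    gt_cols = ["molecule_id", "frame", "true_state", "donor_alive", "acceptor_alive"]
    gt_table = (
        pd.concat(gt_rows, ignore_index=True) if gt_rows else pd.DataFrame(columns=gt_cols)
    )
    gt_table.to_csv(directory / "ground_truth.csv", index=False)
    pd.DataFrame(
        mol_rows, columns=["molecule_id", "donor_bleach_frame", "acceptor_bleach_frame"]
    ).to_csv(directory / "ground_truth_molecules.csv", index=False)

    meta = {"exposure": float(config.exposure), "n_molecules": len(traces),
            "config": _config_to_plain(config)}
    with open(directory / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return directory


def _config_to_plain(config: SimConfig) -> dict:
    d = asdict(config)
    for key in ("state_means_E", "state_sigma_E"):
        d[key] = [float(x) for x in d[key]]
    d["rate_matrix_true"] = [[float(x) for x in row] for row in d["rate_matrix_true"]]
    return d


def read_dataset(directory):
    """Read a dataset written by :func:`write_dataset`.

    Returns (traces, metadata, ground_truth_frame) where the ground-truth
    table is None when no sidecar is present (real data).
    """
    directory = Path(directory)
    with open(directory / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    exposure = float(meta["exposure"])
    table = pd.read_csv(directory / "traces.csv", float_precision="round_trip")
    traces = []
    for mol, grp in table.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            AlexTrace(
                int(mol),
                grp["I_DD"].to_numpy(),
                grp["I_DA"].to_numpy(),
                grp["I_AA"].to_numpy(),
                exposure,
            )
        )
    gt_path = directory / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else None
    return traces, meta, gt
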