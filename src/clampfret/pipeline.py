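"""Pipeline orchestration: simulate -> QC -> correct -> HMM -> kinetics
-> structure mapping, as a configured, logged, reproducible run.

Each stage is an importable function reading the previous stage's files
from the output directory, so the command-line interface can run stages
individually; :func:`run_pipeline` chains them and writes a manifest with
per-stage record counts.  A single global seed is fanned out to the
stochastic stages through ``numpy.random.SeedSequence(seed).generate_state``,
so identical configs and inputs reproduce all numerical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alex, kinetics as kin, qc as qcmod, sim, structure as structmod
from .hmm import HmmConfig, decode_path, fit_hmm, select_model

log = logging.getLogger("clampfret")

__all__ = [
    "PipelineConfig",
    "DependencyError",
    "run_pipeline",
    "stage_simulate",
    "stage_qc",
    "stage_correct",
    "stage_hmm",
    "stage_kinetics",
    "stage_structure",
]


class DependencyError(RuntimeError):
    """A stage was invoked before the stage that produces its inputs."""


@dataclass
class PipelineConfig:
    outdir: str = "clampfret_out"
    input_dir: str | None = None  # existing trace dataset; None -> simulate
    seed: int = 0
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    qc: qcmod.QcCriteria = field(default_factory=qcmod.QcCriteria)
    # photometric overrides; None -> estimate Lk/Dir from the E*-S plane
    lk: float | None = None
    dir: float | None = None
    gamma: float = alex.DEFAULT_GAMMA
    r0: float = alex.DEFAULT_R0
    s_donly_min: float = 0.8
    s_aonly_max: float = 0.2
    # stoichiometry window selecting doubly labelled (D-A) frames for the
    # E* analysis; frames outside it (donor-only / acceptor-only signatures,
    # e.g. short blinks) are excluded
    s_da_min: float = 0.3
    s_da_max: float = 0.8
    hmm: HmmConfig = field(default_factory=HmmConfig)
    # analyze downstream stages with this K regardless of the AIC winner
    # (the model-comparison table is still written); None -> use the winner
    hmm_force_k: int | None = None
    anticorrelation_threshold: float = -0.2
    min_dwells: int = 20
    rate_method: str = "linear"
    structure: dict | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            s = dict(kwargs["sim"])
            for key in ("state_means_E", "state_sigma_E"):
                if key in s:
                    s[key] = tuple(s[key])
            if "rate_matrix_true" in s:
                s["rate_matrix_true"] = tuple(tuple(r) for r in s["rate_matrix_true"])
            kwargs["sim"] = sim.SimConfig(**s)
        if "qc" in kwargs:
            kwargs["qc"] = qcmod.QcCriteria(**kwargs["qc"])
        if "hmm" in kwargs:
            h = dict(kwargs["hmm"])
            if "k_range" in h:
                h["k_range"] = tuple(h["k_range"])
            kwargs["hmm"] = HmmConfig(**h)
        return cls(**kwargs)

    def stage_seeds(self) -> dict:
        """Deterministic fan-out of the global seed to stochastic stages."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        ints = [int(x % (2**31)) for x in state]
        return {"sim": ints[0], "hmm": ints[1], "structure": ints[2]}


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing {path.name}: run the '{producer}' stage first"
        )
    return path


def stage_simulate(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    cfg = sim.SimConfig(**{**asdict_sim(config.sim), "seed": config.stage_seeds()["sim"]})
    traces, truths = sim.simulate_dataset(cfg)
    sim.write_dataset(traces, truths, cfg, out / "dataset")
    log.info("simulate: wrote %d molecules x %d frames", len(traces), cfg.n_frames)
    return {"n_molecules": len(traces), "n_frames": cfg.n_frames}


def asdict_sim(cfg: sim.SimConfig) -> dict:
    d = asdict(cfg)
    return d


def _load_traces(config: PipelineConfig):
    src = Path(config.input_dir) if config.input_dir else Path(config.outdir) / "dataset"
    _require(src / "traces.csv", "simulate")
    return sim.read_dataset(src)


def stage_qc(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    traces, _, _ = _load_traces(config)
    if not traces:
        raise ValueError("input dataset contains no traces")
    report = qcmod.apply_qc_dataset(traces, config.qc)
    report.table.to_csv(out / "qc_report.csv", index=False)
    log.info("qc: %d/%d molecules pass (%s)", report.n_pass, len(traces), report.counts)
    return {"n_molecules": len(traces), "n_pass": report.n_pass, "counts": report.counts}


def stage_correct(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    traces, _, _ = _load_traces(config)
    qc_table = pd.read_csv(_require(out / "qc_report.csv", "qc"))
    trunc = dict(zip(qc_table["molecule_id"], qc_table["truncation_frame"]))
    passed = set(qc_table.loc[qc_table["verdict"] == "pass", "molecule_id"])

    # corrections: explicit overrides, else dataset-level estimate from the
    # E*-S plane of all selected data points
    all_e, all_s = [], []
    effs = []
    for tr in traces:
        if tr.molecule_id not in passed:
            continue
        et = alex.trace_to_efficiency(tr, min(trunc[tr.molecule_id], len(tr)))
        effs.append(et)
        all_e.append(et.e_star[et.included])
        all_s.append(et.s[et.included])
    if not effs:
        raise ValueError("no QC-passing molecules; nothing to correct")
    e_cat = np.concatenate(all_e)
    s_cat = np.concatenate(all_s)
    if config.lk is not None and config.dir is not None:
        corr = alex.CorrectionFactors(config.lk, config.dir, config.gamma, config.r0)
    else:
        est = alex.estimate_corrections(
            e_cat, s_cat, config.s_donly_min, config.s_aonly_max,
            config.gamma, config.r0,
        )
        corr = alex.CorrectionFactors(
            est.lk if config.lk is None else config.lk,
            est.dir if config.dir is None else config.dir,
            config.gamma, config.r0,
        )
    with open(out / "corrections.json", "w") as fh:
        json.dump({"lk": corr.lk, "dir": corr.dir, "gamma": corr.gamma, "r0": corr.r0}, fh, indent=2)

    rows = []
    for et in effs:
        # keep only D-A frames: pre-bleach, finite, S inside the D-A window
        da = et.included & (et.s >= config.s_da_min) & (et.s <= config.s_da_max)
        frames = np.flatnonzero(da)
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": et.molecule_id,
                    "frame": frames,
                    "E_star": et.e_star[frames],
                    "S": et.s[frames],
                    "included": 1,
                }
            )
        )
    eff_table = pd.concat(rows, ignore_index=True)
    eff_table.to_csv(out / "efficiency.csv", index=False)
    log.info(
        "correct: %d included frames from %d molecules (Lk=%.4f Dir=%.4f gamma=%.2f)",
        len(eff_table), len(effs), corr.lk, corr.dir, corr.gamma,
    )
    return {"n_included_frames": len(eff_table), "n_molecules": len(effs),
            "lk": corr.lk, "dir": corr.dir}


def _load_sequences(out: Path):
    eff = pd.read_csv(_require(out / "efficiency.csv", "correct"))
    seqs, ids = [], []
    for mol, grp in eff.groupby("molecule_id", sort=True):
        seqs.append(grp.sort_values("frame")["E_star"].to_numpy())
        ids.append(int(mol))
    return seqs, ids, eff


def stage_hmm(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    _require(out / "qc_report.csv", "qc")
    seqs, ids, _ = _load_sequences(out)
    hmm_cfg = HmmConfig(**{**asdict(config.hmm), "seed": config.stage_seeds()["hmm"]})
    fits = [fit_hmm(seqs, k, hmm_cfg) for k in hmm_cfg.k_range]
    best, table = select_model(fits)
    table.to_csv(out / "model_selection.csv", index=False)
    k_selected = best.k
    if config.hmm_force_k is not None:
        matches = [f for f in fits if f.k == config.hmm_force_k]
        if not matches:
            raise ValueError(
                f"hmm_force_k={config.hmm_force_k} not in k_range {hmm_cfg.k_range}"
            )
        best = matches[0]
    with open(out / "hmm_params.json", "w") as fh:
        json.dump(
            {
                "K": best.k,
                "means": best.means.tolist(),
                "sigmas": best.sigmas.tolist(),
                "pi": best.pi.tolist(),
                "transition_matrix": best.transition_matrix.tolist(),
                "log_likelihood": best.log_likelihood,
                "AIC": best.aic,
            },
            fh, indent=2,
        )
    rows = []
    for mol, seq in zip(ids, seqs):
        path = decode_path(seq, best)
        rows.append(pd.DataFrame({"molecule_id": mol, "frame_index": np.arange(len(path)),
                                  "state": path}))
    pd.concat(rows, ignore_index=True).to_csv(out / "decoded_paths.csv", index=False)
    log.info("hmm: selected K=%d, using K=%d (AIC=%.1f), means=%s",
             k_selected, best.k, best.aic, np.round(best.means, 3))
    return {"K": best.k, "K_selected_by_aic": k_selected,
            "means": best.means.tolist(), "AIC": best.aic}


def stage_kinetics(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    traces, meta, _ = _load_traces(config)
    exposure = float(meta["exposure"])
    with open(_require(out / "hmm_params.json", "hmm")) as fh:
        params = json.load(fh)
    decoded = pd.read_csv(_require(out / "decoded_paths.csv", "hmm"))
    seqs, ids, eff = _load_sequences(out)
    k = int(params["K"])

    trace_by_id = {tr.molecule_id: tr for tr in traces}
    qc_table = pd.read_csv(_require(out / "qc_report.csv", "qc"))
    trunc = dict(zip(qc_table["molecule_id"], qc_table["truncation_frame"]))

    paths, kept_traces, masks, e_views = [], [], [], []
    for mol in ids:
        grp = decoded[decoded["molecule_id"] == mol].sort_values("frame_index")
        path = grp["state"].to_numpy()
        tr = trace_by_id[mol]
        frames = eff.loc[eff["molecule_id"] == mol].sort_values("frame")["frame"].to_numpy()
        mask = np.zeros(len(tr), dtype=bool)
        mask[frames] = True
        paths.append(path)
        kept_traces.append(tr)
        masks.append(mask)
        e_views.append(_EView(mol, eff.loc[eff["molecule_id"] == mol]
                              .sort_values("frame")["E_star"].to_numpy()))

    classes = kin.classify_molecules(
        paths, kept_traces, masks, config.anticorrelation_threshold
    )
    labels = np.array([c.label for c in classes])
    n_static = int((labels == "static").sum())
    n_dynamic = int((labels == "dynamic").sum())

    dyn_paths = [p for p, c in zip(paths, classes) if c.label == "dynamic"]
    dwells = kin.collect_dwells(dyn_paths if dyn_paths else paths, exposure, k)
    fits = [kin.fit_exponential(dwells.uncensored(s), exposure, config.min_dwells)
            for s in range(k)]
    # transition rates describe the dynamic subpopulation: refit the
    # chosen-K model on dynamic traces only, so static molecules do not
    # dilute the per-frame transition probabilities
    dyn_seqs = [s for s, c in zip(seqs, classes) if c.label == "dynamic"]
    if len(dyn_seqs) >= 5:
        hmm_cfg = HmmConfig(**{**asdict(config.hmm), "seed": config.stage_seeds()["hmm"]})
        a_matrix = fit_hmm(dyn_seqs, k, hmm_cfg).transition_matrix
    else:
        a_matrix = np.asarray(params["transition_matrix"])
    rates = kin.rates_from_transition_matrix(a_matrix, exposure, config.rate_method)
    occ = kin.state_occupancy_histogram(paths, e_views, classes, k)
    summary = kin.kinetics_summary_frame(fits, rates, occ)
    summary.to_csv(out / "kinetics_summary.csv", index=False)

    classified = n_static + n_dynamic
    payload = {
        "exposure_s": exposure,
        "n_molecules": len(ids),
        "n_static": n_static,
        "n_dynamic": n_dynamic,
        "fraction_static": n_static / classified if classified else np.nan,
        "fraction_dynamic": n_dynamic / classified if classified else np.nan,
        "lifetimes_s": [f.tau if f.ok else None for f in fits],
        "lifetime_stderr_s": [f.stderr if f.ok else None for f in fits],
        # model lifetimes implied by the fitted exit rates, 1 / sum_j k[i->j];
        # unlike dwell-histogram fits these are free of the Viterbi
        # merge bias that lengthens decoded dwells
        "lifetimes_from_rates_s": [
            (1.0 / r) if r > 0 else None for r in rates.sum(axis=1)
        ],
        "rate_matrix_per_s": rates.tolist(),
        "rate_method": config.rate_method,
        "occupancy": {name: d["occupancy"].tolist() for name, d in occ.splits.items()},
        "e_star_state_means": occ.splits["all"]["e_mean"].tolist(),
    }
    with open(out / "kinetics.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    log.info("kinetics: %d static / %d dynamic; lifetimes %s",
             n_static, n_dynamic, payload["lifetimes_s"])
    return payload


class _EView:
    """Lightweight (molecule_id, included E*) view for occupancy summaries."""

    def __init__(self, molecule_id, e_star):
        self.molecule_id = molecule_id
        self.e_star_included = np.asarray(e_star)


def stage_structure(config: PipelineConfig) -> dict:
    """Structure mapping: R_AV on anchor structures, angle calibration,
    and assignment of each FRET state to a clamp angle.

    Runs standalone from its own config block; uses the corrections file
    and HMM state means when present, else the config-level E_a list.
    """
    out = Path(config.outdir)
    scfg = config.structure
    if not scfg:
        raise ValueError("no structure-mapping configuration supplied")
    donor = _dye_from_cfg(scfg.get("donor"), structmod.CY3B)
    acceptor = _dye_from_cfg(scfg.get("acceptor"), structmod.ALEXA647)
    spacing = float(scfg.get("grid_spacing", 1.0))

    anchors = []
    for item in scfg["calibration"]:
        angle = float(item["angle"])
        if "distance" in item:
            anchors.append((angle, float(item["distance"])))
        else:
            st = structmod.read_structure(item["pdb"])
            anchors.append((angle, st))
    cal = structmod.calibrate_angle_curve(anchors, donor, acceptor, spacing)

    corr_path = out / "corrections.json"
    if corr_path.exists():
        with open(corr_path) as fh:
            c = json.load(fh)
        corr = alex.CorrectionFactors(c["lk"], c["dir"], c["gamma"], c["r0"])
    else:
        corr = alex.CorrectionFactors(0.0, 0.0, config.gamma, config.r0)

    e_a_list = scfg.get("e_a")
    if e_a_list is None:
        with open(_require(out / "hmm_params.json", "hmm")) as fh:
            params = json.load(fh)
        eff = pd.read_csv(_require(out / "efficiency.csv", "correct"))
        s_mean = float(eff["S"].mean())
        e_a_list = []
        for e_star in params["means"]:
            e_pr = alex.proximity_ratio(e_star, s_mean, corr.lk, corr.dir)
            e_a_list.append(float(alex.accurate_fret(e_pr, corr.gamma)))

    states = []
    for e_a in e_a_list:
        r_fret, angle = structmod.assign_state(e_a, corr, cal)
        states.append({"E_a": float(e_a), "R_FRET_A": r_fret, "angle_deg": angle})

    report = {
        "calibration": {
            "angles_deg": cal.angles.tolist(),
            "distances_A": cal.distances.tolist(),
        },
        "states": states,
        "r0_A": corr.r0,
    }
    if "ca_sites" in scfg:
        st = structmod.read_structure(scfg["ca_sites"]["pdb"])
        s1 = tuple(scfg["ca_sites"]["site1"])
        s2 = tuple(scfg["ca_sites"]["site2"])
        report["ca_distance_A"] = structmod.ca_distance(st, (s1[0], int(s1[1])),
                                                        (s2[0], int(s2[1])))
    with open(out / "structure_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("structure: %d states assigned; calibration %s",
             len(states), report["calibration"])
    return report


def _dye_from_cfg(cfg, default: structmod.DyeModel) -> structmod.DyeModel:
    if cfg is None:
        return default
    base = asdict(default) if not isinstance(default, dict) else default
    base.update(cfg)
    base["radii"] = tuple(base["radii"])
    return structmod.DyeModel(**base)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write a manifest of per-stage counts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_snapshot(config), "stages": {}, "started": time.time()}
    if config.input_dir:
        traces_file = Path(config.input_dir) / "traces.csv"
        if traces_file.exists():
            import hashlib

            manifest["input_checksum_md5"] = hashlib.md5(
                traces_file.read_bytes()
            ).hexdigest()
    stages = []
    if config.input_dir is None:
        stages.append(("simulate", stage_simulate))
    stages += [("qc", stage_qc), ("correct", stage_correct), ("hmm", stage_hmm),
               ("kinetics", stage_kinetics)]
    if config.structure:
        stages.append(("structure", stage_structure))
    for name, fn in stages:
        try:
            manifest["stages"][name] = _jsonify(fn(config))
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            manifest["failed_stage"] = name
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    manifest["finished"] = time.time()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    return _jsonify(snap)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
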