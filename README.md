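# clampfret

Single-molecule FRET analysis of RNA polymerase clamp conformational
dynamics from camera-based ALEX (alternating-laser excitation)
time traces.

Bacterial RNA polymerase carries a mobile clamp domain that swings about
a hinge at the switch region. Surface-immobilized, doubly labelled RNAP
molecules imaged by TIRF/ALEX report the clamp conformation as a FRET
efficiency between a donor (Cy3B, β′ clamp tip) and an acceptor
(Alexa647, β pincer tip): an open clamp (rotation ~0°) gives low FRET
(E\* ≈ 0.2), a partly closed clamp (~8°) intermediate FRET (E\* ≈ 0.3),
and a closed clamp (~16°) the highest FRET (E\* ≈ 0.41). Molecules are
either static (one state for the whole observation) or dynamic
(interconverting on the sub-second timescale). This package implements
the full trace-to-kinetics-to-structure analysis for that experiment,
plus a synthetic-trace generator with known ground truth to validate
every step.

## What it computes

For per-frame intensities I_DD (donor emission, donor excitation),
I_DA (acceptor emission, donor excitation) and I_AA (acceptor emission,
acceptor excitation):

- **Photometry** (`clampfret.alex`): apparent FRET
  E\* = I_DA/(I_DD+I_DA), stoichiometry S = (I_DD+I_DA)/(I_DD+I_DA+I_AA),
  leakage Lk = E\*_D/(1−E\*_D) and direct excitation Dir = S_A/(1−S_A)
  from the donor-only/acceptor-only populations, the proximity ratio
  E_PR(E\*, S, Lk, Dir), accurate FRET E_a = E_PR/[γ−(γ−1)E_PR]
  (γ = 0.95 default), and distance R = R₀[(1/E_a)−1]^(1/6) with
  R₀ = 60.1 Å.
- **Trace QC** (`clampfret.qc`): change-point detection of photobleaching
  steps and blinking; selection windows I_DD ∈ [300, 2000] and
  I_AA ∈ [200, 2000] counts; rejection of multi-step bleachers
  (aggregates), early bleaching (frames 1–50) and blinking traces;
  truncation at the first bleach event.
- **State inference** (`clampfret.hmm`): pooled Gaussian-emission hidden
  Markov models fitted by Baum–Welch EM for K = 2..6 states, model
  selection by AIC (2k − 2 log L, k = K² + 2K − 1), Viterbi decoding.
- **Kinetics** (`clampfret.kinetics`): static/dynamic classification
  (> 3 transitions plus anticorrelated I_DD/I_DA), dwell-time extraction
  with first/last-dwell censoring, exponential lifetime fits, and
  transition rates k[i→j] = A[i,j] × frames-per-second.
- **Structure mapping** (`clampfret.structure`): accessible-volume (AV)
  dye modelling on PDB coordinates, mean inter-dye distances R_AV,
  Cα–Cα site distances, and clamp-angle assignment by interpolating a
  monotone (angle, R_AV) calibration curve.
- **Simulation** (`clampfret.sim`): continuous-time three-state Markov
  trajectories discretized by majority occupancy, a photometric forward
  model that is the exact algebraic inverse of the correction cascade,
  Gaussian camera noise, single-step bleaching, telegraph blinking, and
  a configurable static/dynamic molecule mixture.

## Worked example

```python
from clampfret.pipeline import PipelineConfig, run_pipeline
from clampfret.sim import SimConfig

cfg = PipelineConfig(
    outdir="demo_out", seed=7,
    sim=SimConfig(n_molecules=60, n_frames=400, static_fraction=0.0),
)
cfg.hmm.k_range = (2, 3, 4)
manifest = run_pipeline(cfg)
print(manifest["stages"]["hmm"])
```

prints (numbers from this exact run):

```
{'K': 3, 'K_selected_by_aic': 3,
 'means': [0.19925332540625734, 0.2984586790424478, 0.40952223375966773],
 'AIC': -50680.19882289879}
```

i.e. AIC selects the three-state model and recovers the generative E\*
state means 0.20/0.30/0.41 to three decimals; `demo_out/kinetics.json`
then holds the state lifetimes and the per-second transition-rate
matrix, and `demo_out/qc_report.csv` the per-molecule selection
verdicts.

The same pipeline runs from a shell:

```
clampfret run --config config.yaml --seed 7 --outdir demo_out
# or stage by stage:
clampfret simulate ... ; clampfret qc ... ; clampfret correct ... ;
clampfret hmm ... ; clampfret kinetics ... ; clampfret structure ...
```

## Analysis scripts

`analysis/01_simulate.py` … `06_structure_real.py` narrate the full
study on synthetic data: dataset generation, QC and correction, HMM
model selection (K = 3 by AIC), kinetics (≈68%/32% static/dynamic
split, lifetimes in the 150–350 ms range), and structure mapping
(a synthetic clamp-sweep calibration demo; `06` fetches the deposited
RNAP structures 4YG2/4YLN from RCSB — network required — and computes
the ~73 Å labelling-site separation and the closed-clamp R_AV).
Small result tables land in `results/`, bulky raw traces in `scratch/`.

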