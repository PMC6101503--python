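# Methods

## The measurement model

A surface-immobilized RNAP molecule carries one donor (Cy3B on the β′
clamp tip) and one acceptor (Alexa647 on the β pincer tip). Under
alternating-laser excitation the camera integrates, per frame of
exposure Δt (20 ms default; 200 ms supported), three channels: I_DD,
I_DA (donor excitation) and I_AA (acceptor excitation). The clamp
conformation is hidden; the analysis treats it as a continuous-time
Markov chain over K conformational states whose FRET efficiency sets the
split of donor-excitation photons between I_DD and I_DA.

### Photometric cascade

Apparent FRET and stoichiometry are

    E* = I_DA / (I_DD + I_DA),      S = (I_DD + I_DA) / (I_DD + I_DA + I_AA).

Leakage and direct excitation are dataset-level factors estimated from
the E*–S plane: Lk = median(E*_D-only)/(1 − median(E*_D-only)) over
frames with S ≥ 0.8, Dir = median(S_A-only)/(1 − median(S_A-only)) over
frames with S ≤ 0.2 (medians for robustness; the S boundaries are
configuration, defaults documented here). The proximity ratio is

    E_PR = [1 − Dir(1−S)/S − Lk(1−E*)/E*] / [(1−E*)/E* + 1 − Dir(1−S)/S],

accurate FRET E_a = E_PR/[γ − (γ−1)E_PR] with the global detection
factor γ = 0.95 (per-molecule estimation from acceptor-bleach steps,
γ = ΔI_AA/ΔI_DD, is available but not the default), and distance
R = R₀[(1/E_a) − 1]^(1/6), R₀ = 60.1 Å for this dye pair. Frames whose
ratios are undefined (zero denominators, E* or S at 0/1 where the E_PR
formula divides by them) are marked NaN and excluded, never clamped.

Frames entering the E* analysis are additionally gated to the doubly
labelled population by an S window (0.3–0.8 by default). This mirrors
the E*–S sorting of ALEX data into D-only, A-only and D–A species, and
it matters: donor dark intervals too short for the step detector to
resolve otherwise contribute broad-distributed E* outliers that an
extra HMM state will happily absorb, corrupting model selection.

### Simulator

The generator is the measurement model run forwards. A CTMC with the
configured rate matrix is sampled in continuous time and each frame is
labelled by majority occupancy, matching camera integration (sub-frame
events partially average away). State means are specified on the
accurate-FRET scale; the per-frame apparent split fraction is obtained
by inverting the cascade exactly —

    E_PR = γE_a / [1 + (γ−1)E_a],
    E_app = (E_PR + Lk) / [1 + Lk − c(1 − E_PR)],  c = Dir·I_AA/T

— so that on noiseless traces the correction cascade is the identity for
any (Lk, Dir, γ); this is a tested invariant. Noise is Gaussian on the
E* scale per state (default σ = 0.05) plus additive per-channel camera
noise (σ = 25 counts), the EMCCD high-gain regime; counts are clipped
at zero. Photobleaching is a single exponential step per dye (default
0.02 s⁻¹); blinking is a rare two-state telegraph per dye (on 0.01 s⁻¹,
recovery 10 s⁻¹). After acceptor loss the donor dequenches: I_DD gains
the apparent FRET fraction scaled by 1/γ. Defaults place mean
intensities (I_DD+I_DA ≈ 1000, I_AA ≈ 500 counts) inside the QC
windows. A configurable fraction of molecules (default 0.68, the
observed static share) never interconverts; the rest follow the rate
matrix, whose default lifetimes are ~303/200/250 ms — inside the
observed 150–350 ms range, with all six pairwise transitions allowed at
similar rates.

What the generator does *not* emulate: intensity drift and uneven
illumination, acceptor photophysical γ dynamics, spectral crosstalk
beyond single Lk/Dir factors, molecule-to-molecule variation of state
means, and non-exponential dwell behaviour. Passing recovery tests
therefore show the inference machinery is correct under the stated
model, not that real data obey that model.

## Trace selection

Manual trace inspection is replaced by a parameterized detector.
Change points come from recursive binary segmentation on the
two-window mean-difference statistic z = |μ₁ − μ₂|/(σ√(1/n₁+1/n₂))
(threshold 5, persistence 5 frames), with σ the robust noise estimate
1.4826·MAD(Δx)/√2; adjacent-segment steps smaller than 4σ are ignored.
Donor photophysics is read from I_DD + I_DA (acceptor loss barely moves
this sum because of dequenching), acceptor photophysics from I_AA. A
down-step later recovered to within 30% of its pre-step level is a
blink; unreversed down-steps landing below 35% of the prior level are
bleaching candidates. A trace fails on: length < 50 frames; pre-bleach
mean I_DD outside 300–2000 or I_AA outside 200–2000 counts; ≥ 2 bleach
candidates in one channel (aggregates); bleaching within the first 50
frames; any blink. Passing traces are truncated at the first bleach.
The blink/short-bleach boundary is genuinely underdetermined; the
recovery tolerance is exposed as configuration rather than fixed.

## State inference

All QC-passing truncated E* traces are pooled and share one parameter
set (traces are independent realizations). Gaussian-emission HMMs with
K = 2..6 are fitted by maximum-likelihood Baum–Welch EM; this is a
deliberate replacement of empirical-Bayes variational inference — the
conclusions rest on the selected K, the state means and the decoded
paths, all of which ML estimation reproduces, with the converged
log-likelihood playing the bound's role in model comparison. Five EM
initializations spread the initial means over [0.2, 0.4] (emission σ
initialized at 0.05); restarts are screened with 10-iteration short
runs and the best is refined to convergence (|Δlog L| < 0.05, max 200
iterations). Emission σ is floored at 10⁻⁴ against variance collapse; a
state attracting less than one frame of posterior mass marks the
restart degenerate, and degenerate fits lose to any non-degenerate one.
Forward/backward run in scaled linear space with per-frame max-shifted
emissions (stable for arbitrarily small σ); the forward pass is tested
against brute-force path enumeration. Model choice minimizes
AIC = 2k − 2 log L with k = (K−1) + K(K−1) + 2K; ties go to smaller K.
States are reported sorted by mean; paths are Viterbi-decoded.

Pooling is honest only within a homogeneous population: a static/
dynamic mixture violates the shared-transition-matrix assumption, and
AIC then duplicates states into "sticky" and "mobile" copies. The
model-selection study therefore runs on all-dynamic datasets, while
mixture datasets are analyzed under the established three-state model
(`hmm_force_k`), and transition rates are always taken from a refit on
the dynamic molecules only.

## Kinetics

A molecule is dynamic when its decoded path shows strictly more than
three transitions *and* corr(I_DD, I_DA) < −0.2 on included frames
(the anticorrelation threshold replaces visual inspection; traces
shorter than 10 frames stay unclassified). Dwells are maximal constant
runs of the decoded path; first and last runs are censored (their true
extent is unobserved) and excluded from fits; single-frame dwells are
retained since Viterbi already suppresses noise flickers. Lifetimes use
the left-truncated exponential MLE τ = mean(t) − Δt (standard error
τ/√n, floor 20 dwells); a histogram least-squares fit is provided for
parity and agrees within mutual errors at large n. Rates follow the
linear rule k[i→j] = A[i,j]/Δt, with the elementwise −ln(1−p)/Δt
correction available; the linear rule understates rates once
A[i,j] ≳ 0.1 per frame, documented rather than silently corrected.

Known limitation: dwell-histogram lifetimes from decoded paths are
biased long (+15–30% under the default conditions) because Viterbi
absorbs 1–2-frame excursions, merging the dwells around them; on
ground-truth frame labels the same fit is −5%. The kinetics output
therefore also reports the rate-implied lifetimes 1/Σ_j k[i→j], which
derive from soft posterior counts, carry no merge bias, and recover
generative lifetimes within ~10% at 20 ms frames; the recovery study
quotes these.

## Structure mapping

Dye positions on a structure are modelled as an accessible volume: grid
points (1 Å default spacing, symmetric about the attachment Cα so the
grid is bias-free) within the linker length of the attachment atom and
not within dye radius + 1.7 Å of any heavy atom. Reachability is
Euclidean — no path search around obstacles — a standard AV
simplification that ignores occlusion behind thin obstacles. The dye is
a sphere: for each of the three printed semi-axes (Cy3B 6.8/3/1.5 Å,
linker 21 × 4.5 Å; Alexa647 11/4.7/1.5 Å, linker 26 × 4.5 Å) donor and
acceptor AVs are built with the corresponding radius and the three mean
pairwise distances averaged — the single-radius-sweep approximation of
the FRET-positioning methodology. Mean pairwise distance is exact
(chunked) up to 2×10⁷ pairs, else a seeded 4×10⁶-pair subsample
(standard error ≪ 0.1 Å). Clamp angles come from piecewise-linear
interpolation of user-supplied (angle, R_AV) anchors, validated
strictly monotone; queries outside the range clamp to the boundary with
a warning. A rigid-body rotation utility generates synthetic
calibration sweeps; which deposited structure anchors which angle is
user configuration, since hinge-axis and clamp-residue definitions live
outside this package.

## Pipeline and reproducibility

Stages (simulate → qc → correct → hmm → kinetics → structure) read and
write plain-text tables in one output directory; each stage names its
missing prerequisite explicitly. One global seed fans out via
`SeedSequence(seed).generate_state`, one derived stream per stochastic
stage, so identical configuration and inputs reproduce every numerical
output byte-for-byte (trace tables are written at %.17g and parsed with
round-trip float precision). The manifest records the configuration
snapshot and per-stage record counts (molecules in = pass + fail;
frames in = included + excluded).

## Problem sizes

The recovery study uses 10 replicate datasets of 300 molecules × 500
frames (20 ms), K scanned over 2..6 — sizes at which model selection is
decisive and the full study runs in minutes on one core. The
population-split analysis uses 300 molecules × 1000 frames (the 20 s
observation span). Property tests use the smallest sizes that exercise
the contract (e.g. 10⁶ frames for the switch-probability law, T ≤ 8 for
exhaustive path enumeration).
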