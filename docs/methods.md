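# Methods

## Scope

`rejmech` does two things: (i) it turns raw force-extension recordings of
engineered polyproteins into fitted, classified unfolding events and
population statistics; (ii) it generates synthetic recordings with known
ground truth from a kinetic Monte-Carlo model of constant-velocity AFM
pulling. The two halves share one geometry ledger (`rejmech.config`), so
recovery of generator parameters by the analysis is a meaningful test of
both.

## Polymer mechanics

Unfolded polypeptide is modelled as a worm-like chain in the Marko–Siggia
interpolation, F(x) = (kBT/p)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]. Constants:

| quantity | default | unit | rationale |
| --- | --- | --- | --- |
| kB | 0.0138065 | pN·nm/K | Boltzmann constant in AFM units |
| T | 298 | K | room temperature; the experiments state none |
| p | 0.4 | nm | standard unfolded-polypeptide persistence length; held fixed in per-peak fits |
| nm/residue | 0.365 | nm/aa | contour gained per unfolded residue |
| folded N–C | 4.4 (I27), 3.5 (FNIII, MBP), 0 (coil) | nm | reproduces the ~29 nm I27 increment for 89 residues |

The experimental fits were done manually with unstated p and T; both are
configuration here, never "the measured value". WLC inversion uses
bracketed bisection on [0, Lc·(1−1e−9)] (1e−9 nm tolerance): unconditional
convergence for a monotone function. Segment fits are
`scipy.optimize.least_squares` on Lc (and optionally p), with the initial
Lc guessed by inverting the dominant divergent term at the highest-force
point. Extensible-WLC and freely-jointed-chain elasticity are out of scope.

## Construct geometry

Constructs are ordered segment lists with residue counts taken from the
published human polycystin-1 ranges (REJd1 2151–2256, REJd2 2257–2375 by
subtraction, REJd3,4 2380–2575, REJd4 2468–2575). Two deliberate
reinterpretations make the geometry consistent with the observed
increments:

- REJd1/REJd2 are modelled as an 89-residue structured core plus a coil
  tail. Their observed ΔLc is ~29 nm; the full 106/119-residue ranges
  would release 35–40 nm. The tails extend from the start and join the
  spacer.
- MBP carries an effective unfolded length of 103.5 nm (released total
  100 nm, matching the observed ~100 nm rather than the 135 nm its full
  370 residues would give): only the stretch between the pulling
  attachment points unfolds mechanically.

The MBP fusions additionally carry a 90-residue terminal coil representing
expression tags, protease sites and cloning scars; it places the first
unfolding peak beyond the proximal-artifact window, as in the real
recordings. The (I27)₃ constructs carry no linker, so their first-peak
contour length derives purely from the published residue counts — five
folded I27 (22 nm) plus the REJd4 coil (39.4 nm) ≈ 61 nm.

## The pulling simulator

Between unfolding events the system is deterministic: at tip-base position
z the force solves F_wlc(z − F/k_c; Lc) = F (series WLC + Hookean
cantilever, solved by vectorised bisection). Each folded domain carries a
Bell rate k(F) = k0·exp(F·Δx/kBT). Rather than stepping time with per-step
Bernoulli draws — which would need ~1e8 steps per trace to resolve the
rate at high force — the simulator integrates each domain's cumulative
hazard along the force path exactly (the rate is exponential in z where F
is locally linear, so each grid interval contributes its log-mean rate
times its duration) and samples unfolding positions by inverse transform
on per-domain Exp(1) thresholds. This is the exact dt→0 limit of the
discrete scheme. A runtime guard rejects grids that under-resolve the
hazard near the modal force (per-interval hazard ≥ 0.5).

Unfolding releases the domain's contour gain instantly; MBP releases in
two 50 nm steps when its intermediate path is drawn (a per-molecule
Bernoulli event, default probability 0.5). Refolding is out of scope — the
pulls are monotonic. The pull ends at a detachment force drawn uniform on
[420, 600] pN (the published completeness criterion is detachment
> 400 pN; the exact physics of detachment does not matter to the analysis
under test). An early-detachment mode draws uniform [60, 190] pN to
generate the rejected-trace population.

Recorded force adds white Gaussian noise (σ = 8 pN) and a linearly
decaying proximal adhesion bump (amplitude 15 pN over a span drawn uniform
on [10, 30] nm); the underlying mechanics is noise-free, and extension
(tip–sample separation) is computed from the true force. Study-condition
defaults: 0.6 nm/ms pulling speed (mid-range of the published
0.5–0.7 nm/ms), 50 pN/nm cantilever, 0.2 nm sampling grid.

Per-trace seeds derive from the dataset master seed as
`SeedSequence(master_seed, spawn_key=(index,))`; datasets are
byte-reproducible.

### What the generator does and does not emulate

It emulates the statistical structure the analysis relies on: WLC
elasticity with the correct contour bookkeeping, force-dependent unfolding
with realistic force distributions (left-skewed, loading-rate dependent),
multi-domain races, sub-resolution coil extension, measurement noise,
proximal artifacts, and detachment. It does not emulate instrument drift,
hydrodynamic drag, refolding during retraction, tip-chemistry-dependent
pickup geometry (molecules are always grabbed end-to-end), or the
~1-in-500 pickup yield of real experiments. Passing recovery tests on
simulated data therefore validates the pipeline's logic and numerics, not
its robustness to every artifact of real recordings.

## Kinetic calibration

No unfolding kinetics (k0, Δx) exist for these domains; all values are
calibration products, clearly non-measured. Δx is chosen first: the
Bell-Evans force distribution has SD ≈ 1.28·kBT/Δx, so a target SD fixes
Δx within the 0.2–0.6 nm search range (a warning fires if the target SD is
off by more than 2×). k0 is then solved from the modal-force relation
F* = (kBT/Δx)·ln(r·Δx/(k0·kBT)) with loading rate r = k_eff·v, and refined
against simulation. Three closed loops exist, in increasing faithfulness
to how the published numbers were produced:

1. `calibrate_bell` — single-domain pulls from a fixed contour state;
   fast, used for the I27 reference (modal force 200 pN, SD target 18 pN,
   giving Δx ≈ 0.29 nm, k0 ≈ 8e−4 /s — titin-like values).
2. `calibrate_to_detected` — full-construct batches; matches detected
   peaks to ground truth by extension and drives per-class detected means
   onto targets. This absorbs detection biases (sub-threshold events are
   invisible; smoothing biases peak maxima slightly upward).
3. `calibrate_to_population` — drives the pipeline's own pooled
   population statistics (mixture component means) onto targets, since the
   published populations are exactly such statistics.

The loops are stochastic approximations: updates are damped (0.7–0.8) and
the returned k0 is the geometric mean of the final two iterates, which
keeps the last batch's sampling noise out of the calibration. Residual
seed-to-seed scatter of the recovered low-force population mean is ~4 pN
(SE of ~33 pooled events plus mixture-boundary variability).

## Peak pipeline

Detection runs on a moving-average-smoothed force (7 samples): local
maxima with height ≥ 30 pN, prominence ≥ 20 pN, extension separation
≥ 5 nm (ties broken by height, then lower extension), each followed by a
≥ 20 pN drop before the next peak. The 30 pN floor sits below the smallest
population of interest (~60 pN) but above the noise; events below it are
invisible, exactly as in the instrument. Fit windows run from the previous
force minimum to two samples before the peak (the top is rounded by
cantilever dynamics); windows under 4 samples are skipped with a warning.
The contact point (x = 0) is taken from the trace as provided — no
re-zeroing.

ΔLc of a peak is its fitted Lc minus the previous peak's (undefined for
the first); the *released gain* of a peak is the forward difference — the
contour that peak's unfolding event added, measurable because the
detachment peak closes the telescoping sum.

Selection implements the published rules: detachment ≥ 200 pN, and a
"clean initial extension" operationalised as no excursion of
prominence ≥ 20 pN inside the proximal window (≤ 30 nm) — the published
criterion is qualitative; this proxy is ours. An optional expected peak
count (e.g. five I27) can be enforced after classification. Selection is
monotone in the detachment threshold.

## Fingerprint classification

Greedy, construct-aware, in extension order:

1. the final peak is the detachment event;
2. if the construct contains MBP, the low-force (< 120 pN) subset of ≤ 2
   events whose released gains sum into 100 ± 20 nm (each component in its
   own window: ~100 nm all-or-none, or two ~50 nm steps) is labelled
   MBP / MBP-intermediate — robust to another low-force domain unfolding
   before, between or after the pair;
3. remaining peaks with a single-domain-sized increment (either side
   within 29 ± 16 nm) fill the construct's I27 slots, preferring forces
   nearest 200 pN;
4. leftovers with plausible single-domain increments are REJ candidates;
   peaks carrying only fused multi-event increments (the trace of a
   sub-threshold neighbour) are labelled `unassigned` and flagged, never
   silently pooled.

Identity limits are preserved: when a REJ candidate and an I27 fall inside
the same force window the pair is marked unresolved (`resolved=False`),
and for constructs with a single REJ slot the force inference pools the
pair jointly. This mirrors the experimental situation — REJd1 unfolds at
I27-like forces and cannot be told apart trace by trace; only REJd2's
~60 pN population is individually attributable. Label-accuracy claims are
therefore evaluated on resolved events (and as label multisets overall).

## Population statistics

Pooled forces (REJ + I27 by default; MBP and detachment excluded) are
decomposed by maximum-likelihood Gaussian mixtures
(`sklearn.mixture.GaussianMixture`, k-means++ initialisation, 20 restarts,
fixed seed), with the component count chosen by BIC. A candidate component
must hold ≥ 10% of the events and ≥ 5 events to count as a population:
Bell-model force distributions are left-skewed, and without this occupancy
rule BIC carves the skew tail into a spurious second component in roughly
half of single-population batches. The genuine two-population case
(weights ≈ 0.3/0.7) is unaffected. Degenerate (zero-spread) samples return
one component with a 1 pN floor SD; fewer than 10 events is an error. The
20 pN reporting histogram conserves event counts by construction.

Bell–Evans fitting of force distributions across pulling speeds (dynamic
force spectroscopy) is out of scope — the emulated experiments use a
single speed.

## Problem sizes

Recovery runs use 25–50 traces per construct and 500 events for the modal
force, matching the scale of the emulated experiments (21–47 selected
traces, 40–103 pooled events); calibration loops use 40–100-trace batches.
Simulating one trace takes ~15 ms, so the full acceptance recomputation is
under a minute.

## Known limitations

- The lower-population mean recovered by the two-component mixture scatters
  by ~4 pN (1 SD) across dataset seeds at the 50-trace scale; single runs
  can land several pN from the calibration target.
- The classifier's MBP subset search assumes at most one MBP per
  construct (true for all registered constructs).
- Trace files are plain TSV; vendor AFM binary formats are not read.
- No contact-point estimation or drift correction: traces are assumed
  pre-zeroed, which the simulator guarantees and real data may not.
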