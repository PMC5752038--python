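# Methods

## The latent MOMP model

The simulator treats apoptotic priming as a two-guardian buffering problem.
Every cell draws independent anti-apoptotic buffers

    R_B ~ LogNormal(mu_B, sigma_B)     (BCL-2)
    R_M ~ LogNormal(mu_M, sigma_M)     (MCL-1)

Drugs act multiplicatively on the buffer they target; a BH3 peptide challenge
multiplies its target buffer(s) by `1 - efficiency`; the cell commits to MOMP
(cytochrome-C release) iff the residual buffers sum below a threshold:

    f_B * (1 - e_B) * R_B  +  f_M * (1 - e_M) * R_M  <  theta.

Additive buffering is the essential structural assumption: either guardian
alone can cover the threshold, so neutralising one guardian kills only cells
whose other guardian a drug has already removed. This is what makes the
BAD-BH3 / MS1 dichotomy informative and what the complementary-class
combination rule exploits. BCL-XL is deliberately absent (the modelled cell
line does not over-express it); cells protected by a third guardian are out
of scope.

Drugs additionally carry an `intrinsic_lethality`: a buffer-independent
per-cell release probability composed by independence. Because independent
causes compose exactly per Bliss, inert agents with pure intrinsic lethality
provide an exact Bliss-null construction used to calibrate the type-I error
of the supra-additivity test.

## Drug kinetics

Binders act instantaneously: `remaining = 1 - effect`. Synthesis-blocking
mechanisms (transcriptional downregulation, depletion via splicing or
translation arrest) decay with the target protein's half-life:

    remaining(t) = (1 - effect) + effect * 2^(-t / t_half)

with defaults `t_half(MCL-1) = 1 h` and `t_half(BCL-2) = 14 h`. The decay law
is the simplest one consistent with first-order protein turnover under a
synthesis block; no published kinetic equations exist for these assays. Its
consequence is the model's central time asymmetry: a full 4-h MCL-1 synthesis
block leaves 6.25% of the buffer, while a full 4-h BCL-2 block leaves
2^(-4/14) ~ 82% — so BCL-2 downregulators cannot prime a 4-h assay but do
prime at 48 h (9.3% remaining).

On washout, reversible agents restore `remaining = 1`; irreversible agents
freeze at the washout-time level. High-affinity BCL-2 binders are modelled
irreversible on the assay timescale (pre-exposure is as effective as
concurrent exposure), the reversible MCL-1 binder restores its buffer when
rinsed away. Whether the real compound's assay failure is purely
reversibility is an open mechanistic question; the model implements
reversibility without claiming mechanism.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `mu_B`, `mu_M` | 0.0 | ln a.u. | buffer scale is arbitrary; medians set to 1 |
| `sigma_B`, `sigma_M` | 0.25 | ln a.u. | modest cell-to-cell heterogeneity; keeps drug-alone release of screen-passing agents below 10% while saturating primed+challenged conditions |
| `theta` | 0.7 | buffer units | below the single-guardian median: one intact guardian protects (>93% survival), both guardians together make spontaneous MOMP negligible |
| peptide efficiencies | BAD 0.98 on R_B; MS1 0.98 on R_M; PUMA 0.98/0.98; PUMA2A 0/0 | fraction | near-complete target neutralisation at assay concentrations (3 uM BAD/MS1, 100 uM inactive control); concentration is folded into efficiency rather than a binding isotherm |
| `half_life_mcl1` / `half_life_bcl2` | 1 / 14 | h | literature protein half-lives |
| cytc intensity means | 3.5 / 2.0 (retained / released) | log10 a.u. | 1.5-decade separation, shared sigma 0.25: 6-sigma modes, so gating error is negligible against sampling error |
| `aad_lag_prob` | 0.5 | fraction | the viability dye marks a later apoptosis stage and lags MOMP; half of MOMP-positive cells dye-positive at readout is a middle-of-road choice for a 30-min stain |
| `replicate_log_theta_sd` | 0.05 | ln units | per-replicate-table jitter of theta modelling day-to-day biological variability; yields replicate SDs of a few percentage points, the scale visible in triplicate cytometry summaries. Set 0 for a noiseless generator |
| `delta_threshold` (delta*) | 0.30 | delta units | separates weak from strong primers in the dichotomisation; configurable and echoed into every output |
| `drug_alone_ceiling` | 0.10 | fraction | agents killing >=10% on their own during the assay are unclassifiable (over-lethal), mirroring the dose screen's control-peptide ceiling |
| screen bounds | >75% with PUMA, <10% with control | fraction | strict inequalities; the implied minimum change in priming is 65 percentage points |
| `alpha` | 0.05 | — | conventional significance level; no multiple-testing correction by default (an optional Holm step would be an additive feature, not a change of the statistic) |

The default seven-agent panel mirrors the archetypes a combination screen
contains: two clean MCL-1 depleters (pladienolide-B-like, torin1-like,
effect 1.0 — full synthesis block), a high-affinity BCL-2 binder
(ABT-199-like, effect 0.96 — near-complete occupancy while keeping drug-alone
release ~5%, comfortably under the over-lethal ceiling), a transcriptional
BCL-2 downregulator profiled at 48 h (JQ1-like, effect 1.0), a DSB inducer
and a FLT3-inhibitor-like depleter (effect 1.0 with small intrinsic
lethalities 0.02 and 0.01 — buffer-independent collateral kill), and a
reversible MCL-1 binder (effect 0.96, washed off in the profiling assay but
present concurrently in combination conditions).

## Gating

The release gate is a two-component Gaussian mixture on log10 cytochrome-C
intensity, fitted on a pooled calibration control (untreated cells with and
without PUMA challenge, so both modes are guaranteed present); the threshold
is the equal-posterior point between the dim (released) and bright (retained)
components. The fit falls back to the midpoint of the component means — and
is flagged — when a component's weight drops below 2% or the means are closer
than twice the average component SD (unimodal input split in half). Ties at
exactly the threshold count as retained, making the gate bit-exact
reproducible. Quadrant gates on the membrane-potential and viability-dye
channels use negative-control tails: the 0.5th percentile of the untreated
control on the Δψm channel (positive = low) and the 99.5th on the dye channel
(positive = high).

## Statistics

Δ-priming is computed per matched replicate pair — replicate r of
drug+peptide against replicate r of peptide-only — then summarised as
mean ± SD; only the peptide-in-untreated baseline is subtracted (no
drug-alone correction; published variants differ here). The Δ for the
promiscuous PUMA peptide is optional and skipped when its untreated baseline
saturates at 100% release (the normalisation is then undefined).

Combination significance is a one-sided paired t-test (n − 1 df) on
per-replicate differences `observed_i − (A_i + B_i − A_i·B_i)`; pairing by
replicate index preserves within-replicate correlation, and the Bliss
expectation is computed per replicate before averaging. Exactly constant,
positive differences have no variance and are reported as p < 1e-6 with a
degenerate-variance flag. FEA is mean(observed)/mean(expected), reported
unclipped (sub-additivity shows as FEA < 1) and marked not-evaluable when the
expectation is zero. A measured-positive pair means significant AND FEA > 1.

## Numerical choices

* The marginal release probability `P(a·R_B + b·R_M < theta)` is evaluated
  deterministically: closed-form normal CDF when one scale is zero, otherwise
  256-point Gauss–Legendre quadrature over the standard-normal variable
  behind R_B on [−9, z_max], accurate to well under 1e-4 (tested against a
  10^6-draw Monte-Carlo oracle at ±0.005). Results are memoised.
* Per-table seeds derive from SHA-256 of `(base_seed, condition_id,
  replicate, purpose)` reduced below 2^31 — stable across runs and platforms;
  one integer seed reproduces a whole panel byte-for-byte.
* Event CSVs are written with 10 significant digits so write-then-read is an
  identity up to float formatting.
* Degenerate inputs are errors, not silent values: zero events, a saturated
  Δ baseline, a zero Bliss expectation, fewer than two replicates, and fewer
  than 200 threshold-fit events all raise typed exceptions.

## What the generator does and does not emulate

It emulates: bimodal log-normal fluorescence with realistic channel
separation; condition-dependent release probabilities driven by drug
mechanism; protein-decay kinetics; peptide challenge including the inactive
control; washout scheduling; triplicate structure with day-to-day
variability; and the dye-lag between MOMP and late-stage positivity.

It does not emulate: dose–response (a drug is a point effect at its modelled
dose, so no IC50s or 48-h dose-response synergy), mRNA/protein time courses
beyond the single-exponential decay, spectral spillover/compensation,
doublets, debris, acquisition drift, or a third guardian. Passing tests
therefore show that the analysis recovers the truth of *this* generative
family — they do not certify performance on real cytometry artefacts the
generator omits.

## Problem sizes

The default panel runs 66 conditions x 3 replicates at 10,000 events each and
completes, with full analysis, in a few seconds. The repeated-seed evaluations
use 100 panel seeds for prediction concordance (25 in the acceptance script),
200 random agents for classification recovery, 50 tables for gating recovery,
and 1,000 triplicate experiments for the type-I calibration.

## Known limitations

* The additive two-guardian threshold rule is a caricature of BCL-2-family
  stoichiometry; it reproduces the dichotomisation logic, not molecular
  titration of activators and sensitisers.
* Same-side combinations are only approximately Bliss-independent under the
  threshold model (residual buffer still matters slightly), so their measured
  FEA distribution straddles 1 rather than centring exactly on it.
* The screen's PUMA arm saturates in the generator (a fully efficient
  promiscuous peptide releases everything), so the screen discriminates
  drug-alone lethality rather than PUMA-priming adequacy.
* Classification accuracy claims hold for effects >= 0.5; weakly acting
  agents near the delta* threshold are inherently ambiguous.
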