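# Methods

## Scope and shape

`ribotraffic` couples four sub-models — Poisson lesion placement, an
exclusion-process traffic model of RNAPI, two-channel first-order repair,
and threshold-based chromatin state — and derives every observable from the
simulated population state through virtual assays. The forward simulator is
exposed as `run_scenario(...) -> Trajectory`; the inverse problems follow
the Model → `fit()` → Results pattern (estimates, standard errors,
confidence intervals, `summary()`), which is the natural shape for the
estimation stage while the simulator itself is not a model fitted to data.

## Lesion model

Photoproducts on the transcribed strand of each gene copy form an
inhomogeneous Poisson process with piecewise-constant rate λ(x) (per kb).
Two measured damaged fractions calibrate the default profile through the
zero class, P(no lesion in L) = exp(−λL):

* 37.9% of copies carry ≥1 lesion within the promoter-proximal 0.86-kb
  fragment → λ = 0.554/kb on [0, 860).
* 87.3% carry ≥1 lesion within the first 2.96 kb → λ = 0.756/kb on the
  remainder, solved at build time so the joint zero class over [0, 2960)
  matches; the distal rate is extended to the gene end, for which no
  separate measurement exists.

The first-lesion CDF is 1 − exp(−∫₀ˣ λ); its 87.3% quantile under the
default profile is 2,960 bp — the "likely position of the first CPD"
statistic. Lesion types follow the canonical photoproduct mix (75% CPD,
20% 6-4PP, 5% other); all types block elongation equally, and by default
repair at the same rates (a 6-4PP rate multiplier is configurable).
Gaussian approximations of these counts are deliberately replaced by the
exact Poisson forms they approximate.

## Traffic model

Each copy is a single lane with hard-core exclusion (footprint 65 bp,
positions strictly increasing). A fixed-increment scheme (dt = 1 s;
anything up to 5 s is accepted) applies per step: initiation, elongation,
arrest, release, repair, chromatin update. Fixed-increment stepping was
chosen over event-driven simulation because collision handling for several
thousand polymerases is then a handful of vectorised array operations.

* **Initiation.** Open or intermediate copies with a clear entry site
  (no polymerase within one footprint of the start) gain a polymerase at
  position 0. The default attempt probability solves the discrete renewal
  equation so the realised inter-initiation interval equals
  `steady_spacing / elongation_rate` despite the promoter dead time — the
  naive rate v/spacing would undershoot the target density by ~30% because
  the entry site is blocked for footprint/v seconds after each initiation.
  With an explicit `initiation_rate` the probability is simply rate × dt.
  A `post_uv_initiation_factor` (default 1 — the 5′ pile-up must emerge
  from queueing alone) scales attempts after irradiation.
* **Elongation.** Each elongating polymerase advances
  min(v·dt, gap to leader − footprint, first unrepaired template-strand
  lesion − 1, gene end). Leader positions from the step start are used, so
  exclusion can never be violated; reaching the gene end is a termination,
  reaching a lesion an arrest (the lesion becomes TCR-engaged and stays so
  until repaired — the repair machinery, not the polymerase, performs the
  excision, so the mark survives release of the arrested polymerase).
* **Release.** Arrested polymerases leave the template spontaneously at
  `k_release` (default 0.05/min; modes `constant`/`both`) and, while a
  trailing polymerase is pressed against them, at `k_collision` (modes
  `collision`/`both`; default mode `both`). Released and terminated
  polymerases rejoin an unlimited free pool. Making collision release a
  contact-gated *rate* rather than an instantaneous event is essential:
  with instantaneous release the bottleneck throughput equals the arrival
  rate, no queue ever forms, and the observed 5′-end accumulation cannot
  exist.
* **Consistency.** After every step the ordering/footprint invariant is
  re-checked and any violation aborts the run. Trajectories track
  initiations, terminations and releases by cause; at every snapshot
  `initial load + initiations = terminations + releases + on-template`.

## Repair

Each unrepaired lesion flips with probability 1 − exp(−k dt):
k = `k_tcr` for TCR-engaged lesions, `k_ggr` otherwise, both zero in the
NER-deficient (rad14Δ-like) scenario. Defaults: k_tcr = ln2 / 0.5 h (the
midpoint of the measured 40–60% repaired within 30 min, applied to the
engaged subset) and k_ggr = ln2 / 2 h, which puts the aggregate 4-h
repaired fraction at ~88%, inside the measured 60–90% band. An alternative
TCR rule (`open_copy`: every template-strand lesion of a transcribed copy
is eligible) is available as a configuration switch.

## Chromatin

Nucleosome state is a per-bin coverage fraction over the coding region
(default bin 200 bp ≈ nucleosome + linker; the last bin may be shorter when
the bin width does not divide the gene). Bins wholly downstream of the
first unrepaired lesion that have been polymerase-free for
`deposition_delay` (default 5 min — the data cannot fix this value, only
that closing follows vacancy) acquire coverage 1; bins traversed by a
moving polymerase are wiped to 0. Hmo1 is never touched by damage or
deposition: copies open before UV keep the mark. Classification per copy
(or per restriction-fragment region): open if coverage ≤ 0.2, closed if
≥ 0.8 *and* the copy carries no polymerases, otherwise intermediate — a
copy whose 3′ half is nucleosomal while a 5′ queue persists is exactly the
partially-closed material that migrates as a smear between the psoralen
bands. Positioned dyads are not modelled; the assays only read
accessibility.

## Virtual assays

* **ChIP**: per amplicon, the mean per-copy count of polymerases whose
  footprint overlaps the amplicon, scaled so the pre-UV value is 1.0 and
  offset by an additive background (default 0.05, the level reported by
  the spacer amplicon a, which never carries signal).
* **TRO**: per membrane fragment, the mean per-copy count of polymerases
  with elongating status inside the fragment; arrested polymerases are
  excluded, queued-but-elongating ones count. Fragment 1 is a
  non-homologous control and reads 0. Ratios 5′/middle (fragment 2/3) and
  5′/3′ (2/4); zero denominators are flagged, not raised.
* **Miller spreads**: per visible copy (not closed, ≥1 polymerase), the
  position of the most 3′ engaged polymerase × 0.34 nm/bp. Comparisons are
  ordinal (pre-UV ≫ NER-deficient late), not absolute nanometres.
* **Psoralen**: fractions of copies per chromatin class, classified on the
  coverage within the probed restriction fragment; the intergenic spacer
  returns a single closed band.
* **ChEC**: copies carrying the tagged protein in the probed region
  (RNAPI: ≥1 polymerase there; Hmo1: the retention flag; histones:
  coverage above the open threshold) lose `digestion_extent` of their
  signal; residuals are reported per psoralen class.

## Synthetic data

`gen_observed_tables` multiplies noiseless assay values by mean-one
lognormal factors (CV 0.2, four replicates by default, matching the
reported experimental design); signals are positive and their reported SDs
scale with the mean, which rules out additive Gaussian noise. Repair time
courses emulate what the instrument actually measures — the remaining
damage signal S(t) — so noise is applied to S and the repaired fraction is
1 − S(t)/S(0) per replicate. `gen_toy_fixture` is a four-copy, 1,000-bp
deterministic scenario (all stochastic rates zero) whose trajectories are
hand-computable and anchor the unit tests of the stepping scheme. The
generators emulate the statistical structure of the readouts, not the
instruments' systematic errors (cross-linking efficiency, hybridisation
bias, gel migration); passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not robustness to
instrument-specific artefacts.

## Inference

* `LesionRateModel`: λ̂ = −ln(1 − x/n)/L with a Wilson binomial interval
  transformed through the same map (well-behaved at x = 0 and x = n; the
  x = n case is flagged unbounded).
* `RepairKineticsModel`: least squares of −log(1 − f) = k·t through the
  origin — exact for the multiplicative noise of a damage-signal readout;
  saturated points (f ≥ 1), where the log transform is undefined, are
  excluded and flagged; k ≥ 0 is enforced and a t-based interval reported.
* `TrafficModel`: grid search over (release_mode, k_release) scored by the
  summed squared residual between simulated and observed mean ChIP
  profiles, with a common seed across candidates (the simulator is
  stochastic and cheap; common random numbers make self-recovery exact and
  the surface comparable). The full residual surface is returned;
  numerically indistinguishable surfaces are flagged flat.

## Calibration and problem sizes

All kinetic constants above are fixed by the study conditions or by the
locus geometry. The one genuinely free constant, `k_collision`, was
calibrated once against the measured ~20% residual downstream occupancy 30
minutes after UV, by a sweep over 1.5–10 per min (12 seeds per value): the
residual is nearly flat across that range (0.28–0.32) because downstream
queues are resupplied by initiation flux after first-lesion repair, and the
value at the sweep minimum, 4.0/min, was frozen. The residual the model can
reach therefore sits at ~0.28 rather than 0.20; the same mechanism
(elongating-status polymerases queued in the middle fragment) caps the
simulated 30-min TRO 5′/middle ratio near 2.4–2.9 against the measured 3.8,
and Poisson placement puts a lesion 5′ of amplicon c in ~33% of copies,
capping the population-mean 5′ ChIP fold at ~1.45 against the reported
1.5–2×. These gaps are reported as computed; no parameter is tuned to them.

Default problem sizes keep everything desk-scale: 150 copies, dt = 1 s,
four-hour scenarios in ~10 s each; the reproduction script uses 20
replicate one-hour scenarios and a 100,000-copy Monte Carlo and completes
in about a minute on one CPU.

## Known limitations

* Sequence context is ignored: lesion rates are per-kb constants, not
  dipyrimidine-site probabilities of the real rDNA sequence.
* Backtracking, reverse translocation and transcription-through-lesion are
  not modelled; arrest is absorbing until release or repair.
* The free polymerase pool is unlimited; proteasome-dependent degradation
  is deliberately absent.
* Cell-cycle effects (the late over-opening of rDNA chromatin when cells
  accumulate in G1/S) are out of scope, so late-time open fractions top out
  at their pre-UV value.
* ChIP counts polymerases linearly; any differential cross-linking of
  clustered, queued polymerases is unknown and ignored.
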