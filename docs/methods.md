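# Methods

## Replication model

A genomic region of length `region_length` (default 40,000 kb per simulated
molecule) carries replication origins placed as a renewal process: i.i.d.
gaps from the configured spacing distribution, started at a uniform phase
offset. The default gap family is a gamma with shape 4 — regular enough to
avoid unrealistically frequent near-zero gaps while producing a unimodal
interorigin-distance histogram. Conditions with dormant-origin-like firing
add a second, short-mean mixture component (the `cks2_ko` fixture mixes 85%
gamma(mean 250 kb) with 15% gamma(mean 70 kb), overall mean 223 kb).

Each origin fires at a time drawn from the scenario's firing-time
distribution and launches a left and a right fork. Sister forks share a
per-replicon velocity (gamma, fixture means 1.4–1.98 kb/min, CV 0.1) plus
independent Gaussian noise (`sister_noise_sd`, default 0.03 kb/min). A fork
may stall — permanently — as a per-minute Bernoulli event with probability
`stall_rate` (fixtures: 2·10⁻⁴/min wild-type-like, doubled in the `cks2`
knockout, which drives its higher asymmetric-replicon fraction). Stalling is
the only discretised ingredient (1-minute grid); all other kinematics are
event-driven and exact: forks advance linearly, converging forks from
adjacent origins terminate exactly where and when they meet (both forks stop
at the same recorded junction coordinate, so no spurious sub-resolution gap
can appear between their tracks), and the outermost forks clamp at the
region boundaries.

Labeling follows the two-pulse protocol: DNA synthesised during
[0, 20) min is IdU, during [20, 40) min CldU, and anything made before the
pulses (or never made) is unlabeled. Coordinates are kb, 0-based, half-open.

Two generator choices deserve justification:

* **Firing times, uniform on [−6, −3] min before the pulses.** Real origins
  fire throughout S phase; the simulator models the cohort of origins whose
  activity is captured by a 40-minute labeling window, and places their
  firing shortly before the first pulse so that (a) every intact replicon
  carries a measurable unlabeled initiation gap flanked by IdU, and (b)
  origins are not silently lost to pre-pulse fork mergers, which would
  distort the measured interorigin distances. The window is configurable;
  pushing it into the pulses produces the CldU-only and merged-IdU patterns
  seen in real data, at the cost of fewer measurable forks.
* **Velocity dispersion, CV 0.1.** Eligibility filtering is selective:
  fast forks close their junctions with converging neighbours more often and
  are excluded as terminations, and their longer tracks are censored by
  fiber ends more often. Both selection effects scale with the velocity
  variance. Real combing histograms are broader, but much of that spread is
  measurement noise rather than per-replicon biology; the fixtures use a
  modest intrinsic dispersion so that the recovered means stay within a few
  hundredths of a kb/min of the configured ones. With CV 0.2 the residual
  selection bias roughly quadruples.
* **Region length, 40,000 kb.** Gaps that straddle the ends of the simulated
  region are lost, biasing the realised gap population short by roughly
  E[g²]/L; at 40,000 kb this window effect is under 2 kb for all fixtures.

## Observation model

Molecules are cut into fibers at renewal breakpoints with lognormal lengths
(default mean 500 kb, σ_log 0.5 — long enough to host whole replicons, short
enough that most adjacent-origin pairs are split, as in real slides;
interorigin-distance runs raise the mean to 2,000 kb). Segments are clipped
at the cuts, terminal segments abutting a cut are flagged censored, and
labeled segments shorter than the detection limit (1 kb = 0.5 μm, a typical
optical resolution) drop out as unlabeled; a dropped sliver never bridges
two like-labeled neighbours into one track. Lengths convert between kb and
μm through the combing stretch factor, 2 kb per μm, exactly and invertibly.

The image renderer/extractor is deliberately toy — a straight 1-D fiber, a
Gaussian PSF and additive noise, per-channel thresholding and run-length
encoding — and exists to close the loop on the geometry (render → extract
recovers segment boundaries to a pixel); crossing fibers, breakage and
uneven stretching are out of scope.

## Track classification

Patterns are parsed per fiber (I = IdU, C = CldU, U = unlabeled):

| pattern | call |
| --- | --- |
| U flanked by I on both sides | origin (fired pre-pulse); center = gap midpoint |
| I flanked by C on both sides | origin (fired in pulse 1); center = IdU midpoint |
| I with C on exactly one side | ongoing fork (a gap-centred replicon's arms count) |
| C flanked by I on both sides | termination (met during pulse 2) |
| I between two initiation gaps | termination (met during pulse 1) |
| isolated I / isolated C | first- / second-pulse-only track |

A CldU flank that abuts further IdU is a merged termination junction and is
never measured as a flank or a fork. Structures whose segments come within
`edge_margin` (default 1 kb, the detection scale) of a fiber end are flagged
censored and contribute to no statistic — this margin also covers the corner
case where a cut lands so close to a junction that the sub-resolution
remnant of the next track drops out and would otherwise disguise a
termination as an ongoing fork.

## Estimators

* **Velocity** (default `total` mode): (IdU + CldU length)/(total pulse
  time). The field also divides a single fluorescent segment by one pulse
  time; both conventions agree for steady forks, and the two-label form uses
  all the signal, so it is the default with `second_pulse_only` as an
  option. On noiseless, unstalled, uncensored simulated forks the estimator
  is exact, and a test audits that every reported velocity equals the true
  velocity of a surviving ground-truth fork.
* **Asymmetry**: scored on second-pulse flank lengths only, as
  |L − R|/max(L, R) > 0.3. The "ratio greater than ±0.3" rule admits other
  readings (`relative_min`, equivalent to an L/R ratio band, and
  `relative_mean`), provided as config options; the default is symmetric in
  L, R and bounded in [0, 1). Replicon-level mean ± sd are reported over
  three round-robin pseudo-replicates of fibers, standing in for independent
  experiments. No multiple-comparison correction is applied anywhere (raw
  Mann-Whitney p-values are reported).
* **Interorigin distance**: center-to-center distances of consecutive
  eligible origins per fiber, pooled. A pair spanning s kb fits on a fiber
  of length L with probability ∝ (L − s), so the plain pooled mean is biased
  short; the reported mean weights each pair by 1/(L − s) (Horvitz-Thompson),
  with weights truncated at 1/(0.25 × median fiber length) to keep
  near-span-filling pairs from dominating. The raw mean is reported
  alongside. Even on 2,000-kb fibers the correction moves the wild-type
  mean by ~5 kb.
* **Mann-Whitney U**: exact null by full enumeration of label assignments
  (midranks for ties) when n1 + n2 ≤ 12, tie-corrected normal approximation
  with continuity correction otherwise. The two-sided exact p counts
  assignments with |U − n1·n2/2| at least as large as observed. A test
  verifies exact agreement with an independent enumeration oracle for all
  n1, n2 ≤ 6 including heavily tied samples, and with scipy's exact method
  in the tie-free case.

## Cell-cycle model

Each cell draws G1, S and G2/M durations from lognormal distributions
(fixture CV 0.15 per phase); in the default exponential-growth mode its age
is drawn from the stationary age density f(a) ∝ 2^(−a/Tc) on [0, Tc), whose
CDF F(a) = 2(1 − 2^(−a/Tc)) gives the closed-form phase fractions used in
tests (e.g. P(age < Tc/2) = 2 − √2). DNA content is 2N in G1, linear to 4N
across S, 4N in G2/M, with multiplicative Gaussian measurement noise
(CV 0.05). The G1/G2 gates sit within 5% of 2N/4N at zero noise and widen by
two noise SDs otherwise; everything between them is gated S.

BrdU labeling marks any cell whose S phase overlaps the pulse window
([−15, 0] min by default — long enough to be detectable, short relative to
every fixture's S phase). During a chase, cells advance deterministically
through their phases and divide; both daughters inherit the label (analog
dilution is ignored over 24 hr) and draw fresh durations. The
labeled/unlabeled ratio inside the G1 gate rises while the labeled cohort
divides into G1 (within S+G2M of the pulse) and falls again once the cohort
re-enters S — the ratio is *not* monotone over a full cycle.

Genotype fixtures are calibrated, not fitted: the `cks2` knockout's total
cycle is 0.85× wild-type (G1 305, S 535, G2M 180 min vs 780/240/180) with
the G1/S split chosen from the closed-form stationary fractions so its
S-phase occupancy is 3.00× wild-type; the `cks1` knockout is 3× slower
(1937/1423/240 min) with ~2× the S occupancy. With a finite 15-min pulse the
measured BrdU-positive fold is slightly below the occupancy ratio (≈2.9)
because the pulse also catches cells entering S, proportionally more in the
genotype with the longer G1.

## Reproducibility and problem sizes

All randomness flows through a single seeded `numpy` generator per run
(scenario files carry a default seed; the CLI and the acceptance script
override it), and identical scenario + seed reproduce byte-identical tables
and reports. The acceptance script uses 5 molecules × 40,000 kb per genotype
for velocities (≈900–1,400 eligible forks), 12 molecules with 2,000-kb
fibers for interorigin distances (≈1,800–2,400 pooled distances), ≈570
forks per group for the comparison test, 50 tracked cells for cycle
durations and 10,000 cells for BrdU fractions — sizes chosen so each
statistic's Monte-Carlo error is several times smaller than the effects of
interest while the whole script runs in seconds.

## Known limitations

* Stalled forks never restart; restart within the 40-minute window is
  excluded, not denied.
* No replication-licensing biochemistry, dormant-origin signalling or
  checkpoint model: the short-IOD subpopulation is a phenomenological
  mixture component.
* Track-length measurement is noiseless (beyond the detection limit and the
  toy imaging path); real μm-scale measurement error broadens velocity
  histograms without, to first order, moving their means.
* Forks measurable in only one pulse are excluded from velocity estimates;
  origins firing during the pulses are excluded automatically because their
  IdU is shared or absent.
* The population simulator ignores cell death, quiescence and label
  dilution; pseudo-replicates share one simulated population and understate
  true between-experiment variance.

Passing tests therefore demonstrate that the estimators are unbiased and
correctly filtered under this generative model — not that they are robust to
slide artefacts or measurement noise absent from it.
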