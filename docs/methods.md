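# Methods

This note documents the models, rules and numerical choices behind
`epitope-audit`: what each component computes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Digestion-sensitivity scoring

**Statistic.** For a paired measurement with percent-positive `p_u`
(undigested) and `p_d` (digested), the relative change is
`RC = 100·(p_u − p_d)/p_u`, computed as `100·(1 − p_d/p_u)` so that the
upper bound `RC = 100` is attained exactly when `p_d = 0`. RC is undefined
at `p_u = 0`; such replicates must be excluded upstream
(`no_positive_in_undigested`).

**Replicate bands.** Sensitive at `RC ≥ 50`, partially sensitive at
`25 ≤ RC < 50`, insensitive below. The two published bands both contain 50;
we resolve the overlap in favour of sensitivity (bands `[50, 100]` and
`[25, 50)`), one consistent half-open convention. Replicates with
`p_u ≤ 5 %` (rare populations) are scored by visibility instead, because the
ratio statistic inflates for small denominators: a visible digested positive
population means insensitive, an invisible one sensitive. "Visible" is
mechanized as ≥ 25 above-gate events whose median log10 intensity clears the
gate by ≥ 0.3 log10 units; both numbers are config keys
(`detect_min_events`, `detect_min_median_separation`) chosen to stay
permissive for rare populations.

**Inclusion criteria.** A clone needs ≥ 2 distinct donors
(`min_donors`); activation-dependent markers need a CD69 activation control
of ≥ 20 % (`cd69_min_pct` — the source criterion is visual, so the cut-off
is exposed and flagged to users); zero undigested positivity excludes the
replicate. Same-day repeats of one clone/marker/donor are averaged
(arithmetic mean of percentages, logical OR of detectability) before
classification.

**Clone rule.** A category with a strict majority (> 50 %) of included
replicates wins. Any majority-free split — including the published 50/50
full/partial and partial/insensitive ties and the uncovered
full/insensitive tie — is called partially sensitive. This is the only
extension of the stated tie rule consistent with the bundled per-clone
table's totals (12 sensitive clones, 8 of them TotalSeq-C), and it is
verified exhaustively against a brute-force restatement over all category
multisets of size ≤ 6.

**Percent-positive vs MFI.** The percent-positive definition of RC is
normative. An MFI-based variant (same formula on mean channel intensity of
the parent population) is available behind `SensitivityConfig(use_mfi=True)`
for users who prefer the intensity readout.

## Gating

Gates are always learned on a control sample and applied unchanged to the
paired test sample. The default engine (`kde_valley`) places the threshold
at the deepest minimum of a Gaussian-kernel density estimate of the
log10-intensities, between the two highest modes. Details:

* Bandwidth: Silverman's rule of thumb robustified with the IQR,
  `0.9·min(sd, IQR/1.34)·n^(−1/5)`.
* Evaluation: binned FFT convolution on a 512-point grid over the data
  range (statsmodels `KDEUnivariate`, `fft=True`). This is numerically
  equivalent to direct kernel evaluation at grid resolution but costs
  O(n + g·log g), which keeps the 100-seed recovery studies fast; the unit
  suite cross-checks it against a direct-evaluation grid scan.
* Mode admission: modes must be ≥ 0.5 log10 units apart
  (`min_separation`) and reach ≥ 1 % of the main mode's density
  (`min_mode_height_frac`), low enough to admit few-percent positive
  populations while rejecting density wiggles.
* Fallback: without two admissible modes the gate falls back to the 99.5 %
  control quantile (`control_quantile`); the method actually used is
  recorded on the gate.
* Ties at the threshold count as negative ("strictly above" is positive),
  matching the quantile convention. Non-positive intensities are clamped to
  the smallest positive observed value before the log transform.

`percent_positive` is an exact count ratio; no smoothing or interpolation
enters the reported percentage.

## Titration selection

Each antibody is stained at 0.5×/1×/2× the recommended concentration. Per
point, `pct_signal_plus_noise` comes from the unstained-control quantile
gate and `pct_signal` from a KDE-valley gate fit on the stained sample
itself (sharing one threshold engine with the sensitivity pipeline); a
valley fallback means "no positive peak" and a signal of 0. "Does not lose
positive signal" is mechanized as signal ≥ 1 % absolute
(`min_signal_pct`, for dim markers) and within 10 % of the series maximum
(`signal_retention_delta`, for bright ones). Among eligible points the
lowest signal-plus-noise wins; ties go to the lower concentration
(minimizing antibody use and cost). The signal/(signal+noise) ratio is
reported as a diagnostic only. Selection depends only on the ordering of
concentrations, never their absolute values.

## ADT quality control

* **Cell filters.** Drop a cell when its mitochondrial UMI fraction exceeds
  the tissue ceiling (10 % for enzymatically digested islet tissue, 20 % for
  mechanically dissociated spleen), when it has < 200 detected genes, or
  when its total ADT count marks it as an antibody aggregate. The aggregate
  ceiling is the 99.9 % point of a robust log-normal fit to per-cell totals
  (median + 3.09·1.4826·MAD on log1p totals). A fitted rather than
  empirical quantile is used because aggregates sit in the extreme tail: an
  empirical quantile can flag at most 0.1 % of cells regardless of how many
  aggregates are present, while the robust fit is insensitive to the
  aggregates themselves. With near-constant totals (MAD = 0, e.g. tiny
  worked fixtures) the empirical quantile is used instead.
* **Background cut-offs.** Per antibody, the minimum cut-off is the
  KDE valley of the log1p-count distribution; counts below it are zeroed,
  counts at or above kept unchanged, and the threshold is always reported
  so users can override per antibody. Without a valley the column is
  treated as background-only and fully zeroed (fallback quantile 1.0, i.e.
  threshold max+1; lower fallback quantiles are config keys).
* **RNA/protein concordance.** Clusters are called RNA⁺ or ADT⁺ when their
  positive-cell fraction exceeds 0.25 (`pos_fraction_min`, invented and
  config-exposed — the corresponding published calls were made by visual
  inspection, so the published 15/37/10 tally is a structural check only,
  not a reproduction target). Equal non-empty sets → full overlap; disjoint
  sets → no overlap; otherwise partial. Antibodies without an RNA
  counterpart (e.g. isoform-specific ones) are not assessed. Cluster
  assignments are consumed as input; clustering itself is out of scope.

## Synthetic data generator

The generator emulates exactly the structure the rules assume:

* **Fluorescence.** Two log10-normal components (negative at mean 1.0,
  positive at 3.0, both sd 0.25 by default — an 8-sd separation typical of
  a well-resolved marker; positive fraction 0.3).
* **Digestion.** Each positive event loses its epitope entirely with
  probability `c` (cleavage fraction; resampled from the negative
  component) and otherwise keeps a fraction `r` of its intensity
  (`mfi_retention`). This is the smallest model producing both population
  loss and an MFI shift. With the gate fixed on the undigested sample and
  `r = 1`, digestion is binomial thinning, so E[RC] = 100·c; in general
  E[RC] = 100·(1 − (1 − c)·d(r)) with d(r) the fraction of retained
  positives still above a mid-separation gate.
* **Donors.** A shared additive log10 shift (sd 0.1) of both population
  means per donor — this leaves the ground-truth RC donor-invariant,
  matching the practice of pooling donors per clone. Cohort defaults
  (3 donors × 3 replicates, 2·10⁴ events/sample) sit inside the published
  design range of 2–4 donors and 2–18 replicates per clone.
* **Titration.** Positive median intensity follows saturation binding
  `conc/(conc + kd)` (log-shifted, floored at the negative mean);
  nonspecific background raises the negative component's location and
  scale linearly in concentration. The three stained samples share one set
  of base event draws (common random numbers), mirroring aliquots of one
  cell preparation — this is what makes the saturated-series selection
  deterministically favour the lowest concentration.
* **ADT counts.** Negative binomial with variance `μ + μ²/k`
  (dispersion k = 2), background mean 2 and signal mean 200 per antibody,
  30 % signal cells, and an optional planted fraction of aggregate cells
  with 20× inflated means across all antibodies.
* **Reproducibility.** One user seed is combined with a CRC32 hash of each
  sample's key into independent `SeedSequence` substreams, so outputs are
  byte-identical across reruns and independent of generation order.

Not emulated: spectral spillover/compensation, doublets, acquisition-time
drift, hierarchical pre-gating (parents arrive pre-gated, as metadata), and
any digestion effect on the negative population (held fixed — an assumption,
since the behaviour of unstained background under digestion is
uncharacterized). Passing recovery tests therefore demonstrate correctness
of the rules under these idealized conditions, not robustness to instrument
artifacts.

## Bundled reference tables

The per-clone digestion-sensitivity summary (20 clones over 8 markers, with
donor/replicate counts, integer category percentages and TotalSeq-C flags)
and the 63-antibody titration table (three tested concentrations and the
selected one, in µg per 100 µL per 10⁶ cells) ship as checksummed CSV
files. Loading validates row counts, percentage sums (100 ± 1), strictly
increasing concentrations and the TotalSeq-C flag set. Clone-level
classification of the summary table reconstructs per-replicate category
counts as `round(pct·n/100)` and applies the same majority/tie rule as raw
data. One titration row ("CD57 Recombinant") carries a typographical
artifact in its published chosen value; it is recorded as 0.025 and flagged
`transcription_uncertain`. Where a vendor recommendation is a range, only
the three tested values are stored; the range never enters the selection
rule.

Replicate-level aggregates of the original screen (median RC, IQR,
216-replicate category counts, the 75/92 inclusion rate) cannot be
recomputed because the underlying per-replicate dataset is not published in
tabular form; those quantities are exercised on synthetic cohorts instead.

## Problem sizes and numerics

Stochastic checks use 2·10⁴ events per flow sample (percent-positive
sampling error ≈ 0.3 pp), 100 seeds for recovery rates, 5·10³ cells and 30
antibodies for ADT studies — sizes at which the expected effects exceed
sampling noise by an order of magnitude. Event tables round-trip through
CSV at 9 significant digits (well within the 10⁻⁶ relative round-trip
contract). Degenerate inputs are handled explicitly: empty samples error on
gating, constant columns fall back to quantile gates, all-zero ADT columns
warn and pass through with threshold 0.

## Known limitations

* The KDE-valley gate is an automated surrogate for manual gating; on
  marginal bimodality its threshold can differ from an expert's placement,
  which is why the method used (valley vs quantile fallback) is always
  recorded.
* The CD69 activation cut-off (20 %) and the concordance positivity
  cut-off (0.25) mechanize criteria the source protocol applied visually;
  both are config keys and results near these boundaries should be
  inspected.
* FCS ingestion is not built in; event tables arrive as CSV (an adapter can
  wrap the same reader contract without touching the pipeline).
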