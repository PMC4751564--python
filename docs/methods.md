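# Methods

## The measurement model

Every well holds a duplex qPCR reaction: a reporter probe (FAM channel,
ribosome-biogenesis reporter *NSR1*) and a housekeeping probe (JOE channel,
*PEX6* in the primary screen, *NTF2* in the confirmation pass). We assume
perfect amplification efficiency, so Ct falls by one cycle per doubling of
transcript and everything lives on a log2 scale. The per-well statistic is
the F–J value (reporter Ct minus housekeeping Ct); after centering and a
sign flip it becomes a log2 reporter/housekeeping expression ratio in which
higher values mean more reporter transcript.

Wells whose amplification crossed the fluorescence threshold only after 28
cycles on either channel, or never crossed it, are discarded before
analysis. The boundary is strict: Ct exactly 28.0 is retained. Instrument
dRn thresholding is abstracted into channel presence/absence. When one
channel of a well fails, only that well is dropped (the strain's other
condition measurements survive); dropped strains are listed per screen in
the filter report.

## Plate normalization

Separate qPCR runs shift the reporter channel by 0.3–0.6 cycles, which
survives into F–J. On a library plate, most strains repress the reporter
normally and form a majority population; repression-defective strains form
a low-F–J minority. We fit a two-component 1-D Gaussian mixture by EM
(implemented in this package):

* **Initialization** is deterministic: quantile pairs (25/75 and 5/95) plus
  ordered-split starts that partition the sorted data at seven candidate
  fractions, each with per-side means, SDs, and weights. Each start runs a
  short EM (20 iterations); the best by log-likelihood continues to
  convergence (log-likelihood gain < 1e-8 or 200 iterations). A `seed`
  parameter exists only for optional extra random restarts; default fits
  are seed-independent.
* **Variances** are free per component, floored at 1e-3 (log2 units²) to
  avoid singular components; clamping to the floor is the constrained
  M-step maximizer, so the log-likelihood stays monotone.
* **Degeneracy**: when the component means are closer than 0.5 log2 units,
  or the minority weight exceeds 0.4, there is no credible outlier
  population and the plate is centered on its 20%-trimmed mean instead.

For a non-degenerate fit, the "strains without an expression defect" are
the wells with posterior responsibility ≥ 0.5 for the higher-weight
component (ties broken toward the component with the higher mean F–J, since
defects lower F–J). We subtract the *arithmetic mean of those member wells*
— not the EM component mean — so the majority population is centered at
exactly zero by construction. All values are then multiplied by −1.
Normalization is per plate per condition and is invariant to any constant
added to one plate's reporter channel.

Re-arrayed plates (rescreen and subscreens) are mostly hits, violating the
majority assumption; they are centered on designated center-peak control
wells (strains whose primary value sat nearest the distribution mode),
requiring at least 4 control wells per plate.

## Error model and two-stage hit calling

Six library plates (~560 strains) are run through the pipeline twice. The
mean absolute replicate difference estimates the assay error; rounded to
one decimal (0.29 → 0.3) it becomes the SD of the null model N(0, 0.3) for
normalized log2 ratios. Both the mean |Δ| and the SD of Δ are reported; the
null model uses mean |Δ|. At the calling threshold of log2 = 1.0 this null
puts a strain above threshold by chance with probability ≈ 4.3×10⁻⁴
(Z ≈ 3.3). Strains measured on duplicate-run plates enter calling with the
arithmetic mean of their two normalized values (the variance-minimizing
combination).

Calling is strict (">") at every threshold: primary hits at 1.0, re-array
selection at 1.3, confirmation at 1.0 against the second housekeeping gene
on control-normalized re-array plates, subscreen selection at 1.4. The one
deliberate exception is the rapamycin (downstream-of-TORC1) call, which
uses "≥ 1.0"; both comparisons are configurable.

## Epistasis classification

Rapamycin inhibits TORC1 directly. A confirmed hit that still fails to
repress the reporter under rapamycin (control-normalized log2 ≥ 1.0) is
missing a gene downstream of TORC1; one that represses normally acts
upstream of, or parallel to, the TORC1 pathway. The mock subscreen flags
constitutive strains (mock log2 > 1.0): their reporter is deregulated
independent of condition, so they cannot inform TORC1 epistasis and the
constitutive label takes precedence over the rapamycin call. Confirmed hits
never assayed in either subscreen (primary value between 1.0 and the 1.4
subscreen cutoff, or squeezed out by plate capacity) are emitted as
`unclassified`.

## Network connectivity test

Interaction edges carry one of three evidence classes (affinity,
interaction screen, other); the module ships a mapping table from BioGRID
experimental-system names. Duplicate pairs are merged keeping the strongest
class (affinity > interaction_screen > other); self-loops are dropped. The
test statistic is the number of unique unordered interaction pairs inside
the confirmed-hit set. Its null distribution comes from 10,000 uniform
same-sized gene sets drawn without replacement from the screened universe;
the empirical p-value uses the add-one convention (exceedances + 1) /
(permutations + 1), so the smallest reportable value at 10,000 draws is
1/10,001 ≈ 0.01%. Any reference node added for display (e.g. a merged
TORC1 node) is excluded from the observed count. Promiscuous hubs can be
pruned together with nodes whose every edge was to a hub; a node retaining
one non-hub edge always survives. Gene-set enrichment is a generic
upper-tail hypergeometric test on user-supplied sets; no ontology database
is bundled.

## What the synthetic generator emulates

The generator is the test oracle for every stage. Its defaults encode the
study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_strains` | 4709 | library size, 96-well plates, partial plates padded with wild-type filler wells |
| `hit_fraction` | 0.10 | repression-defective strains |
| `hit_effect_range` | [1.0, 4.5] log2 | defect sizes, uniform (the observed outlier range) |
| `well_noise_sd` | 0.26 log2 | technical SD of the F–J difference; each channel gets an independent N(0, 0.26/√2) draw |
| `null_bio_sd` | 0.20 log2 | persistent strain-level spread, shared across replicates and conditions |
| `plate_offset_range` | [0.3, 0.6] | per-plate offset on both channels (cancels in F–J) *plus* a reporter-only run offset of the same magnitude (does not cancel; normalization must remove it), random signs |
| `dropout_rate` | 0.04 | wells emitted with a late (>28) Ct on one channel |
| `mock_shift` | 2.3 log2 | de-repression of the reporter without stress |
| `downstream_fraction_of_hits` | 53/332 | hits failing rapamycin repression |
| `constitutive_fraction_of_hits` | 5/332 | hits deregulated in every condition |

The split of the observed null width (≈0.33 combined) into 0.26 technical
and 0.20 biological is an assumption: the source statistics constrain only
the replicate difference (technical only, mean |Δ| = 0.26·√2·√(2/π) ≈ 0.29)
and the total spread. This split reproduces both the replicate Pearson
r ≈ 0.90–0.94 and the mean |Δ| ≈ 0.29 by construction.

Condition truth: in stress (KCl) a null strain sits at 0 and a hit at its
effect size; in mock every strain is de-repressed at `mock_shift`, with
constitutive strains elevated *above* that baseline by their effect (a
strain whose reporter is condition-independently high must exceed the
de-repressed controls, otherwise it could never be flagged); in rapamycin,
upstream hits repress fully (level 0) while downstream and constitutive
hits stay at their effect. The strain's biological deviation is added to
all three levels.

The graph generator samples background edges uniformly over unordered gene
pairs and plants extra distinct edges inside a chosen set; with the default
calibration (56,500 background edges over 4709 genes, 440-gene set, 584
extras) a random 440-set induces ~492 edges and the planted set ~1076.

**What the generator does not emulate** — and hence what passing tests do
not show about real screens: the synthetic null is exactly Gaussian, so
almost no false positive survives the 1.3 selection cutoff and the
confirmation rate among selected strains comes out ≈95–97%, higher than
the ~85% seen with real, heavier-tailed plate data. There are no
plate-position (edge/row) artifacts, no growth-rate coupling between
dropout and phenotype, no housekeeping-gene expression changes, and the
interaction graph has uniform background topology rather than the hubby,
modular structure of real protein-interaction data (so component-size
statistics are exercised for correctness, not realism).

## Problem sizes used in the test suite

Library-scale checks run at the full 4709-strain default. Repeated-screen
calibrations use 960-strain screens: 200 null-only screens for the
false-positive rate (pooled against the analytic tail of the combined null
SD, within 3 binomial SDs), 25 default screens for sensitivity (≥90%
detection of effects ≥ 1.5, ≤1% null calls). The permutation null-mean
check uses a 1000-node, 2000-edge uniform graph with 100-gene sets at 5000
draws (Monte-Carlo SE ≈ 1/5 of the 2% tolerance band); p-value calibration
uses 100 repeats of 200 draws. These sizes are the package's chosen
trade-off between statistical resolution and a fast default test run.

## Known limitations

* Only two-component mixtures; plates with three expression populations
  fall back to trimmed-mean centering via the degeneracy rule.
* No multi-plate joint normalization and no FDR machinery — the design is
  a fixed Z-derived cutoff with wet-lab-style confirmation.
* The permutation universe is the screened gene set; using a larger
  library universe would change the null mean.
* Evidence-line counts are reported alongside unique-pair counts, but the
  pair count is the primary statistic.
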