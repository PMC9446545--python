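# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED convention); bedGraph shares it.
"Overlap by at least 1 bp" therefore means `min(ends) − max(starts) ≥ 1`,
and abutting intervals do not overlap. Strand is carried through I/O but
ignored by every overlap operator; only promoter-window construction is
strand-aware. Site identity across pipeline stages is the exact
`(chrom, start, end)` triple of the ZCWPW1 peak.

## Peak caller

The caller is a transparent windowed Poisson test rather than a wrapper
around an external caller, so that every statistical choice is visible
and testable. For each window of `window` bp (default 200, step 50) the
fragment count `k` is tested against `P(X ≥ k | λ)`:

* **genome λ** — mean per-bp coverage × window (ZCWPW1/H3K9ac/CUT&Tag
  configurations);
* **local λ** — mean count expected from the ±10 kb flank around the
  window, with the window itself excluded and the estimate floored at
  the genome λ (ATAC configuration). Excluding the window keeps a
  genuine enrichment from inflating its own background estimate.

When a q-threshold is configured, Benjamini–Hochberg runs over all
scanned windows of the track; a p-threshold uses raw p-values.
Significant windows with gaps ≤ `merge_gap` (default 100 bp) merge into
peaks. Each peak's fold enrichment is the maximum of count/λ over its
windows (a summit-based definition; region-mean FE would be smaller and
less stable for narrow planted sites), and a peak survives only when FE
*strictly* exceeds the per-assay threshold ("greater than" read as
strict): 3 for ZCWPW1, 10 for CUT&Tag, 4 for ATAC, none for H3K9ac.

Fold-change signal tracks are `treatment / (control + pseudocount)` per
bp, with the control either a scalar per-bp λ or a control track. The
default pseudocount is 0 — the usual control is a strictly positive
scalar background rate, and a zero pseudocount keeps the identity
`treatment == control → 1.0` exact; a zero-valued control track with a
non-positive pseudocount raises immediately.

## Binned matrices

`compute_matrix` reproduces reference-point binning: peak center is
`floor((start+end)/2)` (midpoint rather than a caller-specific summit,
so any BED input works), window center ± 2 kb, 40-bp bins → 100 bins,
bin value = mean per-bp signal. Bins partially outside a chromosome
average only the covered bases; fully outside bins are 0; bedGraph gaps
read as 0. Heatmap ordering is descending by a per-site statistic —
the mean over all samples of per-sample row means, or the median of one
named sample — with ties broken by genomic position. "Average signal in
all samples" is defined as the mean of per-sample row means (averaging
matrices first would give the same ranking only for equal bin counts;
the row-mean form is well-defined for any aligned panel).

## Classification rules

* **marked**: ZCWPW1 peak overlaps a WT H3K9ac peak by ≥ 1 bp.
* **open**: ZCWPW1 peak overlaps ≥ 20 % *of an ATAC peak* — the
  fraction is measured on the ATAC peak's length (the quoted object),
  inclusive ≥; a config switch measures it on the ZCWPW1 peak instead.
  A site qualifies if any single partner clears the thresholds; overlaps
  are never summed across partners.
* **A1 / A2**: among open sites, accessibility is lost (A1) when
  `mean WT signal / (mean KO signal + 0.01) ≥ 2` over the site interval,
  inclusive at exactly 2-fold; otherwise retained (A2).
* **H1 / H2**: the accessibility axis has the fully explicit loss rule
  above; for H3K9ac we apply the analogous composite rule — a marked site
  *retains* the mark (H2) only if it still overlaps a knockout H3K9ac
  peak by ≥ 1 bp **and** its WT/KO signal ratio is < 2; failing either
  criterion is loss (H1). Both criteria can be toggled independently
  (`require_ko_peak`, `require_ratio`) since the composite form is an
  interpretation.
* **promoter**: overlap ≥ 1 bp with a strand-aware window
  `[TSS − 2000, TSS + 500)` (mirrored on '−'); both extents are
  configurable, as "promoter region" has no single standard width.
* **percentages** are always recomputed from integer counts with
  half-up rounding at the printed precision (integers for group
  fractions, one decimal for promoter fractions); raw counts are always
  reported alongside.

## Synthetic study

The generator emulates the genotype structure of the knockout
comparison at desk scale: 3 chromosomes × 2 Mb, 300 planted
non-overlapping sites (274 hotspot-class, 26 promoter-class), 600 bp
wide, ≥ 5 kb apart so that ±2 kb matrix windows and called peaks never
collide. Coverage is Poisson noise drawn per 10-bp bin and expanded to
per-bp rates (window sums then behave as true Poisson counts with per-bp
mean `background_rate`, default 0.1 fragments/bp → window λ = 20).

Enrichment at planted sites (fold over background): ZCWPW1 12 at
hotspots and 6 at promoter-class sites, H3K9ac 8, ATAC 8, DMC1 10.
Genotype effects: *Zcwpw1*⁻/⁻ removes ZCWPW1 enrichment everywhere and
multiplies the H3K9ac/ATAC enrichment of designated losing sites by 0.2
(promoter-class sites keep multiplier 1 in every genotype); *Prdm9*⁻/⁻
removes all hotspot-class enrichment; *Spo11*⁻/⁻ equals WT with DMC1
absent. Magnitudes are configurable; the defaults were chosen once as
realistic ChIP enrichment levels that the published thresholds (FE > 3,
FE > 4) separate cleanly from background.

The configured group fractions are the study conditions themselves:
45 % of sites marked, 27.3 % open, 74 % of marked sites losing H3K9ac,
67 % of open sites losing accessibility, 84 % of accessibility-losing
sites also losing H3K9ac. Because promoter-class sites are always
marked, open and retaining, these fractions are interpreted over the
*marked*/*open* site sets (their printed denominators) and converted
into exact integer per-class counts (at the defaults: 46 joint-loss, 54
H1-only, 9 hotspot H2, 9 A1-only unmarked, 156 ZCWPW1-only hotspot
sites, 26 promoter sites); infeasible combinations raise. End-to-end
group fractions deviate from the configured values only through peak
calling, not through label sampling.

Randomness: one root seed; every track, the site placement, the TSS
assignment and the RIME table draw from fixed-key child streams of that
seed, so requesting an extra assay never perturbs the draws of another.
Each promoter-class site carries a TSS at its center; decoy TSS are
placed ≥ 5 kb from all sites.

The RIME generator plants `n_true_interactors` (default 177, the union
size of the emulated three-replicate experiment) proteins that pass all
filter criteria in ≥ 1 replicate and never appear in IgG, plus
background proteins that fail the score or spectral-count criterion or
contaminate a batch-matched IgG control.

What the simulator does *not* emulate: read-level artifacts (mappability,
duplicates, GC bias), sequence-composition effects, replicate-to-
replicate biological variance beyond Poisson counting noise, overlapping
or nested peaks, and chromosome-scale covariates. Passing tests
therefore demonstrate that the rules and the caller recover planted
structure under Poisson noise — not that the thresholds are optimal for
real libraries.

## Problem sizes

The default simulated study is 6 Mb with 300 sites; the caller scans
~120 k windows per track; calibration checks use 20 seeded 2-Mb null or
planted genomes. These sizes give stable fractions (group percentages
reproduce the configured values to the printed precision at any seed we
tried) while a full pipeline run stays near ten seconds.

## Known limitations

* The windowed caller is a statistical stand-in, not a re-implementation
  of any specific published caller; absolute peak boundaries are
  window-quantized (±50 bp).
* Fold enrichment uses the max-window definition; tools that report
  region-mean FE will disagree on wide peaks.
* The H1/H2 composite rule is an interpretation (see above); the
  per-criterion toggles exist precisely so either reading can be run.
* Percent reproduction of the printed group fractions by the simulator
  is by construction of the truth labels; what the pipeline adds — and
  what the end-to-end tests actually check — is that calling and
  rule-based classification recover those labels from noisy coverage.
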