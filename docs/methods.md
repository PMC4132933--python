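# Methods

This note documents the models, conventions and design choices behind
`elavscan`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and alphabets

All internal coordinates are 0-based, half-open, matching BED; 1-based
positions appear only in human-readable output. Sequences may be DNA or
RNA in either case; files are never rewritten with a substituted
alphabet. Matching is performed on an upper-cased, U→T-normalised copy,
so `AAUUUUUU` and `aattTTTT` are the same element. `N` never matches:
the criterion is an exact match, and an ambiguous base cannot certify
one.

## Motif scanning and site merging

The scanner reports **every** offset at which any motif of the set
matches exactly, including overlapping and nested occurrences (a run of
ten T's contains three occurrences of the eight-T element). Only the
sense strand is scanned: ELAV binds the transcript, so the reverse
complement of a motif is not a binding site.

Matches whose intervals overlap or are separated by at most `merge_gap`
nucleotides are merged into one EBS, numbered 1..K in 5′→3′ order. No
published rule defines the aggregation of tandem AU runs into discrete
sites, so the gap is a tunable with default **10 nt** — wide enough to
keep a tandem AU-run cluster together, narrow enough not to fuse
separate elements — and is exposed on the CLI. Merging conserves
coverage (the union of member intervals equals the union of site
intervals) and the site count is non-increasing in the gap.

Site-directed mutations are modelled as literal string replacement of a
unique wild-type core (e.g. `ATTTTTT → AGTGTGT`); zero or multiple
occurrences of the core are an error rather than a guess.

## Ultraconservation

A reference site is projected to the minimal alignment-column span whose
ungapped reference content equals the site sequence. A species
*supports* the site when its own ungapped row contains an exact match of
**any** motif in the set whose projected column span lies within the
reference span widened by `W` columns on each side. Two points are
deliberate:

* *Containment, not mere overlap.* The homologous-position tolerance is
  defined as the widened window containing the supporting match. With a
  mere-overlap rule a motif shifted by almost its own length would still
  count at W=0, which defeats the point of a positional tolerance;
  containment makes W interpretable as "how far the element may have
  drifted". Default **W = 10** columns, exposed as a flag. Support is
  monotone non-decreasing in W under either rule.
* *Any motif of the set.* The conservation criterion is "an exact
  match", not "the same motif": a TTGTTTTTTT in one species can support
  a TTTTTTTT site in another.

A site is ultraconserved when supported in at least `k` of the `n`
species in the panel; `k` defaults to **8** only when the panel has 12
species (the drosophilid panel), otherwise it must be given. The
classifier always reports the full support count and species set, so
stricter tiers (e.g. support including the most divergent clade) can be
derived downstream without re-running it.

Whole-locus multi-species alignment is out of scope and consumed as
aligned FASTA from external tools. The bundled Needleman–Wunsch aligner
(linear gap penalty; traceback ties broken deterministically diagonal >
up > left) and the star-MSA builder (pairwise alignments stacked against
one reference, reference gaps reconciled by column insertion) exist for
tests and small synthetic data sets, not as a production aligner.

## Focus detection

Nuclei are segmented from the counterstain channel by Gaussian smoothing
(default σ = 2), a global Otsu threshold, hole filling,
connected-component labelling (4-/6-connectivity) and a size filter
(default 50 voxels). A constant image yields an empty mask.

Foci are detected per nucleus: background is the median of in-nucleus
signal and the robust scale is 1.4826 × MAD (a consistent estimator of
the noise SD under normality); voxels above background + k·scale
(default **k = 4**) form candidate components (8-/26-connectivity), and
components of ≥ 3 voxels become foci with background-subtracted
integrated and peak intensity. Per-nucleus statistics withstand
nucleus-to-nucleus staining variation that a global threshold would not.
There is no upper bound on foci per nucleus; two-per-nucleus is a
biological expectation (one per allele), not a constraint. In a strictly
noise-free image the MAD is zero and the threshold degenerates to
"above background", in which case nearby spots may merge into one
component; total integrated intensity is conserved regardless.

Genotype summaries pool foci per genotype and report the mean foci per
nucleus and the mean integrated intensity per focus, each as a ratio to
a reference genotype (1.0 for the reference itself), plus log₁₀
intensity histograms (20 bins over the pooled observed range). No
parametric curve is fitted to the intensity distributions. Axial
profiles are per-position means with the standard error over
contributing voxels (or over samples when several profiles are
averaged).

## Statistics

* **Wilcoxon signed-rank**: zero differences dropped, average ranks for
  ties, W⁺ = sum of positive-difference ranks. The exact null is the
  distribution of W⁺ over all 2^m sign assignments, computed by
  shift-convolution over doubled ranks (identical to literal
  enumeration, polynomial cost); the exact path is used up to m = 25,
  above which a normal approximation with continuity and tie correction
  takes over (the threshold keeps the exact path well under a second).
  Two-sided p = min(1, 2·min(P≤, P≥)). Sidedness defaults to two-sided
  and is flag-controlled, since published legends rarely state it.
* **Chi-squared**: Pearson χ² with df = 1; Yates correction off by
  default (no published indication either way) and exposed as a flag.
  Zero margins are rejected (an expected count would be 0). Under a
  two-row Binomial null (n = 100, p = 0.3) the test rejects at the
  nominal 5 % within Monte-Carlo error.
* **Percentage↔count reconciliation**: published figures print
  percentages, not counts; the nearest integer count is recovered and
  the round trip is verified against the printed precision plus the
  half-count granularity 50/n. For the four published apoptosis
  percentages this reproduces counts 105/128, 8/86, 69/109 and 83/106.
* **Normalisation**: element-wise target/reference ratios; zero or
  negative reference replicates are an error.

## Synthetic data

Generators are pure functions of spec + seed (bit-identical reruns).

* **Ortholog panels**: a uniform-composition random ancestor, default
  1000 nt, with motifs planted at chosen positions; 12 species (named
  after the drosophilid panel, reference first) diverge independently —
  a star phylogeny, sufficient for testing the classifier's counting
  logic without committing to branch lengths the analysis never uses.
  Default per-site substitution probability 0.2 and indel probability
  0.01 per site (1–3 nt events) represent a diverged but alignable
  panel. Substitutions and indels never touch planted spans, and in
  non-retained species the planted core is replaced by a G/C scramble
  verified by scanning (with flanks) to create no motif match — so the
  ground-truth conservation table is exact. Every planted site must be
  retained in the reference, otherwise it would be undiscoverable on
  the reference row. The true alignment is emitted from the known
  substitution/indel history, not re-estimated. An AU-rich background
  option exists to stress false-positive behaviour of AU-rich motifs.
* **FISH stacks**: non-overlapping spherical nuclei (radius 10 px,
  level 150 over background 5) in a nuclear channel; per nucleus 0–2
  Gaussian foci (σ = 1 px, a diffraction-limited spot at typical
  sampling; amplitude 150 ± 15 over signal background 20) in the signal
  channel; Poisson shot noise then Gaussian read noise (SD 2). A
  two-focus pair is placed antipodally about the nucleus centre at
  0.3–0.4 radii, which keeps spots interior (their mass inside the
  segmented nucleus) and mutually resolvable by construction. Peak SNR
  at these defaults is far above 5.
* **Count tables**: per-hemisegment apoptosis outcomes are independent
  Bernoulli draws; the default genotype panel is the published design
  (128, 86, 109 and 106 hemisegments at the printed fractions). Isoform
  ratios are paired log-normal replicates parameterised by arithmetic
  mean and CV (cv = 0 reproduces the means exactly), with default
  n = 3 replicates matching the study design.

**What the synthetic tests do not show.** The generators emulate the
statistical structure each stage assumes, not real data: no true
phylogeny or rate heterogeneity, no alignment error (the true alignment
is given), no PSF/chromatic effects, no nucleus shape variation or
clustered apoptosis outcomes. Passing recovery tests therefore
demonstrates the correctness of the algorithms under their stated
assumptions, not robustness to the full messiness of genomes or
microscopes. In particular, reproducing the published 16-site catalogue
on the real *Ubx* locus requires the 12 genome sequences and an external
multiple aligner; the procedure is implemented here, but that catalogue
is not bundled.

## Problem sizes in the evaluation experiments

The recovery experiments use 200 ortholog panels of 500 nt × 12 species
(three planted sites each, retention sweeping 1..12), 10 image stacks of
256×256 px with 20 nuclei each (400 planted foci), 3 + 3 samples for the
genotype contrast, and 10,000 null tables for chi-squared calibration —
sizes at which every metric is stable across seeds while the whole suite
runs in seconds.

## Known limitations

* The site-merging gap and the homologous-position window are heuristics
  with no published counterpart; conclusions sensitive to either should
  be checked across a range of values (both are flags).
* Exact-match scanning has no mismatch tolerance by design; degenerate
  or probabilistic motif models are out of scope.
* The focus detector does not split touching spots by local maxima;
  at the default noise levels planted pairs are resolvable, but densely
  packed real foci closer than the threshold footprint would merge.
* `counts_from_percent` cannot detect a misprinted percentage that is
  consistent with some other integer count at the same n.
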