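# Methods

## Quantification model

Each biological sample is split into two half-samples before labelling: an
oxidized-enriched half (free thiols blocked with iodoacetamide, reversibly
oxidized thiols then reduced and tagged) and a total half (every thiol
tagged). Both halves occupy their own channel of a TMT 16-plex, and
quantification starts from reporter-ion signal-to-noise values exported per
peptide-spectrum match (PSM).

PSMs are rolled up to cysteine sites by **summing** S/N per (site, channel).
Summation, not averaging, is the conventional TMT roll-up: it preserves
linearity (duplicating every PSM doubles every site S/N and leaves the
ratio unchanged) and implicitly weights PSMs by signal. Peptides containing
more than one cysteine are excluded — the tag cannot be localised to a
single site — and counted in an exclusion report rather than dropped
silently.

The site statistic is `oxidation% = 100 · oxidized_SN / total_SN` per site
and sample. Absent channels (never-quantified, encoded as empty TSV cells)
propagate as absent, never as zero; a zero *total* also yields absent
(the ratio is undefined). Ratios above 100 % — possible under reporter
noise — are kept and flagged, because clamping would bias the downstream
t-test toward the null asymmetrically.

No channel normalisation is applied by default. The ratio is
within-sample, so per-channel loading effects largely cancel; an optional
per-channel median-centering switch exists for grossly unequal labelling
efficiency, defaults to off, and is recorded in the effective-config echo
of every run.

Sites are tested only when quantified in ≥ `min_reps` (default 2)
replicates of *each* group; 2 is the hard floor because the pooled-variance
t-test needs two observations per group.

## Differential calling

Per site, a two-tailed Student's t-test with pooled variance on
`n1 + n2 − 2` degrees of freedom compares depleted vs control oxidation
percentages (untransformed). Degenerate zero-variance inputs are resolved
deterministically: equal means → P = 1, different means → P = 0. The
relative increase is Δ/mean_control, defined as +∞ when the control mean is
0 and the depleted mean positive, and 0 when both are 0.

A site is **called** when P < alpha (0.05) AND relative increase ≥ rel_min
(0.25) AND the site lies in the top set — the `ceil(top_frac · N)` largest
absolute increases among **all** tested sites (top_frac = 0.15), not only
the P-significant ones. Ties at the top-set boundary break by site id
(lexicographic ascending) so calls are identical across platforms. Raw P
values gate the calls deliberately — the composite rule is a raw-P rule;
a Benjamini–Hochberg FDR column is emitted for reference but never gates.
Decreased-oxidation sites are visible in the table (negative Δ) but there
is no composite criterion for decreases.

Proteins are ranked by called-site count (descending, ties by accession
ascending, ranks 1..N over proteins with ≥ 1 call). Called sites are mapped
onto domain annotations as 1-based closed intervals; overlapping intervals
are rejected at load, a site on an interval end is inside, and uncovered
sites report "unannotated".

## Motif statistics

Foreground flanks are ±6-residue windows around called cysteines (cysteine
fixed at position 0, excluded from testing), padded with 'X' past protein
termini; 'X' cells are excluded from both counts and denominators, so each
position has its own effective n. The background is, by default, the flanks
of **all detected (tested) sites** in the same experiment — self-contained
and controlling for acquisition bias; a whole-proteome background (every
cysteine in the FASTA) is available via a flag.

Each (position, residue) cell is scored with the exact binomial tail,
computed by explicit summation of probability-mass terms in log space (no
normal approximation — foreground sets number in the dozens to hundreds, so
exactness costs nothing): −log10 P[X ≥ k] for overrepresentation (ties
k/n = p0 count as over, keeping the direction rule deterministic), signed
+log10 P[X ≤ k] for underrepresentation. A residue present in the
foreground but with background frequency exactly 0 scores +∞ (infinite
enrichment); finite scores are guaranteed whenever 0 < p0 < 1.

Significance is Bonferroni over the full R·W = 20 residues × 2w positions
family: threshold = −log10(alpha / (R·W)). At the default ±6 window and
alpha = 0.05 this is −log10(0.05/240) = 3.6812, displayed as 3.68 — the
familiar probability-logo red line; that the printed 3.68 arises uniquely
from the 240-test family is why this family was adopted. The foreground
position weight matrix (per-position residue frequencies, 'X' mass
excluded, columns summing to 1) is emitted alongside the score matrix. No
logo image is rendered; the TSVs carry the full information.

## Synthetic experiments

The generator emulates the paired half-sample design: for site *i* with
true oxidation fraction *f* and abundance *A_i*, the oxidized channel has
expected S/N `f·A_i` and the total channel `A_i`, with independent
multiplicative log-normal noise of coefficient of variation `noise_cv`
(mean-one parameterisation, so expectations are exact and `noise_cv = 0`
gives the identity `oxidation% = 100·f` to machine precision — the lever
behind the exact-recovery tests).

Defaults are the study conditions the analysis targets: 7 replicates per
group (2 × 7 × 2 fractions = 28 channels, split over two 16-plexes with
both halves of a sample always co-plexed); 10,000 sites; baseline fractions
`f0 ~ Beta(2, 18)` (mean 10 %, right-skewed — most cysteines mostly
reduced); 1.8 % of sites planted with an additive effect `delta = 0.15` on
the fraction scale (clamped at 0.99), additive so the *relative* increase
stays site-dependent; 10 planted sites concentrated on one hotspot protein
and the remainder spread at ≤ 2 per background protein, so the hotspot
ranking has a known answer; site abundances log-normal around a median S/N
of 100 with log-sd 0.8, spanning roughly the two decades of S/N a reporter
ion experiment covers.

Proteins are assembled from 15-residue single-cysteine blocks (Cys centred,
a lysine at the block end for a tryptic look), giving ≥ 15-residue spacing
between sites so every site yields a single-Cys peptide and the multi-Cys
exclusion rule cannot silently remove simulated sites. Flank residues are
drawn i.i.d. uniform over the **19 non-cysteine** residues (background
frequency 1/19 ≈ 0.053 per residue, analytically known) — uniform over all
20 would plant stray cysteines inside the peptides and break the exclusion
accounting. Planted sites carry K or R at positions −5 and −6 with
probability `motif_bias` (default 0.8), the signal the motif stage must
recover.

The null generator is the identical process with `delta = 0` everywhere
and an empty planted set; it backs the type-I-error calibration.

What the generator does **not** emulate: missed cleavages, co-isolation
interference, plex batch effects or bridge-channel normalisation,
missing-value mechanisms beyond "absent channel", isotopic impurity, or
any correlation between abundance and oxidation. Passing tests therefore
demonstrate correctness of the statistical chain under its stated
assumptions, not robustness to every artefact of real LC-MS data.

## Numerical and scale choices

All tables serialise floats at 12 significant digits, enough for exact
round-trips at double precision in practice; runs are byte-deterministic
given config + seed (single RNG stream, stable sorts, fixed tie-breaks).
Tests and the worked analysis run at 2,000 sites rather than the 10,000
default — every statistic involved (type-I rate, recovery, motif counts)
is already stable at that size, and the full default remains one config
line away.

## Known limitations

- The pooled-variance t-test assumes equal group variances; no
  moderated-variance (empirical-Bayes) alternative is offered.
- Raw-P composite calling controls no formal error rate across sites; the
  BH column is advisory.
- The detected-sites motif background inherits any compositional bias of
  the detected set itself; the proteome background flag trades that for
  acquisition bias.
- Site occupancies are analysed on the percentage scale, untransformed;
  strongly heteroscedastic occupancy data near 0 or 100 % may violate the
  t-test's assumptions.
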