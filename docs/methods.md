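# Methods

## Model and procedure

The analysis treats disorder prediction as two binary per-residue
classifiers applied to a set of experimentally annotated disordered
residues:

* pLDDT (AlphaFold model confidence, normalized to [0, 1] by dividing the
  B-factor-encoded 0–100 value by 100): a residue is called disordered when
  its score is **strictly below** the cutoff *c*ₚ (default 0.7).
* IUPred-style disorder propensity in [0, 1]: disordered when **strictly
  above** the cutoff *c*ᵢ (default 0.425).

Strict inequalities mean residues exactly at a cutoff are called ordered.
The joint call defines quadrants Q1 (order/order), Q2 (pLDDT order, IUPred
disorder), Q3 (pLDDT disorder, IUPred order) and Q4 (disorder/disorder).
Because the input set is annotated disordered, Q4 is agreement with the
experiment and Q1 joint contradiction.

**Matched-rate calibration.** *c*ᵢ is chosen so that IUPred's overall
disordered fraction matches pLDDT's at *c*ₚ.  Candidates are the observed
score values plus 0 (data-driven and deterministic, no arbitrary grid); the
calibrated cutoff is the smallest candidate whose strictly-above fraction
does not exceed the target, and the achieved fraction is reported with it.
With ties in the scores the achieved fraction can undershoot the target;
reporting it makes that visible.

**Region handling.** Annotation coordinates are 1-based inclusive.  Entries
sharing at least one position on a protein are merged into union intervals
carrying the union of all member term sets and source ids; adjacent
intervals are *not* merged (merging is defined by overlap, not contiguity).
Residue-level statistics use the merged set; term-level statistics use the
pre-merge entries, since merging concatenates unrelated term sets.  Regions
are split at 30 residues into long and short after merging — merging first
means a chain of short overlapping entries that unions into a long interval
is treated as one long region, which matches the residue-level use of the
merged set.

**Percentages.** Printed quadrant percentages are integers from
largest-remainder (Hamilton) apportionment of 100·count/total, so the four
columns always sum to exactly 100 and each differs from the exact
proportion by less than one point.  Remainder ties break by larger count,
then label order, for determinism.

**Term enrichment.** For each ontology namespace (ECO evidence, IDPO
structural/transition, GO function) the overall term distribution counts
regions per term (a region with k terms counts once for each); terms with
fewer than 10 occurrences are dropped.  Per-quadrant enrichment is the
ratio of the within-quadrant fraction to the overall fraction (log2 also
emitted; a term absent from a quadrant reports ratio 0 and log2 −∞).  The
minimum-occurrence filter applies to overall counts only, so retained terms
appear in every quadrant's table.  No hypothesis test or multiple-testing
correction is attached: the published comparison is graphical, so the
package emits counts and ratios and leaves inference to the user.  Evidence
terms are counted per (region, term) pair — a region carrying two ECO ids
contributes to both — because the annotation format does not expose
per-evidence attachments.  Region-level quadrants (from mean scores) feed
the term analyses; residue-level quadrants feed the secondary-structure
analysis, since secondary structure is a per-residue property.

**Secondary structure.** DSSP 8-state codes condense to 3 states by the
common convention H/G/I → helix, E/B → sheet, everything else (T, S,
blank/unassigned, and DSSP-4's polyproline-II "P") → coil.  PPII is an
extended conformation without the hydrogen bonding of regular secondary
structure, hence coil.  Residues are pooled per quadrant rather than
averaged per region; pooling weights long regions more but avoids giving
 noisy short regions equal influence.

**Conservation depth.** Ortholog rows in a region-restricted alignment are
tagged Vertebrata, Eumetazoa (accepting "Metazoa" as an alias — both name
the same intermediate tier) or Unicellular.  A row *aligns* to the region
when at least `min_coverage` (default 50%) of the region's alignment
columns are non-gap in that row; presence in the file alone is not enough.
The region's level is the deepest tier with at least `min_orthologs`
(default 3) aligning rows; if none qualifies the region is reported
"unclassified" rather than silently assigned.  The 50% coverage rule is a
design choice: a definition tied to mere presence would let a single
aligned residue count as conservation, and all-gap rows obviously should
not count.  The parameter is exposed and recorded in output metadata.

**Proteome fractions.** For whole proteomes the disordered fraction per
predictor is residue-pooled (disordered residues / total residues), not a
per-protein average; division rollups (Eukaryota/Bacteria/Archaea) are
residue-weighted, with unweighted per-proteome means emitted alongside for
transparency.

**Redundancy filtering.** CD-HIT `.clstr` output is consumed when provided
(keep the starred representatives).  Without it, a naive greedy fallback
runs: longest-first, dropping any sequence whose left-aligned ungapped
identity to a kept sequence (matches / shorter length) exceeds the
threshold (default 40%).  This is deliberately not CD-HIT's word-filter
algorithm — it exists so the pipeline runs end-to-end on synthetic data.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `plddt_cutoff` | 0.7 | score in [0,1] | conventional confidence boundary for disorder from model confidence |
| `iupred_cutoff` | 0.425 | score in [0,1] | matched-rate value; recalibrated per dataset unless `--no-calibrate` |
| `min_long` | 30 | residues | conventional boundary between short segments and long disordered regions |
| `min_term_count` | 10 | occurrences | rarer terms give noise-dominated quadrant breakdowns |
| `min_orthologs` | 3 | sequences | minimum evidence for conservation at a tier |
| `min_coverage` | 0.5 | fraction of region columns | definition of "aligns to the region" |
| `bins` | 50 | per axis | density-grid resolution over [0,1]² |
| `redundancy_identity` | 0.40 | fraction | sequence-identity threshold of the redundancy filter |

## Synthetic-data generator

Proteins are concatenations of 3–8 segments drawn from a grammar of five
classes (defaults: ordered 45%, concordant disorder 30%, helix-in-disorder
9%, disorder-to-order 8%, low-IUPred linker 8%).  Per class, both scores
are i.i.d. Beta with mean/concentration parameterization (a = μ·κ,
b = (1−μ)·κ, κ = 60); means are chosen well-separated from the default
cutoffs so each annotated class lands in one planted quadrant (concordant →
Q4, helix-in-disorder → Q2, disorder-to-order → Q1, linker → Q3).  Scores
are quantized to 4 decimals at generation so written fixtures round-trip
losslessly.  Annotated segments carry the disorder structural-state term
plus class-conditional evidence/transition/function terms (e.g. X-ray
evidence and the disorder-to-order term concentrate in the Q1-planted
class, the flexible-linker term in the Q3-planted class).  Secondary
structure is a uniform run per segment ("H" for confident classes, "-" for
coil classes).  Each annotated region gets a region-restricted MSA whose
per-tier ortholog depths plant a conservation level (3–7 rows at the
planted tier and shallower, 0–2 deeper; 15% gaps, 30% substitutions);
planted levels default to 94.5% Vertebrata / 4% Eumetazoa / 1.5%
Unicellular, reflecting how rarely disordered regions trace to deep
ancestry.  10% of regions are emitted as two overlapping entries to
exercise merging.

What the generator does **not** emulate: real amino-acid composition biases
of disordered regions (sequences are uniform over the 20-letter alphabet),
within-segment score autocorrelation (real tracks are smoothed), partial or
erroneous annotations, and correlated errors between the two predictors.
Passing tests therefore demonstrate that the pipeline's bookkeeping —
parsing, coordinate arithmetic, calibration, classification, tallies — is
correct under known ground truth, not that the predictors behave this way
on real proteins.

## Numerical and degenerate-input choices

* At-cutoff scores are ordered (strict inequalities) everywhere, including
  proteome pooling.
* Calibration on an empty score set, a region outside its track, ragged
  alignments, zero or multiple MSA reference rows, non-consecutive
  score-file positions and unknown DSSP codes are hard errors naming the
  offending record; unknown term namespaces and unknown-term subsets warn
  and degrade.
* Density grids bin [lo, hi) except the last bin, which is closed so 1.0 is
  counted.
* Empty quadrant tables report zero counts and no percentages; quadrants
  without residues are omitted from secondary-structure fractions but keep
  zero counts.
* The DisProt reader keeps every region by default and exposes
  `require_disordered_state=True` to restrict to regions carrying a
  disordered structural-state term (the pipeline default), since annotation
  files may also carry purely functional entries.

## Problem sizes

The test suite and the acceptance script run on generated datasets of
roughly 10³–10⁴ annotated residues (80 proteins for the end-to-end
recovery run, ~250 annotated regions with MSAs), which gives binomial
sampling error well inside the 2-percentage-point recovery tolerance while
keeping the whole suite in seconds.

## Known limitations

* The greedy redundancy fallback is not CD-HIT and can keep near-duplicates
  that differ by an indel (identity is computed without alignment).
* Conservation tags must be provided in the MSA headers; no taxonomy lookup
  is performed.
* GO terms are matched by exact id; no ontology-graph ancestor propagation.
* The DSSP reader consumes only the assignment column; accessibility,
  angles and H-bond fields are ignored.
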