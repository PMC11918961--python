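# Methods

## Scope and model of the problem

The package works entirely in **transcript space**: one coding transcript is
an ordered list of exons and introns (1-indexed) with lengths and optional
sequences, a CDS starting at c.1 (HGVS convention) and ending at the last
base of the stop codon. Genomic strand, liftover and multi-transcript gene
models are deliberately out of scope — every quantity the pipeline computes
(variant localization, splicing consequences, classification) is defined on
the mRNA.

Noncanonical splice variants are handled through three largely independent
evidence channels that the pipeline keeps separate until classification:

* **computational** — thresholded outputs of five external predictors;
* **observational** — aberrant transcript species seen in a minigene or
  patient-RNA assay, plus a qPCR estimate of the residual correctly spliced
  fraction;
* **population** — gnomAD-style genotype counts.

## HGVS c. grammar

The parser covers the grammar subset that splice-variant tables actually
use: substitutions (`c.2349A>G`, `c.613-11G>A`, `c.2090+3A>T`), range
deletions (`c.2996_2998del`) and delins (`c.1669-2_1669-1delinsTT`), with
an optional `/p.(=)` synonymous suffix. Intron offsets are signed distances
from the nearest exon boundary; an offset of ±1/±2 defines a canonical
site. 5′UTR (`c.-N`) and 3′UTR (`c.*N`) positions are rejected rather than
partially supported: no such variant occurs in the problem domain the
package serves, and silent coercion would corrupt coordinates. Parsing and
formatting are exact inverses on this subset, and the normalized
parse→format string is the join key across all tables.

Intronic anchors are validated to sit on the correct exon boundary (a `+`
offset must hang off an exon 3′ end, a `−` offset off an exon 5′ start);
violations raise instead of guessing an adjacent intron.

## Consequence engine

An observed aberration is an event, not a mechanism: `intron_retention` /
`partial_intron_retention` (first *k* intronic bases for a donor-side
event, last *k* for an acceptor-side one, inserted at the junction),
`exon_internal_deletion` (truncation from the stated end, the observable
signature of cryptic-site activation) and `exon_skipping`. No de novo
splice-site scoring is attempted — the inputs are gel/sequencing
observations.

Frame preservation is exactly `size_nt % 3 == 0`. Protein consequences are
obtained by editing the spliced sequence and translating from the original
start:

* **frameshift** — `fs*N`, where the first changed residue is position 1
  and N is the stop position in the shifted frame;
* **premature stop** — the first altered codon is itself a stop (`p.(X123*)`);
* **in-frame insertion / deletion** — the changed residue run,
  right-normalized per the HGVS 3′ rule (the most 3′ placement is named);
* **in-frame delins** — in-frame edits that are not a clean run change,
  including in-frame retentions whose junction is not codon-aligned (the
  inserted peptide then replaces a junction residue);
* **start loss** and **stop-loss extension** are labeled distinctly rather
  than folded into frameshift, so no wrong `fs*N` is ever emitted; a
  frameshift that reaches the end of the transcript without a stop is
  reported as an extension with an unknown stop, not an exception.

Degenerate inputs: an edit entirely 3′ of the stop codon is `no_change`; an
empty edit is `no_change`; events larger than their region are rejected; a
retention event on a length-only model raises a "sequence required" error
rather than substituting Ns.

Exact protein names for the real MYO5B variants require the real reference
sequence, which the packaged length-only model deliberately does not carry
(see below); the engine is therefore validated property-wise against an
independent oracle (next section) plus worked examples engineered on toy
genes to match the published patterns (the 9-nt Ser-Val-Gln retention).

## Independent oracle

`splicedx.simulate.oracle_consequence` recomputes every consequence by a
different route: direct slicing of the raw exon/intron strings, translation
with a local codon table (no Biopython), and peptide comparison. The test
suite requires engine/oracle agreement on ≥1000 random events across random
toy genes, including `fs*N` equality on every frameshift. The oracle is
intentionally naive — clarity over speed — and never used outside tests.

## Synthetic data generator

The generator emulates the *statistical shape* of the study, and its
defaults are those conditions: 11 variants per cohort, a true
splice-aberration rate of 8/11, 3/8 of true positives giving complete
aberrations, residual normal-splicing fractions uniform on 10–35 % with
additive Gaussian measurement noise (sd 0.02, clipped; the category is
assigned from the noisy value, mimicking qPCR variability), and per-tool
(sensitivity, specificity) profiles at the operating points observed on the
11-variant table. Toy transcripts are built codon-aware (ATG + uniform
sense codons + one stop, split across exons; introns are uniform random
with GT…AG ends), which satisfies the ORF invariants by construction.

Scores conditional on a planted call are sampled uniformly on the
call-consistent side of each decision threshold with a 0.02 guard band, so
round-tripping a synthetic table through the thresholding stage recovers
every planted call exactly — a property the tests assert. What the
generator does **not** emulate: realistic splice-site motifs, genuine
predictor score distributions, linkage between tools' errors, or
population-genetic allele-frequency structure. Passing tests therefore
demonstrate correctness of the pipeline's bookkeeping and arithmetic under
known truth, not real-world predictor performance.

## Thresholds and numerical choices

| Quantity | Rule | Note |
|---|---|---|
| SpliceAI | max of reported deltas **> 0.2**, strict | absence of scores is an error, distinct from a score of 0 |
| varSEAK | class **≥ 3** | class 2 ("likely no effect") is negative |
| MaxEntScan | percent change (alt−ref)/ref·100 **≤ −15** | computed unrounded; rounded to 1 decimal for display only; ref = 0 is undefined, not 0 |
| HSF / MutationTaster | any phrase except the two explicit negatives | unknown phrases are logged, never rejected |
| Allele frequency | (2·hom + het)/(2·persons) **< 0.001** | absent from the database ⇒ AF 0; optional stricter popmax mode |

Concordance metrics (accuracy, PPV, NPV) are stored unrounded and rounded
to one decimal for display; zero-denominator ratios are reported as
undefined, never as 0 or 100.

## ACMG point system

Points: supporting ±1, moderate ±2, strong ±4, very strong ±8 (negative for
benign codes; BA1 is treated as very strong for arithmetic). A `_P` /
`_Supporting` suffix lowers a code to supporting strength. Bands: ≥10
pathogenic, 6–9 likely pathogenic, 0–5 VUS, −6…−1 likely benign, ≤−7
benign. The combiner is additive and permutation-invariant; duplicate codes
are rejected.

Reclassification folds a functional result into an evidence set by adding
PS3 (aberrant or partially aberrant splicing — full strong strength in both
cases, matching how the packaged table applies it) or BS3 (no effect).
**Removals are explicit caller inputs**: the packaged table drops different
codes for different variants (PP3 here, PM2_P there) and no consistent
automatic rule reproduces those choices, so inventing one would silently
change results. An opt-in `consistency` mode additionally drops PP3
whenever BS3 is added, for users who want computational splice support
never to coexist with a negative functional result; on the packaged data
this changes points (−3 → −4) but never a tier. Every edit lands in an
audit trail.

## Packaged dataset

`data/variants.tsv` carries the 11 study variants and 2 canonical-site
positive controls with all printed fields, including both values of the one
source-discrepant normal-splicing fraction (0.10 in the text, 0.15 in the
figure; the text value is used, the figure value carried in the notes), and
a note that the 27-nt in-frame exon truncation removes 9 residues (27/3),
not the 12 stated once in prose.

The packaged transcript model is a **synthetic length-only
reconstruction**: exon boundaries pinned by study-variant coordinates
(c.455, c.613, c.839, c.1322, c.1669, c.2090, c.2414/2415, c.3045, c.3538,
c.4852) are honored exactly, the CDS is 5547 nt (1848 residues + stop), and
all other exon ends plus every intron length are placeholders. It supports
localization and coordinate arithmetic; sequence-level consequences for the
real gene require a user-supplied FASTA (`attach_sequences_from_fasta`,
records `exon_N` / `intron_N`).

## Assay interpretation

Outcome categories are structural, not threshold-based: *complete* =
aberrant species only; *predominant* = aberrant species plus any nonzero
normal fraction; *no effect* = normal species only. An aberrant species
with a normal fraction of 1 is an inconsistency error. When minigene and
patient-RNA sources disagree, the package warns and keeps the minigene
category — no automatic resolution is defined, because none is defensible
from single discordant observations.

## Problem sizes

Default test and simulation sizes were chosen to make every property check
decisive yet quick: ≥1000 random events for engine/oracle equivalence,
n = 10 000 cohorts for recovery of planted operating characteristics
(binomial 3-standard-error bounds), n ≈ 100–300 for distributional unit
checks. The full suite runs in well under a minute.

## Known limitations

* Only the HGVS c. grammar subset above; no dup/inv/rep, no UTR coordinates.
* One transcript per analysis; no isoform-aware consequences.
* No NMD prediction, protein-domain annotation, or cryptic-site scoring.
* The packaged transcript model cannot name real-protein consequences
  without user-supplied sequence.
* Tool calls are literal threshold applications; no calibration or
  meta-prediction is attempted.
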