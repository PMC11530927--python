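# Methods

## Scope and data flow

`novolign` turns a table of de novo sequenced peptides into a taxonomic
community profile in five stages: (i) parse/filter the de novo table and
write a query FASTA with one scrambled decoy per peptide; (ii) align
queries against a protein reference database; (iii) collapse each
peptide's hits to a consensus lineage (LCA); (iv) aggregate lineages into
a composition table with false-positive control; (v) quality-control the
spectra and the reference database used for conventional database
searching. A sequencing-error simulator generates the datasets used to
tune and validate the alignment stage.

All peptide and protein sequences are I→L normalized before alignment:
isoleucine and leucine are isobaric and indistinguishable in standard
fragmentation spectra, so the effective residue alphabet has 19 letters.

## De novo input and decoys

Parsing accepts PEAKS-style CSV (`Peptide`, `ALC (%)` or `ALC`, `ppm`,
`Area`, `Scan`), DeepNovo-style TSV (`predicted_sequence` with
comma-separated residues tolerated, `predicted_score`), or any delimited
table with a `Peptide` column. In-line modification annotations in
`(...)` or `[...]` spans are stripped; anything else passes through.

Default quality filters: ALC ≥ 70% (PEAKS) or score ≥ −0.1 (DeepNovo);
optional maximum |ppm| mass error, minimum length, and minimum
intensity/area. Duplicate peptides are kept as separate records —
peptide counts are spectral counts, the abundance unit downstream.

Decoys scramble the residues in front of the tryptic cleavage site: the
C-terminal K/R is held fixed and the prefix is uniformly permuted.
Peptides not ending in K/R (non-tryptic or protein C-terminal) are
permuted whole, which preserves the same null model without discarding
data. Decoys inherit the query id with a `_DECOY` suffix, are aligned and
classified identically, and never contribute to LCA weights or
composition fractions; the fraction of decoys with at least one retained
alignment is reported as the random-match rate.

## Error simulator

Three generators emulate the dominant de novo error modes.

**Equal-mass substitutions.** All residue combinations up to length 6 are
binned by monoisotopic mass at a 10⁻⁴ Da tolerance; at this tolerance the
classes are effectively equal-elemental-composition sets (e.g. N = GG,
Q = AG, {G,Q} = {A,N}). A sliding window scans each peptide left to
right; every window whose residue string has a same-mass alternative of
the configured target length is substituted with the window chance
(25/50/100%; 25% is the calibrated default), and the scan resumes after
the replacement so edits never overlap. An *alternative* is a string with
a different residue multiset: same-multiset reorderings are the inversion
error type, not substitutions. Replacements are drawn uniformly over all
alternative strings (multisets weighted by their number of distinct
arrangements). Mass is conserved within tolerance by construction;
peptide length changes only for the 1↔2 and 2↔3 pairs.

**Inversions.** The peptide is partitioned left to right into fragments
of 2 or 3 residues (length drawn uniformly per fragment; a trailing
single residue is left unchanged); each fragment is shuffled with 5%
probability. Length and composition are conserved.

**Codon-level mutations ("other").** Each residue is reverse-translated
to a uniformly chosen synonymous codon of the standard genetic code; each
nucleotide substitutes to one of the other three bases with 1%
probability; codons mutating to a stop are re-mutated until non-stop,
keeping length fixed; the back-translation is I→L normalized. Mass is
generally not conserved.

Each generated record carries the Levenshtein distance between original
and altered peptide; the per-type error rates (5% inversion/mutation, 25%
substitution window chance) were chosen so the three generators produce
similar edit-distance distributions.

**Combined dataset.** For each input peptide one error type is drawn from
the per-type occurrence rates observed for common de novo tools
(substitutions 1↔1/2 6.3%, 2↔2 13.7%, 3↔3 6.3%, 2↔3 3.7%, 4↔4 9.7%,
5↔5 7.6%, 6↔6 6.8%; inversion 16.1%; other 29.7% — the printed rates sum
to 0.999 and are renormalized). The drawn type is recorded even when the
peptide offers no applicable site (the record is then unchanged), so the
observed type fractions are multinomial at the configured rates. An
optional redraw mode (`max_redraws > 0`) instead redraws inapplicable
types and falls back to the mutation type; it is off by default because
redrawing skews the fractions toward the universally applicable types
(measured ≈ +1% on inversion, −2.3% on 2↔2 at n = 20,000).

**The 13 calibration datasets** produced by `make_error_datasets`: the
seven per-length-pair substitution datasets at the 25% window chance,
pooled-pair substitutions at 25/50/100%, inversion at 5%, codon mutation
at 1%/nt, and the combined dataset. The composition of the suite beyond
"one dataset per configuration" is this package's own layout choice.

## Alignment

Defaults, chosen for short error-bearing peptides: PAM70 (PAM matrices
outperform BLOSUM62 at these lengths), gap open 2 / extend 4 (low opening
and moderate extension suit block-local errors), minimum identity 85%,
minimum query cover 80% (the best-performing range is 75–85%), contiguous
seed mode, up to 25 hits per query.

The **DIAMOND engine** builds the corresponding `diamond blastp` command
and additionally disables low-complexity masking and composition-based
statistics — both silently drop short-peptide hits at defaults. Custom
seed shapes are a pass-through option without a default.

The **internal engine** is an exact affine-gap Smith–Waterman search
(Bio.Align.PairwiseAligner) with the BLAST gap convention (a gap of
length k costs open + k·extend). Candidate subjects are prefiltered by
shared exact 4-mers, mirroring contiguous seeding; candidates are aligned
exactly and filtered by identity/cover. pident counts identities over
alignment columns (gaps included); qcov is the aligned query span over
query length. It searches the database exhaustively within the seed
candidates and is intended for reference-scale fixtures and as the
DIAMOND-free fallback, not for UniRef-scale production runs.

**Bitscores** for the internal engine use ungapped Karlin–Altschul
statistics: λ solves Σᵢⱼ pᵢpⱼ·e^(λsᵢⱼ) = 1 under Robinson–Robinson
background frequencies, H = λ·Σ p·s·e^(λs), and K follows the
lattice-case formula K = λ·e^(−2σ)/(H·(1−e^(−λ))) with σ the Karlin sum
over k-fold convolutions of the score distribution. The solver reproduces
the published ungapped constants (BLOSUM62: λ = 0.3176, K = 0.134,
H = 0.401; PAM70: 0.3345 / 0.229 / 1.029; PAM30: 0.340 / 0.283 / 1.754).
Applying ungapped statistics to gapped raw scores is an approximation;
when DIAMOND output is parsed its gapped bitscores are authoritative.

Hits are filtered at a minimum bitscore of 25 (inclusive: "minimum 25" is
read as ≥ 25) before LCA.

## Consensus taxonomy

TaxIDs parse from `OX=`/`TaxID=` header tokens, a custom regex, or a
2-column accession→taxid map. Lineages project onto the fixed seven-rank
ladder (superkingdom, phylum, class, order, family, genus, species);
intermediate ranks are skipped; taxids absent from the tree are dropped
with a logged count. Taxonomy loads from NCBI-dialect `nodes.dmp` /
`names.dmp` or from an 8-column lineage TSV.

* **CON** walks the ladder top-down and stops at the first rank where the
  hit lineages disagree (a missing rank counts as disagreement).
* **W** computes taxid frequencies over *all* target hits of the run
  (global weights), sorts each peptide's unique hit taxa by descending
  weight (ties by taxid ascending), normalizes the weights over the
  peptide's taxa, and retains the minimal prefix whose cumulative weight
  reaches the cutoff — inclusive of the crossing taxon; CON of the
  retained lineages is the result. At cutoff 1.0, W reduces to CON.
  Per-peptide weighting is available as an option. The default cutoff is
  0.6; 0.8 is a documented stricter configuration.
* **BIT** sums, per rank top-down, hit bitscores per taxon and assigns
  the taxon whose share strictly exceeds the cutoff, stopping at the
  first rank without one. For any cutoff > 0.5 at most one taxon can
  qualify per rank and the assigned lineage is prefix-consistent.

## Composition and database construction

Peptide counts per taxon at the chosen rank form the composition; taxa
under `freq_cut` (default 5) are pooled into an `other` row rather than
dropped, so fractions — computed over classified target peptides only —
always sum to 1. The decoy retained-alignment rate is reported alongside
and never enters the fractions. `spearman_compare` rank-correlates two
compositions over the union of their taxa (absent taxa count 0, `other`
excluded; fewer than 3 taxa → NaN with a warning).

`extract_taxon_sequences` collects all reference sequences whose taxid
projects to a given taxon set at a given rank, honoring an exclusion
list and optionally appending scrambled decoy proteins and the query
peptides. `complement_db` merges a metagenome-derived FASTA with such an
extract, removing exact duplicate sequences after I→L normalization
(first occurrence wins; clustering-based redundancy removal is out of
scope) and tagging provenance in the headers.

## Quality control

Per query the best hit (bitscore, then pident, qcov, accession) sets the
category: `exact` (pident = qcov = 100), `exact_tag` (identity 100, cover
< 100), `aligned`, `aligned_tag`, `unmatched`; comparisons against 100
use a 10⁻⁶ tolerance to absorb tabular rounding. PSM tables join on the
scan reference when both sides carry one, else on the normalized peptide
string. `high_quality_matched_fraction` reports, among spectra with
ALC ≥ 90, the fraction matched in database searching (NaN when none
qualify). The coverage report compares DN_only / DN_all / DB_only /
DB_all peptide-set taxon distributions at order/family/genus;
database-search peptides map to taxa via their protein accessions, with
multi-protein peptides resolved by CON over the proteins' lineages.

## Synthetic data

The fixture generator builds a full seven-rank taxonomy (one
superkingdom/phylum/class; families spread over ⌊families/2⌋ orders; one
genus per species), uniform-random proteomes over the 19-letter alphabet
(K/R then occur at ~10.5%, giving realistic tryptic peptide lengths),
species abundances from a flat Dirichlet, and PEAKS-dialect de novo
tables whose peptides are tryptic fragments (7–30 residues) of the
proteomes, perturbed by the combined error model. Error-bearing peptides
draw ALC from N(76, 8) and clean ones from N(88, 5), clipped to [0, 99],
emulating the score/accuracy coupling of real de novo output; ppm errors
are N(0, 3) and areas log-normal. Ground truth (source species, protein,
applied error, edit distance) is written alongside, keyed by query id.

What the generator does **not** emulate: spectral noise and fragment-ion
physics, retention behavior, homology between species (proteomes are
independent random sequences), shared peptides across taxa, and real
database redundancy. Passing end-to-end tests therefore demonstrates the
pipeline's mechanics — filtering, decoy control, alignment under
sequence errors, LCA arithmetic, reporting thresholds — not classifier
performance against real, highly homologous reference databases, where
correct-taxonomy rates are necessarily lower.

## Numerical and design choices

* Mass tolerance 10⁻⁴ Da (configurable); mass keys are quantized with
  neighboring-bin lookup so boundary rounding cannot split a class.
* Ties everywhere break deterministically (taxid ascending; accession
  lexicographic), and every random draw flows from one seeded generator,
  so identical seeds give bit-identical outputs.
* Empty/degenerate inputs: peptides shorter than 2 pass through decoy
  scrambling and inversion unchanged with a warning; zero-score local
  alignments return an explicit no-alignment hit; compositions without
  classified peptides yield an empty table plus warning.
* Problem sizes used by the shipped checks (the package's own choice):
  error-rate recomputation at n = 20,000 peptides; end-to-end recovery on
  a 10-family / 30-species community with 2,000 peptides via the internal
  engine; property suites at 10,000 peptides (mass conservation, decoys),
  500 alignment pairs, and 1,000 LCA hit sets.

## Known limitations

* The internal engine's bitscores are ungapped-statistics approximations;
  absolute parity with DIAMOND's gapped bitscores is not expected beyond
  a couple of bits.
* DIAMOND's exact custom seed shapes for very short peptides are not
  standardized here; `ctg` mode plus 4-mer prefiltering stands in.
* GTDB or other taxonomies are usable only when supplied in taxdump
  dialect; no cross-release name reconciliation is attempted.
* Functional (KO) annotation is out of scope; the constructed protein
  FASTA is the intended input for external annotation services.
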