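# Methods

## The prioritization model

An AP-MS pull-down yields, per sample, a list of identified proteins with
unique-peptide counts. `apmsrank` treats prioritization as three
independent decisions:

**Abundance estimation (emPAI).** For protein *i* in sample *s*,

    PAI(i, s)   = N_observed(i, s) / N_observable(i)
    emPAI(i, s) = 10^PAI(i, s) − 1

N_observed is the *unique* peptide count (distinct peptide sequences, not
spectral counts) reported by the search engine; N_observable is computed
from the protein sequence alone (below). emPAI is approximately
proportional to molar abundance, so it is comparable across proteins of
very different length — a short, fully covered protein can legitimately
outrank a long one with more raw peptides. PAI may exceed 1 when missed
cleavages or search-space settings yield more distinct observed peptides
than the counting convention predicts; emPAI is then simply large, which
is the desired behavior for ranking. Proteins with N_observable = 0 have
undefined PAI; they are excluded from ranking, reported on a separate skip
list, and never assigned an artificial score.

**Observable-peptide counting.** Proteins are digested in silico with
proline-blocked trypsin ("trypsin/P": cleave after K or R except before
P; a plain trypsin rule without the proline block is also available).
Base fragments are the maximal substrings between cleavage boundaries;
peptides with up to `max_missed_cleavages` internal boundaries are unions
of adjacent fragments. A peptide is *observable* if its length falls in
[`min_length`, `max_length`] (default 7–35 residues) and, when the mass
window is enabled (default), its average mass falls in
[`min_mass`, `max_mass`] (default 500–5000 Da). The defaults emulate a
typical tryptic LC-MS/MS acquisition range while staying
instrument-agnostic; all four thresholds and the missed-cleavage allowance
(default 0) are configurable. N_observable counts *distinct* peptide
sequences — a tryptic peptide arising twice from a repeated region counts
once, matching the unique-count semantics of N_observed. Coordinates are
0-based half-open so `parent[start:end] == peptide`.

**Credibility filter.** A protein is a credible interactor when it is
present (unique-peptide count ≥ `min_unique_peptides`, default 1) in
*every* bait replicate and absent from the *union* of all control
purifications. Union-based control subtraction is the most conservative
reading of "not in the controls"; pooled versus per-replicate control
handling makes no difference under it. Survivors are ranked by the mean
(configurable: median, max) of their per-replicate emPAI, ties broken by
accession so the report is deterministic. The bait is retained and
flagged, never dropped. This is deliberately a presence/absence filter —
no probabilistic contaminant model (SAINT/CompPASS-style) and no FDR
estimate; its failure mode (a contaminant that by chance evades every
control) is inherited knowingly and quantified on synthetic data.

## Sequence-level properties

Molecular masses use the standard average (isotope-weighted) residue-mass
table plus one water (18.01528 Da); a monoisotopic table is available but
average masses are the default because "theoretical molecular weight" of
an intact protein is an average-mass quantity. Ambiguous residue codes
(X/B/Z/U/O, accepted only in permissive parsing mode) have no defined
mass here; peptides containing them are excluded from mass-bearing
computations with a warning rather than being assigned a guessed mass. A
protein consisting only of ambiguous residues therefore has
N_observable = 0 and lands on the skip list.

FASTA headers are parsed as first-token accession with UniProt
`db|ACC|name` tokens reduced to `ACC`, covering both locus-tag and
UniProt-style databases. Duplicate accessions and out-of-alphabet
characters are hard errors; output FASTA is wrapped at 60 columns.

## Ortholog percent identity

Percent identity between a candidate and a putative ortholog is computed
from an optimal pairwise alignment under BLOSUM62 with affine gap
penalties (open 11, extend 1; the first position of a gap costs the open
penalty, each further position the extend penalty). Global
(Needleman–Wunsch) identity uses the full alignment length as
denominator; local (Smith–Waterman) identity uses the local alignment
length, which approximates the identity figures a BLASTP report prints.
When no positive-scoring local alignment exists, local identity is 0 over
an empty region. Among co-optimal alignments the aligner's first
traceback is used — deterministic for fixed inputs — and the argument
pair is canonically ordered before aligning, so identity is exactly
symmetric. Alignment itself is delegated to Biopython's
`PairwiseAligner`; tests verify its scores against an independent
memoized-recursion dynamic program written in the test suite.

## The synthetic experiment generator

The generator emulates the statistical structure the filter assumes, not
any particular instrument:

- **Proteome**: `n_proteins` (default 500) i.i.d.-residue sequences,
  lengths uniform on 100–800, expected K+R frequency `kr_fraction`
  (default 0.11, split evenly between K and R; remaining mass spread
  uniformly over the other 18 residues) — giving realistic tryptic
  fragment statistics.
- **Roles**: one bait, `n_true_preys` (15) preys, `n_contaminants` (30)
  contaminants, the rest silent background. Preys and the bait are
  detectable only in bait replicates; contaminants in *all* samples under
  the identical detection law; background never.
- **Abundances** (arbitrary scale): bait 50, preys uniform 5–20,
  contaminants uniform 10–40, drawn once per protein and shared across
  samples.
- **Detection law**: in each sample, a protein with abundance *a* and
  N_observable = n yields `n_observed ~ Binomial(n, p)` with
  `p = 1 − exp(−k·a)`, k = `detection_rate_per_abundance` = 0.05; a draw
  of 0 means the protein is absent from that sample's table. The
  saturating link makes higher-abundance proteins yield more unique
  peptides, the behavior emPAI ranking relies on; binomial (not Poisson)
  sampling keeps n_observed bounded by n_observable, as a unique count
  must be. Proteins with n_observable = 0 are silently undetectable
  whatever their abundance.
- **Randomness**: one root seed; each sample's stream is derived from
  `SeedSequence([seed, crc32(sample_id)])`, so adding a replicate never
  perturbs existing ones, and every artifact (FASTA, tables, report,
  metrics) is byte-reproducible.

What the generator does **not** emulate: peptide-level identification
(shared peptides between homologous proteins, protein inference),
abundance-correlated contamination, inter-replicate abundance variation,
or search-engine score filtering. Passing recovery tests therefore shows
the filter and ranking behave correctly under the model's assumptions,
not that real AP-MS contaminant behavior is this benign.

With these defaults the expected behavior is strong separation: a prey at
the low end (a = 5, p ≈ 0.22) of the abundance range with 20 observable
peptides is missed by a whole replicate with probability ≈ 0.7%, so prey
recall is high; a contaminant (p ≥ 0.39) evades three controls only
rarely, so leakage is near zero; and the bait (p ≈ 0.92) attains the top
emPAI rank unless a small prey saturates its few observable peptides in
every replicate. The acceptance thresholds (median recall ≥ 0.9, zero
leak and bait rank 1 in ≥ 18 of 20 seeds) encode exactly this.

## Numerical and design choices

- Masses are reported to 2 decimals (Da) in outputs, full precision kept
  internally; emPAI columns are rounded to 2 decimals on write, ranks are
  computed before rounding.
- Report tie-break: aggregate emPAI descending, then accession ascending.
- Evidence tables encode absence by omission; a stored count of 0 is a
  format error, keeping "observed in" semantics unambiguous.
- Problem sizes in the validation suite — 1,000 random sequences for the
  digestion oracle, exhaustive presence/absence patterns up to protein
  relabeling (a symmetry of the filter) for the filter oracle, 20 seeds
  for recovery, 250 short pairs for the alignment oracle — are chosen so
  the whole suite completes in seconds while each property is still
  exercised across its full combinatorial range.

## Known limitations

- emPAI is a coarse abundance estimate; no error model accompanies it.
- The filter cannot rescue a true prey that drops out of one replicate,
  and cannot reject a contaminant absent from all controls — both are
  properties of the published procedure it implements, and both are
  measured (as recall and leak) on synthetic data rather than patched.
- Observable-peptide counting depends on the chosen windows; absolute
  emPAI values are therefore comparable only within one configuration.
- Local-alignment percent identity approximates, but does not reproduce,
  BLASTP identity (different seeding/extension heuristics).
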