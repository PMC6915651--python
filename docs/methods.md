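# Methods

## Scope and intended use

`coibar` designs and interprets COI barcode PCR–RFLP assays: given a
labelled reference panel of barcode sequences, it finds a restriction
enzyme (or small set) whose agarose-gel band patterns separate every
species, and assigns unknown samples — observed band sizes or sequences —
to species by pattern matching. Supporting steps are barcode QC
(premature-stop/NUMT screening), local best-match identification, and
mislabeling summaries. Wet-lab concerns (PCR conditions, digestion
chemistry, electrophoresis physics) and phylogenetic analysis are out of
scope.

## Restriction-site scanning

Recognition sites are IUPAC patterns with a single top-strand cut offset,
parsed from caret notation (`G^ANTC`). Coordinates are 0-based, half-open:
"cut at *p*" severs the backbone between *p*−1 and *p*, so digestion
boundaries are {0} ∪ cuts ∪ {*n*} and fragment lengths always sum to the
sequence length; zero-length fragments (cuts at the ends or coincident
cuts) have no physical band and are dropped.

**Ambiguity semantics.** A pattern position *matches* a sequence position
when the sequence base's IUPAC set is a **subset** of the pattern code's
set; a window in which every position at least intersects, but not all are
subsets, is a *candidate* site. Candidates are reported separately and
never cut: an `N` in a read must not invent or silently suppress a band.
This is the conservative choice; tools differ in how they treat ambiguous
bases, and any more permissive rule can be recovered by resolving the
ambiguity upstream.

**Strand convention.** Gels resolve double-stranded fragment length, so a
site contributes exactly one cut coordinate: the top-strand nick, at
*i* + *c* for a window starting at *i*. For a site found on the bottom
strand, the top-strand nick under the symmetric cut geometry of orthodox
type II enzymes also lies at *i* + *c*; enzymes whose bottom-strand cut is
genuinely asymmetric are approximated by this convention. All five bundled
enzymes (HpaII, HinfI, MboI, RsaI, HindIII) are palindromic, so for them
both-strand scanning coincides exactly with top-strand scanning and the
approximation is exact. One consequence worth noting: because the nick of
an off-centre cutter (e.g. MboI, which cuts at the pattern edge) is not
mirror-symmetric, digesting the reverse complement of a sequence shifts
internal fragment boundaries by *L* − 2*c*; only for central cutters
(RsaI) is the fragment list exactly mirrored. This is a property of
representing a staggered double-strand break by a single coordinate, not a
bug, and it never affects pattern comparison because both strands of a
molecule are always digested together.

## Virtual gel model

Two parameters, both exposed everywhere they matter:

- `min_band` = 100 bp. Small fragments run off or are too faint on the 3%
  agarose gels used to resolve these assays; bands below the threshold are
  treated as invisible.
- `tolerance` = 0.10 (relative, as a fraction of the larger size). Gel
  sizes are read against a 100 bp ladder only approximately; a 10% relative
  window is a realistic reading error for 100–700 bp fragments and is the
  package-wide default for comigration merging, pattern matching and
  assignment scoring.

`make_pattern` drops invisible fragments, sorts descending and repeatedly
merges the first adjacent pair within tolerance into one band at the
multiplicity-weighted mean, rounded half-up to an integer *inside* the
merge loop. Rounding inside the loop (rather than once at the end) makes
the procedure idempotent: the final band list, re-submitted, is already
stable. Multiplicity is recorded (two comigrating fragments are one band)
but ignored by `patterns_match`, because band intensity is not reliably
readable from a gel; it is kept for reporting.

`patterns_match` requires equal band counts and every size-ordered pair
within tolerance; `pattern_distance` greedily matches bands in descending
order and returns the fraction of unmatched bands, so distance 0 coincides
exactly with a pattern match, and two empty patterns are identical by
convention.

## Enzyme discrimination and selection

Within a species, record patterns are clustered greedily in input order
(the first pattern seeds variant 1). Pattern matching is a tolerance
relation and therefore not transitive; greedy order-dependence is accepted
and kept deterministic rather than hidden behind an arbitrary canonical
ordering. Intraspecific variants model real within-species lineages with
polymorphic recognition sites (the swordfish clade I/II patterns are the
motivating case) and do **not** disqualify an enzyme: only a variant
colliding with another species does.

Enzymes are ranked by: discriminates-all (desc), total variant count
(asc — fewer variants mean a simpler reference card), minimum cross-species
band-size gap between equal-band-count variants (desc — wider gaps are
easier to read on a gel), then name. If no single enzyme separates every
pair, a greedy set cover over the undistinguished species pairs builds an
enzyme combination; with the candidate lists used here (≤ 5 enzymes) greedy
is verified against exhaustive search in the tests. An instance where no
enzyme covers a remaining pair is reported infeasible with the offending
pairs named.

Assignment scores an observed pattern against every reference variant as
1 − distance and requires, by default, a full match (threshold 1.0, CLI
`--threshold` to relax): the assay identifies by pattern identity on the
gel, and partial matches are surfaced as `ambiguous`/`unassigned` rather
than guessed. Score ties across species within 10⁻¹² are ambiguous.

## Barcode QC and identification

Translation uses the vertebrate mitochondrial code (NCBI table 2; TGA =
Trp, AGA/AGG = stop). All three forward frames are translated — COI
barcodes are amplified with fixed primers off the coding strand — and the
screen passes when some frame has no internal stop (a stop in the final,
possibly partial codon is terminal and does not count). A `--six-frame`
flag extends the search to the reverse strand for material of unknown
orientation. Sequences shorter than 600 bp are flagged as possible nuclear
pseudogene (NUMT) co-amplicons; the flag is advisory, not a failure.

Identification is a global pairwise alignment with free end gaps
(match +1, mismatch −1, gap −2; biopython's `PairwiseAligner`), and
identity is matches / aligned columns with terminal gap columns excluded,
rounded half-up to two decimals; mislabeling percentages are rounded
half-up to one decimal and always recomputed from the stored counts.
Fixed local scoring makes results reproducible offline; identities against
a *different* reference set than an online database used will of course
differ, so the bundled survey table carries its identities as data.

## Synthetic panel generator

`make_panel` emulates a validated reference panel under the conditions the
assay targets: default five species, two ~700 bp sequences per species,
five candidate enzymes with MboI planted as the discriminating one, and an
intraspecific substitution rate of 0.005/site (typical within-species COI
divergence in fishes is below 1%). Construction:

1. per species, a uniform-random ACGT backbone is drawn and every
   confirmed site of **any** candidate enzyme is removed by bounded,
   seeded point mutation (whole-sequence rejection would essentially never
   terminate at these lengths, since a 700 bp random sequence carries ~11
   sites of the five enzymes in expectation; per-site scrubbing reaches
   the identical postcondition);
2. species-specific cut positions for the planted enzyme are chosen from a
   deterministic candidate grid (0, 1 or 2 cuts) and accepted only if the
   implied gel patterns are pairwise non-matching under the active gel
   parameters — verified with the production `make_pattern`/
   `patterns_match`, so the guarantee is exactly the one the selector
   needs;
3. recognition sites are written at those positions, stray sites re-scrubbed
   (planted windows protected), and the realized cut set verified;
4. intraspecific copies receive per-position substitutions at the given
   rate, each kept only if the confirmed site set of every candidate
   enzyme is unchanged (otherwise another base is tried, then the position
   is skipped).

Everything derives from one `random.Random(seed)`, so identical inputs
give byte-identical FASTA and truth JSON. `make_clade_variant` derives an
intraspecific lineage by creating (or destroying) exactly one site with
minimal substitutions, rejecting any edit whose gel pattern does not
differ from the original.

What the generator does **not** emulate: codon structure, phylogenetic
correlation between species, indels, sequencing error or IUPAC-ambiguous
calls (ambiguity handling is exercised with hand-built fixtures instead),
and realistic base composition. Passing the planted-recovery tests
therefore demonstrates the pipeline's correctness on panels whose
discriminability is knowable by construction — not that any particular
real panel is discriminable, which remains an empirical question answered
by running `select` on real reference data.

## Problem sizes and numerical choices

The randomized test batteries use 1,000 random sequences (length < 200,
2% ambiguous positions) for scanner-oracle agreement and digest
conservation, 50 seeded panels (5 species × 2 records × 700 bp) for
planted-enzyme recovery, and 30 trials of 220-codon constructed coding
sequences for the translation screen; these sizes give stable 100%/0-count
outcomes in a few seconds. All percentage rounding is half-up (survey
conventions), band sizes round half-up to integers, and floating-point
score comparisons use a 10⁻¹² epsilon. Ties in enzyme ranking fall back to
the enzyme name; ties in best-match identification fall back to longest
aligned core, then subject id.

## Known limitations

- Partial digestion, methylation sensitivity, star activity and circular
  templates are not modelled; digestion is assumed complete.
- Non-palindromic enzymes are supported but their staggered cut is
  approximated by the top-strand nick (exact for all bundled enzymes).
- In-silico PCR allows mismatches but not indels in primer footprints.
- Assignment is deterministic pattern matching, not probabilistic; mixed
  (two-species) samples are out of scope and will generally come out
  `unassigned` or `ambiguous`.
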