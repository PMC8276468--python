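# Methods

This note documents the models and procedures implemented in `hadalmeta`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Abundance aggregation

A read assignment is a lineage map (superkingdom…species), possibly
truncated, or an explicit `unclassified` sentinel (never an empty
string, so parsing is unambiguous). Relative abundance at a rank is
`100 × count / total assigned reads`. The denominator deliberately
includes assigned reads that do not resolve to the queried rank — the
aggregation follows the quoted formula literally rather than
renormalizing per rank — so percentages at deep ranks sum below 100 %.
Renormalization (`renormalize=True`) and within-clade restriction
(`within="Eukaryota"`) are explicit parameters, never silent defaults.
Tie-breaks in top-N reports are alphabetical, making reports
deterministic.

## MAG quality control

The medium-quality draft standard is applied as completeness ≥ 50 % and
contamination ≤ 10 %. The field's prose usually words this strictly
("> 50 %, < 10 %") while binning tools apply it as a cutoff
(`-c 50 -x 10`); this package uses **inclusive** boundaries by default
and exposes `strict=True` for the other reading. Tier counts above the
filter (> 70 %, > 90 % completeness) are strict, matching how such
counts are reported. Rejections always carry the failed criterion, and
kept/rejected partition the input exactly.

## Trait classification

Module completeness is `100 × |G ∩ K| / |K|`, rounded to two decimals.
Pathway *presence* defaults to `min_markers_present = 1` — community
surveys typically call a pathway from marker detection rather than a
full-module threshold — with per-pathway overrides in the catalog; the
shipped CBB entry requires both *rbcS* and *prkB* (min 2) because either
alone is weak evidence of the Calvin cycle.

The catalogs are the single source of truth for marker symbols, and each
symbol belongs to exactly one entry. Two consequences:

* the cytochrome c oxidase vs CO dehydrogenase name collision ("cox") is
  resolved at the subunit level: `coxA` (aerobic respiration) vs `coxL`
  (CO oxidation);
* sulfate-reduction markers are split so each appears once —
  assimilatory `{sat, dsrA, dsrB}`, dissimilatory `{aprA, aprB}`. Note
  that *aprAB*/*dsrAB* are classically dissimilatory markers; source
  annotation tables in this field sometimes label them otherwise, so the
  catalog is editable and the split is documented in the catalog file
  itself rather than silently "corrected".

Marker lists for 3-HP, 3-HP/4-HB, methanogenesis, hydrocarbon/aromatic
degradation and H₂ oxidation are not standardized in survey main texts;
the defaults use common field symbols (`mcr`/`pcs`, `4hbd`/`ech`,
`mcrA`/`mcrB`/`mtrA`, `alkB`/`almA`/`ladA`, `benA`/`catA`/`pcaG`/`bphA`,
`hyaB`/`hybC`/`hoxH`) and are expected to be edited to match the user's
annotation database. A fungal catalog (nitrate/sulfate reduction,
organic-sulfur and sulfide-oxidation genes) ships for eukaryotic
communities and runs through the identical engine — there is no
fungal-specific code path.

Lifestyle flags satisfy the structural invariants by construction:
facultative ⇒ aerobic ∧ anaerobic, mixotroph ⇒ heterotroph ∧ autotroph,
and adding a gene never lowers a completeness value or clears a flag.

## Virus–host association

**Composition.** k-mer vectors use the full 4ᵏ = 256 tetranucleotide
space with both-strand counting. Counting both strands already makes
vectors exactly strand-invariant, so collapsing to 136 canonical k-mers
is unnecessary; keeping 256 components also matches the scale on which
the acceptance threshold is calibrated (mean component frequency
1/256 ≈ 0.0039, threshold d = 0.0015). MAE normalizes by the vector
dimension — a literal mean absolute error — giving the analytic bound
0 ≤ d ≤ 2/4ᵏ. Host vectors aggregate counts over all contigs of a
genome before normalizing. Assignment takes the single closest host,
strictly below `d_max = 0.0015`; an exact tie goes to the
lexicographically smallest host id and is flagged in the edge metadata.
Viruses below `min_virus_len = 5000` bp are skipped by default because
short contigs have unstable signatures; set it to 0 to disable.

**CRISPR.** The built-in detector is a minimal stand-in for a dedicated
tool: it seeds on exact 23-mers occurring ≥ 3 times with array-like
periodicity, extends the repeat while all copies agree (23–50 bp), and
emits unique 20–60 bp inter-repeat segments as spacers with 0-based
half-open host coordinates. Spacer matching is a full-length Hamming
scan over both virus strands; the default tolerance of 2 mismatches is a
judgment call (association tables in this field record the mismatch
count but rarely state the cutoff) and is exposed as a flag. Per
(virus, host) pair only the best (fewest-mismatch) spacer alignment is
kept.

**Similarity.** Alignment tables (BLAST outfmt-6 dialect) are filtered
at bit score ≥ 50 and E-value ≤ 0.001 — both inclusive, since these are
stated as thresholds — and collapsed to the best row per pair. The
aligner itself is external; `exact_substring_hits` provides a naive
built-in search for synthetic benchmarks only.

**Network.** All edges are deduplicated to distinct (virus, host) pairs
before aggregation to a bipartite virus-family × host-class graph whose
edge weights count pairs; unmapped ids group under "unclassified".

## AMG flagging

Any CAZyme family annotation on a viral ORF flags a carbohydrate AMG;
nitrogen/sulfur AMGs are driven by a deliberately minimal shipped
catalog (nirK; cysN/nodQ) rather than a padded guess at a fuller KO
list — the catalog is a drop-in YAML. CAZy classes parse by longest
prefix (CBM before C/CB ambiguity), unknown prefixes count under
"other" with a warning. COG summaries count multi-letter assignments
once per letter and tally unannotated ORFs as "unknown function". The
upstream annotation E-value threshold (1e−5) belongs to the external
annotator and is recorded as provenance only.

## Marker workflows

Hit filtering keeps E ≤ 1e−5, identity ≥ 50 %, coverage ≥ 30 %
(inclusive) and retains the best hit per query (lowest E, then highest
identity). "Coverage" means query coverage by default; subject-coverage
mode exists because the convention varies between pipelines.

Trimming keeps columns with occupancy ≥ `gap_threshold` (0.95); if
fewer than `conserve` % (50) survive, the `conserve` % highest-occupancy
columns are kept instead, ties resolved toward the left-most column,
order always preserved. This is this package's fixed, documented
contract — trimming tools implement subtly different `-cons` semantics
across versions, and no claim of tool equivalence is made. The
threshold branch is idempotent; the conserve fallback is not (a second
pass over uniformly low-occupancy columns keeps a fraction again), which
is inherent to a percentage-of-current-columns rule.

Concatenation fills missing genome × marker blocks with gaps and emits a
partition table (0-based half-open internally, 1-based inclusive in the
RAxML-style text export). Shipped rosters: the standard 15 syntenic
ribosomal proteins, and a 40-entry universal single-copy COG set as an
editable default for "conserved protein marker" workflows.

## Synthetic data: what it emulates, and what it does not

Each host genome is an order-3 nucleotide Markov chain whose 64
transition rows are independent symmetric Dirichlet(α = 1) draws — a
uniform prior over transition rows. This gives hosts clearly separable
tetranucleotide signatures (pairwise MAE ~3–4×10⁻³, versus ~3×10⁻⁴
between a prophage and its source host), somewhat cleaner than the
separation among real genomes; passing recovery tests therefore
demonstrates correctness of the machinery, not expected field accuracy.
Prophages are verbatim host substrings (8–12 kb by default, clearing the
5 kb composition length floor), guaranteeing both a similarity link and
a small composition distance. Decoy viruses are sampled from a chain
fitted to the pooled hosts, making them compositionally *near* but
unlinked — non-trivial negatives for the d < 0.0015 rule.

CRISPR arrays use a fixed random 28 bp repeat per array, 3 repeats
around 2 spacers, each spacer copied from a random virus window and
mutated per-position at `spacer_mismatch_rate` (the recorded mismatch
count is the realized number of substitutions). Annotation tables plant
a lifestyle per genome by independent draws (heterotroph 0.8, autotroph
0.4, aerobic 0.85, anaerobic 0.8, chemolithotroph 0.5 — echoing the
high prevalence of mixotrophy and facultative metabolism in deep
sediment communities) and emit exactly the required markers plus
non-marker noise. Read assignments are multinomial draws from a
Dirichlet-distributed abundance vector over a fixed 11-taxon community
template, with a seeded unassigned fraction (default 0.1).

Not emulated: sequencing error models, assembly and binning artifacts,
strain-level mosaicism, horizontal transfer, degraded or partial CRISPR
arrays, and compositional convergence between unrelated genomes. All
generators derive their randomness from named child streams of the
single config seed, so identical configs are byte-identical across runs.

Benchmark problem sizes (5 hosts × 50 kb, 13 viruses, 10⁵ reads) were
chosen so the complete suite runs in seconds on one CPU while every
recovery statistic is still well-populated.

## Known limitations

* The CRISPR detector requires exact repeats and ≥ 3 copies; real arrays
  with diverged repeats need a dedicated tool, whose spacers can be fed
  into `match_spacers` directly.
* Spacer matching is substitution-only (Hamming); indel-containing
  protospacers are missed.
* Composition assignment picks a single best host; co-infection or
  ambiguous sub-threshold hosts are not reported (only exact ties are
  flagged).
* Trait calls are presence-based genomic *potential*, not activity; a
  pathway called from one marker may be incomplete.
* The nitrogen/sulfur AMG catalog is minimal by design and should be
  extended with the user's full KO list for real surveys.
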