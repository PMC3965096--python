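# Methods

## Problem and scope

`negset` derives reference datasets of **non-interacting protein pairs
(NIPs)** — pairs for which there is positive evidence of *absence* of a
physical interaction.  Such negative sets are needed to train and
benchmark protein–protein interaction predictors, where sampling random
pairs as negatives is known to be biased.  The package covers three
evidence routes and the set algebra that combines them:

1. **structural**: two chains that co-occur in a biological assembly but
   never come close to each other are candidate non-interactors;
2. **curated**: literature-annotated non-interactions are consumed as
   Negatome-style TSV datasets (the curation itself is upstream);
3. **text mining triage**: pre-extracted predicate-argument structures
   (PAS) carrying a negated interaction verb are ranked by a confidence
   score to prioritize manual verification.

Semantic role labelling, named-entity recognition and the curation GUI
are out of scope; the package starts from structured inputs.

## Structural non-interaction rule

Each polymer amino-acid residue is reduced to one representative atom:
**Cβ**, or **Cα for glycine** (no side chain) and for residues whose Cβ
is absent from the record.  A chain pair in a biological unit is
classified non-interacting when the minimum over all cross-chain
representative-atom pairs of the Euclidean distance is **strictly greater
than 8 Å**.  The choice of strict inequality at exactly 8.0 Å is ours
(the convention is not published); it is the conservative reading for a
negative set — a borderline pair stays *interacting* and is excluded.
The threshold is a parameter (`ContactConfig.threshold`, Å, default 8.0).

The minimum is computed with a k-d tree (`scipy.spatial.cKDTree`) over
the larger chain; exact equality with the exhaustive O(n·m) scan is a
tested contract, not an approximation.

Other conventions, all deliberate:

* biological units are consumed **pre-expanded** (`*.pdbN` files or
  mmCIF coordinate blocks); applying mmCIF assembly operators is an
  opt-in flag since no expansion procedure is prescribed for the method;
* multi-model (NMR) files: model 1 only — one deterministic geometry;
* altloc alternatives: highest occupancy wins, ties broken by altloc
  label — deterministic and conventional;
* residues with neither Cβ nor Cα are skipped and counted, never fatal;
  non-standard amino acids with usable atoms are admitted.

## Protein-level consolidation

Chains map to UniProt-style accessions via a SIFTS-style table.  Within
one unit a protein pair is non-interacting **only if every chain-copy
pair realizing it is distant** — a single observed contact between any
two copies falsifies non-interaction.  Across units the same logic is
applied globally: a pair seen in contact in *any* processed assembly is
suppressed everywhere.  Whether the original datasets consolidated
contradictions across structures is not documented; global suppression
is our choice, again conservative for a negative set.  Self pairs
(homomer copies of one accession) are excluded.  Isoform suffixes
(`P12345-2`) are kept verbatim by default; `--collapse-isoforms`
truncates at the dash.

## Domain expansion and stringent filtering

Protein pairs expand to PFAM domain pairs as the full cross product of
the two proteins' domain lists (A1–B1, A1–B2, A2–B1, …), canonicalized
and deduplicated.  Domain self-pairs (D, D) are retained so that
homodomain entries of 3DID/iPFAM-style catalogues can subtract them.

All set algebra runs on **canonical pairs** (members sorted
lexicographically), so equality ignores orientation.  *Stringent*
datasets are produced by subtracting known-interaction sets: protein
pairs from MITAB (PSI-MI TAB 2.5, uniprotkb tokens of columns 1–2),
domain pairs from two-column TSV exports and, optionally, domain pairs
derived from the MITAB protein pairs via the same expansion.  Removal
percentages are reported as integers, rounded half away from zero with
integer arithmetic (the convention the published tables use).

## PAS confidence score

The feature set of the score is fixed (argument length, sentence length,
relation type, negation token, agent==theme) but no formula or weights
were ever published, so the functional form is this package's design:

    score = [ w_a·exp(−(max(La,Lt)−1)/τ_arg) + w_s·exp(−(Ls−1)/τ_sent)
            + w_r·lex(verb) + w_n·neg ] / (w_a+w_s+w_r+w_n)
            × (same_entity_factor if agent == theme else 1)

with defaults: equal weights, τ_arg = 10 tokens, τ_sent = 30 tokens,
`neg` = 1 for a common negation word else 0.5, same-entity factor 0.5.
`La, Lt, Ls` are token counts of agent, theme and sentence.  The form
reproduces every qualitative property the score is documented to have —
longer sentences and arguments lower confidence, relation quality enters
through a per-verb lexicon weight, unusual negation words are penalized,
and agent==theme is strictly penalized while the record is *kept* (the
sentence may still describe another non-interaction) — and a best-case
record normalizes to exactly 1.0.  Everything is configurable via YAML.
The default verb lexicon (interact, bind, co-immunoprecipitate,
associate, complex, co-localize) seeds the "verbs that specifically
refer to interaction or binding" restriction and is meant to be
extended.  Only monotone behaviours are asserted anywhere; absolute
score values have no external referent.

## Synthetic data generator

The generator emulates every input the pipeline consumes: biological
units (parallel PDB and mmCIF), chain→accession tables, accession→PFAM
tables, MITAB interaction files with decoys and a non-protein (chebi)
row, two-column domain-pair lists and JSON-lines PAS corpora.  Every
fixture ships machine-readable ground truth, and a fixed seed yields
byte-identical files (the structure writers are fixed-format templates
for exactly this reason).

Chains are random coils with 3.8 Å Cα spacing and a pseudo-Cβ at 1.53 Å;
only representative-atom geometry is meaningful.  Internal coordinates
snap to a 0.125 Å binary lattice so values survive the 3-decimal file
precision exactly.  A chain with a single minimum-gap constraint is
placed by an axis-projection construction that realizes the requested
minimum distance *exactly* — bit-exact for binary-representable gaps, so
a fixture at exactly 8.0 Å genuinely probes the strict inequality after
a file round trip.  Chains with several constraints are placed by damped
iterative refinement to within 0.05 Å; contradictory constraint systems
raise a feasibility error.  Ground-truth distances and classifications
are always computed by exhaustive scan over the coordinates *as written*
(file precision), so truth and file cannot disagree.

What the generator does **not** emulate: real secondary structure,
crystallographic artefacts, chain-length and composition distributions,
SIFTS mapping noise, the tail of MITAB dialect variation, or natural
language (PAS records carry synthetic token counts).  Passing tests
therefore demonstrate correctness of the derivation logic and file
handling, not performance of the method on real PDB/IntAct content.

## Problem sizes and verification

The published headline dataset sizes depend on full mid-2013 PDB and
IntAct snapshots and cannot be recomputed at desk scale.  What *is*
verifiable, and what tests and `scripts/acceptance.py` compute at run
time, are the printed arithmetic relations over sets with the published
cardinalities: 2171 curated and 4397 structure-derived pairs sharing 36
merge to 6532; subtracting known interactions leaves 1991, 4161 and 6136
pairs, i.e. 8%, 5% and 6% removed.  The merged subtraction implies
180 + 236 − 396 = 20 of the removed pairs lie in the 36-pair overlap and
are removed from both sides; the synthetic sets are constructed
accordingly.  Behavioural checks run on generated data: exact
k-d-tree/exhaustive agreement on 100 random 100-residue chain pairs,
strict-threshold classification at 7.9/8.0/8.5 Å through both file
formats, exact ground-truth recovery of the full pipeline on a 6-structure
bundle, and score monotonicity over 1000 random PAS records.  These sizes
keep the whole suite in the seconds range while exercising every code
path; they are the package's chosen test conditions, not tuned values.

## Known limitations

* No interface-area, residue-level contact-map or solvent-accessibility
  analysis: the minimum representative-atom distance is the only metric.
* Assembly generation from crystal symmetry is not implemented; inputs
  must be pre-expanded (or carry mmCIF assembly operators).
* MITAB parsing consumes only interactor columns 1–2; confidence values
  and method terms of interaction records are ignored.
* The PAS scorer presumes upstream role labelling is correct; nested
  events, anaphora, ellipsis and nominalizations are not addressed, and
  entity/compound ambiguity is deferred to manual curation.
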