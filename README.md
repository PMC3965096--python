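# negset

Derivation of **non-interacting protein (NIP) and domain pair datasets**
from three-dimensional structures of biological assemblies, curated
literature datasets and negated text-mining candidates.

Negative reference sets — protein pairs with evidence of *not*
interacting — are as important for training and benchmarking
protein–protein interaction predictors as gold-standard positives, but
far harder to obtain.  `negset` implements the structural derivation
rule, the dataset algebra and the text-mining triage score needed to
build such sets:

* **Structural NIPs** — in every biological unit, a chain pair is
  non-interacting when the minimum Cβ–Cβ distance (Cα for glycine)
  between the chains is strictly greater than 8 Å:
  `min over (i,j) of ||r_i − r_j|| > 8 Å`.  Chain pairs are consolidated
  to protein level via SIFTS-style chain→UniProt mappings; one observed
  contact anywhere falsifies non-interaction.
* **Domain pairs** — protein pairs expand to all PFAM domain
  combinations (A1–B1, A1–B2, A2–B1, …), from which known interacting
  domain pairs (3DID/iPFAM-style lists) are subtracted.
* **Stringent sets** — candidate sets minus pairs reported as
  interacting in a MITAB (PSI-MI TAB 2.5) interaction file, with
  before/after accounting and integer removal percentages.
* **Merging** — union of curated and structure-derived datasets over
  canonical (unordered) pairs, with overlap counts.
* **PAS triage** — pre-extracted predicate-argument structures are
  filtered to negated interaction verbs and ranked by a five-feature
  confidence score (argument length, sentence length, relation type,
  negation token, agent==theme); see `docs/methods.md` for the formula.

A seeded generator (`negset.fixtures`) produces complete synthetic input
bundles — structures in PDB and mmCIF, mapping tables, MITAB files, PAS
corpora — with machine-readable ground truth, so the entire pipeline is
testable without database downloads.

## Worked example

```sh
negset simulate --seed 5 --out sim
negset derive-structural sim/structures --out chainpairs.tsv
negset annotate chainpairs.tsv --mapping sim/chain_mapping.tsv --out nip.tsv
negset filter nip.tsv --known sim/known.mitab --out stringent.tsv
```

which prints

```
simulate: 6 structures, 6 expected NIP pairs, 4 stringent
filter: 6 -> 4 pairs (33% removed)
```

`simulate` generated six biological assemblies plus mapping and
interaction files; the derivation found the 6 protein pairs whose chains
stay beyond 8 Å in every assembly (matching `sim/expected_nip.tsv`
exactly), and subtracting the known-interaction file removed 2 of them
(33%), leaving the 4-pair stringent set.  Continuing,

```sh
negset expand-domains stringent.tsv --domains sim/domain_mapping.tsv --out dom.tsv
negset merge nip.tsv stringent.tsv --out merged.tsv
# merge: |A|=6 |B|=4 overlap=4 union=6
```

The same operations are available as a library:

```python
from negset import read_biounit, enumerate_chain_pairs, ContactConfig

unit = read_biounit("sim/structures/s000.pdb")[0]
for result in enumerate_chain_pairs(unit, ContactConfig(threshold=8.0)):
    print(result.chain_a, result.chain_b,
          round(result.min_distance, 2), result.non_interacting)
# ('A', 1) ('B', 1) 18.0 True
```

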