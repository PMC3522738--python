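# File formats

All tables are TSV with a header row. Coordinates are 1-based, inclusive,
on the ungapped reference sequence.

## Aligned FASTA (input/output)

One family per file; records `>Genus_species|ParalogName` (the paralog part
defaults to the family name, i.e. the file stem). Sequences use the 20
uppercase amino-acid letters plus `-` for gaps and must all have equal
length. Output wraps at 60 columns.

## Species registry (`--registry`)

| column | meaning |
|---|---|
| `species` | `Genus_species` identifier |
| `clades` | comma-separated clade labels (`protostome`, `deuterostome`, `echinoderm`, `hemichordate`, `cephalochordate`, `urochordate`, `vertebrate`, `teleost`, `amniote`, `mammal`) |
| one column per species | pairwise divergence time in billions of years (symmetric matrix, zero diagonal) |

## Residue annotations (`--annotations`)

| column | meaning |
|---|---|
| `species`, `paralog` | the member described (must be the family reference) |
| `structural_lysines` | comma-separated positions, empty for "none known", literal `unknown` for "no structural data" |
| `domains` | `label:start-end` items joined by `;` — list binding/interaction domains only |
| `predictor_hits` | comma-separated positions supported by an external ubiquitylation predictor |

## Copy table (`--copy-table`)

Columns `family`, `species`, `count` (observed gene copies, non-negative).

## Outputs

`scan` — `candidates.tsv`: `family`, `reference_position`, `scope`,
`strength`, `context`, `hydrophobic_offsets`, `rationale`;
`summary.tsv`: `family`, `total_lysines`, `conserved_lysines`,
`conserved_fraction`, `candidate_position`, `candidate_strength`,
`candidate_scope`, `context`.

`rates` — `rates.tsv`: `family`, `rate` (3 decimals), `n_pairs`;
`pathways.tsv`: `pathway`, `n_families`, `min`, `max`, `mean`;
`concordance.tsv`: `family_a`, `rate_a`, `family_b`, `rate_b`, `fold`,
`classification`.

`copynumber` — `events.tsv`: `family`, `species`, `expected`, `observed`,
`losses`, `gains`, `total_events` (weighted family total repeated per row).

`simulate` — `<family>.fasta`, `<family>.annotations.tsv`,
`<family>.truth.json`, optional `<family>.copies.tsv`.

## Precomputed rates (`rates --rates-from-table`)

Columns `family`, `rate`, optional `pathway`; used to summarize and test
concordance on rates computed elsewhere.

## Config file (`--config`)

Flat `key=value` lines (`#` comments allowed); keys are the long flag names
with `-` or `_`. Values act as defaults; explicit flags win.
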