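# hippolys

Phylogenetic prediction of monoubiquitylated lysines in Hippo-pathway
protein families.

Monoubiquitylation attaches a single ubiquitin to a lysine and acts as a
reversible "off/on" switch rather than a degradation signal. Because a
switch site must keep working across deep evolutionary time, candidate
lysines can be screened comparatively: a good candidate is **universally
conserved** across a broad species set, sits in a **conserved sequence
context** with a hydrophobic residue (I/L/V/M) at the −1 or −2 position, and
is **not structural**. `hippolys` implements that screen for protein-family
alignments spanning nine coelomate species (fly through human), together
with the two companion analyses used to corroborate it, and a
ground-truthed simulator so every stage is testable without downloads.

For each family alignment the package computes:

* **Conserved-lysine scan** — columns that are lysine in every member of a
  scope group (all species, or vertebrates only), each with a rendered
  context pattern such as `I/L/M-K-S/T` and a per-member hydrophobic
  −1/−2 test;
* **Candidate classification** — a deterministic strong/modest/none cascade
  over the evidence flags (scope, hydrophobic context, structural status,
  interaction-domain residency, sole-conserved-lysine, external predictor
  support);
* **Substitution rates** — per cross-species pair, p-distance → Poisson
  correction d = −ln(1−p) → rate d/(2T) with T the pairwise divergence time
  in billions of years; family rate = mean over pairs; interacting partners
  differing by >2-fold are flagged *discordant*;
* **Copy-number events** — expected copies per species under the vertebrate
  (2R, ×2) and teleost (3R, ×2) whole-genome duplications, and the per-tip
  gain/loss events implied by observed counts (gains costed 2, losses 1;
  see `docs/methods.md`);
* **Synthetic families** — sequences evolved down the nine-species
  ultrametric tree with planted conserved-lysine sites and exact truth
  records.

## Worked example

Simulate a family with one planted candidate — a universally conserved
lysine at position 120 in an `M-K-E-L-E` context inside a binding domain —
then scan it:

```sh
hippolys simulate --seed 11 --family-name SavLike --length 400 --rate 0.3 \
    --plant "120:M-K-E-L-E:all_species:domain" -o sim
hippolys scan -a sim/SavLike.fasta \
    --annotations sim/SavLike.annotations.tsv -o scan
```

`scan/summary.tsv`:

```text
family   total_lysines  conserved_lysines  conserved_fraction  candidate_position  candidate_strength  candidate_scope  context
SavLike  1              1                  100%                120                 strong              all_species      G/P-C/T-M-K-E-L-E-E/G/T-A/S
```

The reference has one lysine (the planted one: the simulator plants all
lysines explicitly), it is universally conserved (100%), and it classifies
**strong** — it is universal, non-structural, hydrophobic at −1 (the M),
inside a binding domain, and the family's sole conserved lysine, as
`scan/candidates.tsv` records
(`universal;nonstructural;interaction-domain;sole-conserved-lysine`). The
context grew beyond the planted `M-K-E-L-E` because at this substitution
rate the neighbouring columns stayed within three variants across the nine
species.

Rate summaries and partner concordance work directly on a table of family
rates (here the nine Hippo-pathway families with their published rates):

```sh
hippolys rates --rates-from-table rates_in.tsv --pairs pairs.tsv -o rates_out
```

`rates_out/pathways.tsv` and `rates_out/concordance.tsv`:

```text
pathway  n_families  min    max    mean
Hippo    9           0.151  1.379  0.599

family_a    rate_a  family_b       rate_b  fold  classification
Hippo_Mst   0.156   Salvador       0.821   5.26  discordant
Warts_Lats  0.298   Mats_Mob       0.151   1.97  concordant
```

The Hippo kinase and its co-factor Salvador evolve at rates differing more
than five-fold — discordant, suggesting distinct selective constraints —
while the Warts kinase and its co-factor Mats fall within 2-fold.

The library API mirrors the CLI (`hippolys.scan_family`,
`hippolys.family_rate`, `hippolys.count_events`,
`hippolys.generate_family`, …); file formats are documented in
`docs/formats.md` and the models in `docs/methods.md`.

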