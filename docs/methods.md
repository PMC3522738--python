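# Methods

`hippolys` implements a comparative-genomics screen for lysines likely to be
regulated by monoubiquitylation, applied to Hippo-pathway protein families.
This note records the models, the reconstructed rules, the numerical
conventions, and what the synthetic-data tests do and do not demonstrate.

## The prediction logic

Monoubiquitylation is a reversible "off/on" switch rather than a degradation
signal, and it targets lysines. The screen exploits the expectation that a
functional, switch-like modification site should be (1) conserved across a
broad species set, (2) embedded in a conserved sequence context with a
hydrophobic residue (I, L, V or M) at the −1 or −2 position, and (3) not
conserved merely for structural reasons. Structural status and
external-predictor support are *inputs* (curated annotation tables); the
package never infers them.

The species set is nine coelomates — one protostome (fly) and eight
deuterostomes up to human — with fixed pairwise divergence times: fly vs
deuterostomes 1.1 By; echinoderm 0.99; hemichordate 0.90; cephalochordate
0.75; urochordate 0.72; teleost vs amniotes 0.46; bird vs mammals 0.33;
mouse vs human 0.093. The species tree is a ladder, so two species' pairwise
time is the split depth of whichever lineage leaves the backbone earlier.

## Conservation scanning

A lysine is conserved over a scope group (all species, or vertebrates only)
when every scope member has `K` in the same alignment column; any gap or
substitution disqualifies the column. Sites are reported at the widest scope
in which they are conserved, on the 1-based ungapped coordinates of the
reference (human) member. Conserved fractions are `100·n/total` rounded
half-away-from-zero to one decimal, with a trailing `.0` dropped (so 21.875
renders as `21.9%` and 50.0 as `50%`), matching the conventions of published
per-family tables.

**Context window (reconstruction).** Published context strings vary in width
(−1..+1 up to −2..+4) without a stated rule. We grow the window outward from
the lysine, independently on each side, while the scope's residue set at the
next column is gap-free and has at most `max_variants` (default 3) distinct
residues, stopping at the first failure or at ±`max_window` (default 5).
`max_variants = 3` reproduces the widest printed variability (`I/L/M`).
Patterns render as `I/L/M-K-S/T`; `parse ∘ render` is the identity whenever
the candidate lysine is the first invariant-K field (an explicit center index
is accepted otherwise).

**Hydrophobic rule.** The upstream-hydrophobic test is evaluated per member
on its own ungapped sequence: every scope member must have I/L/V/M at its
own −1 or −2, and the satisfying offset may differ between members (e.g. M
at −1 in vertebrates, L at −2 elsewhere). Offsets that fall off the
N-terminus count as non-hydrophobic.

## Candidate classification (reconstruction)

The published strong/modest calls are narrative. The cascade below is the
minimal deterministic rule set consistent with all nine of them:

1. structural lysine → **none**;
2. hydrophobic rule fails → **none**;
3. universally conserved ∧ affirmatively non-structural ∧ at least one of
   {in/near a binding-interaction domain, sole universally conserved lysine,
   external predictor hit} → **strong**;
4. otherwise → **modest** (vertebrate-limited scope, unknown structural
   status, or no corroboration each cap strength).

Two operationalizations matter. "Just upstream of" a domain is a
configurable adjacency margin, default 10 residues. And the annotation table
lists only *binding/interaction* domains: a catalytic kinase domain is not
an interaction surface, which is why a universally conserved lysine upstream
of a kinase domain with no other corroboration classifies as modest while
one upstream of a dimerization interface classifies as strong. The cascade
is monotone: adding pro-candidate evidence never lowers the call.

## Substitution rates

For each cross-species member pair, the proportion of differing sites `p`
(pairwise gap deletion by default; complete deletion behind a flag) is
corrected for multiple hits with the Poisson model, `d = −ln(1 − p)`, and
normalized to a rate `d / (2T)` — both lineages accumulate substitutions
over the divergence time `T`. Within-species paralog pairs are excluded
because paralog divergence predates the speciation time that would
normalize them. The family rate is the arithmetic mean over pairs, reported
to three decimals (half-away-from-zero). Pathway summaries are the min, max
and mean of family rates at the same precision. Two interacting proteins
are *discordant* when their rates differ by strictly more than 2-fold
(configurable).

Exact reproduction of per-family rates from the original sequences is out of
reach (the accession lists and alignment versions are not available in
machine-readable form), so rate checks operate on the printed per-family
values and on simulations; the printed pathway means (0.599, 0.861, 1.184)
are reproduced exactly from the printed family rates.

## Copy-number event accounting

Vertebrates carry a stem whole-genome duplication (2R) and teleosts a
further one (3R). 2R is modeled as a single ×2 because the observed
expectation is two amniote copies per single-copy fly gene (not four);
teleosts get an additional ×2. A `LineageModel` fixes either the fly
baseline or a hypothesized post-2R ancestral-vertebrate count and predicts
expected copies per terminal species.

Accounting is tip-based: per species, `losses = max(expected − observed, 0)`
and `gains = max(observed − expected, 0)` copies. The event total weights a
gained copy at cost 2 and a lost copy at cost 1. The asymmetry is a design
choice: under a WGD-only history a loss is a single deletion, while a gain
must invoke a duplication outside the WGD framework, and gene-content
parsimony conventionally costs duplications above losses. The weighting also
breaks a degeneracy of the unweighted count — for the Tead-like profile
(4, 4, 3, 3 in mammals/bird/fish) the plain L1 total is 6 under both an
ancestral-vertebrate count of 4 and of 2, whereas the weighted count
uniquely selects 4 (6 events: one bird loss, five fish losses) and charges
the ancestral-2 hypothesis 11. Unit costs remain available
(`loss_cost=gain_cost=1`), under which one added observed copy moves a
species' contribution by exactly ±1. Shared losses are deliberately counted
once per terminal species (a loss "in each amniote" is three events); a
tree-parsimony mode that merges shared events onto internal branches is
deferred.

## The synthetic-data generator

Families are evolved down the ultrametric ladder tree implied by the
registry's divergence times. Per branch of duration `t`, each site receives
`Poisson(rate·t)` substitution events, each replacing the residue with a
uniformly chosen different one — multiple hits occur and can revert, the
regime the Poisson correction targets. Defaults are the study conditions:
the nine-species registry, 500-residue alignments, and a rate of 0.5
substitutions/residue/By (mid-range for the slowly evolving signalling
families this screen targets, whose observed rates span 0.151–1.379).

Ground truth is exact by construction:

* planted conserved-lysine sites freeze their context-string columns in the
  designated scope (variable positions are assigned round-robin so every
  listed variant is realized); outside the scope those columns evolve
  freely;
* lysine is excluded from ancestral draws and substitution targets at all
  non-planted columns, so no conserved lysine can arise by chance at any
  rate, including rate 0 — planted-site detection has precision and recall
  1.0 by design.

Truth strength labels are derived from the planted flags; for the label to
be deterministic the planted context must itself settle the hydrophobic
rule (cover −1 or −2 with an all-hydrophobic set, or cover both with
non-hydrophobic sets). Structural/predictor flags become annotation rows;
`in_domain` sites get a synthetic `binding` interval at position −5..+10.
Optional gap injection (testing pairwise deletion) never gaps the reference
or frozen columns; an optional per-species terminal-branch rate multiplier
supports discordance experiments. Everything is deterministic given the
seed.

**What the simulations do not show.** The generator has no indels (gaps are
injected post hoc), no across-site or across-branch rate variation by
default, uniform exchangeabilities rather than an empirical amino-acid
matrix, and one paralog per species. Passing tests therefore validate the
arithmetic and the detection logic, not robustness to alignment error or to
heterogeneous evolution in real families. Because the estimator's Poisson
correction ignores the finite (20-state) alphabet that the generator does
use, rate estimates carry a small downward bias (~2–3% at rate 0.3 over
this tree), well inside the 15% recovery tolerance checked at alignment
length 2000 over 20 seeds — sizes chosen to make the sampling error a small
fraction of that tolerance.

## Numerical conventions and degenerate inputs

* All rounding is half-away-from-zero (`decimal`-based), one decimal for
  percentages, three for rates.
* `p = 1` raises a saturation error rather than returning infinity; columns
  with a gap in either sequence are skipped, and a pair with zero comparable
  sites is an error.
* Conserved-fraction with zero total lysines is an error at the operation
  level; family summaries render the empty case as `0%`.
* Hypothesis ranking is a stable ascending sort; equal event totals keep
  input order and are flagged as ties.
* A conserved column in which the *reference* is gapped is reported with a
  null reference position and flagged rather than dropped.

## Known limitations

* The context-window rule and the strong/modest cascade are reconstructions
  constrained by nine published calls; other rule sets consistent with the
  same calls exist.
* The exact "overall rate" procedure behind the published per-family values
  (mean pairwise vs tree-based, and the divergence normalization used) is
  unstated; this package defines and documents its own (`d/(2T)` mean over
  cross-species pairs) and does not claim to re-derive the printed rates
  from raw sequences.
* Event accounting is per-tip; shared internal-branch losses are over- and
  shared gains under-counted relative to full tree parsimony.
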