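# Methods

## The model of a GPR rule

A gene–protein–reaction rule is a Boolean expression over gene identifiers.
Its intended semantics is structural: an `and` node is an enzyme complex
whose subunits are all required; an `or` node joins catalytically
independent alternatives (isoforms, or whole alternative complexes). The
empty rule means no gene product is required.

Expressions are normalized on construction: associative nesting is
flattened (`a or (b or c)` → a single three-child `or`), duplicate children
are removed, and children are ordered deterministically by their gene-set
signature. Normalization is purely syntactic — no Boolean simplification
beyond idempotence — so the printed rule stays close to what the evidence
supported. The assembly procedure emits at most or-of-ands depth; deeper
nesting can only enter through parsed input and is preserved.

Two conventions are fixed deliberately:

* **The empty rule evaluates to false**, but gene-deletion analysis never
  constrains a reaction carrying it: a no-gene reaction cannot be knocked
  out by deleting genes. Keeping "false" as the evaluation value makes the
  truth table of the empty rule well defined (the single row `F`).
* **Jaccard of two empty gene sets is 1.0** — equal sets must score as full
  overlap, otherwise a correctly reconstructed no-gene rule would count as
  total gene-content disagreement.

## Equivalence decision and the gene cap

Two rules are equivalent iff their truth tables over the union of their
gene sets agree on all 2^N rows. Enumeration is exact and cheap up to the
cap of **20 genes** (the default, configurable), the conventional threshold
beyond which the 2^N tables become impractical. Above the cap the decision
falls back to canonical forms: flatten, deduplicate, absorb
(`x or (x and y)` → `x`), sort. Canonical equality ⇒ equivalent; canonical
inequality is decisive (not equivalent) whenever neither rule is of MIXED
class, because for pure-`and`/pure-`or`/one-gene/no-gene rules equivalence
reduces to gene-set equality; a MIXED mismatch above the cap is reported
INDETERMINATE rather than guessed. The acceptance suite checks the under-cap
decision against an independent brute-force evaluator over all assignments
on 1,000 random expression pairs.

The Hamming similarity between truth tables is oriented as a similarity
(1 = identical, 0 = complementary) and is only attached to negative matches
whose gene sets already coincide: with different gene sets the variable
order of a joint table is not well defined, so gene-content disagreement is
reported through the Jaccard index alone.

The **global Jaccard** index is computed by default over the pooled gene
sets (union of all genes in original rules vs union over generated rules);
a per-reaction mean is available as `method="mean"`. Both definitions are
reasonable readings of "gene coverage across all reactions"; the pooled one
is the default because it measures exactly the phrase "expected genes
present through all reactions" without weighting by rule size.

## Metabolite matching

Model metabolite labels are resolved by a cascade ordered from most to
least trustworthy: a user-extensible **alias table** (shipped with four
curation cases: the acyl-carrier protein written `ACP1`, the
NADPH↔ferredoxin dependency, electron-transfer flavoproteins resolved via
FAD/FADH2, and `diglyceride` for 1,2-diacyl-sn-glycerol), then exact
case-insensitive name/synonym lookup, then InChI string equality when the
query carries one, then fuzzy scoring. The fuzzy score is a token-sort
ratio: both strings lowercased, tokenized, tokens sorted and re-joined, and
similarity computed as `round(100·2M/(len(a)+len(b)))` via
`difflib.SequenceMatcher` — the same Levenshtein-flavoured ratio the
classic fuzzy-matching packages compute, robust to word-order variation in
metabolite synonyms. A candidate is accepted automatically only when it is
the *unique* best scorer at or above the **threshold of 91**, a calibration
chosen to exclude clearly wrong matches; everything else returns a
descending shortlist for confirmation. In non-interactive runs the
documented default is to accept the shortlist top and log the decision; an
answer file can override any label.

## Macro database and reaction matching

Reaction records from all sources are merged into one store keyed by a
canonical signature: the two sorted participant multisets (compound id +
stoichiometric coefficient, kept as exact rationals), taken as the
lexicographically smaller of the two side orderings so that a reaction
written in either direction hashes identically. Sources disagree on written
direction; reversibility metadata is not part of identity. Merged entries
take the union of sources, cross-references, EC numbers and genes, and the
merge is idempotent and order-independent. Protons/water are *not* excluded
from signatures by default — silent participant dropping changes reaction
identity — but a config set of ignorable compound ids is available.

Transport reactions are recognized by a compound appearing on both sides
with different compartment tags; their genes are the union over transporter
records listing any transported substrate, merged with any macro-database
hit for the same participants.

The localization filter keeps a gene iff its *effective* localization set —
manual annotation terms when any exist, otherwise automatic predictions,
otherwise unknown — intersects the reaction compartment's admissible terms
(a small configurable vocabulary maps compartment tags like `c`/`m` to
terms like cytosol/mitochondrion). Genes with no localization data are
kept: the filter is a refinement, and a false drop is costlier than a false
keep at this stage.

## Relationship mining

Five evidence channels produce pairwise SUBUNIT/ISOFORM labels:

| channel | label | mechanism |
|---|---|---|
| annotation text, Interaction section | SUBUNIT | keyword sentences naming another universe gene |
| annotation text, Function section | SUBUNIT | same, separate source tag |
| complex records | SUBUNIT | co-membership in a complex |
| interaction network | SUBUNIT | neighbour sharing a complex-flagged enrichment term |
| orthology groups | ISOFORM | shared functional-ortholog identifier |

The keyword list is the one a frequency analysis of curated annotation text
surfaces — monograms *complex*, *component*, *interact* (stem-tolerant, so
"interacts"/"interaction" match) and the qualifier *by similarity*, plus the
phrases *interact with*, *part of a complex with*, *consist of*, *associate
with*, *heteromerization with* — and is configurable. Gene recognition
inside sentences is exact token match against the organism's symbol/synonym
universe, case-insensitive; no approximate matching is attempted inside
sentences, to avoid inventing partners. The *by similarity* qualifier is
recorded on the evidence but does not change the label: there is no
principled weight for propagated vs direct assertions, so the distinction
is preserved for the reader rather than consumed. Binary "interacts with"
statements are treated as complex-participation (SUBUNIT) evidence; the
Function section is mined for SUBUNIT evidence only.

Conflicts for a pair are settled by source priority, default
`complex_portal > uniprot_interaction > uniprot_function > string >
kegg_orthology` (manually curated structured data over curated text over
predictions), and logged. Pairs with no evidence at all default to ISOFORM:
in the absence of any complex evidence the safe reading is "independent
alternatives", which is also what makes unevidenced multi-gene reactions
come out as flat `or` rules.

## Assembly

Connected components of the SUBUNIT subgraph become `and` groups, joined by
`or` together with the isolated genes. Pairwise labels cannot represent a
gene shared between two *alternative* complexes — the shared gene would
merge them into one component — so when explicit complex sets are supplied
and a gene belongs to two complete complexes within the reaction's gene
set, each complex becomes its own `and` group and the shared gene is
duplicated across groups. Without complex sets the merged-component
interpretation is used and flagged. ISOFORM labels that end up inside an
AND-connected component are tolerated (component membership wins) and
logged as inconsistencies.

## Gene-deletion validation

The solver contract is plain flux-balance analysis: maximize the biomass
flux under steady-state stoichiometric equalities and flux bounds. The
implementation delegates the linear programs to COBRApy/GLPK but drives
the knockouts with this package's own rule evaluation: deleted genes are
set false, every reaction whose rule evaluates false gets zero bounds,
and the optimum is recompared to the positivity tolerance of **1e-9**
(configurable; the criterion is "positive biomass flux"). The test suite
cross-checks the calls against COBRApy's own GPR-driven knockout machinery
on the toy model, keeping the two routes independent. Deletion is monotone
by construction — closing more reactions can only shrink the feasible
region — and the suite asserts this on the toy model over all deletion
pairs and triples.

## Synthetic fixtures: what they emulate, and what not

The generator plants rules with a class mix defaulting to ~30% no-gene,
~45% one-gene and ~25% multi-gene (split 12/8/5 across OR/AND/MIXED),
matching the gross composition reported for well-curated metabolic models.
Complex sizes default to 2–4 members (60/30/10%), isoform groups to 2–3
(60/40%). Every planted complex is witnessed through three independent
channels (complex record, templated annotation sentences built from the
keyword phrases above, network clique with a shared complex term), each
enabled with probability `evidence_completeness`; isoform groups become
orthology groups. Distractor sentences use gene-like tokens absent from
the universe; metabolite labels are perturbed by letter doubling at rate
`name_perturbation` to exercise the fuzzy matcher. Reactions get unique
marker compounds so signatures never collide.

What passing tests on these fixtures shows: the pipeline's mechanics are
lossless — when the databases contain the evidence in the forms the miner
understands, the planted structure is recovered exactly (the correctness
ceiling), and recovery degrades monotonically as evidence is withheld.
What they do not show: performance on real annotation text, which is far
less uniform than the templates (free-form phrasing, nested clauses,
organism-specific nomenclature), on inconsistent cross-database identifiers,
or on genuinely ambiguous metabolite names. Real-data accuracy is bounded
by database annotation quality, not by this machinery.

Default problem sizes (60–300 reactions in tests and the acceptance script)
keep the whole suite in seconds while drawing every rule class tens of
times; the generator scales linearly if larger fixtures are wanted.

## Known limitations

* Truth-table comparison above the 20-gene cap is conservative: MIXED
  mismatches return INDETERMINATE rather than a verdict.
* Text mining is tokenization plus keyword matching — no syntactic parsing;
  a sentence naming a gene in a negative context ("does not interact with
  X") would still yield evidence.
* Transport matching keys on transported substrates only; TC-code semantics
  (mechanism, family) are carried but unused.
* The compound ontology parents are stored but not used for fallback
  matching to parent classes.
* EC-number-based gene inference is out of scope; genes enter only through
  reaction records, transporter records and the mining channels.
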