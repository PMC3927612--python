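# Methods

## Homology subtypes and the quantity of interest

For multidomain proteins the classical homology subtypes (orthology,
paralogy, pseudoparalogy) are incomplete: two proteins can be related only
through the independent acquisition of the same mobile domain family —
epaktology. Epaktologs necessarily differ in domain architecture (DA) and
usually at terminal positions, so any paralog set contaminated with them
overstates the rate of DA change and biases its positional spectrum toward
the termini. Everything in this package exists to (a) separate the two
relationships from similarity data alone and (b) measure how badly the
statistics are distorted when that separation fails.

## TSS networks and components

From an all-against-all hit table, the TSS=k dataset keeps for every query
its k best non-self subjects with e < 1e-5. Ranking is by descending bit
score; the tie-break chain (ascending e-value, then lexicographic subject
id) makes the lists deterministic even where scores saturate. For k' > k
the k-list is a prefix of the k'-list, so the per-k graphs are nested.

The directed network has an edge u→v iff v is in u's list. Strong
components are computed on the directed graph, weak components on its
undirected shadow (both via networkx). The directed reading is what gives
strong components their robustness: an epaktolog may point at its victim
through a one-way best-hit edge without the victim's family pointing back,
which joins the pair in weak but not in strong analysis. A query's
component across k = 1..20, and the per-k counts of components with ≥ 2
members and the largest-component size, reproduce the qualitative
signatures: counts fall and the weak LCC grows with k until shuffled-domain
families coalesce into a giant component; strong-component growth lags by
several k. The "absorbed into the LCC" flag in `trace_query` fires when the
query's component exceeds a configurable 20% of the vertices, since the
giant component is otherwise only qualitatively defined.

Component counting reports clusters with ≥ 2 members as "families"; the
full partition with singletons is also emitted (a singleton strong
component means "no paralog identified" at that k).

## Interspecies clustering and duplication timing

Queries are compared against one target proteome at a time; each query maps
to its best subject at e < 1e-5 (same ranking key as above), and queries
sharing a best subject form a cluster — equivalent to weak components of
the bipartite query/best-subject graph. A duplication younger than a target
species' divergence leaves one ortholog there, clustering the two
descendant queries; a duplication older than the split yields 1:1 matches.
Walking species from the oldest split to the youngest, the transition from
"clustered" to "1:1" brackets the duplication between the two adjacent
split times. 1:1 everywhere places the duplication before the oldest
sampled split (open interval toward the past); clustered everywhere places
it after the youngest split; a pattern that reverts from 1:1 back to
clustered is flagged UNRESOLVED rather than treated as an error, because
incomplete target proteomes produce exactly this artifact. Divergence times
are configuration data, never inferred; the defaults used in examples are
910 My (pre-deuterostome splits) and 800 My (early deuterostomes).

## DA construction and difference classification

Annotations (protein, family, 1-based inclusive coordinates, e-value) are
thresholded at a cutoff and greedily accepted in order of ascending e-value
(ties: longer hit, then smaller start); a hit is rejected if it overlaps an
accepted hit by more than 30% of the shorter hit's length. The accepted
hits in start order are the DA. The 30% tolerance is a design choice —
"overlapping hits were eliminated" admits many readings — and relaxing the
cutoff can only append domains (the stricter hit set is a prefix of the
looser acceptance order), which the tests assert.

Two DAs are aligned by longest common subsequence over family tokens, with
the leftmost LCS chosen for determinism. Every unmatched domain is
classified relative to the matched positions on its own sequence: before
the first match → N-terminal, after the last → C-terminal, otherwise
internal; an unmatched domain lying in a contiguous run of its own family
that also contains a matched copy is a tandem duplication difference
instead, and this rule deliberately takes precedence over the terminal
categories (the precedence is not dictated by the classification itself;
one rule had to be chosen). A pair with no unmatched domain is identical;
with no matched domain, positionally unassigned. The per-pair result is a
category *set* — one pair can be both N- and C-terminal, as tandem-shuffled
epaktologs typically are.

Pairs are classified at four cutoffs (1e-2, 1e-3, 1e-4, 1e-5; strict `<`),
giving four assignments per pair; positional distributions pool all four,
counting each category of an assignment once, so totals may exceed four per
pair. Domain-count differences and transition types (1↔2, 2↔3, N↔N+1 with
N>2) are taken at the 1e-5 DA, and cluster homogeneity is judged at 1e-5
only. The rate bound divides the percent of differing within-cluster
comparisons by an upper bound on the duplication age and is reported to two
significant figures; it is a lower bound on the true rate because the
denominator is an upper bound.

## The simulator

The generator is the package's test bed: it must reproduce the mechanism
(tandem-amplified shared mobile domains inflating epaktolog scores) with
known truth, not mimic any particular database.

*Model.* A fixed ultrametric ladder species tree (split times are
configuration). Root genes carry disjoint non-mobile domain families so
that unrelated lineages share no family by construction; mobile families
enter only through shuffling insertions. Six event kinds occur as Poisson
processes per gene copy per My: gene duplication, terminal gain, internal
gain, loss, tandem duplication, shuffling insertion. Sequences are
per-family random templates of 20 amino acids; instances evolve by i.i.d.
substitutions at `substitution_rate` (default 2e-4 per site per My) along
branches. There are no indels, so domain coordinates stay exact; no
horizontal transfer, no domain-boundary erosion, no nucleotide-level exon
structure — only the protein-level outcome of shuffling.

*Determinism and replay.* Event sampling, template generation and branch
mutations use separate seeded RNG streams (mutation streams are keyed by
branch and instance), so the discrete event log plus the seed fully
determine the proteome: `replay_log` re-applies the log to the ancestral
state and reproduces every protein byte for byte, which is asserted in the
tests. Events that cannot take effect (loss on a single-domain gene) are
dropped before they are logged.

*Labels.* Ortholog: same lineage, different species. Paralog: same root
gene, lineages separated by a duplication. Epaktolog: different root genes
sharing a mobile family acquired by *distinct* shuffling-insertion events
(inheritance of one insertion through duplication never counts). Everything
else is unrelated. Labels come from the event history, never from
sequences.

*Scoring.* The built-in all-against-all comparison scores a pair as the
best colinear chain of same-family instance pairs, each contributing
identity × length × 2 bits, with pseudo e-value 10^(−bits/10) clamped to
[1e-180, 10]. Only ordering and the 1e-5 threshold matter downstream; the
chain construction is what reproduces the score inflation of tandem arrays
(score grows roughly linearly in the number of aligned copies, asserted as
a monotonicity test). Domain annotations map instance identity to the
template through log10 e = −(identity% − 35) × 0.35; instances under 35%
identity are dropped, which makes architectures genuinely
cutoff-dependent (hits between ~35% and ~49% identity pass 1e-2 but not
1e-5).

*The confusion presets.* `shuffle_internal_config` /
`shuffle_terminal_config` script the canonical scenario: gene A (`a-b`)
duplicates at 600 My; gene X (`x-z`) receives a mobile `s` insertion at
900 My, three tandem duplications, then duplicates at 500 and 450 My; an
independent `s` insertion into one A copy at 400 My is amplified likewise.
The variants place `s` internally (`a-s⁴-b` vs `x-s⁴-z`) or terminally
(`s⁴-a-b` vs `x-z-s⁴`). With the default substitution rate the expected
scores order as X-paralogs (~590 bits) > A1*–X epaktologs (~370) >
A1*–A2* paralogs (~190): the epaktolog outranks the true paralog, yet each
tandem-carrying X protein reciprocates with its own paralogs, so strong
components at k ≤ 2 stay paralog-pure while weak components absorb the
epaktolog immediately. Giving the X family three members is essential —
with only two proteins carrying the array, the two epaktologs would be
mutual best hits and form a two-cycle that no component analysis can
split; the same asymmetry protects real families, where the partner family
of a shared mobile domain has close paralogs of its own. The two-species
variant adds an outgroup diverging at 950 My (before all scripted events)
whose unmodified `a-b`/`x-z` proteins act as pre-duplication anchors for
interspecies clustering; the three-species preset (splits at 910/430 My,
duplications at 700 and 150 My) exercises duplication timing.

*What the simulator does not emulate.* Real proteomes have unbalanced
family sizes, domain-length variation within families, indels, erosion of
domain boundaries, annotation noise that is not a monotone function of
identity, and database redundancy/incompleteness (the last is emulated only
by deleting subjects from a target proteome). Passing tests therefore
demonstrate the correctness and the qualitative mechanisms of the pipeline,
not genome-scale numerical agreement with any protein database snapshot.

## Experiments and problem sizes

The benchmark module runs three experiments, sized to finish in seconds:

- *Separation* (50 seeds, both presets): per seed, whether the epaktolog
  outscores the paralog, whether strong components at k ≤ 2 are
  epaktolog-free with paralog precision 1.0, and whether weak components at
  k = 3 admit an epaktolog pair. Precision is paralog pairs over
  within-component pairs; recall is recovered paralog pairs over all.
- *Contamination* (20 seeds × levels 0/20/50%): paralog pairs come from a
  six-gene, one-genome simulation with moderate duplication/gain/loss
  rates (8e-4 / 3–4e-4 / 2e-4 per My — chosen so that a realistic fraction
  of paralog pairs differ, some internally); epaktolog pairs come from the
  confusion preset and are injected to the stated fraction of the pair
  set. Reported: percent of pairs differing at 1e-5 and the terminal share
  (N+C over N+C+internal, in percent — a share rather than a ratio so the
  statistic stays finite when internal counts reach zero at high
  contamination). Both must rise monotonically with the injected fraction.
- *Insertion positions* (10,000 pairs): base DAs of 3–6 distinct domains
  with one new domain inserted at a uniform slot — all N↔N+1 transitions
  with N ≥ 3. Internal slots outnumber the two terminal slots, so the
  internal proportion (~61%) must exceed each terminal proportion (~19%);
  this is the capacity argument for why type-3 transitions are the right
  place to look for positionally unbiased insertion.

`scripts/acceptance.py` reruns all of the above plus a 200-digraph
comparison of the component code against a brute-force transitive-closure
oracle and a monotone-coarsening audit over k = 1..20 on random and
simulated hit tables, and writes the numbers as JSON.

## Numerical and degenerate-input choices

E-values are clamped to [1e-180, 10] to avoid log-domain underflow; all
ranking ties end in lexicographic ids so outputs are reproducible across
platforms. Empty hit tables, empty annotation tables, queries without
qualifying hits, clusters of size < 2 and all-identical record sets are
handled with warnings, never exceptions; malformed hit-table rows fail fast
with the line number. Percentages over empty denominators are NaN, not 0.
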