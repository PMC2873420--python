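# Methods

## Scope and model

`rfxsurvey` re-implements a comparative survey of RFX transcription factors
(defined by a 76-aa winged-helix DNA-binding domain, DBD) and ciliary IFT
genes as a reusable, fully testable pipeline.  The survey's unit operations
are: pairwise protein alignment with a corrected-identity statistic,
anchored acceptance rules, iterative query expansion over ordered taxon
groups, one-way best-hit conservation scanning, distance-based phylogeny
with clade assignment, ungapped profile scanning, and a four-way
co-occurrence classification.  Everything runs at desk scale on synthetic
proteomes with known ground truth; no genome downloads are involved.

## Alignment and scoring

Local (Smith–Waterman) and global (Needleman–Wunsch) alignments use integer
BLOSUM62 scores with affine gap penalties: a gap of length *g* costs
`gap_open + g·gap_extend`, defaults 11/1 — the de facto standard for
protein search.  The original survey's search tool predates this package
and did not record its scoring parameters, so the classic defaults are used
as the least surprising choice; exact reproduction of historical raw scores
is not attempted.  `X` scores 0 against every residue and never counts as
identical.

The acceptance statistic is the **corrected percent identity**:
identical aligned columns divided by the *full ungapped query length*,
×100.  Dividing by the query length (not the aligned length) is what makes
it "corrected": a perfect match to half the domain scores 50, not 100.

Tie-breaking is deterministic so outputs are byte-reproducible: the end
cell is the maximum-scoring cell at the smallest (query, target)
coordinate, and the traceback prefers diagonal moves (fewest gaps), then
gaps in the target.  The DP kernels are compiled with numba; correctness is
pinned by an exhaustive alignment-enumeration oracle on short sequences and
cross-checked against an independent aligner's scores.

**Significance.**  Analytic e-value statistics are replaced by an empirical
composition-preserving shuffle test: the target is permuted *n* times
(default 199, minimum 99) and `p = (1 + #{null ≥ score}) / (n + 1)`.  Hits
are retained at `p ≤ significance_alpha` (default 0.01).  The estimator is
distribution-free, seedable and super-uniform under the null.  One
consequence, verified by the tests: when a best hit is selected over many
decoy proteins or queries before testing, stray significant hits appear at
roughly the nominal rate per comparison.  They carry PIDs far below every
downstream threshold (classification tiers, the ciliation floor), so the
survey's calls are unaffected; the per-pair test is kept because it is the
transparent analogue of a per-hit e-value cut-off.

## Tiered classification

A significant hit is **RFX** iff PID ≥ `pid_accept_threshold` (default 40)
and all nine DNA-contact anchor residues are conserved — inside the aligned
interval, aligned to a residue, and identical.  It is **RFX-like** iff it
fails the RFX rule but has PID ≥ `pid_rfxlike_floor` (default 25) and ≥ 5
anchors.  The floor of 25 sits below the known RFX-like exemplars (29 % and
27 % PID with 5/9 anchors) while excluding random hits, which rarely exceed
~20 % PID or 2–3 anchors.  RFX-like calls are reported but never counted as
RFX genes.  Within a species, calls are named cRFX1, cRFX2, … by descending
PID.

## Iterative survey and query expansion

Taxon groups are processed in a fixed order.  Within a group every species
is searched with the query list frozen at group start (order independence
within the group); afterwards the extracted DBD of each new RFX-tier hit
joins the query list, deduplicated by exact sequence.  Anchors of an
expanded query are the target positions aligned to the parent query's
anchors — because RFX-tier acceptance requires all nine conserved, the
mapping never loses anchors and every expanded query stays rooted in the
seed's anchor geometry.  Only the best hit per protein is kept (no known
RFX protein carries two DBDs).  Expansion is monotone: the calls with
expansion ON are always a superset of calls with it OFF.

## IFT conservation and ciliation

Each of the 24 ciliary queries (Motors 5, Complex A 4, Complex B 9, BBS 6)
is aligned against the whole proteome; the matrix cell is the best hit's
corrected PID if its shuffle-null p-value passes `significance_alpha`, else
absent.  Orthology is one-way best hit by design — no reciprocal-best
filtering.  The original survey took each species' ciliation status from
the literature; because the co-occurrence classification needs a computable
flag, a surrogate is provided: ciliated iff ≥ `cilia_call_fraction`
(default 0.5) of queries have cells at PID ≥ `cilia_call_min_pid` (default
20), boundary inclusive.  Both knobs live in `RunConfig`, and a per-species
manifest override replaces the computed flag where curated knowledge
exists.

## Phylogeny

Distances between DBDs are Poisson-corrected p-distances: global-align the
pair, count mismatched residue columns over residue columns (gap columns
excluded), return −ln(1−p), capped at p = 0.95 (distance ≈ 3.0) to keep
deeply diverged pairs finite.  Pairwise alignment replaces a progressive
MSA here: DBDs are near-equal-length and highly similar, where pairwise and
MSA-column p-distances agree closely.  Arguments are ordered canonically
before aligning so the distance is exactly symmetric even when co-optimal
alignments differ in column composition.

Trees are inferred with Saitou–Nei neighbor joining (Studier–Keppler
Q-criterion), lowest-index tie-breaking, negative branch lengths clamped to
zero with the deficit moved to the sibling branch.  NJ's consistency
theorem — exact recovery of topology and branch lengths from additive
matrices — is the module's primary oracle; an independent NJ implementation
and Robinson–Foulds comparison provide the cross-check.  Clade assignment
gives each query leaf the group of its nearest reference by tree-path
length; ties (within 1e-9) are UNASSIGNED rather than forced.

## Profiles and architectures

The non-DBD domains (AD, B, C, D, DD) are detected with ungapped log-odds
profiles built from small aligned instance sets: column score
`ln((count + pc·b_r) / ((n + pc)·b_r))` with Laplace-style pseudocount
`pc = 1` against Robinson–Robinson background frequencies.  Full profile
HMMs with insert/delete states are deliberately out of scope: the target
domains are short, the downstream use is presence/absence, and the
interface admits a gapped drop-in later.  Acceptance thresholds are
calibrated per profile as the 0.99 quantile of best-window scores over
1 000 random background proteins of 300 residues.  Architecture strings
merge profile windows with the DBD call, resolve overlaps by score (the
DBD, scored on the alignment scale, always wins), and list accepted domains
by start coordinate.

## Synthetic data: what it does and does not emulate

Generators draw decoy residues i.i.d. from Robinson–Robinson frequencies;
implants substitute each site independently with probability *d* to a
*different* residue drawn from the background (anchors optionally exempt);
clade series apply a Poisson number of substitution events per branch
(rate = branch length × non-anchor sites) at uniform non-anchor sites.  No
indels are introduced, so corrected PID and anchor counts have exact
closed forms — e.g. an anchors-preserved implant at divergence *d* has
E[PID] = 100·(1 − d·67/76) — which the tests assert directly.  Branch
lengths of zero are legal (identical domains); negative lengths are errors.

Consequently the simulations exercise detection, thresholds, iteration,
tree recovery and state classification exactly, but they do not emulate:
insertions/deletions within domains, compositional bias or low-complexity
regions, paralog interference, gene structure, or regulatory features
(X-box motifs).  Passing tests demonstrate the machinery's correctness
under the stated model, not performance on real proteomes.

## Numerical and design choices

- Scores are exact integers end to end; only distances, PIDs and profile
  scores are floats.
- Every stochastic step takes an explicit seed; per-item child seeds are
  derived by CRC-mixing stable identifiers, keeping all seeds below 2³¹.
  Reruns are byte-identical, which the end-to-end test asserts.
- Problem sizes used throughout (50-protein proteomes, 99–199 shuffles,
  1 000-protein profile nulls, 100 additive trees, 500-trial null
  calibrations) were chosen as the smallest sizes at which the binomial /
  closed-form bounds quoted in the tests are sharp; they run in about a
  minute on one CPU.
- The degenerate inputs each operation must survive are pinned by tests:
  empty proteomes, score-0 alignments, saturated distances (p ≥ 0.95),
  proteins shorter than a profile, species sets with no calls.

## Known limitations

- No DNA-level (six-frame) search of unannotated genomes; protein inputs
  only.
- No heuristic seeding: full DP per pair, fine at desk scale, not at
  153-genome scale.
- One-way best hits cannot separate orthologs from paralogs.
- The RFX-like floor (25 %) and the ciliation surrogate knobs are
  conventions, not estimates; both are configurable.
- Bootstrap support, maximum-likelihood trees and ancestral-state
  reconstruction are out of scope.
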