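# Methods

This note documents the models and procedures `pulkit` implements, the
parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model and coordinates

Genes are stored 0-based half-open internally; all GFF3 I/O converts
from/to the external 1-based inclusive convention, making the
conversion a bijection and interval/adjacency arithmetic unambiguous.
Gene identity is the GFF `ID` attribute with `locus_tag` as fallback,
matching the common prokaryotic annotation dialects.  CDS features
without a protein sequence in the accompanying FASTA are dropped with a
logged count rather than failing the run, since draft annotations
routinely contain pseudogenes and partial calls.  Floats are serialized
with 6 significant digits and tables sorted by primary key so repeated
runs are byte-identical.

## Consensus annotation

A CAZyme family is assigned to a gene only when at least two of the
three CAZyme sources (Pfam HMM, dbCAN HMM, CAZy BLASTp) report it at or
above their acceptance thresholds.  Family labels are normalized to the
parent family (GH5_46 → GH5) for voting and rule matching; verbatim
labels are retained for reporting.  Two consequences worth noting:

* the vote is per family, so a gene may legitimately carry several
  families (e.g. GH + CBM);
* adding evidence can only add families, never remove them
  (monotonicity), which the property tests assert.

Role calls: SusC-like from the TIGRfam model TIGR04056; SusD-like from
the Pfam models PF12741, PF12771 or PF14322; the two roles are mutually
exclusive on one gene, resolved by the higher score relative to its
threshold, with the conflict logged.  A gene matching a generic TBDT
profile (default list PF00593, PF07715) without TIGR04056 is flagged
`tbdt_non_susC`.  Sulfatases come from SulfAtlas evidence with the S1
subfamily recorded; peptidases from MEROPS.

**Thresholds.** HMM-type sources (pfam, dbcan, tigrfam, sulfatlas) are
filtered at ≥ 25 bits; BLAST-type sources (cazy_blast, merops) carry
−log₁₀ E-values and are filtered at ≥ 4 (E ≤ 10⁻⁴, the usual MEROPS
default).  The original annotation protocols used family-specific
cutoffs that are not reproduced in any table available to this package;
the flat defaults are therefore documented stand-ins, exposed in
`AnnotationConfig` so users with curated cutoffs can supply their own.

**Degradative CAZymes** are genes carrying at least one GH, PL or CE
family.  CBM-only and AA-only genes bind or assist but do not cleave,
so they are excluded from the count, from the per-Mbp statistic, and
from the peptidase:CAZyme ratio denominator (reported as missing when
that denominator is zero).

## PUL detection

PUL identification in comparative genomics is traditionally manual.
The formalization here: signature genes are those with a consensus
CAZyme family or one of the roles susC, susD, tbdt_non_susC, sulfatase.
Maximal runs of signature genes in which consecutive signature genes
are separated by at most `gap_tolerance` non-signature genes form
candidate clusters; intervening non-signature genes become member
genes.  A cluster is emitted as a PUL when it has at least
`min_cazymes` CAZyme genes, or at least one CAZyme gene together with a
susC–susD tandem.  A susCD pair without any CAZyme is a transporter
locus, not a PUL.  Single-gene clusters are never emitted.

* `gap_tolerance` default 3: published PUL figures routinely include a
  few interspersed hypothetical genes; 3 reproduces such architectures
  while keeping independent loci separate.  Because the underlying
  curation practice is manual, this default is a calibration choice,
  echoed into the run manifest so downstream users can see it.
* `min_cazymes` default 2: "CAZyme cluster" implies more than one
  enzyme; the OR-branch keeps a lone CAZyme adjacent to a susCD tandem.
* susC–susD pairing allows ≤ 1 intervening gene and ignores strand
  (tandem pairs in genome diagrams are adjacent or nearly so; strand is
  not part of the published criterion).  Pairing is greedy by distance
  with deterministic tie-breaks.

Completeness: `complete` (≥ 1 pair), `no_susD` (susC without a paired
susD — including the rare case of a susD too far away to pair),
`tbdt_only` (generic TBDT, no susC), `no_susCD`.  All three incomplete
subtypes still count as PULs.

**Putative susE.** No public profile detects SusE-like proteins, and
inventing one silently would overstate the annotation.  By default the
gene on the far side of a paired susD (away from its susC), inside the
cluster and otherwise unannotated, is flagged as putative susE; this
positional heuristic is symmetric under gene-order reversal, so
detection output is orientation-invariant.  Users with curated SusE
evidence labels can list them in `AnnotationConfig.susE_labels`
instead.

## Substrate rules

Rules are declarative: required family counts, "≥ n distinct families
of this set" clauses, forbidden families, tri-state constraints on
PUL-internal sulfatase genes and on a susCDE triplet, and a priority.
Variant rules rank before class-level fallbacks; all matches are
evaluated and non-best matches reported as ambiguity, so a
classification is never silently exclusive.  Classification is a pure
function of the PUL's family multiset, sulfatase count and susCDE
status — deliberately composition-based, not synteny-aware.

Choices within the shipped table:

* Laminarin variants C and D share the same diagnostic content
  (GH16 + GH30 + GH5/CBM6, no GH17); absent a family that separates
  them they are reported jointly as variant "C/D".
* "≥ 2 of {PL6, PL7, PL17}" (alginate) counts *distinct* families: two
  paralogs of one lyase family are weaker evidence for an alginolytic
  system than two different lyase families.
* The sulfatase tri-state consults PUL-internal sulfatase genes only;
  genome-wide sulfatase content says little about one locus.
* The trehalose-like α-1,1-glucan signature is a conservative
  placeholder (GH37 trehalase) pending a vetted family table; further
  substrates (pectin, arabinan, chitin, digeneaside, fructose, sialic
  acid, sulfated rhamnose/galactose) are left to user-supplied YAML
  rules rather than shipped half-specified, and the loader merges such
  rules with the built-in table.

Prevalence summaries report, per substrate, PUL counts and the number
and integer percentage of isolates with ≥ 1 such PUL, plus per-variant
counts.

## SusC/D identity, trees, clusters, congruence

Percent identity comes from one optimal global (end-to-end) pairwise
alignment under BLOSUM62 with affine gap penalties (open 11, extend 1);
identity = 100 × matches / alignment columns, gap columns included.  A
pairwise definition was chosen over MSA-column identity because the
placement threshold (below) needs query-to-reference identities for
sequences that are not part of any fixed alignment; at the divergences
involved the two agree closely, and an externally computed tree can be
imported for exact-parity runs.  The identity is symmetric up to
co-optimal alignment choice; tests compare it against an independent
Gotoh dynamic program.

Trees are neighbor joining on the uncorrected distance
d = 1 − identity/100.  NJ replaces approximate-ML deliberately: the
tree serves cluster extraction and visualization, not phylogenetic
inference, NJ is consistent on additive distances (verified against an
exhaustive least-squares topology search over all 4- and 5-taxon
shapes), and it is fully deterministic.  No Poisson/Kimura distance
correction is applied by default — uncorrected distances are monotone
in identity, which is all cluster extraction needs.  Negative NJ branch
lengths are clamped to zero.  Inputs with fewer than three sequences
are rejected (their topology is trivial).

Substrate clusters: the tree is midpoint-rooted (NJ output is unrooted;
an arbitrary root can split a family), then clades are visited
root-down and a clade is emitted when it has ≥ `min_size` (default 3)
leaves and its labelled leaves reach ≥ `purity_threshold` (default 0.8)
majority-substrate frequency; unlabelled leaves are neutral.  Emitted
clades absorb their subclades; everything else is the
heterogeneous/undefined remainder.

Congruence: over susCD pairs whose SusC lies in some substrate cluster
of the SusC tree *and* whose SusD lies in some cluster of the SusD
tree, the fraction where the two clusters agree on the majority
substrate.  With no eligible pair the statistic is undefined and
reported missing, never 0.

## %NSAF expression profiling

Technical duplicates are averaged arithmetically per (protein, sample);
a missing replicate means the mean runs over those present, with the
replicate count logged.  Within a sample,
NSAF_i = (SpC_i/L_i) / Σ_k (SpC_k/L_k) over **all** proteins of the
sample's table — not just SusC/D-like ones — so %NSAF = 1 is exactly 1%
of the sample's mass-adjusted spectral counts.  Per sample the %NSAF
values sum to 100 (asserted to 1e-9) and are invariant under rescaling
all counts, both properties tested.  A sample with an all-zero count
column has an undefined normalizer and is rejected.

Placement: each expressed query is aligned to every reference of its
class with the same aligner as the reference trees (one identity
definition repo-wide); the best reference's substrate is inherited when
the identity, rounded to 0.1, is ≥ the threshold (default 40).  Ties
inherit only a unanimous substrate, otherwise the query is flagged
ambiguous.  The stated threshold comes without a rounding rule, so the
inclusive comparison on the 0.1-rounded value is pinned here and in the
boundary tests (39.9 → unclassified, 40.0 → placed).

Profiles: a placed protein is retained when its maximum %NSAF across
samples is ≥ `min_pct_nsaf` (default 0.05); retained proteins
contribute all their samples, summed per (substrate, sample).  SusC-
and SusD-like sums are reported separately, never pooled.  Both the
per-protein expression table and the summed profile are emitted, since
either view may be wanted downstream.

Bloom phases: user-supplied labels pass through untouched.  Otherwise,
with the chlorophyll-a maximum as bloom peak, a sample is `mid` at
chl ≥ 15 µg/L, `early` between 5 and 15 before/at the peak, `pre`
below 5 before the peak, and `late` after the peak below 15; a series
never reaching 5 µg/L has no bloom and is all `pre`.  Both thresholds
are configurable.

## Synthetic data: what it emulates, and what not

The generator's defaults define the study conditions the tests run
under: 5 genomes × 8 planted PULs (2 laminarin-A, 1 each laminarin-B,
branched α-1,4-glucan, alginate, sulfated α-mannan, β-mannan, sulfated
xylan — close to the ~7.5 PULs/genome scale of real flavobacterial
isolates), separated by ≥ 5 decoy genes (mean run ≈ 9); single-source
decoy CAZyme hits at rate 0.05 per decoy gene; SusC/D families with
per-site substitution 0.12 within a substrate (expected pairwise
identity 100·((1−p)² + p²/19) ≈ 77.5%) versus ancestors mutated at 0.7
from a common root between substrates (identity near the random
baseline); a 14-sample metaproteome with 2 technical replicates, 300
background proteins at Poisson(30) counts, and planted SusC/D homolog
queries at divergence 0.15 whose counts peak (Poisson(20) vs. baseline
Poisson(1)) at configured samples — yielding peak %NSAF values of order
0.1–0.3.  One pseudo-random stream per artifact is spawned from the
master seed in fixed order (families, genome 0..n−1, proteome), so
identical configurations are byte-identical and adding an artifact
never perturbs the others.

What the generator does **not** emulate: real domain-score
distributions and family-specific cutoffs; overlapping or nested PULs
and regulons spanning loci; horizontal transfer and shared ancestry
between substrates' transporter families; realistic SusC/D lengths
(all 300 aa) and alignment gap structure; compositional biases of real
proteomes; missing values and contaminants in spectral counts.  Passing
tests therefore demonstrate the correctness of the inference chain
under its stated assumptions, not annotation accuracy on real genomes.

## Problem sizes

The test suite and acceptance script size their simulations for a
single CPU: planted-recovery sweeps use 20 seeds × k = 0..10 single
genomes, the NJ cross-check 50 random draws each for 4 and 5 taxa, the
cluster/placement study 20 seeds of 4 families × 5 members (300 aa),
and the full-pipeline acceptance run one 5-genome study with the
default metaproteome.  These sizes exercise every code path while
keeping the whole suite in the tens of seconds.

## Known limitations

* Rule signatures are composition-based; gene order and synteny are
  ignored, so architecturally distinct PULs with identical family
  content are indistinguishable.
* The flat evidence thresholds stand in for family-specific cutoffs.
* Pairwise identity can differ by fractions of a percent from
  MSA-column identity at high divergence.
* Substrate clusters depend on midpoint rooting; on star-like trees
  with near-equal depths the root placement, and hence cluster
  boundaries, can be sensitive to small length differences.
* The susE positional heuristic can only ever flag "putative" genes;
  absence of a susE call is weak evidence of absence.
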