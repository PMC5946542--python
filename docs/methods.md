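# Methods

## The arrangement-identity rule

A mitogenome arrangement is the circular, strand-aware sequence of its
annotated features, drawn from a closed vocabulary: the 37 vertebrate
mitochondrial genes (tRNAs by single-letter code with L1/L2 and S1/S2
isoacceptor disambiguation), the control region (CR), the light-strand
replication origin (OL), anonymous non-coding blocks (NC, always with a
length), and pseudogene copies (a trailing `*`, e.g. `P*`). Two genomes
belong to the same arrangement type iff they have the same components in
the same circular order. Operationally both orders are reduced to a
canonical key — the lexicographically minimal rotation of the
strand-signed token string, with NC lengths stripped — so the rule is
rotation-invariant, and strand is part of token identity (an inversion,
though absent from the eleven known snake types, would not silently
collapse).

Lengths are abstracted from identity with one deliberate exception.
The III-E arrangement is token-identical to Type III and is diagnosed
only by its strongly asymmetric control regions, so its registry entry
carries a mandatory asymmetric-CR marker: a record with a Type III token
order is promoted to III-E when its CR length ratio (max/min) exceeds
the asymmetry threshold. The same marker governs novelty comparison
against the prior six-arrangement registry, otherwise III-E would count
as "already known" merely because its token order matches the common
alethinophidian order. III-F additionally shows CR asymmetry, but its
342 bp NC insertion between ND5 and ND6 is token-level and is treated as
the primary diagnostic; asymmetry there is corroborating.

Records that match no registry type receive a deterministic `NEW-k`
label (k by input order of first appearance of the canonical key), so
novel-type discovery is reproducible; a record is never left unlabeled.

## CR numbering

The paperwork around duplicated snake control regions is only jointly
consistent under one numbering, which this package adopts throughout:
CR1 is the ancestral-position control region (between the
CYTB–tRNA-Thr–tRNA-Pro block and tRNA-Phe) and CR2 is the duplicated
copy inside the IQM cluster (between tRNA-Ile and the translocated
tRNA-Leu(UUR)). Under this convention: Type III-B translocates tRNA-Pro
to 5′ of CR2 (a real change relative to Type III, where P already sits
5′ of CR1); III-B1 adds P* 5′ of CR1; III-C adds P* 5′ of CR2; III-D
inserts the extra tRNA-Ile 5′ of CR1; III-E has CR1 = 2878 bp,
CR2 = 4110 bp.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `nc_threshold_bp` | 50 | bp | unannotated gaps at least this long become NC tokens; typical intergenic spacers are < 30 bp while the smallest diagnostic insertion scored here is 342 bp, so 50 separates the regimes |
| `cr_asymmetry_ratio` | 1.2 | ratio | the one diagnostic printed ratio is 4110/2878 ≈ 1.43 and must pass; concertedly evolving CR pairs sit near 1.0; 1.2 splits the regimes |
| `anchor` | `F` (fallback `12S`) | — | both anchors are universally present and outside every rearranged locus |
| `resolution_mode` | DELTRAN | — | see below; ACCTRAN available |

Both thresholds are exposed in `PipelineConfig`; how sub-threshold
spacers were treated in the original typing of real genomes is not
recorded anywhere we know of, so the 50 bp NC cut is this package's own
operationalization.

## Feature detection

Translocation calling compares circular neighbourhoods: a gene is
called iff it occurs exactly once in both orders and *both* its
neighbours differ, after (a) deleting tokens absent from either order
(so one insertion does not cascade into calls on its flanking genes;
when copy numbers differ, the copies whose name-context matches the
other order are retained, so a fresh duplicate is the copy deleted) and
(b) disambiguating surviving duplicate names by occurrence index along
the anchor-rotated order (without this, tRNA-Pro's move from
(T, CR1) to (I, CR2) would be invisible — both neighbours are named
"CR"). An adjacent swap makes both displaced genes' neighbourhoods
change symmetrically; calls that are explained by deleting another
called gene are suppressed, mutual cases resolved in favour of the tRNA
(single-tRNA translocation being the expected mitochondrial mechanism,
e.g. tRNA-Lys in III-A rather than ATP8).

Hotspot assignment maps each diagnostic event of a type to one locus:
**CR-flank** when the event concerns a control region (duplication,
asymmetry) or a token sitting or landing circularly adjacent to a CR in
the type's own order; **WANCY** when the subject or its resting context
lies inside the W–A–N–(OL)–C–Y span — a translocation is judged where
the gene *lands*, so tRNA-Gln moving into the cluster (Type I) is a
WANCY event; **other** otherwise. Under these rules 7 of the 11 types
have at least one CR-flank event (III, III-B, III-B1, III-C, III-D,
III-E, III-F) and three carry WANCY-locus events (I, II, III-G);
III-A's tRNA-Lys move is the sole "other"-only type, and III-F's NC
insertion between ND5 and ND6 is "other" while its CR asymmetry is
CR-flank.

## Parsimony mapping

Characters are unordered; trees are rooted and may be multifurcating
(soft polytomies are folded by iterated pairwise intersection in
child-list order in the Fitch pass, which is deterministic and
documented). The Fitch down-pass score counts empty intersections and
equals the true parsimony score on binary trees; an exhaustive
enumerator over ancestral labelings (≤ 12 tips) is kept as an
independent oracle and is property-tested against it.

Single ancestral states are resolved over the *full* minimal-cost state
sets (Sankoff with unit costs), not the down-pass sets, because
down-pass sets miss states that participate only in non-canonical
optimal labelings. Ties are broken by DELTRAN — keep the parent's state
whenever equally parsimonious, delaying transformations toward the tips
— which is the convention matching a parallel-gains reading of sparse
derived characters (ACCTRAN is available behind a flag). Outgroup
knowledge enters as a virtual root neighbour carrying the outgroup
state at one edge of unit cost. This matters for the O_L character:
within snakes alone the cheapest reading of O_L absence in both blind
snake families is a single basal loss plus a regain, but lizard
outgroups retain the O_L, and with the virtual outgroup the root
resolves to "present" and DELTRAN places two independent losses on the
Leptotyphlopidae and Typhlopidae stems.

For the multistate arrangement-type character the root is *forced* to
the sentinel UNKNOWN: the ancestral snake arrangement is deliberately
left indeterminate, transitions out of UNKNOWN are counted as edges of
the derivation graph, and their event paths come from the registry's
stored diagnostic events rather than from diffing against a concrete
ancestor. All other derivation-graph edges are annotated by the
deterministic event decomposition (losses → insertions →
pseudogenizations → duplications → translocations → CR asymmetry,
alphabetical within category). The graph must be a DAG. A dataset with
a single observed type yields a single node and no edges, since no
derivation is inferable.

The basal topology of the bundled tree is a root trifurcation
(Leptotyphlopidae, Typhlopidae, Alethinophidia). Basal snake
relationships are weakly supported, and with the root forced to UNKNOWN
a resolved basal dichotomy would manufacture a spurious II→III (or
III→II) derivation edge; the soft polytomy yields exactly
UNKNOWN→{I, II, III}.

## The synthetic panel

The bundled 65-species / 14-family panel
(`data/synthetic_fixture_taxa.tsv`, `data/synthetic_fixture_tree.nwk`)
is a constructed stand-in, labelled synthetic in both filename and
header. Species names are real snakes with published mitogenomes, but
the per-species type assignments and the topology are reconstructions
chosen so the panel realizes the published distribution of snake
arrangement diversity: Type I confined to Leptotyphlopidae, II to
Typhlopidae, III prevailing across Alethinophidia, III-B throughout
Viperidae except *Ovophis okinavensis* (III-B1), III-C in six
independent colubrid/homalopsid lineages, and III-A/III-D/III-E/III-F/
III-G each on a single species. Every count reported by the package is
recomputed from generated gene orders and the tree — the taxon table's
type column is used only to pick which arrangement to generate and to
cross-check classification.

Record generation realizes a type's reference token order with feature
lengths from a documented table of typical vertebrate sizes (tRNA
~70 bp, rRNAs 950/1550 bp, per-gene typical PCG sizes, CR 1100 bp,
OL 35 bp), a small seed-deterministic jitter on gene lengths (±4 bp
tRNA, ±20 bp rRNA, ±15 bp PCG) for realism, and *no* jitter on CR, NC,
OL or pseudogene lengths, which carry the diagnostics. GenBank emission
uses standard qualifiers (anticodon-bearing tRNA products, D-loop,
rep_origin, misc_feature) and round-trips exactly through the parser.

What the generator does **not** emulate: nucleotide-level evolution (no
substitution model; sequences are random or `N`-filled), annotation
error and boundary noise, heteroplasmy, concerted-evolution dynamics of
the CR pair, and within-type length variation beyond the jitter.
Passing tests therefore demonstrate that the pipeline's logic is
correct on cleanly annotated inputs, not that it is robust to
real-world annotation artifacts; with real GenBank files the
L1/L2–S1/S2 positional inference and the NC threshold are the two
places where annotation quality matters most.

## Numerical and degenerate-input choices

Rotation minimization breaks ties lexicographically over strand-signed
token names, so duplicated anchors are deterministic. Classification
with unmeasured CR lengths treats asymmetry as false and logs a caveat
(III-E can then not be distinguished from III). `detect_ol` treats two
OL tokens as an integrity error (observed in no known type). Empty
orders, missing anchors, unknown gene names after synonym mapping,
duplicate taxon ids and tree/character mismatches are hard errors
raised at the boundary; overlapping GenBank features are logged, not
fatal. CLI exit codes: 0 success, 2 input/contract error, 3
panel-integrity error.

## Problem sizes

The shipped analysis is desk-scale by design: 65 genomes of ~40 tokens,
one 65-tip tree, and property tests over a few hundred randomized small
instances (200 random ≤ 8-tip trees against the exhaustive oracle, 100
single-event perturbations, 500 rotations). The full suite runs in a
few seconds on one CPU.

## Known limitations

* Parsimony counts depend on the tree: the bundled counts are
  statements about the bundled topology, and alternative resolutions of
  weakly supported nodes can change independent-origin counts.
* Tandem-duplication–random-loss scenarios are not enumerated; the
  event decomposition reports *what* changed (loss, duplication,
  translocation, insertion, pseudogenization, asymmetry), not the
  mechanistic duplication-loss path that produced it.
* Whether Types I and II arose truly independently cannot be decided by
  parsimony without the ancestor; the package reports the two
  transition edges out of the UNKNOWN root and leaves independence as
  an interpretive statement.
* No probabilistic (likelihood/Bayesian) ancestral-state models; no
  inversion detection beyond strand mismatch in the identity rule; no
  rescue of partial or ambiguous annotations.
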