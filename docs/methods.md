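# Methods

## Problem and model

Two enzymes are *isofunctional* when they catalyse the same reaction, which
is operationalised as matching Enzyme Commission numbers: to level 3
(sub-subclass, "reaction level") or level 4 (substrate-specific serial). A
level counts as matched only when it is determined in both operands, so an
entry with EC 3.5.2.− can never match at level 4. Homology is
operationalised purely structurally: identical catalytic-domain CATH code
at all four levels (Class.Architecture.Topology.Homologous-superfamily).
Anything else with the same EC is an analogue — a candidate case of
convergent evolution. This is deliberately conservative: distant divergence
and convergence are often indistinguishable, and the package does not try
to adjudicate between them (a caveat, not a computation).

Convergence is then measured on three axes per pair — active-site geometry,
catalytic mechanism, cofactor usage — and summarised as a paradigm label.

## Active-site geometry

### Functional atoms

Each catalytic residue contributes exactly three atoms. Main-chain
contributors (including residues curated only as "Any") use N/CA/C; all
other types use a side-chain triple centred on the chemistry-bearing atoms
(His → ND1/CE1/NE2, Asp → CG/OD1/OD2, Ser → OG/CB/CA, …; full table in
`sites.FUNCTIONAL_ATOMS`). The convention — terminal functional atoms plus
enough neighbours to fix orientation — is standard for catalytic-site
templates, but the exact triples are this package's own reconstruction of
that convention; absolute RMSDs against values produced with a different
atom table can shift by a few tenths of an Å. The table ships as data and
is overridable by a JSON file for exactly this reason.

### Template matching

All residue subsets of size 2, 3 and 4 of each site are templates; equal
sizes are compared all-against-all. Residues may pair within equivalence
classes of chemically similar types — {Asp,Glu}, {Asn,Gln}, {Ser,Thr},
{Lys,Arg}, {Tyr,Phe,Trp}, {Val,Leu,Ile,Met,Ala}, with His, Cys and "Any"
matching only themselves — and chemically indistinguishable atoms within a
residue may swap (both carboxylate oxygens, Arg NH1/NH2, His ND1/NE2,
aromatic ring direction). Every admissible residue bijection × atom pairing
is scored by a unit-weight Kabsch fit; the candidate search is exhaustive
(≤ 4! bijections × 2⁴ swaps per template pair), so no heuristic can miss
the optimum. A match is accepted below an RMSD cutoff of 3.5 Å, chosen
between curated values treated as aligned (3.14 Å) and as dissimilar
(4.04 Å); it is a parameter, not a constant.

The reference mapping for a pair is the accepted match with the largest
residue count, then the lowest RMSD. Size-first selection was a genuine
design choice (the two orderings are not equivalent); the larger
correspondence is preferred because the mapping's job is to be a reference
frame, and more residue pairs constrain that frame better than a marginally
lower RMSD on fewer residues. Ties break lexicographically on residue
indices, making the whole search deterministic. Size-2 matches are flagged
*motif-level*: small templates match spuriously often, so they are never,
alone, treated as evidence of structural convergence.

### Weighted superposition

Given the mapping, sites are fitted with an iteratively re-weighted Kabsch
algorithm: starting from unit weights, alternately fit and reset
w_i = exp(−d_i²/2σ²) from the residual distances d_i, until the largest
weight change falls below 1e-4 or 50 iterations. σ = 2.0 Å by default — a
soft scale separating "catalytically equivalent position" from "different
position", of the order of the acceptance cutoff but softer. The Kabsch
step itself is the weighted SVD solution with reflection correction
(det = +1 enforced); fewer than three or collinear points leave rotational
degrees of freedom unconstrained, and such fits are returned but flagged
degenerate rather than refused. The reported per-pair RMSD is the
*unweighted* value over mapped functional atoms in the final frame (the
comparable, honest number); wRMSD is the quantity the iteration optimises;
coverage is mapped residues over the residue count of the larger site. On
converging runs wRMSD is non-increasing between steps; an increase is
recorded as non-convergence, never raised.

The implementation is cross-checked in the test suite against two
independent oracles: a closed-form quaternion (Horn) solver on 1000 random
weighted instances (agreement to 1e-8 Å) and a brute-force rotation-space
grid-plus-refinement minimiser.

## Mechanism similarity

A mechanism is a sequence of steps, each a molecular graph (atoms with
element, formal charge and a protein/substrate/cofactor/water role flag;
bonds with integer order) plus curly arrows moving 1 or 2 electrons from a
source (bond or lone pair) to a sink (atom, bond, or new bond). Each arrow
becomes a canonical *arrow environment* key: the endpoint atoms' descriptors
plus two shells of neighbouring atoms and bonds, encoded as a
bounded-depth tree with sorted branches, so the key is invariant under any
relabelling of atom ids. Truncation at the depth limit is marked explicitly
(a trailing `*`), so a shell cut off at the horizon can never collide with
a genuinely terminal atom. A mechanism's profile is the set of its keys
over all steps; similarity is the Jaccard index |A∩B|/|A∪B|.

Scores at or above 0.2 count as "similar". The threshold sits below the
smallest curated similar-pair percentage in the packaged survey (23%) while
all curated not-similar pairs score 0%; it is configurable. Profiles can
legitimately be empty (no detailed curation): the score is then *not
computable* — explicitly not 0, since absence of curation is not evidence
of dissimilarity — and the pair stays unknown unless a curated override
supplies the call. Overrides always win over computed scores, in both
directions; every override is logged with its source. The descriptor
vocabulary (element, charge, role; bond order) is a minimal
chemistry-complete choice; the upstream encodings that produced curated
percentages are not public, so those percentages are carried as fixture
data and are not recomputation targets.

## Cofactors

Only catalysis-relevant cofactors are compared. Labels are normalised
(charge-state spellings collapse, organic cofactors map to canonical
names; curated distinctions like NADH vs NADPH are preserved verbatim) and
compared as sets: identical non-empty → same/both_present_identical; both
empty → same/both_absent; otherwise different, split by whether exactly one
side is empty. NAD/CoA-type carriers count as cofactors when they
participate in the reaction regardless of whether they are regenerated.

## Paradigm classification

A pair is *structurally convergent* when its superposition maps ≥ 2
residues at RMSD ≤ 3.5 Å and curation has not flagged the match spurious.
Crossed with the mechanism call: structural ∧ similar →
structural_and_mechanistic; structural ∧ ¬similar → structural_motif_only
(reported under the structural paradigm in survey-style summaries, since
such alignments sit on ubiquitous motifs like His-acid dyads); ¬structural
∧ similar → mechanistic_only; otherwise reaction_only. An unknown mechanism
call yields "unclassified", never a silent default. The spurious flag is a
curated input, not a computation: quantitative measures alone demonstrably
misfire on small templates, and the package treats the manual override as
part of the data.

## Sequence comparison

Global (Needleman-Wunsch) and local (Smith-Waterman) identities use
affine-gap dynamic programming via Biopython's PairwiseAligner with
BLOSUM62, gap open 10, extend 0.5. Identity is matches over aligned
residue-residue columns; coverage is aligned columns over the shorter
sequence. The local optimum is verified in tests against an exhaustive
enumeration of all local alignments on 6-mers.

## Synthetic data

The generator plants ground truth for every stage. Site pairs: residue
centres ≥ 2 Å apart in an 8 Å cube, three functional atoms per residue
(non-collinearity enforced), copy B = uniform random proper rotation +
translation of a residue subset plus independent per-axis Gaussian noise,
0.1 Å by default — the order of coordinate uncertainty in well-resolved
crystal structures. Decoy sites reuse a composition with geometry resampled
wider and sparser, and are explicitly checked to admit no 3+-residue match
against their source (motif-level matches may remain — deliberately, as
the spurious-match phenomenon is part of what is tested). Mechanism pairs
take k shared and a/b private keys from a 30-key alphabet of structurally
distinct toy steps, so Jaccard = k/(k+a+b) exactly; the defaults (3/2/2)
give 0.43, comfortably above threshold. Catalogues mix paradigm ground
truths 0.4/0.3/0.3; non-structural pairs draw their two sites from
equivalence-class-disjoint residue pools so that no template match is
admissible by construction. All randomness flows from one seeded numpy
PCG64 generator; a fixed seed reproduces byte-identical fixture files.

What the generator does **not** emulate: real backbone geometry and
side-chain rotamers, crystallographic artefacts (altlocs beyond the reader
tests, missing atoms, occupancy), chemically realistic multi-step
mechanisms, or the curation noise of real databases. Passing the synthetic
recovery tests therefore demonstrates correctness of the algorithms under
their stated model — rigid motion + isotropic noise, set-based mechanism
overlap — not field performance on arbitrary crystal structures.

## Problem sizes and determinism of the shipped checks

The packaged curated survey fixture holds 34 analogue groups; classifying
it is instantaneous and fully deterministic. The property suites use 1000
random Kabsch instances, 500 seeded site pairs for mapping recovery
(expected ≥ 99% exact recovery at 0.1 Å noise) and 200 seeded catalogues
of 3 analogue groups for end-to-end paradigm recovery (expected ≥ 95%);
these sizes give tight binomial evidence while keeping the whole suite in
tens of seconds on one CPU. Recomputing curated superposition RMSDs on
real structures needs live M-CSA/PDBe access and ships as an example
script; its agreement is expected within ~0.3 Å, limited by the
reconstructed functional-atom table.

## Known limitations

- Homology detection is CATH identity only; no sequence-profile or
  structure-alignment screening for remote homology.
- Whole-chain structural alignment, flexible fitting, protonation and
  missing-atom modelling are out of scope; CATH codes are taken as given.
- The mechanism score is set-based: step order is ignored, and two
  mechanisms sharing chemistry but curated at different granularity can
  score low — hence the curated-override channel.
- Cofactor identity follows curated labels; near-identical organic
  cofactors are as distinct as their labels.
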