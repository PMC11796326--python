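# enzconverge

Convergence analysis for isofunctional enzymes — pairs of enzymes that
catalyse the same reaction (identical EC number) from unrelated folds
(different catalytic-domain CATH superfamilies). Such *analogues* are
products of convergent evolution, but "convergent" can mean very different
things: active sites that superpose in 3D, mechanisms that share the same
electron-pushing chemistry, or nothing beyond the overall reaction.
`enzconverge` quantifies all three axes and classifies each pair into a
convergence paradigm. It is written for structural bioinformaticians and
enzymologists working with curated catalytic-site resources (M-CSA-style
annotations, PDB/mmCIF structures).

## What it computes

**Pair enumeration.** From a JSON catalogue of enzyme entries (EC, CATH,
reference structure, catalytic residues, cofactors, mechanism), all
unordered pairs matching in EC at the reaction level (EC x.x.x.−) or the
full substrate level (EC x.x.x.x) are enumerated, labelled homologue
(identical CATH at all four levels) or analogue, filtered (multi-domain
sites, incomplete annotations, curated exclusions) and deduplicated to one
representative per (EC, unordered CATH pair).

**Active-site geometry.** Each catalytic residue is reduced to three
*functional atoms* (mechanism-bearing side-chain atoms, or backbone N/CA/C
for main-chain contributors). Templates of 2–4 residues are compared
all-against-all between the two sites under chemical-equivalence rules
(Asp~Glu, Ser~Thr, carboxylate-oxygen and His ND1/NE2 swaps, …); every
admissible correspondence is scored with a Kabsch least-squares fit, and the
best accepted match (largest size, then lowest RMSD, cutoff 3.5 Å) seeds a
Gaussian-weighted iterative superposition with weights

&nbsp;&nbsp;&nbsp;&nbsp;*w&#8342; = exp(−d&#8342;² / 2σ²)*,&nbsp;&nbsp;σ = 2 Å,

reporting an unweighted RMSD over mapped functional atoms, a weighted
wRMSD, and coverage (mapped residues / residues of the larger site).

**Mechanism similarity.** Curly-arrow mechanism steps are abstracted into
canonical *arrow environments* (the arrow's source/sink atoms plus two
shells of neighbouring atoms and bonds, canonicalised against relabelling);
two mechanisms are scored by the Jaccard index of their environment sets,
|A∩B|/|A∪B|, thresholded at 0.2 with support for curated overrides.

**Paradigm classification.** A pair with ≥ 2 aligned residues at
RMSD ≤ 3.5 Å (and no curated spurious flag) is structurally convergent;
combined with the mechanism call this yields *structural-and-mechanistic*,
*structural motif only*, *mechanistic-only*, or *reaction-only*.

## Worked example

```bash
python examples/superpose_synthetic_sites.py
```

builds a 4-residue active site and a rigidly moved copy with 0.1 Å
per-axis coordinate noise, recovers the planted correspondence and prints

```
best template match: size 4, rmsd 0.148 Å
weighted fit: rmsd 0.148 Å, wrmsd 0.148 Å, coverage 1.00, 2 iteration(s), converged=True
```

— the recovered RMSD sits at the level implied by the injected noise
(√3·0.1 ≈ 0.17 Å), and coverage 1.0 means every residue of the larger site
was mapped. Classifying the packaged curated survey of 34 analogous
enzyme groups (`python examples/classify_survey.py`) prints

```
raw label counts:    {'structural_and_mechanistic': 13, 'structural_motif_only': 1,
                      'mechanistic_only': 11, 'reaction_only': 9}
survey-style counts: {'structural_and_mechanistic': 14, 'mechanistic_only': 11,
                      'reaction_only': 9, 'unclassified': 0}
```

i.e. the published 14 / 11 / 9 paradigm split, recomputed from the
per-pair metrics by the classification rules rather than copied.

The same pipeline is scriptable from the shell:

```bash
enzconverge simulate --seed 5 --n-groups 4 --out fixture/
enzconverge pairs    --catalogue fixture/catalogue.json --out tables/
enzconverge compare  --catalogue fixture/catalogue.json --out metrics.tsv
enzconverge classify --metrics metrics.tsv --out classified.tsv
```

Other examples: `pair_enumeration.py` (the six-entry β-lactamase example:
15 pairs → 6 homologous + 9 analogous → 1 unique analogue case),
`mechanism_similarity.py` (Jaccard scoring and curated overrides),
`synthetic_pipeline.py` (end-to-end ground-truth recovery), and
`reproduce_survey_rmsds.py` (recomputes curated superposition RMSDs from
live M-CSA/PDBe data; requires network access).

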