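"""Template-match and superpose two active sites with a known relationship.

Generates a 4-residue active site and a rigidly moved, noisy copy (0.1 Å
per-axis noise), finds the best residue/atom correspondence by exhaustive
template matching, then runs the Gaussian-weighted iterative Kabsch fit.
"""

from enzconverge import SyntheticConfig, best_site_mapping, iterative_weighted_fit
from enzconverge.synthetic import make_site_pair

cfg = SyntheticConfig(seed=7, residues_per_site=(4, 4), noise_sigma=0.1)
pair = make_site_pair(cfg)

print("site A residues:", [str(r.residue) for r in pair.site_a.residues])
print("site B residues:", [str(r.residue) for r in pair.site_b.residues])
print("planted mapping:", pair.mapping)

mapping = best_site_mapping(pair.site_a, pair.site_b)
print(f"\nbest template match: size {mapping.size}, rmsd {mapping.rmsd:.3f} Å")
print("matched residue pairs:", [(str(a), str(b)) for a, b in mapping.residue_pairs])

result = iterative_weighted_fit(pair.site_a, pair.site_b, mapping, sigma=2.0)
print(
    f"\nweighted fit: rmsd {result.rmsd:.3f} Å, wrmsd {result.wrmsd:.3f} Å, "
    f"coverage {result.coverage:.2f}, {result.iterations} iteration(s), "
    f"converged={result.converged}"
)
print()
print("The rmsd is the unweighted value over the mapped functional atoms; with")
print("0.1 Å per-axis noise it should sit near 0.17 Å (sqrt(3)*0.1). Coverage 1.0")
print("means every residue of the larger site is mapped.")
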