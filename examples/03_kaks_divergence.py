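"""Ka/Ks of a simulated duplicate pair.

Simulates a CDS pair at a known synonymous distance (Jukes–Cantor,
uniform over sites), back-translates the protein alignment to codons,
and estimates Ka, Ks with the exact Nei–Gojobori method and the
kappa-aware MYN-style approximation.  Under neutral simulation Ka ≈ Ks
and the ratio is near 1; purifying selection in real duplicates drives
it below 1.
"""

import numpy as np
from Bio.Seq import Seq

from paraminer.kaks_engine import codon_align, kaks_pair
from paraminer.synthetic_fixtures import simulate_cds_pair

rng = np.random.default_rng(5)
true_ks = 0.2
cds_a, cds_b = simulate_cds_pair(600, true_ks, rng)


def protein(cds):
    p = str(Seq(cds).translate())
    return p[:-1] if p.endswith("*") else p


aln = codon_align((protein(cds_a), protein(cds_b)), cds_a, cds_b,
                  gene_a="copyA", gene_b="copyB")
print(f"codon columns kept: {len(aln.pairs())} "
      f"(trimmed: {aln.n_trimmed_gap} gap, {aln.n_trimmed_stop} stop)")

for method in ("NG", "MYN"):
    r = kaks_pair(aln, method)
    kappa = f", kappa={r.kappa:.2f}" if r.kappa else ""
    print(f"{method:>3}: S={r.S:.1f} N={r.N:.1f}  Ka={r.Ka:.4f} Ks={r.Ks:.4f} "
          f"Ka/Ks={r.ratio:.3f}{kappa}")

print(f"\nsimulated synonymous distance was {true_ks}; Ks recovers it.")
print("Ka/Ks sits a little below 1: the simulation is neutral except that")
print("nonsense changes (to stop codons) never fix, which mildly suppresses")
print("the nonsynonymous rate. The MYN estimate agrees with NG since the")
print("simulation has no transition/transversion bias (kappa = 1).")
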