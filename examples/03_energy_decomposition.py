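"""Position-by-position free energy of one guide-site duplex.

Scores a guide against a 2-mismatch off-target and prints the 19
per-stack contributions.  Matched stacks carry their nearest-neighbor
stack energy; the mismatch run is scored as one interior loop whose
total energy is split evenly over the stacks it spans (marked *).
"""

from crisprthermo import (
    DuplexKind,
    GuideRNA,
    TargetSite,
    delta_g_h,
    load_tables,
    pairing_states,
    positional_hybrid_contributions,
)
from crisprthermo.weights import packaged_weights

guide = GuideRNA("demo", "GACGCAUAAAGAUGAGACGC")
proto = list(guide.as_dna)
proto[9], proto[10] = "C", "C"  # tandem mismatch: a 2x2 interior loop
site = TargetSite(protospacer="".join(proto), pam="AGG")

hybrid = load_tables()[DuplexKind.RNA_DNA]
contrib = positional_hybrid_contributions(guide, site, hybrid)
match = pairing_states(guide, site)
gamma = packaged_weights()

print(f"guide        5'-{guide.sequence}-3'")
print(f"protospacer  5'-{site.protospacer}-3'   PAM {site.pam}\n")
print(f"{'stack':>5} {'pairs':>7} {'dG':>7} {'Gamma':>6} {'weighted':>9}")
for i, value in enumerate(contrib.values):
    in_loop = not (match[i] and match[i + 1])
    tag = "*" if in_loop else " "
    print(
        f"{i + 1:>5} {guide.sequence[i:i+2]}/{site.protospacer[i:i+2]:<4}"
        f"{value:>7.2f}{tag} {gamma.values[i]:>6.2f} {gamma.values[i] * value:>9.2f}"
    )

print(f"\nunweighted duplex energy : {contrib.total:8.2f} kcal/mol")
print(f"Cas9-weighted dG_H       : {delta_g_h(contrib, gamma):8.2f} kcal/mol")
print(
    "\nThe positional weights rise toward the PAM-proximal end (stack 19),"
    "\nwhere base-pair stability matters most for Cas9 binding."
)
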