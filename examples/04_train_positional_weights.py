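"""Re-derive Cas9 positional weights from association-rate data.

Generates a synthetic dCas9 association-rate dataset in which stack 12
is constructed to dominate the rate-weighted energy sums, trains the
19 positional weights from it, and compares them with the packaged
production weights.  The minimum trained weight is exactly 1 by the
normalization Gamma[i] = log10(|W_i|/min|W_j|) + 1.
"""

from crisprthermo import DuplexKind, load_tables
from crisprthermo.synthetic import make_association_dataset
from crisprthermo.weights import packaged_weights, train_weights

hybrid = load_tables()[DuplexKind.RNA_DNA]
data = make_association_dataset(seed=7, n=50, dominant_position=12)
trained = train_weights(data, hybrid)
production = packaged_weights()

print(f"trained on {len(data.records)} synthetic association records\n")
print(f"{'position':>8} {'trained':>8} {'packaged':>9}")
for i, (t, p) in enumerate(zip(trained.values, production.values), start=1):
    marker = "  <- constructed dominant stack" if i == 12 else ""
    print(f"{i:>8} {t:>8.3f} {p:>9.2f}{marker}")

print(f"\nmin(trained)    = {min(trained.values):.12f}  (pinned at 1 by the normalization)")
print(f"argmax(trained) = {max(range(19), key=lambda i: trained.values[i]) + 1}")
print(
    "\nThe packaged weights come from real biochemical profiling and peak"
    "\nin the PAM-proximal region; the synthetic set instead peaks where"
    "\nits generator planted the dominant stack, which the training recovers."
)
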