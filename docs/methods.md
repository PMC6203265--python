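# Methods

## Scope and model

`crisprthermo` approximates the free energy of a Cas9–gRNA–DNA ternary
complex as

ΔG_B[g,t] = δ_PAM(t) · ( ΔG_H[g,t] − ΔG_O[t] − ΔG_U[g] )

and derives two quantities from it: a per-site confidence score
(CRISPRoff = −ΔG_B) and a guide-level specificity
(CRISPRspec = −log10 of the off-target fraction of the Boltzmann ensemble
over all candidate sites).  The model covers substitution-only off-targets:
bulged alignments are out of scope, so no bulge-loop parameters are carried.
Only the 20-nt DNA-binding region of the guide is modeled; the sgRNA
scaffold is ignored.

Positions are numbered 1..20 from the guide's 5' end (PAM-distal) to the
PAM-proximal end; the 20-bp duplex has 19 dinucleotide stacks and all sums
run over those stacks.  Duplex-initiation and terminal-AU/AT penalties are
deliberately omitted from ΔG_H and ΔG_O: both energies enter ΔG_B through
differences of stack sums, and the score definitions contain stack/loop
terms only.

## Nearest-neighbor parameters

Three duplex chemistries are parameterized in
`src/crisprthermo/data/nn_stacks.tsv` (ΔG°37, kcal/mol; top strand 5'→3',
bottom strand 3'→5'):

| table | Watson–Crick stacks | mismatch-containing stacks |
|---|---|---|
| RNA:RNA | Xia et al. 1998 (Turner 2004 set) | Turner 2004 interior-loop mismatch terms |
| DNA:DNA | SantaLucia 1998 unified set | Allawi & SantaLucia 1997–1998, Peyret et al. 1999 (ΔG°37 from published ΔH°/ΔS° at 310.15 K) |
| RNA:DNA | Sugimoto et al. 1995 (measured) | completed by averaging (below) |

The hybrid table keeps every measured Sugimoto value and fills all remaining
keys over its alphabet with the arithmetic mean of the corresponding
RNA:RNA and DNA:DNA values under the U↔T strand correspondence.  A stack key
belongs to the alphabet when at least one of its two columns is a
Watson–Crick pair; doubly-mismatched stacks are never needed because
mismatch runs are scored as loops closed by matched pairs.  G·U/G·T pairs
are treated as mismatches throughout the duplex model.  The exact editions
of the source tables were a genuinely open choice; the packaged TSV is the
auditable record of the dialect used, and
`scripts/build_parameter_tables.py` regenerates it from its sources.

Interior-loop initiation penalties (`loop_init.tsv`) are indexed by total
unpaired nucleotides: Turner 2004 values for RNA (sizes 2–12), the
SantaLucia–Hicks 2004 internal-loop table for DNA with size 2 set to 0
(a DNA single mismatch is a pure nearest-neighbor term in that model) and
Jacobson–Stockmayer extrapolation beyond size 9.  The hybrid loop penalty
is the per-size mean of the two, consistent with the stack-averaging rule.
Loops larger than the tabulated range clamp to the largest tabulated size;
with the default search cap of 6 mismatches this is never reached.

## Positional decomposition of ΔG_H

Runs of consecutive matches contribute one Watson–Crick stack energy per
stack position.  Each maximal mismatch run of length m, with its closing
matched pairs, is one interior loop scored as: mismatch terms of the
available closing stacks + loop_init(2m) (the loop is symmetric by
construction — substitutions only).  The loop total is divided equally over
the stack positions the loop spans.  The span includes the closing-stack
positions by default (`include_closing_in_division=True`); for a single
mismatch those are the only touched positions, so the two definitions
coincide there.  This makes the 19 positional contributions an exact
partition: their sum equals the loop-aware whole-duplex energy, which the
test suite checks against an independent single-pass implementation on
randomized duplexes.

Two edge cases are defined by construction rather than by the published
loop model: a mismatch run touching position 1 or 20 has only one closing
stack, and is scored with that single closing term plus the loop initiation
(logged at debug level); a duplex with zero matches degenerates to a single
loop-initiation penalty spread over all 19 positions.  Both are outside the
≤6-mismatch regime the scores are meant for.

ΔG_H weights the 19 contributions with Γ_Cas9: the packaged vector is
{1.80, 1.96, 1.90, 2.13, 1.38, 1.46, 1.00, 1.39, 1.51, 1.98, 1.88, 1.72,
2.02, 1.93, 2.08, 1.94, 2.15, 2.04, 2.25}, minimum 1 at position 7 and
maximum at the PAM-proximal stack 19.

## Weight training

Given association-rate records (ô_n, ã_n) for one guide ĝ, the trainer
computes per-position energies as the 19 raw stack terms looked up
individually (Watson–Crick stack or single-mismatch term; no loop division —
this intentionally differs from scoring-time loop handling), forms
W_i = Σ_n ã_n · ΔG_i[ĝ, ô_n], and returns Γ[i] = log10(|W_i| / min_j |W_j|) + 1.
Because the W_i are sums of negative stack energies weighted by positive
rates, the ratio is taken on magnitudes; this is the only reading that
yields all-≥1 weights and pins the minimum at exactly 1.  Mixed-sign or
zero W vectors are rejected with the offending positions named.  A stack
whose two columns are both mismatched has no tabulated term and contributes
0 during training; the synthetic generator never produces such stacks and
real profiling data make them vanishingly rare.  Weights are
scale-invariant in the rates by construction.

## ΔG_U backends

The default backend is ViennaRNA (Python bindings if importable, else the
`RNAfold` executable) at its default model settings, cached per guide.  The
built-in fallback is a Zuker-style dynamic program over the packaged Turner
2004 parameters (stacks, hairpin/bulge/interior initiation, terminal
mismatches, 1×1/2×1/2×2 special tables, Ninio asymmetry, terminal-AU,
linear multiloops; no dangling ends, no tetraloop bonuses).  At matched
model options (dangles off, special hairpins off) it reproduces ViennaRNA
MFEs exactly on random 20-mers, which the suite verifies; against
ViennaRNA defaults small dangle/tetraloop differences remain, so outputs
record which backend produced ΔG_U.  Positive MFEs are clamped to 0 (no
penalty without a stabilizing structure).

## Scores

CRISPRspec is evaluated in log-sum-exp form; the suite checks equality with
naive summation to 1e−9 on 50-site ensembles.  β defaults to
1/(R·T) = 1.6227 mol/kcal (R = 1.987×10⁻³ kcal/(mol·K), T = 310.15 K) —
the value is a model choice recorded in every output header and
configurable, since the score's ranking behavior, not its absolute scale,
is what the partition function fixes.  δ_PAM applies to every site,
on-target included, so a single ΔG_B definition is used everywhere.  A
guide whose ensemble contains no off-target has specificity +∞, reported
as a configurable cap (default 100) with an explicit flag.  When several
perfect-match sites exist, the annotated one (or the coordinate-first one)
is the on-target and the rest remain in the off-target sum; repeated sites
are kept as separate ensemble members.

## Search

`find_sites` enumerates every 23-nt window (protospacer+PAM) on both
strands with PAM ∈ {NGG, NAG, NGA} and Hamming distance ≤ 6 by default,
using pigeonhole-partitioned exact seeding (split the 20-mer into k+1
segments; any hit with ≤ k substitutions contains one exact segment) with
full verification.  Coordinates are 0-based half-open on the plus-strand
frame; minus-strand hits report the reverse-complement window.  Windows
containing N are skipped rather than counted as mismatches, because the
energy tables are undefined for ambiguous bases.  The suite checks the
hit set against a quadratic brute-force scan on seeded 10-kb genomes for
every k in 0..6.

## Synthetic data

`synthetic.make_genome` draws i.i.d. background sequence (default GC 0.41,
a genome-like composition) and plants non-overlapping 23-nt sites with an
exact mismatch count, on either strand, recording ground-truth coordinates
in a manifest; regeneration from the same seed is byte-identical.
`synthetic.make_association_dataset` emulates the structure of a
massively parallel dCas9 association-rate experiment: one fixed guide,
off-target variants with 0–3 substitutions, and log-uniform rates over
three decades (0.1–100, arbitrary units).  The guide carries its strongest
stack at a chosen dominant position and the generator never mutates that
stack's bases, so the dominant position is a recoverable ground truth for
the trainer.  What these fixtures do not emulate: chromatin context,
sequencing noise, position-dependent mismatch tolerance of real Cas9, or
the scale of a genome — passing tests show internal correctness of the
energy model, search and training pipeline, not predictive accuracy on
real off-target data, which requires external benchmark datasets.

## Numerical choices and limitations

Test problem sizes (10-kb genomes, 50-record training sets, 50-site
ensembles, 1000-duplex conservation sweeps) keep the full suite under a
minute while exercising every code path; they are desk-scale stand-ins,
not calibrated benchmarks.  Scores are deterministic for fixed inputs;
ties in off-target ranking break by genomic coordinate.  Energy parameters
are ΔG°37 only — no enthalpy/entropy split, so no temperature
extrapolation.  Known limitations: no bulged off-targets, no
concentration/abundance weighting of the ensemble, PAM corrections are
fixed empirical constants for SpCas9, and specificity values depend on the
completeness of the supplied off-target set (genome-wide input including
the on-target is the intended use).
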