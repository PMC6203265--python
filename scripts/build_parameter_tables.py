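#!/usr/bin/env python
"""Regenerate the packaged nearest-neighbor parameter files.

Maintenance tool, not needed at run time.  Provenance of each table:

- RNA:RNA Watson-Crick stacks: Xia et al. 1998 dG37 (Turner 2004 set).
- RNA:RNA mismatch stack terms: Turner 2004 generic interior-loop mismatch
  parameters, read from the Turner 2004 parameter distribution.
- DNA:DNA Watson-Crick stacks: SantaLucia 1998 unified set.
- DNA:DNA single-mismatch terms: Allawi & SantaLucia 1997/1998 and Peyret
  et al. 1999, dG37 computed from the published dH/dS at 310.15 K (read
  from Biopython's transcription of those papers).
- RNA:DNA measured stacks: Sugimoto et al. 1995 dG37.
- Loop initiation: Turner 2004 interior array (RNA); SantaLucia-Hicks 2004
  internal loops with Jacobson-Stockmayer extrapolation past size 9 (DNA).
- Folding parameters (stacks incl. wobble, hairpin/bulge/interior arrays,
  terminal mismatches, 1x1/2x1/2x2 special loops, multiloop/Ninio/misc):
  the Turner 2004 parameter file distributed with ViennaRNA.

Usage: python scripts/build_parameter_tables.py /path/to/rna_turner2004.par
"""

import itertools
import json
import math
import re
import sys
from pathlib import Path

from Bio.SeqUtils import MeltingTemp as mt

T = 310.15
OUT = Path(__file__).resolve().parent.parent / "src" / "crisprthermo" / "data"

WC_RNA = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WC_DNA = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def rot(key):
    """Same physical stack read from the opposite strand."""
    top, bottom = key
    return (bottom[1] + bottom[0], top[1] + top[0])


# --- Watson-Crick stacks (published dG37, 10 unique values each) ---------
XIA_1998 = {
    ("AA", "UU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08, ("CA", "GU"): -2.11, ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35, ("CG", "GC"): -2.36, ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
SANTALUCIA_1998 = {
    ("AA", "TT"): -1.00, ("AT", "TA"): -0.88, ("TA", "AT"): -0.58,
    ("CA", "GT"): -1.45, ("GT", "CA"): -1.44, ("CT", "GA"): -1.28,
    ("GA", "CT"): -1.30, ("CG", "GC"): -2.17, ("GC", "CG"): -2.24,
    ("GG", "CC"): -1.84,
}


def expand(base):
    full = dict(base)
    for key, value in base.items():
        full.setdefault(rot(key), value)
    assert len(full) == 16
    return full


def turner_mismatch_bonus(top, bottom):
    """Turner 2004 interior mismatch terms adjacent to a WC pair."""
    return {("A", "G"): -0.8, ("G", "A"): -1.0, ("G", "G"): -1.0,
            ("U", "U"): -0.6}.get((top, bottom), 0.0)


def rna_mismatch_stacks():
    out = {}
    for x, y, w, z in itertools.product("ACGU", repeat=4):
        left, right = (x, w) in WC_RNA, (y, z) in WC_RNA
        if left and not right:
            out[(x + y, w + z)] = turner_mismatch_bonus(y, z)
        elif right and not left:
            out[(x + y, w + z)] = turner_mismatch_bonus(w, x)
    assert len(out) == 96
    return out


def dna_mismatch_stacks():
    imm = {}
    for key, (dh, ds) in mt.DNA_IMM1.items():
        if "I" in key:
            continue
        top, bottom = key.split("/")
        imm[(top, bottom)] = round(dh - T * ds / 1000.0, 2)
    for key, value in list(imm.items()):
        imm.setdefault(rot(key), value)
    out = {}
    for x, y, w, z in itertools.product("ACGT", repeat=4):
        if ((x, w) in WC_DNA) != ((y, z) in WC_DNA):
            out[(x + y, w + z)] = imm[(x + y, w + z)]
    assert len(out) == 96
    return out


def sugimoto_stacks():
    out = {}
    for key, (dh, ds) in mt.R_DNA_NN1.items():
        if "init" in key or key == "sym":
            continue
        top, bottom = key.split("/")
        out[(top.replace("T", "U"), bottom)] = round(dh - T * ds / 1000.0, 1)
    assert len(out) == 16
    return out


def loop_tables():
    rna = dict(zip(range(2, 13),
                   [1.0, 1.0, 1.1, 2.0, 2.0, 2.1, 2.3, 2.4, 2.5, 2.6, 2.7]))
    dna = {2: 0.0, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.8, 9: 4.9}
    for n in (10, 11, 12):
        dna[n] = round(dna[9] + 2.44 * 0.0019872 * T * math.log(n / 9.0), 1)
    return rna, dna


def write_stack_tsv():
    rna_wc, dna_wc = expand(XIA_1998), expand(SANTALUCIA_1998)
    with open(OUT / "nn_stacks.tsv", "w") as fh:
        fh.write("# Nearest-neighbor stack dG37 (kcal/mol), top strand 5'->3', bottom 3'->5' (antiparallel).\n")
        fh.write("# WC/WC stacks: Xia 1998 (RNA:RNA), SantaLucia 1998 unified (DNA:DNA), Sugimoto 1995 (RNA:DNA measured subset).\n")
        fh.write("# Mismatch-containing stacks: Turner 2004 interior mismatch terms (RNA:RNA); Allawi/SantaLucia 1997-1998 + Peyret 1999 (DNA:DNA).\n")
        fh.write("kind\ttop\tbottom\tdG\n")
        for kind, table in [("RNA:RNA", rna_wc), ("RNA:RNA", rna_mismatch_stacks()),
                            ("DNA:DNA", dna_wc), ("DNA:DNA", dna_mismatch_stacks()),
                            ("RNA:DNA", sugimoto_stacks())]:
            for (top, bottom), dg in sorted(table.items()):
                fh.write(f"{kind}\t{top}\t{bottom}\t{dg:.2f}\n")

    rna_loop, dna_loop = loop_tables()
    with open(OUT / "loop_init.tsv", "w") as fh:
        fh.write("# Interior-loop initiation dG37 (kcal/mol) by total unpaired size.\n")
        fh.write("# RNA: Turner 2004; DNA: SantaLucia-Hicks 2004 internal loops (size-2 loops are pure NN mismatches, penalty 0),\n")
        fh.write("# Jacobson-Stockmayer extrapolation beyond size 9.\n")
        fh.write("kind\tsize\tdG\n")
        for kind, table in [("RNA:RNA", rna_loop), ("DNA:DNA", dna_loop)]:
            for size, dg in sorted(table.items()):
                fh.write(f"{kind}\t{size}\t{dg:.2f}\n")


# --- folding parameters from a Turner 2004 .par file ---------------------

PAIRS = ["CG", "GC", "GU", "UG", "AU", "UA", "NN"]


def par_section(par_text, name):
    match = re.search(rf"^# {re.escape(name)}\n(.*?)(?=^# )", par_text, re.S | re.M)
    body = re.sub(r"/\*.*?\*/", "", match.group(1))
    return [None if tok == "INF" else int(tok) for tok in body.split()]


def par_mmtab(par_text, name):
    values = par_section(par_text, name)
    letters = "EACGU"
    out, idx = {}, 0
    for pair in PAIRS:
        for a in range(5):
            for b in range(5):
                v = values[idx]; idx += 1
                if pair != "NN" and a and b:
                    out[pair + letters[a] + letters[b]] = (
                        v / 100.0 if v is not None else None
                    )
    return out


def par_trimmed_flat(par_text, name, dims, keep):
    """Flatten a table, dropping NN-pair rows and index-0 letter slots."""
    values = par_section(par_text, name)
    strides, prod = [], 1
    for d in reversed(dims):
        strides.insert(0, prod)
        prod *= d
    ranges = [
        range(1, d) if k == "drop0" else (range(d - 1) if k == "droplast" else range(d))
        for d, k in zip(dims, keep)
    ]
    out = []
    for idx in itertools.product(*ranges):
        v = values[sum(i * s for i, s in zip(idx, strides))]
        out.append("x" if v is None else str(v))
    return " ".join(out)


def write_fold_params(par_path):
    par = Path(par_path).read_text()
    stack_vals = par_section(par, "stack")
    stack = {}
    for i, p in enumerate(PAIRS):
        for j, q in enumerate(PAIRS):
            if p != "NN" and q != "NN":
                stack[p + q] = stack_vals[i * 7 + j] / 100.0

    def arr(name):
        return [None if v is None else v / 100.0 for v in par_section(par, name)[:31]]

    ml = par_section(par, "ML_params")
    ninio = par_section(par, "NINIO")
    misc = par_section(par, "Misc")
    fold = {
        "stack": stack,
        "hairpin": arr("hairpin"),
        "bulge": arr("bulge"),
        "internal": arr("internal"),
        "mismatch_hairpin": par_mmtab(par, "mismatch_hairpin"),
        "mismatch_internal": par_mmtab(par, "mismatch_internal"),
        "ml_closing": ml[2] / 100.0, "ml_intern": ml[4] / 100.0,
        "ml_unpaired": ml[0] / 100.0,
        "ninio": ninio[0] / 100.0, "ninio_max": ninio[2] / 100.0,
        "terminal_au": misc[2] / 100.0,
    }
    with open(OUT / "fold_params.json", "w") as fh:
        json.dump(fold, fh, indent=1, sort_keys=True)

    special = {
        # dekacal; dims after trimming: int11 [6][6][4][4],
        # int21 [6][6][4][4][4], int22 [6][6][4][4][4][4]
        "int11": par_trimmed_flat(par, "int11", (7, 7, 5, 5),
                                  ("droplast", "droplast", "drop0", "drop0")),
        "int21": par_trimmed_flat(par, "int21", (7, 7, 5, 5, 5),
                                  ("droplast", "droplast", "drop0", "drop0", "drop0")),
        "int22": par_trimmed_flat(par, "int22", (6, 6, 4, 4, 4, 4), (None,) * 6),
        "mismatch_internal_1n": par_mmtab(par, "mismatch_internal_1n"),
        "mismatch_internal_23": par_mmtab(par, "mismatch_internal_23"),
    }
    with open(OUT / "fold_int_loops.json", "w") as fh:
        json.dump(special, fh, sort_keys=True)


if __name__ == "__main__":
    write_stack_tsv()
    if len(sys.argv) > 1:
        write_fold_params(sys.argv[1])
    print(f"parameter files written to {OUT}")
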