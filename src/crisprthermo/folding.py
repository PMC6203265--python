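"""Guide self-structure penalty ΔG_U.

A guide that folds on itself must be unfolded before it can pair with
its genomic target, so the minimum free energy (MFE) of the 20-nt
binding region enters the binding model as a penalty.  The default
backend delegates to ViennaRNA (Python bindings when importable, else
the RNAfold executable); a built-in Zuker-style dynamic program over
the packaged Turner 2004 parameters serves as a dependency-free
fallback.  MFE values are capped at zero: a guide with no stabilizing
predicted structure pays no unfolding penalty.
"""

from __future__ import annotations

import functools
import json
import shutil
import subprocess
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

__all__ = ["FoldResult", "delta_g_u", "builtin_mfe", "vienna_mfe", "available_backends"]

INF = float("inf")
_PAIRS = {"CG", "GC", "GU", "UG", "AU", "UA"}
MIN_HAIRPIN = 3


@dataclass(frozen=True)
class FoldResult:
    """MFE (kcal/mol, ≤ 0) and dot-bracket structure of a guide."""

    mfe: float
    structure: str
    backend: str

    def __post_init__(self):
        if self.mfe > 0:
            raise ValueError("FoldResult mfe must be <= 0")


@functools.lru_cache(maxsize=1)
def _params() -> Dict:
    ref = resources.files("crisprthermo.data").joinpath("fold_params.json")
    return json.loads(ref.read_text())


_PAIR_INDEX = {"CG": 0, "GC": 1, "GU": 2, "UG": 3, "AU": 4, "UA": 5}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@functools.lru_cache(maxsize=1)
def _int_loop_tables() -> Dict:
    """Tabulated 1x1 / 2x1 / 2x2 interior-loop energies (kcal/mol)."""
    ref = resources.files("crisprthermo.data").joinpath("fold_int_loops.json")
    raw = json.loads(ref.read_text())
    out = {}
    for name in ("int11", "int21", "int22"):
        out[name] = [
            INF if tok == "x" else int(tok) / 100.0 for tok in raw[name].split()
        ]
    out["mm_1n"] = raw["mismatch_internal_1n"]
    out["mm_23"] = raw["mismatch_internal_23"]
    return out


def _int11(t, t1, t2, a, b):
    return t["int11"][((t1 * 6 + t2) * 4 + a) * 4 + b]


def _int21(t, t1, t2, a, b, c):
    return t["int21"][(((t1 * 6 + t2) * 4 + a) * 4 + b) * 4 + c]


def _int22(t, t1, t2, a, b, c, d):
    return t["int22"][((((t1 * 6 + t2) * 4 + a) * 4 + b) * 4 + c) * 4 + d]


def _try_import_vienna():
    try:
        import RNA  # type: ignore

        return RNA
    except ImportError:
        return None


def available_backends() -> Tuple[str, ...]:
    out = ["builtin"]
    if shutil.which("RNAfold"):
        out.insert(0, "rnafold")
    if _try_import_vienna() is not None:
        out.insert(0, "vienna")
    return tuple(out)


def vienna_mfe(seq: str, dangles: int = 2, special_hp: bool = True):
    """MFE via ViennaRNA with configurable dangle/special-hairpin handling."""
    RNA = _try_import_vienna()
    if RNA is not None:
        md = RNA.md()
        md.dangles = dangles
        md.special_hp = 1 if special_hp else 0
        fc = RNA.fold_compound(seq, md)
        structure, mfe = fc.mfe()
        return float(mfe), structure
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("ViennaRNA backend requested but not available")
    args = [exe, "--noPS", f"-d{dangles}"]
    if not special_hp:
        args.append("-4")
    proc = subprocess.run(
        args, input=seq + "\n", capture_output=True, text=True, check=True
    )
    lines = proc.stdout.strip().splitlines()
    structure, energy = lines[-1].rsplit(None, 1)
    return float(energy.strip("()")), structure


def _can_pair(a: str, b: str) -> bool:
    return a + b in _PAIRS


def _loop_arr(arr, size: int) -> float:
    if size >= len(arr):
        return arr[-1]
    v = arr[size]
    return INF if v is None else v


def _mm(table: Dict, pair: str, a: str, b: str) -> float:
    v = table.get(pair + a + b)
    return 0.0 if v is None else v


def _terminal_au(p: Dict, a: str, b: str) -> float:
    return p["terminal_au"] if a + b not in ("CG", "GC") else 0.0


def builtin_mfe(seq: str) -> Tuple[float, str]:
    """Zuker-style MFE over the packaged Turner 2004 parameters.

    Models stacks, hairpins (with terminal mismatches), generic interior
    and bulge loops, terminal-AU penalties, and linear multiloops; no
    dangling ends, no tetraloop bonuses, no special 1×1/2×2 tables.
    """
    p = _params()
    s = seq
    n = len(s)
    stack = p["stack"]

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]   # >=1 branch, multiloop interior
    WM2 = [[INF] * n for _ in range(n)]  # >=2 branches
    tb: Dict[Tuple[str, int, int], tuple] = {}

    def hairpin(i, j):
        size = j - i - 1
        if size < MIN_HAIRPIN:
            return INF
        e = _loop_arr(p["hairpin"], size)
        e += _mm(p["mismatch_hairpin"], s[i] + s[j], s[i + 1], s[j - 1])
        return e

    spec = _int_loop_tables()

    def two_loop(i, j, k, l):
        """Energy of the loop between closing pair (i,j) and inner pair (k,l)."""
        u1, u2 = k - i - 1, j - l - 1
        # stacks and loop tables index the enclosed pair reversed: (s_l, s_k)
        if u1 == 0 and u2 == 0:
            return stack.get(s[i] + s[j] + s[l] + s[k], INF)
        if u1 == 0 or u2 == 0:
            u = max(u1, u2)
            e = _loop_arr(p["bulge"], u)
            if u == 1:
                e += stack.get(s[i] + s[j] + s[l] + s[k], INF)
            else:
                e += _terminal_au(p, s[i], s[j]) + _terminal_au(p, s[l], s[k])
            return e
        t1 = _PAIR_INDEX.get(s[i] + s[j])
        t2 = _PAIR_INDEX.get(s[l] + s[k])
        if t1 is None or t2 is None:
            return INF
        si1, sj1 = _BASE_INDEX[s[i + 1]], _BASE_INDEX[s[j - 1]]
        sp1, sq1 = _BASE_INDEX[s[k - 1]], _BASE_INDEX[s[l + 1]]
        if u1 == 1 and u2 == 1:
            return _int11(spec, t1, t2, si1, sj1)
        if u1 == 1 and u2 == 2:
            return _int21(spec, t1, t2, si1, sq1, sj1)
        if u1 == 2 and u2 == 1:
            return _int21(spec, t2, t1, sq1, si1, sp1)
        if u1 == 2 and u2 == 2:
            return _int22(spec, t1, t2, si1, sp1, sq1, sj1)
        e = _loop_arr(p["internal"], u1 + u2)
        e += min(p["ninio"] * abs(u1 - u2), p["ninio_max"])
        if u1 == 1 or u2 == 1:
            mm = spec["mm_1n"]
        elif u1 + u2 == 5:
            mm = spec["mm_23"]
        else:
            mm = p["mismatch_internal"]
        e += _mm(mm, s[i] + s[j], s[i + 1], s[j - 1])
        e += _mm(mm, s[l] + s[k], s[l + 1], s[k - 1])
        return e

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            # V
            if _can_pair(s[i], s[j]):
                best, back = hairpin(i, j), ("hairpin",)
                for k in range(i + 1, j):
                    for l in range(max(k + MIN_HAIRPIN + 1, j - 1 - 30), j):
                        if l <= k or V[k][l] == INF or not _can_pair(s[k], s[l]):
                            continue
                        e = two_loop(i, j, k, l) + V[k][l]
                        if e < best:
                            best, back = e, ("two", k, l)
                for k in range(i + 1, j - 1):
                    if WM[i + 1][k] < INF and WM2[k + 1][j - 1] < INF:
                        e = (
                            p["ml_closing"]
                            + p["ml_intern"]
                            + _terminal_au(p, s[j], s[i])
                            + WM[i + 1][k]
                            + WM2[k + 1][j - 1]
                        )
                        if e < best:
                            best, back = e, ("multi", k)
                V[i][j] = best
                tb[("V", i, j)] = back
            # WM / WM2 (per-unpaired cost is zero in this parameter set)
            wm, wmb = INF, None
            if V[i][j] < INF:
                e = V[i][j] + p["ml_intern"] + _terminal_au(p, s[i], s[j])
                wm, wmb = e, ("branch",)
            if i + 1 <= j and WM[i + 1][j] + p["ml_unpaired"] < wm:
                wm, wmb = WM[i + 1][j] + p["ml_unpaired"], ("skip5",)
            if j - 1 >= i and WM[i][j - 1] + p["ml_unpaired"] < wm:
                wm, wmb = WM[i][j - 1] + p["ml_unpaired"], ("skip3",)
            wm2, wm2b = INF, None
            for k in range(i, j):
                if WM[i][k] < INF and WM[k + 1][j] < INF:
                    e = WM[i][k] + WM[k + 1][j]
                    if e < wm:
                        wm, wmb = e, ("split", k)
                    if e < wm2:
                        wm2, wm2b = e, ("split", k)
            WM[i][j] = wm
            WM2[i][j] = wm2
            if wmb is not None:
                tb[("WM", i, j)] = wmb
            if wm2b is not None:
                tb[("WM2", i, j)] = wm2b

    # exterior loop
    W = [0.0] * (n + 1)
    wtb: Dict[int, tuple] = {}
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        wtb[j] = ("unpaired",)
        for i in range(0, j):
            if V[i][j - 1] < INF:
                e = W[i] + V[i][j - 1] + _terminal_au(p, s[i], s[j - 1])
                if e < W[j]:
                    W[j] = e
                    wtb[j] = ("pair", i)

    mfe = W[n]
    structure = ["."] * n

    def trace_v(i, j):
        structure[i], structure[j] = "(", ")"
        kind = tb[("V", i, j)]
        if kind[0] == "two":
            trace_v(kind[1], kind[2])
        elif kind[0] == "multi":
            trace_wm(i + 1, kind[1], False)
            trace_wm(kind[1] + 1, j - 1, True)

    def trace_wm(i, j, two):
        key = ("WM2" if two else "WM", i, j)
        kind = tb.get(key)
        if kind is None:
            return
        if kind[0] == "branch":
            trace_v(i, j)
        elif kind[0] == "skip5":
            trace_wm(i + 1, j, False)
        elif kind[0] == "skip3":
            trace_wm(i, j - 1, False)
        elif kind[0] == "split":
            trace_wm(i, kind[1], False)
            trace_wm(kind[1] + 1, j, False)

    def trace_w(j):
        while j > 0:
            kind = wtb[j]
            if kind[0] == "unpaired":
                j -= 1
            else:
                trace_v(kind[1], j - 1)
                j = kind[1]

    if mfe < 0:
        trace_w(n)
    else:
        mfe = 0.0
    return round(mfe, 2), "".join(structure)


@functools.lru_cache(maxsize=4096)
def _fold_cached(seq: str, backend: str) -> FoldResult:
    if backend == "auto":
        avail = available_backends()
        backend = avail[0]
    if backend in ("vienna", "rnafold"):
        mfe, structure = vienna_mfe(seq)
        used = backend
    elif backend == "builtin":
        mfe, structure = builtin_mfe(seq)
        used = "builtin"
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    if mfe >= 0:
        return FoldResult(0.0, "." * len(seq), used)
    return FoldResult(float(mfe), structure, used)


def delta_g_u(g, backend: str = "auto") -> FoldResult:
    """MFE self-structure of the guide's 20-nt binding region.

    Accepts a GuideRNA or a plain RNA string; returns 0 with an
    unstructured string when no negative-energy structure exists.
    """
    seq = getattr(g, "sequence", g)
    return _fold_cached(seq, backend)
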