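"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: translation goes
through Bio.Seq, pathway counting through itertools permutations, Fisher
probabilities through math.comb, and alignment scores through exhaustive
enumeration of all global alignments.
"""

from __future__ import annotations

import cmath
import math
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(codon_pairs):
    """Brute-force NG86: fractional sites by mutating every base, pathway
    averaging by permutation enumeration, JC correction applied last.

    Returns dict with N, S, Nd, Sd, pn, ps, ka, ks (None when undefined).
    """
    S = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        for codon in (ca, cb):
            for pos in range(3):
                syn = valid = 0
                for base in BASES:
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1:]
                    if _translate(alt) == "*":
                        continue
                    valid += 1
                    if _translate(alt) == _translate(codon):
                        syn += 1
                if valid:
                    S += 0.5 * syn / valid
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        if diffs:
            paths = []
            for order in permutations(diffs):
                cur = ca
                steps = []
                ok = True
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if _translate(nxt) == "*":
                        ok = False
                        break
                    steps.append(_translate(cur) == _translate(nxt))
                    cur = nxt
                if ok:
                    paths.append(steps)
            assert paths, "all pathways blocked between sense codons"
            Sd += sum(sum(p) for p in paths) / len(paths)
            Nd += sum(len(p) - sum(p) for p in paths) / len(paths)
    total = 3.0 * len(codon_pairs)
    N = total - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0

    return {"N": N, "S": S, "Nd": Nd, "Sd": Sd, "pn": pn, "ps": ps,
            "ka": jc(pn), "ks": jc(ps)}


def alignment_score_oracle(a: str, b: str, matrix, gap_open=-10.0,
                           gap_extend=-0.5) -> float:
    """Max score over every global alignment, enumerated recursively.

    A gap of length L scores gap_open + (L-1)*gap_extend, matching the
    production aligner's convention.
    """
    best = [-math.inf]

    def rec(i, j, score, prev_move):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev_move == "D" else gap_open
            rec(i + 1, j, score + cost, "D")
        if j < len(b):
            cost = gap_extend if prev_move == "I" else gap_open
            rec(i, j + 1, score + cost, "I")

    rec(0, 0, 0.0, "")
    return best[0]


def fisher_oracle(n_with_a, n_total_a, n_with_b, n_total_b) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins."""
    m = n_with_a + n_with_b
    big_n = n_total_a + n_total_b
    denom = math.comb(big_n, m)
    lo = max(0, m - n_total_b)
    hi = min(m, n_total_a)
    pmf = {k: math.comb(n_total_a, k) * math.comb(n_total_b, m - k) / denom
           for k in range(lo, hi + 1)}
    obs = pmf[n_with_a]
    return min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-9)))


def hydrophobic_moment_oracle(hydrophobicities, delta_deg=100.0) -> float:
    """Direct complex summation of the helical moment."""
    d = math.radians(delta_deg)
    total = 0j
    for n, h in enumerate(hydrophobicities):
        total += h * cmath.exp(1j * n * d)
    return abs(total) / len(hydrophobicities)


def pearson_oracle(x, y) -> float:
    """Textbook covariance-formula Pearson r."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def motif_scan_oracle(sequence: str, motifs) -> list[int]:
    """Sliding-window scan against explicit expansion sets (1-based)."""
    import itertools

    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
             "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}
    hits = set()
    for motif in motifs:
        words = {"".join(p) for p in itertools.product(*(iupac[c] for c in motif))}
        k = len(motif)
        for i in range(len(sequence) - k + 1):
            if sequence[i:i + k] in words:
                hits.add(i + 1)
    return sorted(hits)
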