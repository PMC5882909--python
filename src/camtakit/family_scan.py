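"""Domain-architecture scanning and protein-property computation.

Two matching engines are bundled:

* a consensus-pattern engine for the literature-derived CaMBD and IQ
  motifs, where ``X`` is any residue, ``[...]`` a residue class and
  ``(k)`` repeats the preceding element ``k`` times;
* a position-weight-matrix engine for the CG-1, TIG and ankyrin domains,
  built from bundled seed alignments and scored as log-odds against a
  uniform background.

The NLS rule is a bipartite basic-residue pattern: two clusters of >= 2
K/R separated by a 9-12 residue non-basic linker.
"""

from __future__ import annotations

import cmath
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .models import AA_ALPHABET, GeneModel, ProteinRecord, ValidationError

# ---------------------------------------------------------------------------
# bundled residue tables
# ---------------------------------------------------------------------------

#: Average residue masses (Da), Expasy convention; add one water per chain.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

#: Side-chain / termini pKa values (EMBOSS set).
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

#: Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

_NEGATIVE = set("DE")
_POSITIVE = set("KRH")
_HYDROPHOBIC = set("AVLIMFWC")


def residue_class(aa: str) -> str:
    if aa in _NEGATIVE:
        return "negative"
    if aa in _POSITIVE:
        return "positive"
    if aa in _HYDROPHOBIC:
        return "hydrophobic"
    return "hydrophilic"


# ---------------------------------------------------------------------------
# consensus patterns
# ---------------------------------------------------------------------------

CONSENSUS_PATTERNS = {
    # calmodulin-binding region consensus
    "CaMBD": "WXVX(2)[LVI]XKX(2)[L][R][W][R]X[KR]X(3)[FL][R]X",
    # strict IQ motif
    "IQ": "IQXXXRGXXXR",
    # relaxed IQ variant, off by default in classification
    "IQ_relaxed": "[IL]QXXXRXXXXR",
}

_NLS_REGEX = re.compile(r"[KR]{2,}[^KR]{9,12}[KR]{2,}")

_TOKEN = re.compile(r"(\[[A-Z]+\]|[A-Z])(\((\d+)\))?")


def consensus_to_regex(pattern: str) -> re.Pattern:
    """Compile a consensus string (X / [classes] / (k) repeats) to a regex."""
    pos = 0
    parts = []
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"bad consensus syntax at {pattern[pos:]!r}")
        elem, _, rep = m.groups()
        piece = "." if elem == "X" else elem
        if rep is not None:
            piece += "{%d}" % int(rep)
        parts.append(piece)
        pos = m.end()
    return re.compile("".join(parts))


# ---------------------------------------------------------------------------
# bundled PWM seed alignments (CG-1 seeds carry the bipartite NLS layout)
# ---------------------------------------------------------------------------

PWM_SEEDS = {
    "CG1": [
        "AKKWSDLQGHVNTRKEAGFLYDPMSTEQVL",
        "GKKWSDLQGHVNTRKEAGFLYDPMSTEQVI",
        "AKRWSELQGHVNTRKDAGFLYEPMSTDQVL",
        "AKKWTDLQGHINTRKEAGFMYDPMSTEQVL",
        "AKKWSDLQAHVNSRKEGGFLYDPLSTEQVL",
    ],
    "TIG": [
        "GFEVPFSPTQLVTSNVEWVRDGAT",
        "GFEVPYSPTQLVTSNVEWVRDGST",
        "GFDVPFSPSQLVTSNIEWVRDGAT",
        "GFEVPFAPTQLITSNVEWVREGAT",
    ],
    "ANK": [
        "GTPLHLAARNGHLEVVKLLLEAGA",
        "GTPLHVAARNGHLEVVKLLLDAGA",
        "GSPLHLAAQNGHLEVVRLLLEAGA",
        "GTPLHLAARNGHIEVVKLLIEAGA",
    ],
}

_AA_ORDER = sorted(AA_ALPHABET)
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}


class PositionWeightMatrix:
    """Log-odds PWM against a uniform 1/20 background."""

    def __init__(self, seeds: list[str], pseudocount: float = 0.5):
        if len({len(s) for s in seeds}) != 1:
            raise ValueError("seed sequences must share one length")
        self.length = len(seeds[0])
        counts = np.full((self.length, 20), pseudocount)
        for s in seeds:
            for j, aa in enumerate(s):
                counts[j, _AA_INDEX[aa]] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        self.logodds = np.log2(probs / (1.0 / 20.0))
        self.min_seed_score = min(self.score(s) for s in seeds)

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        return float(
            sum(self.logodds[j, _AA_INDEX[aa]] for j, aa in enumerate(window)
                if aa in _AA_INDEX)
        )

    def scan(self, sequence: str, threshold: float) -> list[tuple[int, float]]:
        """Greedy left-to-right non-overlapping hits: (0-based start, score)."""
        hits = []
        i = 0
        while i + self.length <= len(sequence):
            s = self.score(sequence[i:i + self.length])
            if s >= threshold:
                hits.append((i, s))
                i += self.length
            else:
                i += 1
        return hits


_PWMS = {name: PositionWeightMatrix(seeds) for name, seeds in PWM_SEEDS.items()}

#: Fraction of the weakest seed's own score a window must reach.
PWM_THRESHOLD_FRACTION = 0.8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    domain: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    matched_text: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError("domain hit with illegal coordinates")


@dataclass
class DomainArchitecture:
    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)
    is_camta: bool = False
    tig_type: str = "n/a"  # TIG | non-TIG | n/a
    iq_count: int = 0


@dataclass
class HelixWindowScore:
    window_start: int
    window_len: int
    hydrophobic_moment: float
    mean_hydrophobicity: float
    wheel_classes: list[str]


KNOWN_PATTERNS = ("CG1", "TIG", "ANK", "IQ", "CaMBD", "NLS")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scan_consensus(protein: ProteinRecord, pattern_name: str,
                   relaxed_iq: bool = False) -> list[DomainHit]:
    """All non-overlapping left-to-right matches of one domain pattern."""
    seq = protein.sequence
    if pattern_name in _PWMS:
        pwm = _PWMS[pattern_name]
        thr = PWM_THRESHOLD_FRACTION * pwm.min_seed_score
        return [
            DomainHit(pattern_name, i + 1, i + pwm.length, seq[i:i + pwm.length])
            for i, _score in pwm.scan(seq, thr)
        ]
    if pattern_name == "NLS":
        regex = _NLS_REGEX
    elif pattern_name == "IQ":
        key = "IQ_relaxed" if relaxed_iq else "IQ"
        regex = consensus_to_regex(CONSENSUS_PATTERNS[key])
    elif pattern_name in CONSENSUS_PATTERNS:
        regex = consensus_to_regex(CONSENSUS_PATTERNS[pattern_name])
    else:
        raise ValueError(f"unknown pattern {pattern_name!r}; "
                         f"known: {KNOWN_PATTERNS}")
    name = "IQ" if pattern_name.startswith("IQ") else pattern_name
    return [
        DomainHit(name, m.start() + 1, m.end(), m.group(0))
        for m in regex.finditer(seq)
    ]


def scan_all(protein: ProteinRecord, relaxed_iq: bool = False) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for name in ("CG1", "TIG", "ANK", "IQ", "CaMBD", "NLS"):
        hits.extend(scan_consensus(protein, name, relaxed_iq=relaxed_iq))
    return sorted(hits, key=lambda h: (h.start, h.end))


def classify_architecture(hits: list[DomainHit],
                          protein: ProteinRecord) -> DomainArchitecture:
    """Family membership: CG-1 present AND (IQ or CaMBD present); TIG status
    distinguishes TIG-type from non-TIG members."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    domains = {h.domain for h in hits}
    iq_count = sum(1 for h in hits if h.domain == "IQ")
    is_camta = "CG1" in domains and ("IQ" in domains or "CaMBD" in domains)
    if not is_camta:
        tig_type = "n/a"
    elif "TIG" in domains:
        tig_type = "TIG"
    else:
        tig_type = "non-TIG"
    return DomainArchitecture(
        protein_id=protein.id, hits=hits, is_camta=is_camta,
        tig_type=tig_type, iq_count=iq_count,
    )


def compute_mw(protein: ProteinRecord) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    if not protein.sequence:
        raise ValidationError(f"protein {protein.id!r}: empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(protein.sequence, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValidationError(
                f"protein {protein.id!r}: non-standard residue {aa!r} "
                f"at position {pos}"
            ) from None
    return total


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge over termini and ionizable side chains."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in sequence:
        if aa in PKA_POSITIVE and aa != "nterm":
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def compute_pi(protein: ProteinRecord, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH where the net charge crosses zero.

    The charge curve is strictly decreasing in pH, so bisection on [0, 14]
    converges to the unique root.
    """
    if not protein.sequence:
        raise ValidationError(f"protein {protein.id!r}: empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(protein.sequence, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(protein: ProteinRecord, start: int, window: int = 18,
                       delta: float = 100.0) -> HelixWindowScore:
    """Mean hydrophobic moment of one helix window.

    ``start`` is 1-based; ``delta`` is the per-residue helical rotation in
    degrees. mu_H = |sum_n h_n * exp(i*n*delta)| / window on the Eisenberg
    scale.
    """
    if start < 1 or start + window - 1 > protein.length:
        raise ValidationError(
            f"window [{start}, {start + window - 1}] exceeds protein "
            f"{protein.id!r} of length {protein.length}"
        )
    segment = protein.sequence[start - 1:start - 1 + window]
    h = [EISENBERG[aa] for aa in segment]
    rad = math.radians(delta)
    total = sum(hn * cmath.exp(1j * n * rad) for n, hn in enumerate(h))
    return HelixWindowScore(
        window_start=start,
        window_len=window,
        hydrophobic_moment=abs(total) / window,
        mean_hydrophobicity=sum(h) / window,
        wheel_classes=[residue_class(aa) for aa in segment],
    )


#: mu_H above which a window is called amphipathic (Eisenberg scale).
AMPHIPATHIC_THRESHOLD = 0.2


def best_amphipathic_window(protein: ProteinRecord, window: int = 18,
                            delta: float = 100.0) -> HelixWindowScore | None:
    """Highest-moment window of the protein, or None if it is too short."""
    if protein.length < window:
        return None
    best = None
    for start in range(1, protein.length - window + 2):
        score = hydrophobic_moment(protein, start, window, delta)
        if best is None or score.hydrophobic_moment > best.hydrophobic_moment:
            best = score
    return best


def intron_counts(gene_models: list[GeneModel]) -> dict[str, int]:
    """Introns per gene = exon count - 1 (0 for single-exon genes)."""
    return {g.id: g.intron_count for g in gene_models}


def architecture_report(proteins: list[ProteinRecord],
                        gene_models: list[GeneModel] | None = None,
                        relaxed_iq: bool = False):
    """Per-protein summary table: classification plus physical properties."""
    import pandas as pd

    introns = intron_counts(gene_models) if gene_models else {}
    rows = []
    for p in proteins:
        arch = classify_architecture(scan_all(p, relaxed_iq=relaxed_iq), p)
        domain_str = ";".join(f"{h.domain}:{h.start}-{h.end}" for h in arch.hits)
        rows.append({
            "id": p.id,
            "length_aa": p.length,
            "mw_da": round(compute_mw(p), 2),
            "pi": round(compute_pi(p), 2),
            "is_camta": arch.is_camta,
            "tig_type": arch.tig_type,
            "iq_count": arch.iq_count,
            "domains": domain_str,
            "introns": introns.get(p.id, pd.NA),
        })
    return pd.DataFrame(rows)
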