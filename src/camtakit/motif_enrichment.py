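"""Promoter extraction, IUPAC degenerate motif scanning, and Fisher's
exact enrichment against a random control set."""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GeneModel, ValidationError

DEFAULT_MOTIFS = ("MCGCGB", "MCGTGT")
DEFAULT_PROMOTER_LENGTH = 1000
DEFAULT_CONTROL_N = 700

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Matcher:
    """Compiled IUPAC motif: accepts exactly the expansion set."""

    motif: str
    regex: re.Pattern          # full-kmer matcher
    search_regex: re.Pattern   # lookahead form, finds overlapping starts
    length: int

    def matches(self, kmer: str) -> bool:
        return self.regex.fullmatch(kmer) is not None

    def find_all(self, sequence: str) -> list[int]:
        """0-based start positions of all (overlapping) matches."""
        return [m.start() for m in self.search_regex.finditer(sequence)]

    def expansion(self) -> list[str]:
        return ["".join(p) for p in itertools.product(*(IUPAC[c] for c in self.motif))]


def iupac_expand(motif: str) -> Matcher:
    """Build a matcher for an IUPAC degenerate motif. N in the scanned
    sequence never matches (it is not in any symbol's expansion class)."""
    motif = motif.upper()
    bad = [c for c in motif if c not in IUPAC]
    if bad:
        raise ValidationError(f"non-IUPAC symbol(s) {bad} in motif {motif!r}")
    pattern = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in motif
    )
    return Matcher(motif=motif, regex=re.compile(pattern),
                   search_regex=re.compile("(?=" + pattern + ")"),
                   length=len(motif))


@dataclass
class PromoterSet:
    entries: dict[str, str]
    promoter_length: int = DEFAULT_PROMOTER_LENGTH
    truncated_flags: dict[str, bool] = field(default_factory=dict)


def extract_promoters(genome: dict[str, str], models: list[GeneModel],
                      length: int = DEFAULT_PROMOTER_LENGTH) -> PromoterSet:
    """Strand-aware upstream sequences.

    Plus strand: the ``length`` bases ending immediately before the gene
    start. Minus strand: reverse complement of the ``length`` bases starting
    immediately after the gene end. Promoters running over a chromosome edge
    are truncated and flagged.
    """
    entries: dict[str, str] = {}
    flags: dict[str, bool] = {}
    for g in models:
        if g.chromosome not in genome:
            raise ValidationError(f"chromosome {g.chromosome!r} not in genome")
        chrom = genome[g.chromosome]
        if g.strand == "+":
            lo = max(0, g.start - 1 - length)
            seq = chrom[lo:g.start - 1]
        else:
            seq = reverse_complement(chrom[g.end:g.end + length])
        entries[g.id] = seq
        flags[g.id] = len(seq) < length
    return PromoterSet(entries=entries, promoter_length=length,
                       truncated_flags=flags)


def scan_promoter(promoter: str, matchers: list[Matcher],
                  both_strands: bool = True) -> list[int]:
    """All (possibly overlapping) match start positions, 1-based.

    With ``both_strands`` each motif's reverse complement is scanned too;
    positions hit by more than one motif are reported once.
    """
    promoter = promoter.upper()
    all_matchers = list(matchers)
    if both_strands:
        all_matchers += [iupac_expand(reverse_complement(m.motif)) for m in matchers]
    positions: set[int] = set()
    for m in all_matchers:
        positions.update(i + 1 for i in m.find_all(promoter))
    return sorted(positions)


def set_frequency(promoters: PromoterSet, matchers: list[Matcher],
                  both_strands: bool = True, mode: str = "presence"
                  ) -> tuple[float, int, dict[str, int]]:
    """Motif statistic over a promoter set.

    mode="presence" (default): fraction of promoters with >= 1 match.
    mode="count": mean number of match positions per promoter.
    Returns (frequency, n_with_motif, per-promoter match counts).
    """
    if not promoters.entries:
        raise ValidationError("empty promoter set")
    counts = {
        gid: len(scan_promoter(seq, matchers, both_strands))
        for gid, seq in promoters.entries.items()
    }
    n_with = sum(1 for c in counts.values() if c > 0)
    if mode == "presence":
        freq = n_with / len(counts)
    elif mode == "count":
        freq = sum(counts.values()) / len(counts)
    else:
        raise ValidationError(f"unknown frequency mode {mode!r}")
    return freq, n_with, counts


@dataclass
class MotifEnrichmentResult:
    set_name: str
    n_total: int
    n_with_motif: int
    frequency: float
    control_n_total: int
    control_n_with: int
    odds_ratio: float
    p_value: float


_LGAMMA_CACHE: dict[int, float] = {}


def _log_comb(n: int, k: int) -> float:
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))


def fisher_enrichment(n_with_a: int, n_total_a: int,
                      n_with_b: int, n_total_b: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on presence/absence counts.

    p sums hypergeometric probabilities no larger than that of the observed
    table (with a small relative tolerance for float ties). The sample odds
    ratio (ad/bc) is reported; when any cell is zero, 0.5 is added to all
    four cells (Haldane–Anscombe) before forming the ratio.

    Returns (odds_ratio, p_value).
    """
    if n_total_a <= 0 or n_total_b <= 0:
        raise ValidationError("group totals must be positive")
    if not (0 <= n_with_a <= n_total_a and 0 <= n_with_b <= n_total_b):
        raise ValidationError("counts must satisfy 0 <= n_with <= n_total")
    a, b = n_with_a, n_with_b
    c, d = n_total_a - a, n_total_b - b
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    odds_ratio = (oa * od) / (ob * oc)

    m = a + b                     # total successes
    big_n = n_total_a + n_total_b
    lo = max(0, m - n_total_b)
    hi = min(m, n_total_a)
    log_denom = _log_comb(big_n, m)
    log_pmf = {
        k: _log_comb(n_total_a, k) + _log_comb(n_total_b, m - k) - log_denom
        for k in range(lo, hi + 1)
    }
    observed = log_pmf[a]
    eps = 1e-7
    p = sum(
        math.exp(lp) for lp in log_pmf.values() if lp <= observed + eps
    )
    return odds_ratio, min(p, 1.0)


def sample_control(all_genes: list[str], exclude: set[str],
                   n: int = DEFAULT_CONTROL_N, seed: int = 0) -> list[str]:
    """Uniform seeded sample (without replacement) from genes not excluded."""
    pool = sorted(set(all_genes) - set(exclude))
    if len(pool) < n:
        raise ValidationError(
            f"only {len(pool)} candidate genes for a control of {n}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picked)]


def enrichment_report(sets: dict[str, PromoterSet], control: PromoterSet,
                      matchers: list[Matcher], both_strands: bool = True,
                      mode: str = "presence") -> pd.DataFrame:
    """Per-set frequency and Fisher comparison against the control."""
    ctrl_freq, ctrl_with, _ = set_frequency(control, matchers, both_strands, mode)
    rows = []
    for name, pset in sets.items():
        freq, n_with, _ = set_frequency(pset, matchers, both_strands, mode)
        odds, p = fisher_enrichment(
            n_with, len(pset.entries), ctrl_with, len(control.entries)
        )
        rows.append(MotifEnrichmentResult(
            set_name=name, n_total=len(pset.entries), n_with_motif=n_with,
            frequency=freq, control_n_total=len(control.entries),
            control_n_with=ctrl_with, odds_ratio=odds, p_value=p,
        ))
    rows.append(MotifEnrichmentResult(
        set_name="control", n_total=len(control.entries),
        n_with_motif=ctrl_with, frequency=ctrl_freq,
        control_n_total=len(control.entries), control_n_with=ctrl_with,
        odds_ratio=1.0, p_value=1.0,
    ))
    return pd.DataFrame([vars(r) for r in rows])


def write_match_bed(genome: dict[str, str], models: list[GeneModel],
                    matchers: list[Matcher], path: str | Path,
                    length: int = DEFAULT_PROMOTER_LENGTH,
                    both_strands: bool = True) -> None:
    """Match coordinates on the genome (BED, 0-based half-open)."""
    pset = extract_promoters(genome, models, length)
    by_id = {g.id: g for g in models}
    with open(path, "w") as fh:
        for gid, seq in pset.entries.items():
            g = by_id[gid]
            for pos in scan_promoter(seq, matchers, both_strands):
                if g.strand == "+":
                    promoter_start0 = max(0, g.start - 1 - length)
                    s0 = promoter_start0 + pos - 1
                else:
                    s0 = g.end + len(seq) - pos - matchers[0].length + 1
                fh.write(f"{g.chromosome}\t{s0}\t{s0 + matchers[0].length}\t{gid}\n")
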