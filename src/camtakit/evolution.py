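"""Comparative-evolutionary operations.

Pairwise global protein alignment (BLOSUM62, affine gaps), paralog and
reciprocal-best-hit ortholog detection, codon back-translation, an
in-repo Nei–Gojobori (1986) Ka/Ks estimator with Jukes–Cantor correction,
selection labeling, duplication typing/dating, and neighbor-joining trees
with bootstrap supports.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .models import AA_ALPHABET, GeneModel, ProteinRecord, ValidationError

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# genetic code tables
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return "*" if codon in STOP_CODONS else CODON_TO_AA[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValidationError("CDS length not divisible by 3")
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# pairwise protein alignment
# ---------------------------------------------------------------------------

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -10.0    # score of a length-1 gap
GAP_EXTEND = -0.5   # per additional gapped position


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float
    similarity_pct: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def align_global(a: ProteinRecord, b: ProteinRecord) -> PairwiseAlignment:
    """Optimal global alignment (BLOSUM62, gap open 10 / extend 0.5).

    identity = % identical columns among columns aligning two residues;
    similarity = % of those columns with a positive BLOSUM62 score;
    coverage = residue-residue columns as % of the longer input length.
    """
    for p in (a, b):
        bad = set(p.sequence) - AA_ALPHABET
        if bad or not p.sequence:
            raise ValidationError(
                f"protein {p.id!r}: not alignable (symbols {sorted(bad)})"
            )
    aln = _ALIGNER.align(a.sequence, b.sequence)[0]
    row_a, row_b = aln[0], aln[1]
    aligned = ident = positive = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        aligned += 1
        if ca == cb:
            ident += 1
        if BLOSUM62[ca, cb] > 0:
            positive += 1
    longer = max(len(a.sequence), len(b.sequence))
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, aligned_a=row_a, aligned_b=row_b,
        score=float(aln.score),
        identity_pct=100.0 * ident / aligned if aligned else 0.0,
        coverage_pct=100.0 * aligned / longer,
        similarity_pct=100.0 * positive / aligned if aligned else 0.0,
    )


# ---------------------------------------------------------------------------
# paralog / ortholog detection
# ---------------------------------------------------------------------------

def passes_paralog_rule(coverage_pct: float, similarity_pct: float,
                        coverage_thr: float = 70.0,
                        similarity_thr: float = 70.0) -> bool:
    """Strict '>' on both coverage and similarity, per the 70/70 rule."""
    return coverage_pct > coverage_thr and similarity_pct > similarity_thr


def detect_paralogs(proteins: list[ProteinRecord],
                    coverage_thr: float = 70.0,
                    similarity_thr: float = 70.0,
                    similarity_metric: str = "positive",
                    ) -> list[PairwiseAlignment]:
    """All unordered pairs passing the coverage/similarity rule.

    ``similarity_metric`` selects which alignment statistic feeds the rule:
    "positive" (% positive-scoring columns, default) or "identity".
    """
    if len(proteins) < 2:
        raise ValidationError("paralog detection needs >= 2 proteins")
    accepted = []
    for a, b in itertools.combinations(proteins, 2):
        aln = align_global(a, b)
        sim = aln.similarity_pct if similarity_metric == "positive" else aln.identity_pct
        if passes_paralog_rule(aln.coverage_pct, sim, coverage_thr, similarity_thr):
            accepted.append(aln)
    return accepted


def rbh_orthologs(set_a: list[ProteinRecord], set_b: list[ProteinRecord]
                  ) -> tuple[list[tuple[str, str]], list[str]]:
    """Reciprocal-best pairs by alignment score; ties yield no pair.

    Returns (pairs, tie_log).
    """
    if not set_a or not set_b:
        raise ValidationError("both protein sets must be non-empty")
    scores = {
        (a.id, b.id): align_global(a, b).score for a in set_a for b in set_b
    }

    def best(queries, targets, lookup):
        out = {}
        ties = []
        for q in queries:
            ranked = sorted(targets, key=lambda t: lookup(q, t), reverse=True)
            if len(ranked) > 1 and lookup(q, ranked[0]) == lookup(q, ranked[1]):
                ties.append(q.id)
                out[q.id] = None
            else:
                out[q.id] = ranked[0].id
        return out, ties

    best_ab, ties_a = best(set_a, set_b, lambda q, t: scores[(q.id, t.id)])
    best_ba, ties_b = best(set_b, set_a, lambda q, t: scores[(t.id, q.id)])
    tie_log = [f"tie for {x}" for x in ties_a + ties_b]
    pairs = [
        (a_id, b_id) for a_id, b_id in best_ab.items()
        if b_id is not None and best_ba.get(b_id) == a_id
    ]
    for msg in tie_log:
        log.info("rbh_orthologs: %s", msg)
    return pairs, tie_log


# ---------------------------------------------------------------------------
# duplication typing
# ---------------------------------------------------------------------------

@dataclass
class DuplicationCall:
    pair: tuple[str, str]
    dup_type: str            # segmental | tandem
    same_chromosome: bool
    genomic_distance: int | None


def classify_duplication(pair: tuple[str, str], models: list[GeneModel],
                         tandem_window: int = 100_000) -> DuplicationCall:
    """Tandem iff same chromosome and inter-gene gap <= tandem_window."""
    by_id = {g.id: g for g in models}
    try:
        g1, g2 = by_id[pair[0]], by_id[pair[1]]
    except KeyError as exc:
        raise ValidationError(f"gene {exc.args[0]!r} missing from models") from None
    same = g1.chromosome == g2.chromosome
    if not same:
        return DuplicationCall(pair, "segmental", False, None)
    gap = max(0, max(g1.start, g2.start) - min(g1.end, g2.end))
    dup_type = "tandem" if gap <= tandem_window else "segmental"
    return DuplicationCall(pair, dup_type, True, gap)


# ---------------------------------------------------------------------------
# codon back-translation
# ---------------------------------------------------------------------------

def backtranslate_alignment(aln: PairwiseAlignment, cds_a: str, cds_b: str
                            ) -> list[tuple[str, str]]:
    """Project a protein alignment onto the CDS pair, dropping gapped codons.

    Each protein gap becomes a 3-base gap; codon columns containing a gap in
    either row are excluded from the returned list (NG86 gap-exclusion).
    """
    for label, cds, row in (("a", cds_a, aln.aligned_a), ("b", cds_b, aln.aligned_b)):
        prot = row.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValidationError(
                f"CDS {label}: length {len(cds)} != 3 x {len(prot)} residues"
            )
        trans = translate_cds(cds)
        for i, (aa_cds, aa_prot) in enumerate(zip(trans, prot)):
            if aa_cds != aa_prot:
                raise ValidationError(
                    f"CDS {label}: codon {i + 1} translates to {aa_cds!r} "
                    f"but protein has {aa_prot!r}"
                )
    codons = []
    ia = ib = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = cds_a[3 * ia:3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = cds_b[3 * ib:3 * ib + 3]
            ib += 1
        if codon_a is not None and codon_b is not None:
            codons.append((codon_a, codon_b))
    return codons


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986)
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float | None
    ps: float | None
    ka: float | None
    ks: float | None
    ratio: float | None = None
    selection: str = "undefined"
    date_mya: float | None = None
    flags: list[str] = field(default_factory=list)


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """Synonymous fraction at each codon position.

    At each position the fraction is (synonymous changes) / (changes not
    creating a stop codon); changes to stop codons are excluded from the
    denominator so that N + S always totals 3 per codon.
    """
    if codon in STOP_CODONS:
        raise ValidationError(f"stop codon {codon!r} in coding sequence")
    fractions = []
    aa = translate_codon(codon)
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if translate_codon(alt) == aa:
                syn += 1
        fractions.append(syn / valid if valid else 0.0)
    return tuple(fractions)


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, non-synonymous) difference counts.

    All orderings of the differing positions are weighted equally; pathways
    passing through a stop codon are excluded and the rest re-weighted. If
    every pathway is blocked (cannot happen between sense codons differing
    at <= 3 positions under the standard code, but kept for safety) all
    pathways are used.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValidationError(f"stop codon {c!r} in coding sequence")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    pathways = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append(
                "syn" if translate_codon(current) == translate_codon(nxt)
                else "nonsyn"
            )
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:  # pragma: no cover - unreachable for sense codons
        for order in itertools.permutations(diff_positions):
            current = codon_a
            steps = []
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
                steps.append(
                    "syn" if translate_codon(nxt) != "*"
                    and translate_codon(current) == translate_codon(nxt)
                    else "nonsyn"
                )
                current = nxt
            pathways.append(steps)
    sd = sum(p.count("syn") for p in pathways) / len(pathways)
    nd = sum(p.count("nonsyn") for p in pathways) / len(pathways)
    return (sd, nd)


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def nei_gojobori(codon_aln: list[tuple[str, str]]) -> KaKsResult:
    """NG86 Ka/Ks on a gap-free codon alignment.

    Site fractions are computed per sequence and averaged; differing codons
    contribute pathway-averaged difference counts; Jukes–Cantor correction
    is applied to pn and ps separately.
    """
    if not codon_aln:
        raise ValidationError("empty codon alignment")
    S = Sd = Nd = 0.0
    for codon_a, codon_b in codon_aln:
        fa = codon_site_fractions(codon_a)
        fb = codon_site_fractions(codon_b)
        S += (sum(fa) + sum(fb)) / 2.0
        sd, nd = codon_pair_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd
    total_sites = 3.0 * len(codon_aln)
    N = total_sites - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    flags = []
    if ks is None:
        flags.append("ps >= 3/4: Ks undefined under Jukes-Cantor")
    if ka is None:
        flags.append("pn >= 3/4: Ka undefined under Jukes-Cantor")
    return KaKsResult(N=N, S=S, Nd=Nd, Sd=Sd, pn=pn, ps=ps,
                      ka=ka, ks=ks, flags=flags)


NEUTRAL_TOLERANCE = 0.05


def kaks_ratio_and_selection(ka: float | None, ks: float | None,
                             neutral_tol: float = NEUTRAL_TOLERANCE
                             ) -> tuple[float | None, str]:
    """Ka/Ks ratio and selection label.

    Ratio < 1 - tol -> purifying, > 1 + tol -> positive, within the band ->
    neutral; undefined when Ks is 0 or either rate is undefined.
    """
    if ka is None or ks is None:
        return None, "undefined"
    if ka < 0 or ks < 0:
        raise ValidationError("ka and ks must be non-negative")
    if ks == 0:
        return None, "undefined"
    ratio = ka / ks
    if ratio < 1.0 - neutral_tol:
        return ratio, "purifying"
    if ratio > 1.0 + neutral_tol:
        return ratio, "positive"
    return ratio, "neutral"


DEFAULT_CLOCK_RATE = 1.5e-8  # synonymous substitutions per site per year


def date_duplication(ks: float, lambda_rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Duplication age T = Ks / (2 lambda), in million years."""
    if lambda_rate <= 0:
        raise ValidationError("lambda_rate must be positive")
    if ks < 0:
        raise ValidationError("ks must be non-negative")
    return ks / (2.0 * lambda_rate) / 1e6


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceTree:
    graph: nx.Graph          # nodes: leaf names + internal ints; edge attr 'length'
    leaves: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    negative_branches_clamped: bool = False

    def path_distance(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side not holding
        the lexicographically smallest leaf."""
        ref = min(self.leaves)
        splits = set()
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {n for n in nx.node_connected_component(g, u) if n in set(self.leaves)}
            if ref in side:
                side = set(self.leaves) - side
            if 2 <= len(side) <= len(self.leaves) - 2:
                splits.add(frozenset(side))
        return splits

    def to_newick(self) -> str:
        """Serialize rooted at an arbitrary internal node."""
        leafset = set(self.leaves)
        root = next((n for n in self.graph.nodes if n not in leafset), self.leaves[0])

        def rec(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{rec(c, node)}:{self.graph.edges[node, c]['length']:.6g}"
                for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"


def _nj_once(dist: np.ndarray, labels: list) -> tuple[nx.Graph, bool]:
    g = nx.Graph()
    nodes = list(labels)
    d = dist.astype(float).copy()
    clamped = False
    next_internal = 0
    while len(nodes) > 2:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"_nj{next_internal}"
        next_internal += 1
        g.add_edge(nodes[i], new, length=li)
        g.add_edge(nodes[j], new, length=lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
    # two nodes remain
    length = d[0, 1]
    if length < 0:
        clamped = True
        length = 0.0
    if len(labels) == 2:
        # split evenly through a junction so both pendant branches are reported
        mid = "_nj_mid"
        g.add_edge(nodes[0], mid, length=length / 2.0)
        g.add_edge(nodes[1], mid, length=length / 2.0)
    else:
        g.add_edge(nodes[0], nodes[1], length=length)
    return g, clamped


def p_distance_matrix(sequences: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise proportion-of-differing-columns matrix from equal-length seqs."""
    labels = list(sequences)
    arrs = [np.frombuffer(sequences[x].encode(), dtype="S1") for x in labels]
    if len({a.size for a in arrs}) != 1:
        raise ValidationError("sequences must have equal length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.mean(arrs[i] != arrs[j]))
    return d, labels


def nj_tree(distances: np.ndarray, taxa: list[str],
            alignment: dict[str, str] | None = None,
            bootstrap_reps: int = 0, seed: int = 0) -> DistanceTree:
    """Standard neighbor joining with optional column-bootstrap supports.

    ``distances`` must be symmetric with a zero diagonal. When ``alignment``
    is given together with ``bootstrap_reps``, columns are resampled with
    replacement, p-distances recomputed, and supports reported as the % of
    replicates containing each internal bipartition.
    """
    distances = np.asarray(distances, dtype=float)
    if len(taxa) < 2:
        raise ValidationError("need >= 2 taxa")
    if distances.shape != (len(taxa), len(taxa)):
        raise ValidationError("distance matrix shape mismatch")
    if np.max(np.abs(distances - distances.T)) > 1e-9:
        raise ValidationError("distance matrix is asymmetric beyond 1e-9")
    g, clamped = _nj_once(distances, taxa)
    tree = DistanceTree(graph=g, leaves=list(taxa),
                        negative_branches_clamped=clamped)
    if alignment is not None and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        target_splits = tree.bipartitions()
        counts = {s: 0 for s in target_splits}
        seqs = {t: alignment[t] for t in taxa}
        mats = {t: np.frombuffer(seqs[t].encode(), dtype="S1") for t in taxa}
        ncol = len(next(iter(seqs.values())))
        for _ in range(bootstrap_reps):
            cols = rng.integers(0, ncol, size=ncol)
            resampled = {t: mats[t][cols].tobytes().decode() for t in taxa}
            d, labels = p_distance_matrix(resampled)
            rep_g, _ = _nj_once(d, labels)
            rep = DistanceTree(graph=rep_g, leaves=labels)
            rep_splits = rep.bipartitions()
            for s in target_splits:
                if s in rep_splits:
                    counts[s] += 1
        tree.supports = {
            s: 100.0 * c / bootstrap_reps for s, c in counts.items()
        }
    return tree


# ---------------------------------------------------------------------------
# gene-structure signatures
# ---------------------------------------------------------------------------

def gene_structure_signature(models: list[GeneModel]
                             ) -> dict[str, tuple[int, tuple[int, ...]]]:
    """Per-gene (intron count, exon-length vector)."""
    return {
        g.id: (g.intron_count, tuple(b - a + 1 for a, b in g.exons))
        for g in models
    }


def group_by_structure(models: list[GeneModel], rel_tol: float = 0.2
                       ) -> list[list[str]]:
    """Group genes with equal intron counts and exon lengths within
    ``rel_tol`` relative tolerance, by greedy single-linkage."""
    sig = gene_structure_signature(models)

    def same(a, b):
        (ia, ea), (ib, eb) = sig[a], sig[b]
        if ia != ib:
            return False
        return all(
            abs(x - y) <= rel_tol * max(x, y) for x, y in zip(ea, eb)
        )

    groups: list[list[str]] = []
    for gid in sig:
        for grp in groups:
            if same(gid, grp[0]):
                grp.append(gid)
                break
        else:
            groups.append([gid])
    return groups
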