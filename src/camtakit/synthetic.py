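"""Seeded generators for every input the pipeline consumes.

All generators take an explicit integer seed and are byte-deterministic
for a fixed (config, seed). Ground truth is returned (and written) as
plain tables so downstream tests never reach into generator internals.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import family_scan
from .evolution import (
    STOP_CODONS,
    codon_pair_differences,
    codon_site_fractions,
    translate_cds,
    translate_codon,
)
from .io import write_expression_tsv, write_fasta, write_gff3, write_tsv
from .models import GeneModel, ValidationError

_BASES = "ACGT"

# synonymous codon choices per amino acid
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in sorted(set("".join(p) for p in itertools.product(_BASES, repeat=3)) - STOP_CODONS):
    _AA_TO_CODONS.setdefault(translate_codon(_codon), []).append(_codon)

_AA_LIST = sorted(set("ACDEFGHIKLMNPQRSTVWY"))


class CapacityError(ValidationError):
    """Requested genes do not fit on the requested chromosome."""


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 10
    chrom_length: int = 200_000
    promoter_length: int = 1000
    planted_motif_fraction: float = 0.3
    gc_content: float = 0.4
    target_ka: float = 0.1
    target_ks: float = 0.4
    n_stages: int = 5
    focal_module_size: int = 10
    anti_module_size: int = 5
    noise_sd: float = 0.05
    trait_r: float = 0.6
    n_camta: int = 2       # genes planted with the full domain architecture
    n_non_tig: int = 1     # of which this many omit the TIG segment

    def __post_init__(self) -> None:
        for name in ("planted_motif_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValidationError("gc_content must be in (0, 1)")
        if self.target_ka < 0 or self.target_ks < 0:
            raise ValidationError("target rates must be non-negative")
        if abs(self.trait_r) > 1.0:
            raise ValidationError("trait_r must be in [-1, 1]")
        if self.n_camta > self.n_genes or self.n_non_tig > self.n_camta:
            raise ValidationError("n_non_tig <= n_camta <= n_genes required")


# ---------------------------------------------------------------------------
# annotated genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    models: list[GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: pd.DataFrame  # columns: gene, role

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "cds": outdir / "cds.fasta",
            "proteins": outdir / "proteins.fasta",
            "truth": outdir / "truth_genes.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.models, paths["gff3"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.proteins, paths["proteins"])
        write_tsv(self.truth, paths["truth"])
        return paths


_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return _DNA_BYTES[idx].tobytes().decode()


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LIST, size=length)) if length else ""


_CONSENSUS_TOKEN = re.compile(r"(\[[A-Z]+\]|[A-Z])(\((\d+)\))?")


def _expand_consensus(rng: np.random.Generator, pattern: str) -> str:
    """A concrete peptide drawn uniformly from a consensus pattern
    (X = any residue, [..] = class, (k) = k independent repeats)."""
    out = []
    pos = 0
    while pos < len(pattern):
        m = _CONSENSUS_TOKEN.match(pattern, pos)
        if m is None:
            raise ValidationError(f"bad consensus syntax at {pattern[pos:]!r}")
        elem, _, rep = m.groups()
        choices = _AA_LIST if elem == "X" else list(elem.strip("[]"))
        for _ in range(int(rep) if rep else 1):
            out.append(choices[int(rng.integers(len(choices)))]
                       if len(choices) > 1 else choices[0])
        pos = m.end()
    return "".join(out)


def _camta_protein(rng: np.random.Generator, with_tig: bool) -> str:
    """Full planted architecture: CG1 [TIG] ANK IQ IQ CaMBD, with linkers."""
    def linker(lo=8, hi=20):
        return _random_peptide(rng, int(rng.integers(lo, hi)))

    parts = [
        _random_peptide(rng, int(rng.integers(3, 8))),
        str(rng.choice(family_scan.PWM_SEEDS["CG1"])),
    ]
    if with_tig:
        parts += [linker(), str(rng.choice(family_scan.PWM_SEEDS["TIG"]))]
    parts += [
        linker(), str(rng.choice(family_scan.PWM_SEEDS["ANK"])),
        linker(), _expand_consensus(rng, family_scan.CONSENSUS_PATTERNS["IQ"]),
        linker(), _expand_consensus(rng, family_scan.CONSENSUS_PATTERNS["IQ"]),
        linker(), _expand_consensus(rng, family_scan.CONSENSUS_PATTERNS["CaMBD"]),
        _random_peptide(rng, int(rng.integers(3, 8))),
    ]
    return "".join(parts)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous back-translation (no stop codons by construction)."""
    return "".join(str(rng.choice(_AA_TO_CODONS[aa])) for aa in protein)


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` pieces, each >= 3."""
    if parts * 3 > total:
        parts = max(1, total // 3)
    cuts = sorted(rng.choice(np.arange(1, total // 3), size=parts - 1, replace=False)) if parts > 1 else []
    bounds = [0] + [3 * int(c) for c in cuts] + [total]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def gen_annotated_genome(config: SimConfig) -> SyntheticGenome:
    """Genome + gene models + CDS + proteins with planted family members.

    Every model is GFF3-consistent (exons within bounds, CDS divisible by
    3, no internal stops); proteins are exact translations of their CDS;
    the first ``n_camta`` genes carry the planted architecture, of which
    the last ``n_non_tig`` omit the TIG segment.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    models: list[GeneModel] = []
    roles = []
    cursor = 0  # 0-based position of the next free base
    genome_parts = []

    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        if i < config.n_camta:
            with_tig = i < config.n_camta - config.n_non_tig
            prot = _camta_protein(rng, with_tig)
            role = "camta_full" if with_tig else "camta_non_tig"
        else:
            prot = _random_peptide(rng, int(rng.integers(80, 160)))
            role = "background"
        seq_cds = back_translate(prot, rng)
        n_exons = int(rng.integers(1, 5))
        exon_lens = _split_lengths(rng, len(seq_cds), n_exons)
        intron_lens = [int(rng.integers(50, 200)) for _ in range(len(exon_lens) - 1)]
        gene_len = sum(exon_lens) + sum(intron_lens)
        start0 = cursor + config.promoter_length  # leave the promoter upstream
        end0 = start0 + gene_len                  # exclusive
        if end0 > config.chrom_length:
            raise CapacityError(
                f"gene {gid} would end at {end0} > chrom_length "
                f"{config.chrom_length}; reduce n_genes or grow the chromosome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = seq_cds if strand == "+" else _revcomp(seq_cds)
        exons = []
        gpos = start0
        epos = 0
        pieces = []
        for k, elen in enumerate(exon_lens):
            exons.append((gpos + 1, gpos + elen))  # 1-based inclusive
            pieces.append(embedded[epos:epos + elen])
            epos += elen
            gpos += elen
            if k < len(intron_lens):
                pieces.append(_random_dna(rng, intron_lens[k], config.gc_content))
                gpos += intron_lens[k]
        models.append(GeneModel(id=gid, chromosome=chrom, strand=strand,
                                start=start0 + 1, end=end0, exons=exons))
        genome_parts.append(_random_dna(rng, start0 - cursor, config.gc_content))
        genome_parts.append("".join(pieces))
        cursor = end0
        proteins[gid] = prot
        cds[gid] = seq_cds
        roles.append({"gene": gid, "role": role})

    genome_parts.append(_random_dna(rng, config.chrom_length - cursor,
                                    config.gc_content))
    genome_seq = "".join(genome_parts)
    assert len(genome_seq) == config.chrom_length
    for g in models:  # embedding sanity: protein == translate(spliced exons)
        spliced = "".join(genome_seq[a - 1:b] for a, b in g.exons)
        if g.strand == "-":
            spliced = _revcomp(spliced)
        assert translate_cds(spliced) == proteins[g.id]
    return SyntheticGenome(
        genome={chrom: genome_seq}, models=models, cds=cds, proteins=proteins,
        truth=pd.DataFrame(roles, columns=["gene", "role"]),
    )


_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# diverged codon pairs
# ---------------------------------------------------------------------------

@dataclass
class EvolvedPair:
    seq_a: str
    seq_b: str
    n_syn_changes: int = 0
    n_nonsyn_changes: int = 0
    n_skipped: int = 0
    flags: list[str] = field(default_factory=list)


def _inverse_jc(d: float) -> float:
    """Observed difference proportion with expected distance d under JC."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_codon_pair(cds: str, target_ka: float, target_ks: float,
                      seed: int) -> EvolvedPair:
    """Diverge an ancestor into two descendants at controlled Ka/Ks.

    Site classes come from NG86 fractional counting on the ancestor. Each
    position independently receives a synonymous difference with
    probability JC^-1(target_ks) * f_syn, or a non-synonymous one with
    probability JC^-1(target_ka) * (1 - f_syn); JC^-1 inverts the
    Jukes-Cantor correction so that the corrected estimates are centred on
    the targets. Changes creating stop codons, and synonymous changes that
    would raise the pathway-averaged non-synonymous difference count of
    their codon, are redrawn from the remaining alternatives (skipped if
    none remain; this is the documented small downward bias).
    """
    if len(cds) % 3:
        raise ValidationError("CDS length must be divisible by 3")
    if target_ka < 0 or target_ks < 0:
        raise ValidationError("target rates must be non-negative")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValidationError(f"internal stop codon {c!r} in ancestor")
    rng = np.random.default_rng(seed)
    p_s = _inverse_jc(target_ks)
    p_n = _inverse_jc(target_ka)
    a = list(codons)
    b = list(codons)
    n_syn = n_nonsyn = n_skipped = 0
    for ci, anc in enumerate(codons):
        fractions = codon_site_fractions(anc)
        for pos in range(3):
            f = fractions[pos]
            ps_eff = p_s * f
            pn_eff = p_n * (1.0 - f)
            u = rng.random()
            if u < ps_eff:
                kind = "syn"
            elif u < ps_eff + pn_eff:
                kind = "nonsyn"
            else:
                continue
            side = a if rng.random() < 0.5 else b
            other = b if side is a else a
            cur = side[ci]
            aa_cur = translate_codon(cur)
            candidates = []
            for base in _BASES:
                if base == cur[pos]:
                    continue
                alt = cur[:pos] + base + cur[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                is_syn = translate_codon(alt) == aa_cur
                if kind == "syn" and is_syn:
                    _, nd0 = codon_pair_differences(cur, other[ci])
                    _, nd1 = codon_pair_differences(alt, other[ci])
                    if nd1 <= nd0 + 1e-9:
                        candidates.append(alt)
                elif kind == "nonsyn" and not is_syn:
                    candidates.append(alt)
            if not candidates:
                n_skipped += 1
                continue
            side[ci] = candidates[int(rng.integers(len(candidates)))]
            if kind == "syn":
                n_syn += 1
            else:
                n_nonsyn += 1
    flags = []
    if n_skipped:
        flags.append(f"{n_skipped} proposals skipped (stop/pathway guard)")
    return EvolvedPair(seq_a="".join(a), seq_b="".join(b),
                       n_syn_changes=n_syn, n_nonsyn_changes=n_nonsyn,
                       n_skipped=n_skipped, flags=flags)


# ---------------------------------------------------------------------------
# promoter sets with planted motifs
# ---------------------------------------------------------------------------

def gen_promoters(n: int, length: int, motifs: list[str],
                  planted_fraction: float, gc: float, seed: int
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """i.i.d.-background promoters with exactly round(n * planted_fraction)
    of them carrying >= 1 planted motif instance.

    Background G and C each occur at gc/2. Labels record planting, not
    total matches — background can create additional chance matches.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValidationError("planted_fraction must be in [0, 1]")
    from .motif_enrichment import iupac_expand

    matchers = [iupac_expand(m) for m in motifs]
    for m in matchers:
        if m.length > length:
            raise ValidationError(
                f"motif {m.motif!r} is longer than the promoter ({length} bp)"
            )
    rng = np.random.default_rng(seed)
    n_planted = round(n * planted_fraction)
    planted_idx = set(
        int(i) for i in rng.choice(n, size=n_planted, replace=False)
    ) if n_planted else set()
    promoters: dict[str, str] = {}
    labels = []
    for i in range(n):
        pid = f"p{i + 1:05d}"
        seq = _random_dna(rng, length, gc)
        planted = i in planted_idx
        if planted:
            m = matchers[int(rng.integers(len(matchers)))]
            instance = m.expansion()[int(rng.integers(len(m.expansion())))]
            pos = int(rng.integers(0, length - m.length + 1))
            seq = seq[:pos] + instance + seq[pos + m.length:]
        promoters[pid] = seq
        labels.append({"promoter": pid, "planted": planted})
    return promoters, pd.DataFrame(labels, columns=["promoter", "planted"])


# ---------------------------------------------------------------------------
# expression matrices with planted modules
# ---------------------------------------------------------------------------

def gen_expression(n_genes: int, n_stages: int, focal_module_size: int,
                   anti_module_size: int, noise_sd: float, seed: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix with a focal gene, a positively and a negatively
    co-varying module, and independent background genes.

    Module genes are affine transforms of the focal profile (positive
    slope for the positive module, negative for the anti-module) plus
    Gaussian noise; values are clipped at 0 afterwards.
    """
    if n_stages < 3:
        raise ValidationError("n_stages must be >= 3")
    if focal_module_size + anti_module_size + 1 > n_genes:
        raise ValidationError("modules (plus the focal gene) exceed n_genes")
    rng = np.random.default_rng(seed)
    focal_profile = rng.uniform(2.0, 10.0, size=n_stages)
    while np.std(focal_profile) == 0:  # pragma: no cover - measure-zero
        focal_profile = rng.uniform(2.0, 10.0, size=n_stages)
    stage_labels = [f"stage{j + 1}" for j in range(n_stages)]
    rows = {}
    truth = []
    rows["g000001"] = focal_profile
    truth.append({"gene": "g000001", "role": "focal"})
    hi, lo = focal_profile.max(), focal_profile.min()
    for i in range(n_genes - 1):
        gid = f"g{i + 2:06d}"
        if i < focal_module_size:
            slope = rng.uniform(0.5, 2.0)
            intercept = rng.uniform(0.0, 2.0)
            base = slope * focal_profile + intercept
            role = "positive"
        elif i < focal_module_size + anti_module_size:
            slope = rng.uniform(0.5, 2.0)
            intercept = rng.uniform(0.0, 2.0)
            base = slope * (hi + lo - focal_profile) + intercept
            role = "negative"
        else:
            base = rng.uniform(0.0, 10.0, size=n_stages)
            role = "background"
        noise = rng.normal(0.0, noise_sd, size=n_stages) if noise_sd > 0 else 0.0
        rows[gid] = np.clip(base + noise, 0.0, None)
        truth.append({"gene": gid, "role": role})
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=stage_labels)
    matrix.index.name = "gene"
    return matrix, pd.DataFrame(truth, columns=["gene", "role"])


# ---------------------------------------------------------------------------
# additive trees (for distance-tree recovery tests)
# ---------------------------------------------------------------------------

def gen_additive_tree(n_taxa: int, seed: int):
    """Random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix.

    Returns (networkx.Graph with 'length' edge attributes, leaf labels,
    distance matrix).
    """
    import networkx as nx

    if n_taxa < 2:
        raise ValidationError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    leaves = [f"L{i + 1}" for i in range(n_taxa)]
    g.add_edge(leaves[0], leaves[1], length=float(rng.uniform(0.05, 1.0)))
    inner = 0
    for leaf in leaves[2:]:
        edges = sorted(g.edges)
        u, v = edges[int(rng.integers(len(edges)))]
        total = g.edges[u, v]["length"]
        g.remove_edge(u, v)
        mid = f"I{inner}"
        inner += 1
        split = float(rng.uniform(0.1, 0.9)) * total
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=total - split)
        g.add_edge(mid, leaf, length=float(rng.uniform(0.05, 1.0)))
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        lengths = nx.shortest_path_length(g, leaves[i], weight="length")
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = lengths[leaves[j]]
    return g, leaves, d


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def gen_trait_table(n_genotypes: int, trait_r: float, seed: int
                    ) -> tuple[pd.Series, pd.Series]:
    """dCt and trait vectors whose population correlation between 1/dCt
    and the trait equals ``trait_r`` exactly.

    The proxy 1/dCt is an affine function of a standard-normal latent z,
    and the trait is trait_r * z + sqrt(1 - trait_r^2) * e.
    """
    if abs(trait_r) > 1.0:
        raise ValidationError("trait_r must be in [-1, 1]")
    if n_genotypes < 3:
        raise ValidationError("n_genotypes must be >= 3")
    rng = np.random.default_rng(seed)
    z = np.clip(rng.standard_normal(n_genotypes), -6.0, 6.0)
    proxy = 0.25 + 0.03 * z          # 1/dCt, strictly positive
    dct = 1.0 / proxy
    e = rng.standard_normal(n_genotypes)
    trait = trait_r * z + math.sqrt(max(0.0, 1.0 - trait_r ** 2)) * e
    idx = pd.Index([f"geno{i + 1:05d}" for i in range(n_genotypes)], name="genotype")
    return pd.Series(dct, index=idx, name="dct"), pd.Series(trait, index=idx, name="trait")


def gen_trait_frame(n_genotypes: int, trait_r: float, seed: int,
                    target_trait: str = "FS") -> tuple[pd.Series, pd.DataFrame]:
    """Convenience: a full six-trait table where only ``target_trait``
    correlates with 1/dCt at ``trait_r``; the rest are independent noise."""
    from .traits_qpcr import TRAIT_COLUMNS

    dct, trait = gen_trait_table(n_genotypes, trait_r, seed)
    rng = np.random.default_rng(seed + 1)
    data = {}
    for col in TRAIT_COLUMNS:
        if col == target_trait:
            data[col] = trait.to_numpy()
        else:
            data[col] = rng.standard_normal(n_genotypes)
    return dct, pd.DataFrame(data, index=dct.index)


# ---------------------------------------------------------------------------
# bundle writer used by the CLI
# ---------------------------------------------------------------------------

def write_promoters(promoters: dict[str, str], labels: pd.DataFrame,
                    outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(promoters, outdir / "promoters.fasta")
    write_tsv(labels, outdir / "truth_promoters.tsv")


def write_expression(matrix: pd.DataFrame, truth: pd.DataFrame,
                     outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(matrix, outdir / "expression.tsv")
    write_tsv(truth, outdir / "truth_expression.tsv")
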