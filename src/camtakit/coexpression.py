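"""Focal-gene co-expression networks from FPKM matrices.

The matrix convention is a pandas DataFrame with genes as the index and
ordered developmental stages as columns; all values are FPKM >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .models import ValidationError

log = logging.getLogger(__name__)

POS_THRESHOLD = 0.95
NEG_THRESHOLD = -0.95


def validate_expression(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise ValidationError("expression matrix contains negative values")


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """value -> log2(value + pseudocount); monotone and defined at zero."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    validate_expression(matrix)
    return np.log2(matrix + pseudocount)


def focal_correlations(matrix: pd.DataFrame, focal: str) -> pd.Series:
    """Pearson r of every other gene's profile with the focal profile.

    Genes with zero variance across stages have undefined r; they are
    excluded and logged.
    """
    if focal not in matrix.index:
        raise ValidationError(f"focal gene {focal!r} missing from matrix")
    if matrix.shape[1] < 3:
        raise ValidationError("correlation needs >= 3 stages")
    f = matrix.loc[focal].to_numpy(dtype=float)
    if np.std(f) == 0:
        raise ValidationError("focal profile has zero variance")
    others = matrix.drop(index=focal)
    x = others.to_numpy(dtype=float)
    sx = x.std(axis=1)
    defined = sx > 0
    n_dropped = int((~defined).sum())
    if n_dropped:
        log.info("focal_correlations: excluded %d zero-variance genes", n_dropped)
    xc = x[defined] - x[defined].mean(axis=1, keepdims=True)
    fc = f - f.mean()
    r = (xc @ fc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(fc))
    return pd.Series(r, index=others.index[defined], name="r")


@dataclass
class CoexpressionNetwork:
    focal: str
    edges: list[tuple[str, float]] = field(default_factory=list)
    pcoeg: set[str] = field(default_factory=set)
    ncoeg: set[str] = field(default_factory=set)


def build_network(r_values: pd.Series, focal: str,
                  pos_thr: float = POS_THRESHOLD,
                  neg_thr: float = NEG_THRESHOLD) -> CoexpressionNetwork:
    """Threshold per-gene correlations into positive/negative edge sets.

    Thresholds are inclusive: r >= pos_thr joins pcoeg, r <= neg_thr joins
    ncoeg.
    """
    if not neg_thr < pos_thr:
        raise ValidationError("neg_thr must be below pos_thr")
    pcoeg = set(r_values.index[r_values >= pos_thr]) - {focal}
    ncoeg = set(r_values.index[r_values <= neg_thr]) - {focal}
    edges = [
        (g, float(r_values[g])) for g in sorted(pcoeg | ncoeg)
    ]
    return CoexpressionNetwork(focal=focal, edges=edges, pcoeg=pcoeg, ncoeg=ncoeg)


def stage_summary(matrix: pd.DataFrame, gene_set: set[str] | list[str]) -> pd.DataFrame:
    """Per-stage median and quartiles over a gene set.

    Percentiles use linear interpolation between order statistics.
    """
    genes = [g for g in gene_set]
    if not genes:
        raise ValidationError("gene set is empty")
    missing = set(genes) - set(matrix.index)
    if missing:
        raise ValidationError(f"genes missing from matrix: {sorted(missing)[:5]}")
    sub = matrix.loc[genes].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "q25": np.percentile(sub, 25, axis=0),
            "median": np.percentile(sub, 50, axis=0),
            "q75": np.percentile(sub, 75, axis=0),
        },
        index=matrix.columns,
    )


def write_sif(network: CoexpressionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, r in network.edges:
            rel = "pos" if gene in network.pcoeg else "neg"
            fh.write(f"{network.focal}\t{rel}\t{gene}\n")


def write_graphml(network: CoexpressionNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.add_node(network.focal, role="focal")
    for gene, r in network.edges:
        role = "pcoeg" if gene in network.pcoeg else "ncoeg"
        g.add_node(gene, role=role)
        g.add_edge(network.focal, gene, r=r)
    nx.write_graphml(g, path)


def write_memberships(network: CoexpressionNetwork, path: str | Path) -> None:
    rows = [
        {"gene": gene, "set": "pcoeg" if gene in network.pcoeg else "ncoeg",
         "r": r}
        for gene, r in network.edges
    ]
    pd.DataFrame(rows, columns=["gene", "set", "r"]).to_csv(path, sep="\t", index=False)
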