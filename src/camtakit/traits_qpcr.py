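"""qRT-PCR relative quantification (2^-ddCt) and expression–trait
correlation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

log = logging.getLogger(__name__)

TRAIT_COLUMNS = ("FL", "FS", "UR", "MIC", "BN", "BW")


def average_technical_replicates(ct: pd.DataFrame,
                                 sample_col: str = "sample",
                                 ct_cols: tuple[str, str] = ("ct_target", "ct_reference"),
                                 ) -> pd.DataFrame:
    """Mean Ct per sample over technical replicates (averaging happens on
    the Ct scale, before any exponential transform)."""
    for col in (sample_col, *ct_cols):
        if col not in ct.columns:
            raise ValidationError(f"Ct table lacks column {col!r}")
    return ct.groupby(sample_col, as_index=False)[list(ct_cols)].mean()


def delta_ct(ct_target, ct_ref):
    """dCt = Ct(target) - Ct(reference)."""
    return np.asarray(ct_target, dtype=float) - np.asarray(ct_ref, dtype=float)


def delta_delta_ct(ct_target, ct_ref, calibrator_dct: float):
    """Fold change 2^-ddCt, with ddCt = (Ct_t - Ct_ref) - calibrator dCt."""
    dct = delta_ct(ct_target, ct_ref)
    if not np.all(np.isfinite(dct)) or not np.isfinite(calibrator_dct):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** -(dct - calibrator_dct)


def expression_proxy(dct):
    """Expression proxy 1/dCt (undefined at dCt = 0).

    Negative dCt yields a negative proxy; this sign pathology is kept
    deliberately and logged.
    """
    dct = np.asarray(dct, dtype=float)
    if np.any(dct == 0):
        raise ValidationError("dCt of 0 gives an undefined 1/dCt proxy")
    if np.any(dct < 0):
        log.warning("expression_proxy: negative dCt values produce negative proxies")
    return 1.0 / dct


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def trait_scan(proxies: pd.Series, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait (r, p, n) against the expression proxy.

    Genotypes are matched on the index; missing values are handled
    pairwise-complete and the effective n reported. Traits with fewer than
    3 complete pairs are flagged, not computed. No multiplicity correction
    is applied (noted in the output).
    """
    common = proxies.index.intersection(traits.index)
    if len(common) == 0:
        raise ValidationError("no shared genotypes between proxies and traits")
    rows = []
    for trait in traits.columns:
        pair = pd.concat(
            [proxies.loc[common], traits.loc[common, trait]], axis=1
        ).dropna()
        n = len(pair)
        if n < 3:
            rows.append({"trait": trait, "n": n, "r": np.nan, "p": np.nan,
                         "flag": "insufficient complete pairs"})
            continue
        r, p = pearson_with_p(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
        rows.append({"trait": trait, "n": n, "r": r, "p": p, "flag": ""})
    out = pd.DataFrame(rows)
    out.attrs["note"] = "p-values are uncorrected for multiple traits"
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional BH adjustment (off by default in trait_scan)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj
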