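"""Cross-platform quantification concordance.

Agreement diagnostics between two abundance matrices (e.g. a long-read and
a short-read quantifier run on the same samples): TPM/CPM scaling, per-sample
and per-feature Pearson correlation, Fisher-z comparison of correlations,
Jensen-Shannon divergence between per-sample expression distributions,
expression-filter sweeps, and length/GC bias regressions.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .datatypes import AbundanceMatrix, GeneModel


def compute_tpm(
    matrix: AbundanceMatrix,
    lengths: Mapping[str, float] | pd.Series | None = None,
    length_normalize: bool = True,
) -> AbundanceMatrix:
    """Scale counts to transcripts-per-million.

    With ``length_normalize`` each count is first divided by its feature
    length (a true TPM); without, the result is a CPM-like quantity that is
    still often labelled TPM for long-read quantifiers. The flag is recorded
    on the returned matrix.
    """
    data = matrix.data.astype(float)
    if length_normalize:
        if lengths is None:
            raise ValueError("lengths are required for length normalization")
        lens = pd.Series(lengths, dtype=float).reindex(data.index)
        if lens.isna().any():
            missing = data.index[lens.isna()][:5].tolist()
            raise ValueError(f"missing lengths for features {missing}")
        data = data.div(lens, axis=0)
    totals = data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total for sample {zero.index[0]!r}")
    scaled = data.div(totals, axis=1) * 1e6
    return AbundanceMatrix(
        scaled, unit="TPM", level=matrix.level, length_normalized=length_normalize
    )


def _aligned(a: AbundanceMatrix, b: AbundanceMatrix):
    samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not samples:
        raise ValueError("no shared samples")
    features = a.feature_ids.intersection(b.feature_ids)
    return a.data.loc[features, samples], b.data.loc[features, samples]


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log1p":
        return np.log2(values + 1.0)
    if scale == "raw":
        return values
    raise ValueError(f"unknown scale {scale!r}")


def correlate_samples(
    a: AbundanceMatrix, b: AbundanceMatrix, scale: str = "log1p"
) -> pd.DataFrame:
    """Per-sample Pearson r across the shared-feature intersection."""
    da, db = _aligned(a, b)
    if len(da) < 3:
        raise ValueError("need at least 3 shared features")
    rows = []
    for sample in da.columns:
        x = _transform(da[sample].to_numpy(float), scale)
        y = _transform(db[sample].to_numpy(float), scale)
        r = stats.pearsonr(x, y).statistic
        rows.append({"sample_id": sample, "r": r, "n": len(x), "scale": scale})
    return pd.DataFrame(rows)


def correlate_features(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    min_expression: float = 0.0,
    scale: str = "log1p",
) -> pd.DataFrame:
    """Per-feature Pearson r across samples.

    Features must have mean abundance >= ``min_expression`` in both
    matrices; constant features are excluded with reason ``zero variance``.
    """
    da, db = _aligned(a, b)
    if da.shape[1] < 3:
        raise ValueError("need at least 3 shared samples")
    keep = (da.mean(axis=1) >= min_expression) & (db.mean(axis=1) >= min_expression)
    rows = []
    for fid in da.index[keep]:
        x = _transform(da.loc[fid].to_numpy(float), scale)
        y = _transform(db.loc[fid].to_numpy(float), scale)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"feature_id": fid, "r": np.nan, "n": len(x),
                         "scale": scale, "excluded": "zero variance"})
            continue
        r = stats.pearsonr(x, y).statistic
        rows.append({"feature_id": fid, "r": r, "n": len(x), "scale": scale,
                     "excluded": ""})
    return pd.DataFrame(
        rows, columns=["feature_id", "r", "n", "scale", "excluded"]
    )


def correlation_sweep(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    thresholds: Sequence[float],
    r_threshold: float = 0.8,
    scale: str = "log1p",
) -> pd.DataFrame:
    """Count features and highly correlated features over a filter sweep."""
    rows = []
    for threshold in thresholds:
        per_feature = correlate_features(a, b, min_expression=threshold, scale=scale)
        usable = per_feature[per_feature["excluded"] == ""]
        rows.append(
            {
                "min_expression": threshold,
                "n_features": len(usable),
                "n_high_corr": int((usable["r"] >= r_threshold).sum()),
            }
        )
    return pd.DataFrame(rows)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's z.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided standard-normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the z transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def jensen_shannon_divergence(p, q, base: float = 2.0) -> float:
    """JSD between two non-negative vectors (renormalised to sum 1).

    0 for identical distributions; bounded by 1 in base 2; symmetric.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("all-zero vector")
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=base) ** 2)


def sample_jsd(a: AbundanceMatrix, b: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample JSD between the two platforms' gene-probability vectors."""
    da, db = _aligned(a, b)
    rows = []
    for sample in da.columns:
        rows.append(
            {
                "sample_id": sample,
                "jsd": jensen_shannon_divergence(
                    da[sample].to_numpy(float), db[sample].to_numpy(float)
                ),
                "n": len(da),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BiasRegressionResult:
    covariate: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int


def bias_regression(
    matrix: AbundanceMatrix,
    gene_models: Mapping[str, GeneModel] | pd.DataFrame,
    covariate: str = "log10_length",
) -> BiasRegressionResult:
    """OLS of per-gene mean log2(abundance + 1) on a gene covariate.

    ``covariate`` is ``log10_length`` (union-exon length) or
    ``gc_fraction``. A significantly non-zero slope indicates quantifier
    bias with respect to that covariate.
    """
    if isinstance(gene_models, pd.DataFrame):
        table = gene_models.set_index("gene_id")
        lengths = table.get("length", table.get("union_exon_length"))
        gcs = table.get("gc_fraction")
    else:
        lengths = pd.Series(
            {g: m.union_exon_length for g, m in gene_models.items()}, dtype=float
        )
        gcs = pd.Series(
            {g: m.gc_fraction for g, m in gene_models.items()}, dtype=float
        )
    if covariate == "log10_length":
        x = np.log10(pd.Series(lengths, dtype=float))
    elif covariate == "gc_fraction":
        x = pd.Series(gcs, dtype=float)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    shared = matrix.feature_ids.intersection(x.dropna().index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes with covariate values")
    y = np.log2(matrix.data.loc[shared].astype(float).mean(axis=1) + 1.0).to_numpy()
    xv = x.loc[shared].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("zero-variance covariate")
    if np.ptp(y) == 0:
        # degenerate but well-defined: a flat response has no bias
        return BiasRegressionResult(covariate, 0.0, float(y[0]), 0.0, 0.0, 1.0,
                                    len(shared))
    fit = stats.linregress(xv, y)
    return BiasRegressionResult(
        covariate=covariate,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(shared),
    )
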