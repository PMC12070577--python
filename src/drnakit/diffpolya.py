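"""Differential polyadenylation testing.

Per gene, a linear mixed model on the log2 tail length of every read:
``log2(tail) = b0 + b1 * 1[viral] + u_batch + e`` with a random intercept
per sample batch, fitted by restricted maximum likelihood (REML profiled
over the variance ratio). The infection-type coefficient ``b1`` is the
log2 fold change of tail length (positive = longer tails under viral
infection); its two-sided p-value uses a t reference distribution with
Satterthwaite-approximated denominator degrees of freedom. With a single
batch, or when the batch variance estimate hits the zero boundary, the
fit reduces to ordinary least squares (a pooled two-sample t-test).

Gene-level p-values are Benjamini-Hochberg adjusted; a gene is called
differentially polyadenylated (DPG) when adjusted p < alpha and
|log2FC| >= lfc_threshold. A stratified bootstrap refits each candidate
on reads resampled with replacement within each (gene, sample) stratum
to measure how robustly the call survives resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import bh_adjust
from .datatypes import usable_reads

_LOG_LAMBDA_BOUNDS = (-15.0, 10.0)
_BOUNDARY_LAMBDA = 1e-6


@dataclass
class LMMFit:
    log2fc: float
    se: float
    df: float
    p_value: float
    method: str            # "reml" or "ols"
    sigma2: float
    sigma2_batch: float
    n: int


class _SuffStats:
    """Per-batch sufficient statistics for the random-intercept model.

    Design X = [1, viral]; everything needed for the profiled REML
    criterion is expressible through group sizes, group sums of X and y,
    and the global cross-products.
    """

    def __init__(self, y: np.ndarray, viral: np.ndarray, batch_codes: np.ndarray):
        self.n = len(y)
        n_groups = int(batch_codes.max()) + 1
        self.n_g = np.bincount(batch_codes, minlength=n_groups).astype(float)
        sv = np.bincount(batch_codes, weights=viral, minlength=n_groups)
        self.s_g = np.column_stack([self.n_g, sv])          # group sums of X
        self.t_g = np.bincount(batch_codes, weights=y, minlength=n_groups)
        nv = viral.sum()
        self.sxx = np.array([[self.n, nv], [nv, nv]], dtype=float)
        self.sxy = np.array([y.sum(), (y * viral).sum()])
        self.syy = float(y @ y)

    def components(self, lam: float):
        """A = X'V^-1 X, b = X'V^-1 y, q = y'V^-1 y (unit sigma^2) and
        log|V| for V = I + lam * ZZ'."""
        c = lam / (1.0 + lam * self.n_g)
        a = self.sxx - (self.s_g * c[:, None]).T @ self.s_g
        b = self.sxy - self.s_g.T @ (c * self.t_g)
        q = self.syy - float(c @ (self.t_g**2))
        logdet_v = float(np.log1p(lam * self.n_g).sum())
        return a, b, q, logdet_v

    def gls(self, lam: float):
        a, b, q, logdet_v = self.components(lam)
        beta = np.linalg.solve(a, b)
        rss = q - float(beta @ b)
        sign, logdet_a = np.linalg.slogdet(a)
        return beta, rss, logdet_v, logdet_a, a

    def profile_objective(self, lam: float) -> float:
        """-2 REML log-likelihood profiled over beta and sigma^2 (+const)."""
        _, rss, logdet_v, logdet_a, _ = self.gls(lam)
        if rss <= 0:
            return np.inf
        return (self.n - 2) * np.log(rss) + logdet_v + logdet_a

    def reml_m2ll(self, sigma2: float, sigma2_b: float) -> float:
        """-2 REML log-likelihood at given variance components (+const)."""
        lam = sigma2_b / sigma2
        _, rss, logdet_v, logdet_a, _ = self.gls(lam)
        return (
            (self.n - 2) * np.log(sigma2) + logdet_v + logdet_a + rss / sigma2
        )

    def var_beta1(self, sigma2: float, sigma2_b: float) -> float:
        """Sampling variance of the infection-type coefficient."""
        lam = sigma2_b / sigma2
        a, _, _, _ = self.components(lam)
        return sigma2 * float(np.linalg.inv(a)[1, 1])


def _ols_fit(y: np.ndarray, viral: np.ndarray) -> LMMFit:
    """Pooled two-sample t-test, identical to OLS on [1, viral]."""
    y_b = y[viral == 0]
    y_v = y[viral == 1]
    n_b, n_v = len(y_b), len(y_v)
    beta = y_v.mean() - y_b.mean()
    rss = float(((y_b - y_b.mean()) ** 2).sum() + ((y_v - y_v.mean()) ** 2).sum())
    df = n_b + n_v - 2
    if df <= 0 or rss <= 0:
        raise ValueError("zero residual variance")
    s2 = rss / df
    se = float(np.sqrt(s2 * (1.0 / n_b + 1.0 / n_v)))
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return LMMFit(float(beta), se, float(df), float(p), "ols", s2, 0.0, n_b + n_v)


def _satterthwaite_df(ss: _SuffStats, sigma2: float, sigma2_b: float) -> float:
    """Satterthwaite df for b1: 2 f^2 / (g' C g) with f = var(b1_hat),
    g its gradient in the variance components and C their REML covariance
    (inverse observed information), all by central finite differences."""
    theta = np.array([sigma2, sigma2_b])
    steps = np.maximum(1e-4 * theta, 1e-10)

    def f(th):
        return ss.var_beta1(max(th[0], 1e-12), max(th[1], 0.0))

    grad = np.empty(2)
    for i in range(2):
        up = theta.copy(); up[i] += steps[i]
        dn = theta.copy(); dn[i] -= steps[i]
        grad[i] = (f(up) - f(dn)) / (2 * steps[i])

    def m2ll(th):
        return ss.reml_m2ll(max(th[0], 1e-12), max(th[1], 1e-12))

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            pp = theta.copy(); pp[i] += steps[i]; pp[j] += steps[j]
            pm = theta.copy(); pm[i] += steps[i]; pm[j] -= steps[j]
            mp = theta.copy(); mp[i] -= steps[i]; mp[j] += steps[j]
            mm = theta.copy(); mm[i] -= steps[i]; mm[j] -= steps[j]
            hess[i, j] = hess[j, i] = (
                m2ll(pp) - m2ll(pm) - m2ll(mp) + m2ll(mm)
            ) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(0.5 * hess)
    except np.linalg.LinAlgError:
        return float(ss.n - 2)
    fval = f(theta)
    denom = float(grad @ cov @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(ss.n - 2)
    df = 2.0 * fval**2 / denom
    return float(np.clip(df, 1.0, ss.n - 2))


def fit_gene_lmm(
    y: np.ndarray, viral: np.ndarray, batch: np.ndarray
) -> LMMFit:
    """Fit the per-gene random-intercept model on log2 tail lengths.

    Parameters are parallel arrays over reads: the log2 tail, a 0/1 viral
    indicator, and a batch label array. Falls back to OLS when fewer than
    two batches are present or the batch variance estimate is at the zero
    boundary.
    """
    y = np.asarray(y, dtype=float)
    viral = np.asarray(viral, dtype=float)
    codes = pd.factorize(np.asarray(batch))[0]
    if len(y) < 3 or viral.min() == viral.max():
        raise ValueError("need reads in both conditions")
    if codes.max() == 0:
        return _ols_fit(y, viral)

    ss = _SuffStats(y, viral, codes)
    res = optimize.minimize_scalar(
        lambda u: ss.profile_objective(np.exp(u)),
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    # accept the boundary (OLS) solution when it is at least as good
    if lam <= _BOUNDARY_LAMBDA or _ols_objective(ss) <= res.fun + 1e-10:
        return _ols_fit(y, viral)
    beta, rss, _, _, _ = ss.gls(lam)
    sigma2 = rss / (ss.n - 2)
    if sigma2 <= 0:
        raise ValueError("zero residual variance")
    sigma2_b = lam * sigma2
    se = float(np.sqrt(ss.var_beta1(sigma2, sigma2_b)))
    df = _satterthwaite_df(ss, sigma2, sigma2_b)
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return LMMFit(
        float(beta[1]), se, df, float(p), "reml", float(sigma2),
        float(sigma2_b), ss.n,
    )


def _ols_objective(ss: _SuffStats) -> float:
    beta = np.linalg.solve(ss.sxx, ss.sxy)
    rss = ss.syy - float(beta @ ss.sxy)
    sign, logdet = np.linalg.slogdet(ss.sxx)
    return (ss.n - 2) * np.log(rss) + logdet


def fit_gene_records(gene_records: pd.DataFrame) -> LMMFit:
    """Convenience wrapper taking read records for one gene."""
    reads = gene_records[gene_records["polya_length"].notna()]
    y = np.log2(reads["polya_length"].to_numpy(float))
    viral = (reads["condition"] == "viral").to_numpy(float)
    return fit_gene_lmm(y, viral, reads["batch"].to_numpy())


def dp_test_all(
    records: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Test every eligible gene for differential polyadenylation.

    A gene is eligible with at least ``min_reads`` usable reads in each
    condition. Raw p-values are BH-adjusted across fitted genes and the
    DPG flag applies the dual cutoff (adjusted p < alpha and
    |log2FC| >= lfc_threshold). Genes skipped for eligibility are listed
    in ``result.attrs["skipped"]`` with a reason.
    """
    reads = usable_reads(records)
    rows = []
    skipped = []
    for gene_id, group in reads.groupby("gene_id", sort=True):
        n_b = int((group["condition"] == "bacterial").sum())
        n_v = int((group["condition"] == "viral").sum())
        if min(n_b, n_v) < min_reads:
            skipped.append({"gene_id": gene_id,
                            "reason": f"fewer than {min_reads} reads in a condition"})
            continue
        try:
            fit = fit_gene_records(group)
        except ValueError as exc:
            skipped.append({"gene_id": gene_id, "reason": str(exc)})
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "log2fc": fit.log2fc,
                "se": fit.se,
                "df": fit.df,
                "p_value": fit.p_value,
                "n_bacterial": n_b,
                "n_viral": n_v,
                "method": fit.method,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["gene_id", "log2fc", "se", "df", "p_value",
                 "n_bacterial", "n_viral", "method"],
    )
    if len(result):
        result["p_adj"] = bh_adjust(result["p_value"].to_numpy())
        result["is_dpg"] = (result["p_adj"] < alpha) & (
            result["log2fc"].abs() >= lfc_threshold
        )
    else:
        result["p_adj"] = pd.Series(dtype=float)
        result["is_dpg"] = pd.Series(dtype=bool)
    result.attrs["skipped"] = pd.DataFrame(skipped, columns=["gene_id", "reason"])
    result.attrs["n_dpg_up"] = int(
        (result["is_dpg"] & (result["log2fc"] > 0)).sum()
    )
    result.attrs["n_dpg_down"] = int(
        (result["is_dpg"] & (result["log2fc"] < 0)).sum()
    )
    return result


def bootstrap_robustness(
    records: pd.DataFrame,
    candidate_genes,
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    robust_quantile: float = 0.95,
    stratify: str = "sample",
) -> pd.DataFrame:
    """Resampling sensitivity of DPG calls.

    For each bootstrap replicate, the reads of every candidate gene are
    resampled with replacement — within each (gene, sample) stratum by
    default (``stratify="sample"``), or pooled across samples
    (``stratify="pooled"``) — all candidates are refitted, their p-values
    BH-adjusted within the replicate, and a candidate scores a success
    when its adjusted p stays below ``alpha``. ``robust_fraction`` is the
    success rate over replicates; replicates where a resample empties a
    condition count as failures.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if stratify not in ("sample", "pooled"):
        raise ValueError("stratify must be 'sample' or 'pooled'")
    candidates = list(candidate_genes)
    reads = usable_reads(records)
    per_gene = {}
    for gene in candidates:
        group = reads[reads["gene_id"] == gene]
        if not len(group):
            raise ValueError(f"candidate gene {gene} has no usable reads")
        per_gene[gene] = {
            "y": np.log2(group["polya_length"].to_numpy(float)),
            "viral": (group["condition"] == "viral").to_numpy(float),
            "batch": pd.factorize(group["batch"].to_numpy())[0],
            "strata": pd.factorize(group["sample_id"].to_numpy())[0],
        }

    successes = np.zeros(len(candidates))
    attempts = np.zeros(len(candidates))
    for rep in range(n_boot):
        rng = np.random.default_rng([int(seed), 5, rep])
        p_rep = np.full(len(candidates), np.nan)
        for gi, gene in enumerate(candidates):
            data = per_gene[gene]
            n = len(data["y"])
            if stratify == "sample":
                idx = np.empty(n, dtype=int)
                pos = 0
                for stratum in np.unique(data["strata"]):
                    members = np.flatnonzero(data["strata"] == stratum)
                    take = rng.integers(0, len(members), size=len(members))
                    idx[pos : pos + len(members)] = members[take]
                    pos += len(members)
            else:
                idx = rng.integers(0, n, size=n)
            attempts[gi] += 1
            y = data["y"][idx]
            viral = data["viral"][idx]
            if viral.min() == viral.max():
                continue  # a condition emptied by resampling: failure
            try:
                fit = fit_gene_lmm(y, viral, data["batch"][idx])
            except ValueError:
                continue
            p_rep[gi] = fit.p_value
        mask = ~np.isnan(p_rep)
        if mask.any():
            adj = bh_adjust(p_rep[mask])
            successes[np.flatnonzero(mask)[adj < alpha]] += 1
    robust_fraction = successes / np.maximum(attempts, 1)
    return pd.DataFrame(
        {
            "gene_id": candidates,
            "robust_fraction": robust_fraction,
            "is_robust": robust_fraction >= robust_quantile,
            "n_boot": attempts.astype(int),
        }
    )
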