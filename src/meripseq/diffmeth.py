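"""Differential methylation and expression via precision-weighted linear models.

The statistical stage mirrors the standard count-based workflow for MeRIP
differential analysis: CPM inclusion filters, trimmed-mean-of-M-values (TMM)
library normalization, a log-CPM transform with mean-variance precision
weights, feature-wise weighted least squares on the design
``y ~ condition + sequencing_batch + library_batch + ip_procedure``,
empirical-Bayes variance moderation, moderated t-statistics, and
Benjamini-Hochberg adjustment.  A feature is called significant when its
adjusted p-value is below 0.05 and |log2 fold change| exceeds 1.

The module exposes both the individual operations (``tmm_factors``,
``voom_transform``, ``fit_moderated_lm``, ``bh_adjust`` ...) and a
statsmodels-style pair of objects: :class:`DifferentialModel` built from a
count matrix plus sample metadata, whose :meth:`DifferentialModel.fit`
returns a :class:`DifferentialResults` carrying estimates, moderated
statistics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .defaults import DEFAULTS
from .genomic_io import SampleMetadata

BATCH_FACTORS = ("sequencing_batch", "library_batch", "ip_procedure")


# ---------------------------------------------------------------------------
# filters

def cpm(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    return counts / np.asarray(library_sizes, dtype=float) * 1e6


def filter_by_cpm(
    counts: pd.DataFrame,
    samples: Sequence[SampleMetadata],
    min_cpm: float = DEFAULTS["min_cpm"],
    min_samples: int = DEFAULTS["min_cpm_samples"],
    ip_procedure_rule: bool = False,
    min_per_procedure: int = DEFAULTS["min_cpm_per_procedure"],
    library_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """CPM inclusion filters for the differential analysis.

    Rule 1: keep features with >= *min_cpm* CPM in >= *min_samples* samples.
    Rule 2 (peaks only, *ip_procedure_rule*): additionally require
    >= *min_cpm* CPM in >= *min_per_procedure* IP and Input samples of each
    IP procedure within each condition (roles absent from the matrix are
    not constrained).
    """
    sample_by_id = {s.sample_id: s for s in samples}
    if library_sizes is None:
        library_sizes = np.array(
            [sample_by_id[c].library_size for c in counts.columns], dtype=float
        )
    c = cpm(counts.to_numpy(dtype=float), library_sizes)
    ok = (c >= min_cpm).sum(axis=1) >= min_samples
    if ip_procedure_rule:
        cols = [sample_by_id[cname] for cname in counts.columns]
        conditions = sorted({s.condition for s in cols})
        procedures = sorted({s.ip_procedure for s in cols})
        roles = sorted({s.role for s in cols})
        for cond in conditions:
            for proc in procedures:
                for role in roles:
                    idx = [
                        j
                        for j, s in enumerate(cols)
                        if s.condition == cond and s.ip_procedure == proc and s.role == role
                    ]
                    if not idx:
                        continue
                    ok &= (c[:, idx] >= min_cpm).sum(axis=1) >= min_per_procedure
    return counts.loc[ok]


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(
    counts: np.ndarray,
    library_sizes: np.ndarray | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values normalization factors.

    The reference library is the one whose upper quartile (of counts scaled
    by library size) is closest to the mean upper quartile.  For each
    library, M (log2 ratio vs reference) and A (average log2 abundance) are
    computed over features expressed in both, the most extreme 30% of M and
    5% of A are trimmed, and the factor is 2 to the precision-weighted mean
    of the remaining M values; factors are rescaled to geometric mean 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("TMM needs a features x samples matrix with >= 2 samples")
    if library_sizes is None:
        library_sizes = x.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any() or (x.sum(axis=0) <= 0).any():
        raise ValueError("TMM: every sample needs positive counts and library size")
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(x.shape[1])
    for k in range(x.shape[1]):
        f[k] = _tmm_pair(x[:, k], x[:, ref], lib[k], lib[ref],
                         logratio_trim, sum_trim)
    f = f / np.exp(np.mean(np.log(f)))
    return f


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim) -> float:
    both = (obs > 0) & (ref > 0)
    if both.sum() == 0:
        return 1.0
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    fbar = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(fbar):
        return 1.0
    return float(2.0 ** fbar)


# ---------------------------------------------------------------------------
# voom-style transform

def voom_transform(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    norm_factors: np.ndarray | None = None,
    design: np.ndarray | None = None,
    span: float = 0.5,
    min_features: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """log2-CPM with precision weights from the mean-variance trend.

    y = log2((count + 0.5) / (effective library size + 1) * 1e6); an
    unweighted fit of *design* gives per-feature residual standard
    deviations, the lowess trend of sqrt(sd) against average log2 count is
    interpolated at each observation's fitted log2 count, and the weight is
    the predicted standard deviation to the power -4.  With fewer than
    *min_features* features the trend is not estimable and unit weights are
    returned with a warning.
    """
    x = np.asarray(counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    y = np.log2((x + 0.5) / (lib + 1.0) * 1e6)
    n_features, n_samples = x.shape
    if design is None:
        design = np.ones((n_samples, 1))
    if n_features < min_features:
        warnings.warn(
            f"voom: only {n_features} features (< {min_features}); using unit weights"
        )
        return y, np.ones_like(y)
    beta, fitted, sigma, _df = _lm_series(y, np.ones_like(y), design)
    if _df <= 0 or not np.isfinite(sigma).any():
        warnings.warn("voom: no residual degrees of freedom; using unit weights")
        return y, np.ones_like(y)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    order = np.argsort(sx, kind="stable")
    lo = lowess(sy[order], sx[order], frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    fitted_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sd = np.interp(fitted_logcount, lx, ly)
    pred_sd = np.clip(pred_sd, 1e-6, None)
    weights = pred_sd ** -4
    return y, weights


# ---------------------------------------------------------------------------
# weighted least squares + empirical Bayes moderation

def _lm_series(y: np.ndarray, w: np.ndarray, design: np.ndarray):
    """Feature-wise weighted least squares.

    Returns (coefficients, fitted values, residual variances, residual df).
    """
    n_features, n_samples = y.shape
    p = design.shape[1]
    df = n_samples - p
    beta = np.empty((n_features, p))
    fitted = np.empty_like(y)
    sigma2 = np.empty(n_features)
    for g in range(n_features):
        wg = w[g]
        sw = np.sqrt(wg)
        xw = design * sw[:, None]
        yw = y[g] * sw
        b, res, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
        beta[g] = b
        fitted[g] = design @ b
        r = yw - xw @ b
        sigma2[g] = float(r @ r) / df if df > 0 else np.nan
    return beta, fitted, sigma2, df


def trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square prior.

    Returns (prior df d0, prior variance s0^2); d0 may be inf when the
    observed log-variances are less dispersed than chi-square sampling
    alone implies.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    evar = evar - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * float(trigamma_inverse(np.array([evar]))[0])
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def fit_moderated_lm(
    y: np.ndarray,
    weights: np.ndarray,
    design: np.ndarray,
    coef_names: Sequence[str] | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Weighted least squares per feature with empirical-Bayes moderation.

    The residual variances are squeezed toward a common prior estimated by
    method of moments on the log variances; the moderated t-statistic for
    each coefficient uses (d0 s0^2 + d s^2)/(d0 + d) and d0 + d degrees of
    freedom.  ``prior_df=0`` disables moderation (classical t-tests);
    ``prior_df=inf`` pools all features to the prior variance.

    Returns a long DataFrame with one row per (feature, coefficient).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    design = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = _aliased_columns(design, coef_names)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    n_features = y.shape[0]
    p = design.shape[1]
    if coef_names is None:
        coef_names = [f"x{j}" for j in range(p)]
    beta, _fitted, s2, df = _lm_series(y, w, design)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    if prior_df is None:
        d0, s0_2 = squeeze_var(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.nanmean(s2))
    elif np.isinf(prior_df):
        d0, s0_2 = np.inf, float(np.exp(np.mean(np.log(s2[s2 > 0]))))
    else:
        d0 = float(prior_df)
        _, s0_2 = squeeze_var(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    # unscaled standard errors per coefficient (weights differ per feature)
    rows = []
    for g in range(n_features):
        wg = w[g]
        xtwx_inv = np.linalg.inv(design.T @ (design * wg[:, None]))
        se_unscaled = np.sqrt(np.diag(xtwx_inv))
        se = se_unscaled * np.sqrt(s2_post[g])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[g] / se
        if np.isinf(df_total):
            pvals = 2.0 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        for j, name in enumerate(coef_names):
            rows.append((g, name, beta[g, j], se[j], t[j], pvals[j]))
    out = pd.DataFrame(rows, columns=["feature", "coef", "estimate", "se", "t", "p"])
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    out.attrs["residual_df"] = df
    return out


def _aliased_columns(design: np.ndarray, names: Sequence[str] | None) -> list[str]:
    names = list(names) if names else [f"x{j}" for j in range(design.shape[1])]
    keep: list[int] = []
    aliased = []
    for j in range(design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# multiple testing and calls

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are excluded from the family and propagated unchanged.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def call_significant(
    table: pd.DataFrame,
    lfc: float = DEFAULTS["lfc_threshold"],
    alpha: float = DEFAULTS["adj_p_threshold"],
) -> pd.DataFrame:
    """Flag features with adjusted p < alpha and |logFC| > lfc (strict)."""
    table = table.copy()
    table["significant"] = (table["p_adj"] < alpha) & (table["logFC"].abs() > lfc)
    return table


def classify_peaks_vs_expression(
    peak_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    peak_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Cross peak-level and transcript-level significance.

    Categories: ``meth_and_expr`` (peak and host gene both significant),
    ``meth_only`` (peak significant, gene unchanged), ``not_significant``.
    Peaks without a host gene are excluded with a warning.
    """
    gene_sig = dict(zip(gene_results["feature_id"], gene_results["significant"]))
    rows = []
    n_orphans = 0
    for _, row in peak_results.iterrows():
        gene = peak_gene.get(row["feature_id"])
        if gene is None or gene == ".":
            n_orphans += 1
            continue
        if row["significant"]:
            cat = "meth_and_expr" if gene_sig.get(gene, False) else "meth_only"
        else:
            cat = "not_significant"
        rows.append((row["feature_id"], gene, cat))
    if n_orphans:
        warnings.warn(f"{n_orphans} peak(s) without a host gene excluded")
    return pd.DataFrame(rows, columns=["feature_id", "gene_id", "category"])


def remove_batch_effects(
    y: np.ndarray,
    design_condition: np.ndarray,
    design_batch: np.ndarray,
) -> np.ndarray:
    """Subtract fitted batch-term contributions, retaining condition effects.

    The full model [condition | batch] is fitted by ordinary least squares
    per feature and the batch columns' fitted contribution is removed —
    suitable input for ordination or heat maps, not for inference.
    """
    y = np.asarray(y, dtype=float)
    if design_batch.size == 0 or design_batch.shape[1] == 0:
        return y.copy()
    x = np.hstack([design_condition, design_batch])
    beta, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    p_cond = design_condition.shape[1]
    batch_part = design_batch @ beta[p_cond:, :]
    return y - batch_part.T


# ---------------------------------------------------------------------------
# model / results objects

def build_design(
    samples: Sequence[SampleMetadata],
    condition_ref: str | None = None,
    batch_factors: Sequence[str] = BATCH_FACTORS,
) -> tuple[np.ndarray, list[str], int]:
    """Treatment-coded design matrix: intercept + condition + batch factors.

    Factors with a single level are dropped (they carry no information);
    returns (matrix, column names, number of non-batch columns).
    """
    conditions = sorted({s.condition for s in samples})
    if condition_ref is None:
        condition_ref = "CONV" if "CONV" in conditions else conditions[0]
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["Intercept"]
    for level in conditions:
        if level == condition_ref:
            continue
        cols.append(np.array([1.0 if s.condition == level else 0.0 for s in samples]))
        names.append(f"condition[{level}]")
    n_condition_cols = len(names)
    for factor in batch_factors:
        levels = sorted({getattr(s, factor) for s in samples})
        for level in levels[1:]:
            cols.append(
                np.array([1.0 if getattr(s, factor) == level else 0.0 for s in samples])
            )
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), names, n_condition_cols


@dataclass
class DifferentialModel:
    """Precision-weighted linear model for count-based differential analysis.

    Built from a features x samples count matrix and sample metadata;
    ``fit()`` runs TMM -> log-CPM transform with precision weights ->
    feature-wise WLS -> empirical-Bayes moderation and returns a
    :class:`DifferentialResults`.
    """

    counts: pd.DataFrame
    samples: list[SampleMetadata]
    condition_ref: str | None = None
    batch_factors: tuple[str, ...] = BATCH_FACTORS
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        by_id = {s.sample_id: s for s in self.samples}
        missing = [c for c in self.counts.columns if c not in by_id]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        self.samples = [by_id[c] for c in self.counts.columns]
        if self.library_sizes is None:
            libs = np.array([s.library_size for s in self.samples], dtype=float)
            if (libs <= 0).any():
                libs = self.counts.to_numpy(dtype=float).sum(axis=0)
            self.library_sizes = libs
        self.design, self.design_names, self.n_condition_cols = build_design(
            self.samples, self.condition_ref, self.batch_factors
        )

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        condition_ref: str | None = None,
    ) -> "DifferentialModel":
        samples = [
            SampleMetadata(
                sample_id=str(r["sample_id"]),
                role=str(r.get("role", "Input")),
                pair_id=str(r.get("pair_id", r["sample_id"])),
                condition=str(r["condition"]),
                sequencing_batch=str(r.get("sequencing_batch", "b1")),
                library_batch=str(r.get("library_batch", "b1")),
                ip_procedure=str(r.get("ip_procedure", "p1")),
                library_size=int(r.get("library_size", 0)),
            )
            for _, r in metadata.iterrows()
        ]
        return cls(counts=counts, samples=samples, condition_ref=condition_ref)

    def fit(self, prior_df: float | None = None) -> "DifferentialResults":
        x = self.counts.to_numpy(dtype=float)
        factors = tmm_factors(x, self.library_sizes)
        y, w = voom_transform(x, self.library_sizes, factors, self.design)
        table = fit_moderated_lm(y, w, self.design, self.design_names, prior_df)
        return DifferentialResults(
            model=self,
            coef_table=table,
            norm_factors=factors,
            logcpm=y,
            weights=w,
        )


@dataclass
class DifferentialResults:
    """Estimates, moderated statistics and significance calls of a fit."""

    model: DifferentialModel
    coef_table: pd.DataFrame
    norm_factors: np.ndarray
    logcpm: np.ndarray
    weights: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def prior_df(self) -> float:
        return self.coef_table.attrs["prior_df"]

    def contrast(
        self,
        condition: str,
        baseline: str | None = None,
        lfc: float = DEFAULTS["lfc_threshold"],
        alpha: float = DEFAULTS["adj_p_threshold"],
    ) -> pd.DataFrame:
        """Per-feature table for one condition coefficient vs the reference.

        Columns: feature_id, logFC, t, p, p_adj, significant.  *baseline*
        other than the fitted reference is not re-fitted; pass it as
        ``condition_ref`` when constructing the model.
        """
        name = f"condition[{condition}]"
        if name not in set(self.coef_table["coef"]):
            raise KeyError(
                f"no coefficient for condition {condition!r}; fitted: "
                f"{sorted(set(self.coef_table['coef']))}"
            )
        sub = self.coef_table[self.coef_table["coef"] == name].reset_index(drop=True)
        table = pd.DataFrame(
            {
                "feature_id": [self.model.counts.index[i] for i in sub["feature"]],
                "logFC": sub["estimate"].to_numpy(),
                "t": sub["t"].to_numpy(),
                "p": sub["p"].to_numpy(),
            }
        )
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        return call_significant(table, lfc=lfc, alpha=alpha)

    def batch_corrected(self) -> np.ndarray:
        """log-CPM with fitted batch-term contributions removed."""
        n = self.model.n_condition_cols
        return remove_batch_effects(
            self.logcpm, self.model.design[:, :n], self.model.design[:, n:]
        )

    def summary(self, condition: str | None = None) -> str:
        """Human-readable fit summary, optionally for one contrast."""
        m = self.model
        lines = [
            "Differential analysis (precision-weighted LM, moderated t)",
            "=" * 60,
            f"features: {m.counts.shape[0]}    samples: {m.counts.shape[1]}",
            f"design columns: {', '.join(m.design_names)}",
            f"residual df: {self.coef_table.attrs['residual_df']}    "
            f"prior df: {self.prior_df:.3g}    prior var: "
            f"{self.coef_table.attrs['prior_var']:.4g}",
            "TMM factors: "
            + ", ".join(f"{f:.3f}" for f in self.norm_factors),
        ]
        if condition is not None:
            t = self.contrast(condition)
            n_sig = int(t["significant"].sum())
            lines += [
                "-" * 60,
                f"contrast condition[{condition}] vs reference:",
                f"  significant features (adj p < {DEFAULTS['adj_p_threshold']}, "
                f"|logFC| > {DEFAULTS['lfc_threshold']}): {n_sig}",
                t.sort_values("p_adj").head(10).to_string(index=False),
            ]
        return "\n".join(lines)
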