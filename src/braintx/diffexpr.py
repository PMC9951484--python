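"""Covariate-adjusted differential expression for small bulk cohorts.

The model is deliberately simple: counts are normalized with
median-of-ratios size factors, log2-transformed with a pseudocount of 1,
and each gene is fitted with an ordinary least-squares linear model

    log2(norm_count + 1) ~ sex + batch + condition

The condition coefficient is reported as the log2 fold change (stress vs
control) with a two-sided t-test p-value, and p-values are
Benjamini-Hochberg adjusted across all tested genes.  With so few residual
degrees of freedom per gene, raw per-gene variance estimates are unstable;
by default the residual variances are therefore moderated with the
standard empirical-Bayes squeeze (an inverse-gamma prior fitted to the
observed variances; posterior variance a prior/data compromise, t-test
degrees of freedom increased by the prior's), which is the field's usual
remedy for small cohorts.  Genes below a minimal
mean-normalized-expression filter are excluded from testing (and from the
BH family); the filter is recorded on the results object.

This produces calibrated DEG / background partitions for the downstream
cell-type and region enrichment stages; it makes no attempt at negative
binomial dispersion modelling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_size_factors",
    "adjust_bh",
    "DifferentialExpression",
    "DEResults",
    "split_by_direction",
]


def estimate_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (one strictly positive factor/sample).

    For each gene with nonzero counts in *all* samples, the ratio of each
    sample's count to the gene's geometric mean is formed; a sample's factor
    is the median of its ratios.  Genes with any zero are excluded from the
    reference set.
    """
    if isinstance(counts, GeneCountMatrix):
        counts = counts.counts
    values = counts.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "cannot estimate size factors: no gene has nonzero counts in "
            "every sample"
        )
    logc = np.log(values[usable])
    ratios = np.exp(logc - logc.mean(axis=1, keepdims=True))
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    q_i = min_{j >= i} (p_(j) * m / j), capped at 1, with a stable sort so
    ties keep their input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, dof: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes moderation of per-gene residual variances.

    Fits a scaled inverse-chi-square prior (prior variance ``s0^2``, prior
    degrees of freedom ``d0``) to the observed variances by matching the
    moments of ``log s2`` against its theoretical chi-square spread, then
    returns the posterior variances ``(d0*s0^2 + dof*s2) / (d0 + dof)`` and
    ``d0``.  ``d0 = inf`` (all information pooled) is returned when the
    observed spread is no wider than chance.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        return s2.copy(), 0.0
    e = np.log(s2[positive]) - float(digamma(dof / 2.0)) + np.log(dof / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, dof / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_sq)
        post[~positive] = s0_sq
        return post, d0
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(
        np.exp(np.mean(e) + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    )
    post = (d0 * s0_sq + dof * s2) / (d0 + dof)
    return post, d0


def _parse_subset(subset) -> dict[str, str]:
    if subset is None:
        return {}
    if isinstance(subset, dict):
        return dict(subset)
    key, _, value = str(subset).partition("=")
    if not value:
        raise ValueError(f"subset must look like 'column=value', got {subset!r}")
    return {key.strip(): value.strip()}


class DifferentialExpression:
    """Per-gene covariate-adjusted linear model on log-normalized counts.

    Parameters
    ----------
    data
        Bulk counts with metadata (condition, sex, batch).
    min_mean
        Genes with mean normalized count below this are not tested.
    covariates
        Metadata columns adjusted for besides condition.
    moderate_variance
        Empirical-Bayes squeeze of per-gene residual variances (default);
        set False for the plain per-gene t-test.
    """

    def __init__(
        self,
        data: GeneCountMatrix,
        min_mean: float = 1.0,
        covariates: tuple[str, ...] = ("sex", "batch"),
        moderate_variance: bool = True,
    ):
        self.data = data
        self.min_mean = float(min_mean)
        self.covariates = tuple(covariates)
        self.moderate_variance = bool(moderate_variance)

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, metadata: pd.DataFrame,
                        **kwargs) -> "DifferentialExpression":
        return cls(GeneCountMatrix(counts, metadata), **kwargs)

    # -- design ----------------------------------------------------------
    def _design(self, meta: pd.DataFrame) -> pd.DataFrame:
        ref, alt = self.data.condition_levels
        design = pd.DataFrame(
            {"intercept": 1.0}, index=meta.index, dtype=float
        )
        for cov in self.covariates:
            levels = sorted(meta[cov].unique())
            if len(levels) < 2:
                logger.info("covariate %r constant after subsetting; dropped", cov)
                continue
            for lvl in levels[1:]:
                design[f"{cov}[{lvl}]"] = (meta[cov] == lvl).astype(float)
        design[f"condition[{alt}]"] = (meta["condition"] == alt).astype(float)
        X = design.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            collinear = []
            for j, col in enumerate(design.columns):
                reduced = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    collinear.append(col)
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(collinear)
            )
        return design

    # -- fitting ----------------------------------------------------------
    def fit(self, alpha: float = 0.05, subset=None) -> "DEResults":
        """Fit the per-gene model and return a results table.

        ``subset`` restricts samples first (e.g. ``"sex=M"`` for a
        sex-stratified reanalysis); a covariate left with a single level is
        dropped from the design.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        meta = self.data.metadata
        counts = self.data.counts
        for col, value in _parse_subset(subset).items():
            keep = meta[col].astype(str) == value
            if not keep.any():
                raise ValueError(f"subset {col}={value} matches no samples")
            meta = meta[keep]
            counts = counts[meta.index]
        cond_counts = meta["condition"].value_counts()
        if (cond_counts < 2).any() or len(cond_counts) < 2:
            raise ValueError(
                "need at least two samples per condition; got "
                + ", ".join(f"{k}={v}" for k, v in cond_counts.items())
            )
        size_factors = estimate_size_factors(counts)
        norm = counts / size_factors
        base_mean = norm.mean(axis=1)
        tested = base_mean >= self.min_mean
        n_filtered = int((~tested).sum())
        if n_filtered:
            logger.info(
                "expression filter (mean normalized count >= %g) removed "
                "%d of %d genes before testing",
                self.min_mean, n_filtered, len(tested),
            )
        if tested.sum() == 0:
            raise ValueError("no genes pass the expression filter")

        design = self._design(meta)
        X = design.to_numpy()
        cond_col = design.columns.get_loc(design.columns[-1])
        n, p = X.shape
        dof = n - p
        if dof < 1:
            raise ValueError("not enough residual degrees of freedom")

        Y = np.log2(norm.loc[tested].to_numpy() + 1.0)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = Y @ (XtX_inv @ X.T).T
        resid = Y - beta @ X.T
        sigma2 = (resid**2).sum(axis=1) / dof
        if self.moderate_variance:
            sigma2, d0 = squeeze_variances(sigma2, dof)
            t_dof = dof + d0 if np.isfinite(d0) else 1e6
        else:
            t_dof = dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[cond_col, cond_col], 0.0))
        lfc = beta[:, cond_col]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), t_dof)

        zero_var = Y.var(axis=1) < 1e-24
        lfc = np.where(zero_var, 0.0, lfc)
        pvals = np.where(zero_var, 1.0, pvals)
        padj = adjust_bh(pvals)

        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": np.nan,
                "p": np.nan,
                "padj": np.nan,
                "tested": tested,
            },
            index=counts.index,
        )
        table.loc[tested, "log2fc"] = lfc
        table.loc[tested, "p"] = pvals
        table.loc[tested, "padj"] = padj
        table["set"] = classify_sets(table, alpha)
        return DEResults(
            table=table,
            alpha=alpha,
            size_factors=size_factors,
            design=design,
            n_filtered=n_filtered,
            subset=_parse_subset(subset) or None,
        )


def classify_sets(table: pd.DataFrame, alpha: float) -> pd.Series:
    """Assign each gene to up / down / background / filtered.

    Significance uses the strict inequality ``padj < alpha``; a gene with
    ``padj`` exactly at the threshold is background.  Untested (filtered)
    genes belong to none of the three analysis sets.
    """
    sets = pd.Series("background", index=table.index, dtype=object)
    sig = table["padj"] < alpha
    sets[sig & (table["log2fc"] > 0)] = "up"
    sets[sig & (table["log2fc"] < 0)] = "down"
    sets[~table["tested"].astype(bool)] = "filtered"
    return sets


def split_by_direction(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str], list[str]]:
    """(up, down, background) gene lists from a DE table.

    Background are the tested genes not significant at ``padj < alpha`` —
    the "unchanged" comparison set for enrichment.
    """
    sets = classify_sets(table, alpha)
    up = table.index[sets == "up"].tolist()
    down = table.index[sets == "down"].tolist()
    background = table.index[sets == "background"].tolist()
    return up, down, background


class DEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table
        Per-gene frame with ``base_mean``, ``log2fc``, ``p``, ``padj``,
        ``tested`` and ``set`` (up / down / background / filtered).
    """

    def __init__(self, table, alpha, size_factors, design, n_filtered,
                 subset=None):
        self.table = table
        self.alpha = alpha
        self.size_factors = size_factors
        self.design = design
        self.n_filtered = n_filtered
        self.subset = subset

    @property
    def up(self) -> list[str]:
        return self.table.index[self.table["set"] == "up"].tolist()

    @property
    def down(self) -> list[str]:
        return self.table.index[self.table["set"] == "down"].tolist()

    @property
    def background(self) -> list[str]:
        return self.table.index[self.table["set"] == "background"].tolist()

    def gene_sets(self) -> dict[str, list[str]]:
        return {"up": self.up, "down": self.down, "background": self.background}

    def summary(self) -> str:
        lines = [
            "Differential expression (log-linear model, BH-adjusted)",
            f"  samples: {self.design.shape[0]}   design: "
            + " + ".join(self.design.columns),
            f"  genes tested: {int(self.table['tested'].sum())} "
            f"(filtered: {self.n_filtered})",
            f"  significant at padj < {self.alpha:g}: "
            f"{len(self.up)} up, {len(self.down)} down",
        ]
        if self.subset:
            lines.insert(1, f"  subset: {self.subset}")
        sig = self.table[self.table["set"].isin(["up", "down"])]
        if len(sig):
            top = sig.nsmallest(min(10, len(sig)), "padj")
            lines.append("  top genes:")
            for gene, row in top.iterrows():
                lines.append(
                    f"    {gene:<12} log2FC={row['log2fc']:+.3f}  "
                    f"padj={row['padj']:.3g} ({row['set']})"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
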