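"""Cell-type enrichment of DEG sets against a single-cell reference.

Two steps:

1. **PEM normalization.**  Per-cell-type mean expression profiles
   ``X[g, i]`` (pseudobulk means) are normalized into a preferential
   expression measure that corrects for the unequal total expression mass
   ``S[i]`` of each cell type::

       PEM[g, i] = log10( (sum_i S[i] / S[i]) * (X[g, i] / sum_i X[g, i]) )

   PEM is 0 when a gene's expression is spread over the types in proportion
   to their totals, positive when it is preferentially expressed in type i.

2. **K-S enrichment.**  For each cell type, a two-sample
   Kolmogorov-Smirnov test compares the PEM values of the DEG set against
   those of the unchanged (background) genes; a right-shifted DEG
   distribution means the DEGs are preferentially expressed in that type.
   P-values are BH-adjusted across the cell types of one call, and the
   enrichment score is reported as -log10(padj).
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellTypeProfiles, PEMMatrix
from .diffexpr import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "pseudobulk_means",
    "compute_pem",
    "CellTypeEnrichment",
    "EnrichmentResults",
    "ks_enrichment",
]


def pseudobulk_means(
    reference: ad.AnnData,
    level: str = "class",
    min_cells: int = 3,
    normalize: str | None = "cp10k",
) -> CellTypeProfiles:
    """Per-cell-type mean expression from a labeled single-cell reference.

    Parameters
    ----------
    reference
        AnnData of cells x genes counts with the label column ``level`` in
        ``.obs`` (``class`` or ``subclass``).
    min_cells
        Types with fewer cells are dropped (logged).
    normalize
        ``"cp10k"`` scales each cell to 10,000 total counts before
        averaging; ``None`` averages raw counts.
    """
    if reference.n_obs == 0:
        raise ValueError("reference contains no cells")
    if level not in reference.obs.columns:
        raise ValueError(
            f"unknown label level {level!r}; available: "
            f"{list(reference.obs.columns)}"
        )
    if normalize not in (None, "cp10k"):
        raise ValueError("normalize must be 'cp10k' or None")
    X = np.asarray(
        reference.X.toarray() if hasattr(reference.X, "toarray") else reference.X,
        dtype=float,
    )
    if normalize == "cp10k":
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        X = X / totals * 1e4
    labels = reference.obs[level].astype(str)
    means = {}
    for ctype, idx in labels.groupby(labels).groups.items():
        n_cells = len(idx)
        if n_cells < min_cells:
            logger.warning(
                "cell type %r has %d cells (< %d); dropped from profiles",
                ctype, n_cells, min_cells,
            )
            continue
        rows = labels.index.get_indexer(idx)
        means[ctype] = X[rows].mean(axis=0)
    if len(means) < 2:
        raise ValueError("fewer than two cell types survive the cell filter")
    profile = pd.DataFrame(means, index=reference.var_names)
    return CellTypeProfiles(profile, level=level)


def compute_pem(
    profiles: CellTypeProfiles, pseudocount: float = 1e-3
) -> PEMMatrix:
    """Preferential expression measure from cell-type profiles.

    The pseudocount is added to every entry of ``X`` before the type totals
    ``S`` and the ratios are formed, so every PEM value is finite.  A
    pseudocount of 0 is admissible only when all entries are positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    X = profiles.X.to_numpy() + pseudocount
    if (X <= 0).any():
        raise ValueError(
            "pseudocount must be positive when the profile matrix has zeros"
        )
    S = X.sum(axis=0)
    gene_tot = X.sum(axis=1, keepdims=True)
    ee = (S.sum() / S)[None, :] * (X / gene_tot)
    pem = pd.DataFrame(
        np.log10(ee), index=profiles.X.index, columns=profiles.X.columns
    )
    return PEMMatrix(
        pem=pem,
        S=pd.Series(S, index=profiles.X.columns, name="S"),
        pseudocount=float(pseudocount),
    )


# scipy's `alternative` describes the CDF of the first sample; enrichment
# toward *higher* PEM in the DEG set means its CDF lies *below* the
# background CDF, hence the mapping below.
_SCIPY_ALTERNATIVE = {"two-sided": "two-sided", "greater": "less"}


class CellTypeEnrichment:
    """K-S enrichment of a DEG set vs background genes, per cell type.

    Parameters
    ----------
    pem
        PEM matrix (or a raw profile matrix via ``values``); distributions
        are compared per column.
    deg_genes, background_genes
        Disjoint gene sets; genes absent from the matrix are dropped and
        counted.
    alternative
        ``"two-sided"`` (default) or ``"greater"`` — the latter tests for a
        shift of the DEG set toward higher values.
    method
        K-S p-value computation: ``"asymp"`` (default), ``"exact"`` or
        ``"auto"``.
    """

    def __init__(
        self,
        pem: PEMMatrix | pd.DataFrame,
        deg_genes,
        background_genes,
        alternative: str = "two-sided",
        method: str = "asymp",
        min_genes: int = 10,
    ):
        self.values = pem.pem if isinstance(pem, PEMMatrix) else pem
        self.deg_genes = list(dict.fromkeys(deg_genes))
        self.background_genes = list(dict.fromkeys(background_genes))
        overlap = set(self.deg_genes) & set(self.background_genes)
        if overlap:
            raise ValueError(
                f"DEG and background sets overlap: {sorted(overlap)[:5]}"
            )
        if alternative not in _SCIPY_ALTERNATIVE:
            raise ValueError("alternative must be 'two-sided' or 'greater'")
        self.alternative = alternative
        self.method = method
        self.min_genes = int(min_genes)

    def fit(self) -> "EnrichmentResults":
        universe = self.values.index
        deg = [g for g in self.deg_genes if g in universe]
        bg = [g for g in self.background_genes if g in universe]
        n_deg_missing = len(self.deg_genes) - len(deg)
        n_bg_missing = len(self.background_genes) - len(bg)
        if n_deg_missing or n_bg_missing:
            logger.info(
                "dropped genes absent from the PEM universe: %d DEG, %d background",
                n_deg_missing, n_bg_missing,
            )
        if len(deg) < self.min_genes or len(bg) < self.min_genes:
            raise ValueError(
                f"need at least {self.min_genes} DEG and background genes in "
                f"the PEM universe; have {len(deg)} and {len(bg)}"
            )
        rows = []
        skipped = []
        for ctype in self.values.columns:
            col = self.values[ctype]
            d_vals = col.loc[deg].to_numpy(float)
            b_vals = col.loc[bg].to_numpy(float)
            d_vals = d_vals[np.isfinite(d_vals)]
            b_vals = b_vals[np.isfinite(b_vals)]
            if len(d_vals) < self.min_genes or len(b_vals) < self.min_genes:
                logger.warning(
                    "cell type %r skipped: too few finite values", ctype
                )
                skipped.append(ctype)
                continue
            res = stats.ks_2samp(
                d_vals,
                b_vals,
                alternative=_SCIPY_ALTERNATIVE[self.alternative],
                method=self.method,
            )
            shift = float(np.median(d_vals) - np.median(b_vals))
            rows.append(
                {
                    "cell_type": ctype,
                    "D": float(res.statistic),
                    "shift_sign": int(np.sign(shift)),
                    "p": float(res.pvalue),
                    "n_deg_used": len(d_vals),
                    "n_background_used": len(b_vals),
                }
            )
        if not rows:
            raise ValueError("no cell type had enough genes to test")
        table = pd.DataFrame(rows).set_index("cell_type")
        table["padj"] = adjust_bh(table["p"].to_numpy())
        with np.errstate(divide="ignore"):
            table["score"] = -np.log10(table["padj"])
        table = table[
            ["D", "shift_sign", "p", "padj", "score",
             "n_deg_used", "n_background_used"]
        ]
        return EnrichmentResults(
            table=table,
            alternative=self.alternative,
            method=self.method,
            skipped=skipped,
            n_deg_missing=n_deg_missing,
            n_background_missing=n_bg_missing,
        )


class EnrichmentResults:
    """Per-cell-type K-S enrichment table with BH adjustment.

    ``table`` columns: D (K-S statistic), shift_sign (sign of the median
    PEM difference, DEG minus background), p, padj (BH across the cell
    types of this call), score (-log10 padj), and gene counts used.
    """

    def __init__(self, table, alternative, method, skipped,
                 n_deg_missing, n_background_missing):
        self.table = table
        self.alternative = alternative
        self.method = method
        self.skipped = skipped
        self.n_deg_missing = n_deg_missing
        self.n_background_missing = n_background_missing

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.sort_values("padj").head(n)

    def summary(self) -> str:
        lines = [
            f"Cell-type enrichment (K-S, {self.alternative}, "
            f"{self.method} p-values; BH across {len(self.table)} types)",
            f"  genes used: {int(self.table['n_deg_used'].iloc[0])} DEG vs "
            f"{int(self.table['n_background_used'].iloc[0])} background",
        ]
        if self.skipped:
            lines.append(f"  skipped types: {', '.join(self.skipped)}")
        for ctype, row in self.top(8).iterrows():
            arrow = {1: "higher", 0: "equal", -1: "lower"}[int(row["shift_sign"])]
            lines.append(
                f"  {ctype:<22} D={row['D']:.3f}  padj={row['padj']:.3g}  "
                f"score={row['score']:.2f}  (DEG PEM {arrow})"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def ks_enrichment(
    pem,
    deg_genes,
    background_genes,
    alternative: str = "two-sided",
    method: str = "asymp",
    min_genes: int = 10,
) -> EnrichmentResults:
    """Functional wrapper around :class:`CellTypeEnrichment`."""
    return CellTypeEnrichment(
        pem, deg_genes, background_genes,
        alternative=alternative, method=method, min_genes=min_genes,
    ).fit()
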