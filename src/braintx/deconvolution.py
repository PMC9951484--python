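"""Signature-based cell-type fraction estimation from bulk counts.

A transparent deconvolution: the signature collects, for each cell type,
the top-k genes by PEM (the most preferentially expressed genes); both the
signature and the bulk samples are put on a counts-per-million scale; each
sample's signature-gene vector is then regressed on the signature columns
by non-negative least squares and the coefficients renormalized to sum to
one.  Group differences in the estimated fractions are assessed per cell
type with an unpaired Welch t-test (no multiplicity correction, matching
the usual per-type bar-plot convention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    CellTypeProfiles,
    FractionTable,
    GeneCountMatrix,
    PEMMatrix,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_signature",
    "FractionDeconvolution",
    "FractionResults",
    "estimate_fractions",
    "compare_fractions",
]


def build_signature(
    profiles: CellTypeProfiles, pem: PEMMatrix, k: int = 50
) -> SignatureMatrix:
    """Top-k-by-PEM marker signature, in counts-per-million units.

    For each cell type the k genes with the highest PEM are selected; the
    union (a gene marking several types appears once) forms the signature
    rows, whose values are the type profiles rescaled so each type column
    totals 1e6 over the full gene universe.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not profiles.X.index.equals(pem.pem.index) or not profiles.X.columns.equals(
        pem.pem.columns
    ):
        raise ValueError("profiles and PEM matrix are not aligned")
    n_genes = profiles.X.shape[0]
    if k > n_genes:
        logger.warning("k=%d exceeds %d available genes; capped", k, n_genes)
        k = n_genes
    markers: dict[str, list[str]] = {}
    selected: list[str] = []
    for ctype in pem.pem.columns:
        top = pem.pem[ctype].nlargest(k).index.tolist()
        markers[ctype] = top
        selected.extend(top)
    union = list(dict.fromkeys(selected))
    cpm = profiles.X / profiles.S * 1e6
    data = cpm.loc[union]
    nonzero = ~(data.to_numpy() == 0).all(axis=1)
    data = data.loc[nonzero]
    return SignatureMatrix(data=data, markers=markers, k=k)


class FractionDeconvolution:
    """NNLS deconvolution of bulk samples against a marker signature.

    Parameters
    ----------
    bulk
        Bulk counts (:class:`GeneCountMatrix` or a genes x samples frame).
    signature
        CPM-scale marker signature from :func:`build_signature`.
    weighting
        ``"inverse_mean"`` (default) rescales each signature gene's row by
        the inverse of its mean signature expression before the NNLS fit.
        RNA-seq noise is approximately multiplicative (constant CV), so its
        variance grows with the square of the mean; inverse-mean row
        weights are the corresponding weighted-least-squares choice and
        keep a handful of very highly expressed genes from dominating the
        fit.  ``"none"`` fits plain NNLS on the CPM values.
    """

    def __init__(self, bulk, signature: SignatureMatrix,
                 weighting: str = "inverse_mean"):
        if weighting not in ("inverse_mean", "none"):
            raise ValueError("weighting must be 'inverse_mean' or 'none'")
        self.weighting = weighting
        if isinstance(bulk, GeneCountMatrix):
            self.metadata = bulk.metadata
            bulk = bulk.counts
        else:
            self.metadata = None
        self.bulk = bulk
        self.signature = signature
        shared = signature.genes.intersection(bulk.index)
        if len(shared) < signature.data.shape[1]:
            raise ValueError(
                f"only {len(shared)} signature genes found in the bulk matrix; "
                f"need at least {signature.data.shape[1]} (one per cell type)"
            )
        self._shared = shared
        A = signature.data.loc[shared].to_numpy()
        if np.linalg.matrix_rank(A) < A.shape[1]:
            corr = np.corrcoef(A.T)
            pairs = [
                f"{signature.cell_types[i]}~{signature.cell_types[j]}"
                for i in range(len(corr))
                for j in range(i + 1, len(corr))
                if abs(corr[i, j]) > 1 - 1e-9
            ]
            raise ValueError(
                "signature matrix is rank deficient; collinear cell types: "
                + (", ".join(pairs) if pairs else "(unidentified)")
            )

    def fit(self) -> "FractionResults":
        sig = self.signature.data.loc[self._shared]
        A = sig.to_numpy()
        totals = self.bulk.sum(axis=0).to_numpy(dtype=float)
        totals[totals == 0] = 1.0
        cpm = self.bulk.to_numpy(dtype=float) / totals[None, :] * 1e6
        gene_rows = self.bulk.index.get_indexer(self._shared)
        B = cpm[gene_rows, :]
        if self.weighting == "inverse_mean":
            w = 1.0 / np.maximum(A.mean(axis=1), 1e-12)
        else:
            w = np.ones(A.shape[0])
        Aw = A * w[:, None]
        fracs = np.zeros((self.bulk.shape[1], A.shape[1]))
        resid = np.zeros(self.bulk.shape[1])
        for j in range(self.bulk.shape[1]):
            coef, rnorm = optimize.nnls(Aw, B[:, j] * w)
            total = coef.sum()
            if total <= 0:
                raise ValueError(
                    f"NNLS returned an all-zero solution for sample "
                    f"{self.bulk.columns[j]!r}"
                )
            fracs[j] = coef / total
            resid[j] = rnorm
        fractions = pd.DataFrame(
            fracs, index=self.bulk.columns, columns=sig.columns
        )
        residuals = pd.Series(resid, index=self.bulk.columns, name="residual")
        return FractionResults(
            FractionTable(fractions, residuals), self.metadata, self.signature
        )


class FractionResults:
    """Estimated cell-type fractions with optional group comparison."""

    def __init__(self, fraction_table: FractionTable, metadata, signature):
        self.fraction_table = fraction_table
        self.metadata = metadata
        self.signature = signature

    @property
    def fractions(self) -> pd.DataFrame:
        return self.fraction_table.fractions

    @property
    def residuals(self) -> pd.Series:
        return self.fraction_table.residuals

    def compare(self, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        meta = metadata if metadata is not None else self.metadata
        if meta is None:
            raise ValueError("no sample metadata available for comparison")
        return compare_fractions(self.fraction_table, meta)

    def summary(self) -> str:
        means = self.fractions.mean(axis=0).sort_values(ascending=False)
        lines = [
            f"Cell-type fractions ({self.fractions.shape[0]} samples x "
            f"{self.fractions.shape[1]} types; NNLS on "
            f"{self.signature.data.shape[0]}-gene signature)",
            "  mean fractions:",
        ]
        for ctype, m in means.head(8).items():
            lines.append(f"    {ctype:<22} {m:7.2%}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["residual"] = self.residuals
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def estimate_fractions(bulk, signature: SignatureMatrix) -> FractionTable:
    """Functional wrapper: NNLS fractions for each bulk sample."""
    return FractionDeconvolution(bulk, signature).fit().fraction_table


def compare_fractions(
    fractions: FractionTable | pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-type Welch t-test of fractions between the two conditions.

    Returns mean and SEM per group plus the t statistic and two-sided
    p-value; identical groups give t = 0, p = 1.
    """
    table = (
        fractions.fractions
        if isinstance(fractions, FractionTable)
        else FractionTable(fractions).fractions
    )
    meta = metadata.loc[table.index]
    levels = sorted(meta["condition"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    ref = "control" if "control" in levels else levels[0]
    alt = [x for x in levels if x != ref][0]
    g_ref = table[meta["condition"] == ref]
    g_alt = table[meta["condition"] == alt]
    if len(g_ref) < 2 or len(g_alt) < 2:
        raise ValueError("need at least two samples per condition group")
    rows = []
    for ctype in table.columns:
        a = g_alt[ctype].to_numpy()
        r = g_ref[ctype].to_numpy()
        if np.ptp(a) == 0 and np.ptp(r) == 0 and a.mean() == r.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, r, equal_var=False)
        rows.append(
            {
                "cell_type": ctype,
                f"mean_{ref}": r.mean(),
                f"sem_{ref}": r.std(ddof=1) / np.sqrt(len(r)),
                f"mean_{alt}": a.mean(),
                f"sem_{alt}": a.std(ddof=1) / np.sqrt(len(a)),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
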