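"""Shared data containers for the bulk / single-cell integration pipeline.

The containers are thin, validated wrappers around pandas / numpy objects:

* :class:`GeneCountMatrix` — bulk counts (genes x samples) plus per-sample
  metadata (condition, sex, batch).
* :class:`CellTypeProfiles` — per-cell-type mean expression (genes x types),
  the pseudobulk profiles computed from a labeled single-cell reference.
* :class:`PEMMatrix` — preferential expression measure, log10 of observed /
  expected expression per gene per cell type.
* :class:`SignatureMatrix` — marker-gene signature for deconvolution.
* :class:`FractionTable` — estimated cell-type fractions per bulk sample.
* :class:`ExpressionVolume` — voxelized, region-annotated expression volume
  (an in-silico stand-in for developing-brain ISH energy data).
* :class:`GroundTruth` — the simulator's bookkeeping of planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountMatrix",
    "CellTypeProfiles",
    "PEMMatrix",
    "SignatureMatrix",
    "FractionTable",
    "ExpressionVolume",
    "GroundTruth",
]


class GeneCountMatrix:
    """Non-negative integer bulk count matrix with sample metadata.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers; the index holds
        gene identifiers, the columns sample identifiers.
    metadata
        One row per sample (indexed by sample id) with at least the columns
        ``condition`` (exactly two levels), ``sex`` and ``batch``.
    """

    REQUIRED_COLUMNS = ("condition", "sex", "batch")

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        metadata = metadata.copy()
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)

        missing = set(counts.columns) - set(metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
        for col in self.REQUIRED_COLUMNS:
            if col not in metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        metadata = metadata.loc[list(counts.columns)]
        levels = sorted(metadata["condition"].unique())
        if len(levels) != 2:
            raise ValueError(
                f"condition must have exactly two levels, got {levels}"
            )
        self.counts = counts
        self.metadata = metadata

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def condition_levels(self) -> tuple[str, str]:
        """(reference, treatment); 'control' is the reference if present."""
        levels = sorted(self.metadata["condition"].unique())
        if "control" in levels:
            other = [x for x in levels if x != "control"][0]
            return ("control", other)
        return (levels[0], levels[1])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneCountMatrix({self.counts.shape[0]} genes x "
            f"{self.counts.shape[1]} samples)"
        )


class CellTypeProfiles:
    """Per-cell-type mean expression profiles (genes x cell types).

    ``S`` holds the per-type totals (column sums of ``X``), the expression
    mass of each cell type; it is recomputed from ``X`` so the two can never
    disagree.
    """

    def __init__(self, X: pd.DataFrame, level: str = "class"):
        if (X.to_numpy() < 0).any():
            raise ValueError("profile matrix must be non-negative")
        if X.shape[1] < 2:
            raise ValueError("need at least two cell types")
        if X.columns.duplicated().any():
            raise ValueError("duplicate cell-type names")
        self.X = X.astype(float)
        self.level = level

    @property
    def S(self) -> pd.Series:
        return self.X.sum(axis=0)

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def cell_types(self) -> pd.Index:
        return self.X.columns


@dataclass
class PEMMatrix:
    """Preferential expression measure: log10(observed / expected) per type.

    For gene g and cell type i with type means ``X[g, i]`` and type totals
    ``S[i]``::

        pem[g, i] = log10( (sum(S) / S[i]) * (X[g, i] / sum_i X[g, i]) )

    A value of 0 means the gene's expression is allocated to type i exactly
    in proportion to that type's total expression mass; positive values mean
    preferential expression in that type.
    """

    pem: pd.DataFrame
    S: pd.Series
    pseudocount: float

    @property
    def cell_types(self) -> pd.Index:
        return self.pem.columns

    @property
    def genes(self) -> pd.Index:
        return self.pem.index


@dataclass
class SignatureMatrix:
    """Marker-gene signature for deconvolution, in counts-per-million units.

    ``data`` is genes x cell types; ``markers`` records which genes were
    selected for each type (top-k by PEM).
    """

    data: pd.DataFrame
    markers: dict[str, list[str]]
    k: int

    def __post_init__(self) -> None:
        if (self.data.to_numpy() == 0).all(axis=1).any():
            raise ValueError("signature contains all-zero gene rows")

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def genes(self) -> pd.Index:
        return self.data.index


class FractionTable:
    """Estimated cell-type fractions per sample (rows sum to one)."""

    def __init__(self, fractions: pd.DataFrame, residuals: pd.Series | None = None):
        values = fractions.to_numpy()
        if (values < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1 (tolerance 1e-9)")
        self.fractions = fractions.astype(float)
        if residuals is None:
            residuals = pd.Series(np.nan, index=fractions.index, name="residual")
        self.residuals = residuals.loc[fractions.index]

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index


class ExpressionVolume:
    """A voxel grid with one region label per voxel and per-gene energies.

    ``region_labels`` is a 3-D integer array indexing into ``region_names``;
    ``energy`` is a 4-D array of shape ``(n_genes,) + grid_shape`` with
    non-negative per-voxel expression energies. The section axis (default
    ``z``) runs lateral -> medial, so index 0 is the lateral-most sagittal
    plane.
    """

    AXES = ("x", "y", "z")

    def __init__(
        self,
        region_labels: np.ndarray,
        region_names: list[str],
        genes: list[str],
        energy: np.ndarray,
        section_axis: str = "z",
    ):
        region_labels = np.asarray(region_labels)
        energy = np.asarray(energy, dtype=float)
        if region_labels.ndim != 3:
            raise ValueError("region_labels must be a 3-D array")
        if energy.shape != (len(genes),) + region_labels.shape:
            raise ValueError(
                f"energy shape {energy.shape} does not match "
                f"(n_genes,)+grid {(len(genes),) + region_labels.shape}"
            )
        if (energy < 0).any():
            raise ValueError("energies must be non-negative")
        if region_labels.min() < 0 or region_labels.max() >= len(region_names):
            raise ValueError("region label out of range of region_names")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene names in volume panel")
        if section_axis not in self.AXES:
            raise ValueError(f"section_axis must be one of {self.AXES}")
        self.region_labels = region_labels
        self.region_names = list(region_names)
        self.genes = list(genes)
        self.energy = energy
        self.section_axis = section_axis
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.region_labels.shape

    def gene_energy(self, gene: str) -> np.ndarray:
        if gene not in self._gene_index:
            raise KeyError(f"gene {gene!r} not in volume panel")
        return self.energy[self._gene_index[gene]]

    def region_mask(self, region: str) -> np.ndarray:
        if region not in self.region_names:
            raise KeyError(f"unknown region {region!r}")
        return self.region_labels == self.region_names.index(region)

    # -- long-format interchange ----------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (voxel, gene) with its energy."""
        nx, ny, nz = self.grid_shape
        xs, ys, zs = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        voxels = pd.DataFrame(
            {
                "x": xs.ravel(),
                "y": ys.ravel(),
                "z": zs.ravel(),
                "region": np.asarray(self.region_names)[self.region_labels.ravel()],
            }
        )
        frames = []
        for i, gene in enumerate(self.genes):
            f = voxels.copy()
            f["gene"] = gene
            f["energy"] = self.energy[i].ravel()
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, section_axis: str = "z"
    ) -> "ExpressionVolume":
        required = {"x", "y", "z", "region", "gene", "energy"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"volume table missing columns: {sorted(missing)}")
        shape = tuple(int(frame[a].max()) + 1 for a in ("x", "y", "z"))
        genes = sorted(frame["gene"].unique().tolist())
        region_names = sorted(frame["region"].unique().tolist())
        labels = np.full(shape, -1, dtype=int)
        energy = np.zeros((len(genes),) + shape)
        gidx = {g: i for i, g in enumerate(genes)}
        ridx = {r: i for i, r in enumerate(region_names)}
        x = frame["x"].to_numpy(int)
        y = frame["y"].to_numpy(int)
        z = frame["z"].to_numpy(int)
        labels[x, y, z] = [ridx[r] for r in frame["region"]]
        energy[[gidx[g] for g in frame["gene"]], x, y, z] = frame[
            "energy"
        ].to_numpy(float)
        if (labels < 0).any():
            raise ValueError("volume table does not cover the full voxel grid")
        return cls(labels, region_names, genes, energy, section_axis=section_axis)


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping emitted alongside simulated data.

    ``true_fractions``: samples x cell types (rows sum to 1);
    ``de_table``: one row per planted DE gene (gene, log2fc, direction,
    home_types); ``marker_table``: gene -> home cell type for marker genes.
    """

    true_fractions: pd.DataFrame
    de_table: pd.DataFrame
    marker_table: pd.Series
    expected_means: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.allclose(self.true_fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true_fractions rows must sum to 1")
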