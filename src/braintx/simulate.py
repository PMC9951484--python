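"""Synthetic data generator for the integrative analysis pipeline.

Emulates the statistical structure of a prenatal-stress fetal-brain study:

* a labeled single-cell reference of the E15.5 mouse brain with 16 major
  cell classes dominated by neurons (~54%), neuroblasts (~24%) and
  glioblasts (~14%), with cell-type marker genes;
* a small two-batch, both-sexes bulk RNA-seq cohort (9 control vs 7
  stressed animals) whose expected expression is the cell-fraction-weighted
  mixture of the type profiles, with mild planted condition effects
  (|log2FC| ~ 0.5) acting through specific cell types, and a small
  condition shift in cell composition;
* a voxelized, region-annotated expression volume standing in for
  developing-brain ISH energy data, with gene sets homed to regions.

Counts are negative binomial with variance mu + mu^2 / dispersion.  All
three generators are bit-reproducible from ``(seed, config)``: each stage
draws from its own `numpy` SeedSequence substream, so e.g. regenerating the
volume never perturbs the bulk cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .containers import ExpressionVolume, GeneCountMatrix, GroundTruth

__all__ = [
    "DESpec",
    "SimulationConfig",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_BASE_FRACTIONS",
    "DEFAULT_REGIONS",
    "type_profiles",
    "marker_table",
    "planted_de_table",
    "simulate_reference",
    "simulate_bulk_cohort",
    "simulate_ish_volume",
]

# 16 major cell classes of the E15.5 mouse brain reference, dominated by
# neurons, neuroblasts and glioblasts (the three together ~92% of cells).
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "neuron",
    "neuroblast",
    "glioblast",
    "radial_glia",
    "mesenchyme",
    "vascular",
    "ependymal",
    "immune",
    "blood",
    "olfactory_ensheathing",
    "pericyte",
    "endothelial",
    "microglia",
    "cajal_retzius",
    "choroid_plexus",
    "neural_crest",
)

_DOMINANT = {"neuron": 0.5394, "neuroblast": 0.2423, "glioblast": 0.1375,
             "radial_glia": 0.021}


def _default_fractions(cell_types: tuple[str, ...]) -> np.ndarray:
    frac = np.zeros(len(cell_types))
    rest = [i for i, t in enumerate(cell_types) if t not in _DOMINANT]
    for i, t in enumerate(cell_types):
        if t in _DOMINANT:
            frac[i] = _DOMINANT[t]
    remaining = 1.0 - frac.sum()
    if rest:
        frac[rest] = remaining / len(rest)
    else:  # custom panel without the dominant names: uniform
        frac[:] = 1.0 / len(cell_types)
    return frac


DEFAULT_BASE_FRACTIONS = _default_fractions(DEFAULT_CELL_TYPES)

DEFAULT_REGIONS: tuple[str, ...] = (
    "cortical_plate",
    "hippocampal_formation",
    "dorsal_forebrain",
    "ventral_forebrain",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "hindbrain",
)


@dataclass(frozen=True)
class DESpec:
    """One planted differential-expression block.

    ``n_genes`` marker genes of ``cell_types`` receive a stress-vs-control
    effect of ``log2fc`` acting on the expression contributed by those home
    types only; with ``global_effect`` the fold change applies to the gene's
    whole bulk expression regardless of cell type.
    """

    name: str
    n_genes: int
    cell_types: tuple[str, ...]
    log2fc: float
    global_effect: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("de_spec n_genes must be >= 1")
        object.__setattr__(self, "cell_types", tuple(self.cell_types))


def _default_de_spec(config: "SimulationConfig") -> tuple[DESpec, ...]:
    """Mild, cell-type-specific planted signal: up-regulation through the
    stem-like radial glia, down-regulation through neurons.

    Block sizes keep the study's up:down imbalance (fewer up- than
    down-regulated genes) scaled to the configured gene universe, capped by
    the markers available per type.
    """
    n_markers = int(round(config.marker_frac * config.n_genes))
    per_type = n_markers // config.n_cell_types
    if per_type < 1 or not {"radial_glia", "neuron"} <= set(config.cell_types):
        return ()
    n_up = min(max(3, round(25 * config.n_genes / 2000)), per_type)
    n_down = min(max(3, round(35 * config.n_genes / 2000)), per_type)
    return (
        DESpec("up_radial_glia", n_up, ("radial_glia",), +0.5),
        DESpec("down_neuron", n_down, ("neuron",), -0.5),
    )


@dataclass
class SimulationConfig:
    """All knobs of the three generators, with study-like defaults.

    Defaults describe the emulated study: 2000 genes, 16 cell classes with
    neuron/neuroblast/glioblast-dominated composition, a 9-control vs
    7-stress two-batch cohort with both sexes, mild cell-type-specific
    planted DE (|log2FC| = 0.5) and a +3-percentage-point neuroblast /
    -3-point neuron composition shift under stress.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cell_types: int = 16
    cell_types: tuple[str, ...] | None = None
    n_cells_per_type: int = 100
    base_fractions: np.ndarray | None = None
    n_control: int = 9
    n_stress: int = 7
    sex_assignment: tuple[str, ...] | None = None
    batch_assignment: tuple[str, ...] | None = None
    marker_frac: float = 0.3
    marker_fold: float = 8.0
    de_spec: tuple[DESpec, ...] | None = None
    fraction_shift: dict[str, float] = field(
        default_factory=lambda: {"neuroblast": +0.03, "neuron": -0.03}
    )
    nb_dispersion: float = 20.0
    library_size_mean: float = 1e6
    library_size_cv: float = 0.1
    batch_effect_sd: float = 0.1
    sex_effect_sd: float = 0.1
    cell_depth_mean: float = 5000.0
    cell_depth_cv: float = 0.3
    # ISH-like volume
    grid_shape: tuple[int, int, int] = (12, 10, 8)
    region_names: tuple[str, ...] = DEFAULT_REGIONS
    region_sizes: tuple[int, ...] | None = None
    ish_panel_frac: float = 0.4
    ish_fold: float = 10.0
    ish_background: float = 1.0
    ish_noise_shape: float = 5.0
    ish_up_region: str = "cortical_plate"
    ish_down_region: str = "midbrain"

    def __post_init__(self) -> None:
        if self.cell_types is None:
            if self.n_cell_types == len(DEFAULT_CELL_TYPES):
                self.cell_types = DEFAULT_CELL_TYPES
            else:
                self.cell_types = tuple(
                    f"type_{i:02d}" for i in range(self.n_cell_types)
                )
        else:
            self.cell_types = tuple(self.cell_types)
            self.n_cell_types = len(self.cell_types)
        if self.base_fractions is None:
            self.base_fractions = _default_fractions(self.cell_types)
        self.base_fractions = np.asarray(self.base_fractions, dtype=float)
        if self.de_spec is None:
            self.de_spec = _default_de_spec(self)
        else:
            self.de_spec = tuple(
                s if isinstance(s, DESpec) else DESpec(**s) for s in self.de_spec
            )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least two cell types")
        if len(self.base_fractions) != self.n_cell_types:
            raise ValueError("base_fractions length != number of cell types")
        if (self.base_fractions < 0).any():
            raise ValueError("base_fractions must be non-negative")
        if not np.isclose(self.base_fractions.sum(), 1.0, atol=1e-8):
            raise ValueError("base_fractions must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name, v in (
            ("library_size_mean", self.library_size_mean),
            ("cell_depth_mean", self.cell_depth_mean),
            ("marker_fold", self.marker_fold),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.marker_frac <= 1.0:
            raise ValueError("marker_frac must lie in [0, 1]")
        known = set(self.cell_types)
        for spec in self.de_spec:
            unknown = set(spec.cell_types) - known
            if unknown:
                raise ValueError(
                    f"de_spec {spec.name!r} names unknown cell types: "
                    f"{sorted(unknown)}"
                )
        unknown = set(self.fraction_shift) - known
        if unknown:
            raise ValueError(f"fraction_shift names unknown cell types: {sorted(unknown)}")
        if len(self.region_names) < 2:
            raise ValueError("need at least two regions")
        for r in (self.ish_up_region, self.ish_down_region):
            if r not in self.region_names:
                raise ValueError(f"unknown home region {r!r}")
        if self.region_sizes is not None:
            if len(self.region_sizes) != len(self.region_names):
                raise ValueError("region_sizes length != region_names length")
            if sum(self.region_sizes) > self.grid_shape[0]:
                raise ValueError(
                    "region_sizes request more voxel slabs than the grid has "
                    f"({sum(self.region_sizes)} > {self.grid_shape[0]})"
                )
        if len(self.region_names) > self.grid_shape[0]:
            raise ValueError("more regions than x-planes in the grid")

    # -- config-file round trip -----------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build from a plain mapping (YAML/JSON); unknown keys rejected."""
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("cell_types", "sex_assignment", "batch_assignment",
                    "grid_shape", "region_names", "region_sizes"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        if data.get("de_spec") is not None:
            data["de_spec"] = tuple(
                DESpec(**d) if isinstance(d, dict) else d for d in data["de_spec"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(data)

    # -- derived structure ------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata for the bulk cohort.

        Default assignment alternates sexes within each condition (starting
        M for controls, F for stress — giving the study's 5M/4F and 3M/4F
        split at the default group sizes) and blocks batches in pairs so sex
        and batch are not confounded.
        """
        n = self.n_control + self.n_stress
        condition = ["control"] * self.n_control + ["stress"] * self.n_stress
        if self.sex_assignment is not None:
            if len(self.sex_assignment) != n:
                raise ValueError("sex_assignment length != number of samples")
            sex = list(self.sex_assignment)
        else:
            sex = [("M", "F")[i % 2] for i in range(self.n_control)]
            sex += [("F", "M")[i % 2] for i in range(self.n_stress)]
        if self.batch_assignment is not None:
            if len(self.batch_assignment) != n:
                raise ValueError("batch_assignment length != number of samples")
            batch = list(self.batch_assignment)
        else:
            batch = [f"b{(i // 2) % 2 + 1}" for i in range(self.n_control)]
            batch += [f"b{(i // 2) % 2 + 1}" for i in range(self.n_stress)]
        sample_ids = [f"S{i + 1:02d}" for i in range(n)]
        return pd.DataFrame(
            {"condition": condition, "sex": sex, "batch": batch},
            index=pd.Index(sample_ids, name="sample_id"),
        )


# ---------------------------------------------------------------------------
# deterministic substreams: one per generator stage
_STREAMS = {
    "baseline": 0,
    "markers": 1,
    "reference": 2,
    "de_genes": 3,
    "bulk": 4,
    "volume": 5,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS[stage]])
    )


def marker_table(config: SimulationConfig) -> pd.Series:
    """gene -> home cell type for the marker genes (others absent)."""
    rng = _rng(config, "markers")
    n_markers = int(round(config.marker_frac * config.n_genes))
    genes = np.asarray(config.gene_names)
    idx = np.sort(rng.choice(config.n_genes, size=n_markers, replace=False))
    types = np.asarray(config.cell_types)[
        np.arange(n_markers) % config.n_cell_types
    ]
    # shuffle the type assignment so marker identity is not ordered by index
    rng.shuffle(types)
    return pd.Series(types, index=genes[idx], name="marker_type")


def type_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Relative expression profiles, genes x cell types; columns sum to 1.

    All types share a heavy-tailed baseline; each marker gene's mean is
    multiplied by ``marker_fold`` in its home type.
    """
    rng = _rng(config, "baseline")
    baseline = rng.lognormal(mean=1.0, sigma=1.2, size=config.n_genes)
    P = np.tile(baseline[:, None], (1, config.n_cell_types)).astype(float)
    markers = marker_table(config)
    type_index = {t: j for j, t in enumerate(config.cell_types)}
    gene_index = {g: i for i, g in enumerate(config.gene_names)}
    for gene, home in markers.items():
        P[gene_index[gene], type_index[home]] *= config.marker_fold
    P /= P.sum(axis=0, keepdims=True)
    return pd.DataFrame(P, index=config.gene_names, columns=list(config.cell_types))


def planted_de_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministically choose the planted DE genes for this config.

    Cell-type-specific blocks draw from the markers of their home types;
    global blocks draw from non-marker genes.  Shared between the bulk and
    volume generators so spatial homing stays consistent with planted DE.
    """
    rng = _rng(config, "de_genes")
    markers = marker_table(config)
    rows = []
    used: set[str] = set()
    for spec in config.de_spec:
        if spec.global_effect:
            pool = [g for g in config.gene_names
                    if g not in markers.index and g not in used]
        else:
            pool = [g for g in markers.index
                    if markers[g] in spec.cell_types and g not in used]
        if len(pool) < spec.n_genes:
            raise ValueError(
                f"de_spec {spec.name!r} requests {spec.n_genes} genes but only "
                f"{len(pool)} are available in its pool"
            )
        chosen = rng.choice(np.asarray(pool), size=spec.n_genes, replace=False)
        for g in sorted(chosen):
            rows.append(
                {
                    "gene": g,
                    "log2fc": spec.log2fc,
                    "direction": "up" if spec.log2fc > 0 else "down",
                    "home_types": ",".join(spec.cell_types)
                    if not spec.global_effect
                    else "*",
                    "block": spec.name,
                }
            )
            used.add(g)
    return pd.DataFrame(rows, columns=["gene", "log2fc", "direction",
                                       "home_types", "block"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """NB with variance mean + mean^2 / dispersion (size = dispersion)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + np.maximum(mean, 1e-300))
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(dispersion, p[pos])
    return out


def simulate_reference(config: SimulationConfig) -> ad.AnnData:
    """Simulate a labeled single-cell reference (cells x genes counts).

    Returns an AnnData with integer counts, per-cell ``class`` and
    ``subclass`` labels in ``.obs``, marker assignments in
    ``.var['marker_type']`` and the generating relative profiles in
    ``.varm['type_profiles']`` (genes x types, column-normalized).
    """
    if config.n_cells_per_type < 1:
        raise ValueError("n_cells_per_type must be >= 1")
    rng = _rng(config, "reference")
    P = type_profiles(config)
    n_types = config.n_cell_types
    n_cells = n_types * config.n_cells_per_type
    sigma = np.sqrt(np.log1p(config.cell_depth_cv**2))
    mu_log = np.log(config.cell_depth_mean) - sigma**2 / 2
    depths = rng.lognormal(mean=mu_log, sigma=sigma, size=n_cells)

    counts = np.zeros((n_cells, config.n_genes), dtype=np.int64)
    classes = np.empty(n_cells, dtype=object)
    for j, ctype in enumerate(config.cell_types):
        sl = slice(j * config.n_cells_per_type, (j + 1) * config.n_cells_per_type)
        mu = np.outer(depths[sl], P.iloc[:, j].to_numpy())
        counts[sl] = _nb_draw(rng, mu, config.nb_dispersion)
        classes[sl] = ctype

    obs = pd.DataFrame(
        {
            "class": classes,
            # two subclasses per class; profiles are shared, the split only
            # exercises the finer label granularity downstream
            "subclass": [
                f"{c}_{'ab'[i % 2]}" for i, c in enumerate(classes)
            ],
        },
        index=pd.Index(
            [f"cell_{i:05d}" for i in range(n_cells)], name="cell_id"
        ),
    )
    var = pd.DataFrame(index=pd.Index(config.gene_names, name="gene"))
    markers = marker_table(config)
    var["marker_type"] = markers.reindex(var.index)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.varm["type_profiles"] = P.to_numpy()
    adata.uns["cell_types"] = list(config.cell_types)
    adata.uns["nb_dispersion"] = float(config.nb_dispersion)
    return adata


def _shifted_fractions(config: SimulationConfig) -> np.ndarray:
    frac = config.base_fractions.copy()
    for t, delta in config.fraction_shift.items():
        frac[list(config.cell_types).index(t)] += delta
    frac = np.clip(frac, 0.0, None)
    return frac / frac.sum()


def simulate_bulk_cohort(
    config: SimulationConfig, reference: ad.AnnData
) -> tuple[GeneCountMatrix, GroundTruth]:
    """Simulate the bulk cohort as a mixture of the reference type profiles.

    Each sample's expected expression is the fraction-weighted sum of the
    cell-type profiles, times gene-wise log-normal batch and sex nuisance
    multipliers, times the planted condition fold change applied to each DE
    gene's home-type contribution; counts are NB around the expectation
    scaled to the sample's library size.
    """
    cell_types = list(reference.uns["cell_types"])
    missing = set(config.cell_types) - set(cell_types)
    if missing:
        raise ValueError(f"reference lacks cell types: {sorted(missing)}")
    P = pd.DataFrame(
        reference.varm["type_profiles"],
        index=reference.var_names,
        columns=cell_types,
    )[list(config.cell_types)]
    genes = P.index
    meta = config.sample_table()
    rng = _rng(config, "bulk")

    base = config.base_fractions
    shifted = _shifted_fractions(config)
    fractions = pd.DataFrame(
        [base if c == "control" else shifted for c in meta["condition"]],
        index=meta.index,
        columns=list(config.cell_types),
    )

    # gene-wise nuisance multipliers, independent of condition
    batches = sorted(meta["batch"].unique())
    sexes = sorted(meta["sex"].unique())
    batch_eff = pd.DataFrame(
        rng.normal(0.0, config.batch_effect_sd, size=(len(genes), len(batches))),
        index=genes, columns=batches,
    )
    sex_eff = pd.DataFrame(
        rng.normal(0.0, config.sex_effect_sd, size=(len(genes), len(sexes))),
        index=genes, columns=sexes,
    )

    de_table = planted_de_table(config)
    Pv = P.to_numpy()
    type_idx = {t: j for j, t in enumerate(config.cell_types)}
    gene_idx = {g: i for i, g in enumerate(genes)}

    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    mu_log = np.log(config.library_size_mean) - sigma**2 / 2
    lib_sizes = rng.lognormal(mean=mu_log, sigma=sigma, size=len(meta))

    expected = np.zeros((len(genes), len(meta)))
    counts = np.zeros((len(genes), len(meta)), dtype=np.int64)
    for s, (sample, row) in enumerate(meta.iterrows()):
        f = fractions.loc[sample].to_numpy()
        mix = Pv @ f
        if row["condition"] == "stress" and len(de_table):
            for _, de in de_table.iterrows():
                g = gene_idx[de["gene"]]
                factor = 2.0 ** de["log2fc"]
                if de["home_types"] == "*":
                    mix[g] *= factor
                else:
                    home = [type_idx[t] for t in de["home_types"].split(",")]
                    home_mass = float(Pv[g, home] @ f[home])
                    mix[g] = (mix[g] - home_mass) + factor * home_mass
        mix = mix * np.exp(
            batch_eff[row["batch"]].to_numpy() + sex_eff[row["sex"]].to_numpy()
        )
        mean = mix / mix.sum() * lib_sizes[s]
        expected[:, s] = mean
        counts[:, s] = _nb_draw(rng, mean, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    gcm = GeneCountMatrix(counts_df, meta)
    truth = GroundTruth(
        true_fractions=fractions,
        de_table=de_table,
        marker_table=marker_table(config),
        expected_means=pd.DataFrame(expected, index=genes, columns=meta.index),
    )
    return gcm, truth


def _region_grid(config: SimulationConfig) -> np.ndarray:
    """Partition the grid into contiguous x-slabs, one per region."""
    nx = config.grid_shape[0]
    n_regions = len(config.region_names)
    if config.region_sizes is not None:
        sizes = list(config.region_sizes)
        sizes[-1] += nx - sum(sizes)  # pad the last slab to fill the grid
    else:
        base, extra = divmod(nx, n_regions)
        sizes = [base + (1 if i < extra else 0) for i in range(n_regions)]
    labels = np.zeros(config.grid_shape, dtype=int)
    x0 = 0
    for r, width in enumerate(sizes):
        labels[x0 : x0 + width] = r
        x0 += width
    return labels


def simulate_ish_volume(config: SimulationConfig) -> ExpressionVolume:
    """Simulate a region-annotated expression volume (ISH-energy-like).

    Every panel gene has one home region where its mean energy is elevated
    ``ish_fold``-fold over the ``ish_background`` level; planted up-DE genes
    are homed to ``ish_up_region`` and down-DE genes to ``ish_down_region``,
    mirroring region-specific expression of condition-responsive gene sets.
    Energies are gamma-distributed around the regional mean (shape
    ``ish_noise_shape``; 0 disables noise).
    """
    rng = _rng(config, "volume")
    labels = _region_grid(config)

    de_table = planted_de_table(config)
    de_genes = list(de_table["gene"])
    n_panel = max(int(round(config.ish_panel_frac * config.n_genes)), len(de_genes))
    pool = [g for g in config.gene_names if g not in set(de_genes)]
    n_extra = n_panel - len(de_genes)
    extra = rng.choice(np.asarray(pool), size=n_extra, replace=False)
    panel = sorted(de_genes + list(extra))

    region_index = {r: i for i, r in enumerate(config.region_names)}
    home = pd.Series(
        rng.integers(0, len(config.region_names), size=len(panel)),
        index=panel,
    )
    for _, de in de_table.iterrows():
        target = config.ish_up_region if de["direction"] == "up" else config.ish_down_region
        home[de["gene"]] = region_index[target]

    energy = np.empty((len(panel),) + config.grid_shape)
    for i, gene in enumerate(panel):
        mean = np.full(config.grid_shape, config.ish_background)
        mean[labels == home[gene]] *= config.ish_fold
        if config.ish_noise_shape > 0:
            energy[i] = rng.gamma(
                config.ish_noise_shape, mean / config.ish_noise_shape
            )
        else:
            energy[i] = mean
    return ExpressionVolume(
        labels, list(config.region_names), panel, energy, section_axis="z"
    )
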