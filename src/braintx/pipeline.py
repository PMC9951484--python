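"""End-to-end orchestration: simulate -> DE -> enrichment -> deconvolution
-> brain-region mapping, with a run manifest.

Every stage writes its outputs as plain-text files in the run directory;
the manifest (JSON) records the tool version, a hash of the configuration,
sha256 checksums of every output, timestamps and warnings.  A rerun with
the same configuration and seed reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from .brainmap import module_spatial_score, region_contrast, region_summary
from .containers import GeneCountMatrix
from .deconvolution import FractionDeconvolution, build_signature
from .diffexpr import DifferentialExpression
from .enrichment import CellTypeEnrichment, compute_pem, pseudobulk_means
from .simulate import (
    SimulationConfig,
    simulate_bulk_cohort,
    simulate_ish_volume,
    simulate_reference,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "enrich", "deconv", "brainmap")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig | dict = field(default_factory=dict)
    alpha: float = 0.05
    de_min_mean: float = 1.0
    enrich_level: str = "class"
    enrich_alternative: str = "two-sided"
    enrich_min_genes: int = 10
    pem_pseudocount: float = 1e-3
    signature_k: int = 50
    deg_gmt: Path | None = None  # precomputed gene sets for enrich-only runs
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            sim["seed"] = int(sim.get("seed", self.seed))
            self.simulation = SimulationConfig.from_dict(sim)
        if self.deg_gmt is not None:
            self.deg_gmt = Path(self.deg_gmt)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data.update(overrides)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        def canon(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: canon(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: canon(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, Path):
                return str(obj)
            return obj

        payload = canon(self)
        payload.pop("out_dir", None)  # where outputs land is not semantic
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _ManifestWarnings(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``out_dir/manifest.json``); on a
    stage failure the manifest is still written, with the failing stage and
    message recorded, and the exception re-raised.
    """
    from . import __version__

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    capture = _ManifestWarnings()
    logging.getLogger("braintx").addHandler(capture)
    manifest: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
        "warnings": [],
        "status": "running",
    }

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {"outputs": sorted(str(p) for p in files.values())}
        for name, p in files.items():
            manifest["outputs"][name] = {
                "path": str(p),
                "sha256": _sha256(p),
            }

    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            _run_stage(stage, config, state, out, record)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = state.get("current_stage")
        manifest["error"] = str(exc)
        raise
    finally:
        manifest["warnings"] = capture.messages
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        logging.getLogger("braintx").removeHandler(capture)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _require(state: dict, key: str, stage: str, hint: str):
    if key not in state:
        raise ValueError(
            f"stage {stage!r} needs {key!r}; enable {hint} or provide the "
            f"corresponding input files"
        )
    return state[key]


def _run_stage(stage, config: PipelineConfig, state, out: Path, record):
    state["current_stage"] = stage
    sim = config.simulation
    if stage == "simulate":
        reference = simulate_reference(sim)
        bulk, truth = simulate_bulk_cohort(sim, reference)
        volume = simulate_ish_volume(sim)
        state.update(reference=reference, bulk=bulk, truth=truth, volume=volume)

        ref_counts = pd.DataFrame(
            reference.X, index=reference.obs_names, columns=reference.var_names
        )
        files = {
            "reference_counts": out / "reference_counts.tsv",
            "reference_labels": out / "reference_labels.tsv",
            "bulk_counts": out / "bulk_counts.tsv",
            "bulk_metadata": out / "bulk_metadata.tsv",
            "true_fractions": out / "true_fractions.tsv",
            "true_de_genes": out / "true_de_genes.tsv",
            "volume": out / "volume.tsv",
        }
        btio.write_counts(ref_counts, files["reference_counts"])
        btio.write_labels(reference.obs[["class", "subclass"]],
                          files["reference_labels"])
        btio.write_counts(bulk.counts, files["bulk_counts"])
        btio.write_metadata(bulk.metadata, files["bulk_metadata"])
        tf = truth.true_fractions.copy()
        tf.index.name = "sample_id"
        tf.to_csv(files["true_fractions"], sep="\t")
        truth.de_table.to_csv(files["true_de_genes"], sep="\t", index=False)
        btio.write_volume(state["volume"], files["volume"])
        record(stage, files)

    elif stage == "de":
        bulk = _require(state, "bulk", stage, "the simulate stage")
        results = DifferentialExpression(
            bulk, min_mean=config.de_min_mean
        ).fit(alpha=config.alpha)
        state["de"] = results
        files = {"deg_table": out / "deg_table.tsv",
                 "deg_sets": out / "deg_sets.gmt"}
        results.to_tsv(files["deg_table"])
        btio.write_gmt(results.gene_sets(), files["deg_sets"])
        record(stage, files)

    elif stage == "enrich":
        reference = _require(state, "reference", stage, "the simulate stage")
        if "de" in state:
            sets = state["de"].gene_sets()
        elif config.deg_gmt is not None:
            sets = btio.read_gmt(config.deg_gmt)
        else:
            raise ValueError(
                "enrich stage needs DE results or a precomputed GMT "
                "(deg_gmt) with 'up', 'down' and 'background' sets"
            )
        state["deg_sets"] = sets
        profiles = pseudobulk_means(reference, level=config.enrich_level)
        pem = compute_pem(profiles, pseudocount=config.pem_pseudocount)
        state.update(profiles=profiles, pem=pem)
        files = {"pem_matrix": out / "pem_matrix.tsv"}
        pem_out = pem.pem.copy()
        pem_out.index.name = "gene"
        pem_out.to_csv(files["pem_matrix"], sep="\t")
        for direction in ("up", "down"):
            if len(sets.get(direction, [])) < config.enrich_min_genes:
                logger.warning(
                    "%s DEG set too small (%d genes); enrichment skipped",
                    direction, len(sets.get(direction, [])),
                )
                continue
            res = CellTypeEnrichment(
                pem, sets[direction], sets["background"],
                alternative=config.enrich_alternative,
                min_genes=config.enrich_min_genes,
            ).fit()
            state[f"enrichment_{direction}"] = res
            files[f"enrichment_{direction}"] = out / f"enrichment_{direction}.tsv"
            res.to_tsv(files[f"enrichment_{direction}"])
        record(stage, files)

    elif stage == "deconv":
        bulk = _require(state, "bulk", stage, "the simulate stage")
        if "pem" not in state:
            reference = _require(state, "reference", stage, "the simulate stage")
            profiles = pseudobulk_means(reference, level=config.enrich_level)
            state["profiles"] = profiles
            state["pem"] = compute_pem(profiles,
                                       pseudocount=config.pem_pseudocount)
        signature = build_signature(
            state["profiles"], state["pem"], k=config.signature_k
        )
        results = FractionDeconvolution(bulk, signature).fit()
        state["fractions"] = results
        files = {"fractions": out / "fractions.tsv",
                 "fraction_comparison": out / "fraction_comparison.tsv"}
        results.to_tsv(files["fractions"])
        results.compare().to_csv(files["fraction_comparison"], sep="\t")
        record(stage, files)

    elif stage == "brainmap":
        volume = _require(state, "volume", stage, "the simulate stage")
        sets = state.get("deg_sets")
        if sets is None and "de" in state:
            sets = state["de"].gene_sets()
        if sets is None:
            raise ValueError("brainmap stage needs DEG sets (run de/enrich)")
        files = {}
        maps = {}
        for direction in ("up", "down"):
            genes = sets.get(direction, [])
            if not genes:
                logger.warning("%s module empty; spatial map skipped", direction)
                continue
            smap = module_spatial_score(volume, genes, name=direction)
            maps[direction] = smap
            files[f"region_summary_{direction}"] = (
                out / f"region_summary_{direction}.tsv"
            )
            region_summary(smap, volume).to_csv(
                files[f"region_summary_{direction}"], sep="\t"
            )
        if "up" in maps and "down" in maps:
            files["region_contrast"] = out / "region_contrast.tsv"
            region_contrast(maps["up"], maps["down"], volume).to_csv(
                files["region_contrast"], sep="\t"
            )
        state["spatial_maps"] = maps
        record(stage, files)
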