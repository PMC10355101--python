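"""End-to-end orchestration: simulate/load -> pG4 calling -> annotation ->
differential testing -> enrichment report.

A run is driven by one :class:`PipelineConfig`, built in code or from a
YAML file with sections ``simulate`` (or ``inputs``), ``g4hunter``,
``annotation`` and ``differential``.  Given a seed the run is fully
deterministic: every output file is byte-identical across repeats, and a
manifest records the config hash, seed and a content hash per output
(the timing log is excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .annotation import AnnotationParams, annotate_peaks, build_promoters, \
    feature_distribution, write_annotated
from .differential import run_differential, write_results
from .enrichment import EnrichmentReport, enrichment_report, round_sig, \
    write_per_dar_counts
from .g4hunter import G4HunterParams, call_pg4, write_pg4_bed, write_pg4_scores
from .genome import GenomeSequence
from .io import load_counts, read_bed, read_gtf_genes
from .simulate import SimConfig, config_from_dict, simulate_dataset

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("genome", "genes", "peaks", "counts", "samples")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One serialisable source of truth for a pipeline run."""

    output_dir: Path = Path("g4access_out")
    seed: int = 0
    log_level: str = "INFO"
    sim: Optional[SimConfig] = None
    inputs: Optional[Dict[str, str]] = None
    g4: G4HunterParams = field(default_factory=G4HunterParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    dar_fdr: float = 0.1
    deg_fdr: float = 0.05
    deg_lfc: float = 2.0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if (self.sim is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation block and real input paths "
                "must be configured")
        if self.inputs is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
        if min(self.dar_fdr, self.deg_fdr) <= 0 or self.deg_lfc < 0:
            raise ValueError("differential thresholds must be positive")
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # ------------------------------------------------------------- loading

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: Dict = {}
        for key in ("output_dir", "seed", "log_level",
                    "dar_fdr", "deg_fdr", "deg_lfc"):
            if key in raw:
                kwargs[key] = raw[key]
        diff = raw.get("differential", {})
        for key in ("dar_fdr", "deg_fdr", "deg_lfc"):
            if key in diff:
                kwargs[key] = diff[key]
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", kwargs.get("seed", 0))
            kwargs["sim"] = config_from_dict(sim)
        if "inputs" in raw:
            kwargs["inputs"] = dict(raw["inputs"])
        if "g4hunter" in raw:
            kwargs["g4"] = G4HunterParams(**raw["g4hunter"])
        if "annotation" in raw:
            kwargs["annotation"] = AnnotationParams(**raw["annotation"])
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_canonical_dict(self) -> Dict:
        d = {
            "output_dir": str(self.output_dir), "seed": self.seed,
            "log_level": self.log_level,
            "dar_fdr": self.dar_fdr, "deg_fdr": self.deg_fdr,
            "deg_lfc": self.deg_lfc,
            "g4hunter": dataclasses.asdict(self.g4),
            "annotation": dataclasses.asdict(self.annotation),
        }
        if self.sim is not None:
            d["simulate"] = dataclasses.asdict(self.sim)
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _mark_partial(paths: List[Path]) -> None:
    for p in paths:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".partial"))


def run_pipeline(config: PipelineConfig) -> EnrichmentReport:
    """Execute the full chain and write all outputs.

    Writes (under ``config.output_dir``): the simulated dataset (in
    simulate mode), ``pg4.bed`` / ``pg4_scores.tsv``, ``annotated.tsv``,
    ``feature_distribution.tsv``, ``dar_results.tsv``, ``report.json``,
    ``per_dar_pg4_counts.tsv`` and ``manifest.json``.  On stage failure a
    :class:`StageError` is raised and files from the failing stage keep a
    ``.partial`` suffix.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("g4access")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    written: List[Path] = []
    stage = "setup"
    try:
        # ---------------------------------------------------------- inputs
        stage = "inputs"
        stage_paths: List[Path] = []
        if config.sim is not None:
            logger.info("simulating dataset (seed %d)", config.sim.seed)
            sim_paths = simulate_dataset(config.sim, out)
            stage_paths = list(sim_paths.values())
            genome_path, genes_path = sim_paths["genome"], sim_paths["genes"]
            peaks_path = sim_paths["peaks"]
            counts_path, samples_path = sim_paths["counts"], sim_paths["samples"]
        else:
            genome_path = Path(config.inputs["genome"])
            genes_path = Path(config.inputs["genes"])
            peaks_path = Path(config.inputs["peaks"])
            counts_path = Path(config.inputs["counts"])
            samples_path = Path(config.inputs["samples"])
        genome = GenomeSequence.from_fasta(genome_path)
        genes = read_gtf_genes(genes_path)
        peaks = read_bed(peaks_path)
        matrix = load_counts(counts_path, samples_path)
        written += stage_paths

        # -------------------------------------------------------- score-g4
        stage = "score-g4"
        stage_paths = [out / "pg4.bed", out / "pg4_scores.tsv"]
        pg4s = call_pg4(genome, config.g4)
        logger.info("%d pG4 regions called", len(pg4s))
        write_pg4_bed(pg4s, stage_paths[0])
        write_pg4_scores(pg4s, stage_paths[1])
        written += stage_paths

        # -------------------------------------------------------- annotate
        stage = "annotate"
        stage_paths = [out / "annotated.tsv", out / "feature_distribution.tsv"]
        promoters = build_promoters(
            genes, config.annotation,
            {name: genome.length(name) for name in genome})
        annotated = annotate_peaks(peaks, genes, config.annotation, promoters)
        write_annotated(annotated, stage_paths[0])
        dist = feature_distribution(annotated)
        with open(stage_paths[1], "w") as fh:
            fh.write("feature_class\tfraction\n")
            for cls, frac in dist.items():
                fh.write(f"{cls}\t{frac:.6f}\n")
        written += stage_paths

        # ------------------------------------------------------------ diff
        stage = "diff"
        stage_paths = [out / "dar_results.tsv"]
        results = run_differential(matrix, config.dar_fdr, config.deg_fdr,
                                   config.deg_lfc)
        n_dar = sum(r.is_significant_dar for r in results)
        logger.info("%d/%d regions significant at FDR < %g",
                    n_dar, len(results), config.dar_fdr)
        write_results(results, stage_paths[0], mode="dar")
        written += stage_paths

        # ---------------------------------------------------------- enrich
        stage = "enrich"
        stage_paths = [out / "report.json", out / "per_dar_pg4_counts.tsv"]
        report = enrichment_report(results, annotated, pg4s)
        report.to_json(stage_paths[0])
        write_per_dar_counts(report, stage_paths[1])
        logger.info(
            "%d/%d promoter DARs contain a pG4 (background %.3f): "
            "binomial P = %g",
            report.n_dars_with_pg4, report.n_dars, report.background_rate,
            round_sig(report.binomial_tail_p))
        written += stage_paths

        # -------------------------------------------------------- manifest
        stage = "manifest"
        manifest = {
            "g4access_version": __version__,
            "seed": config.seed,
            "config": config.to_canonical_dict(),
            "config_hash": config.config_hash(),
            "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        _mark_partial(stage_paths)
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
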