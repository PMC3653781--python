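"""End-to-end pipeline: simulate -> normalize -> call peaks -> classify -> tabulate.

One master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(master).spawn``, so identical config + seed
yields byte-identical TSV outputs; every output file is digested into a run
manifest together with the full parameter snapshot and stage-level counts.
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
import yaml

from . import differential, simulate
from .arrayio import normalize, write_annotation, write_bed, write_profile
from .differential import ClassificationThresholds
from .peaks import PeakCallingParams, call_peaks, scan_windows, write_peaks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration mirroring every stage's defaults."""

    n_genes: int = 1000
    normalization: str = "biweight"
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    mixture: simulate.MixtureModel = field(default_factory=simulate.MixtureModel)
    peak_params: PeakCallingParams = field(default_factory=PeakCallingParams)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            n_genes=raw.get("n_genes", 1000),
            normalization=raw.get("normalization", "biweight"),
            simulation=simulate.SimulationConfig(**raw.get("simulation", {})),
            mixture=simulate.MixtureModel(**raw.get("mixture", {})),
            peak_params=PeakCallingParams(**raw.get("peak_params", {})),
            thresholds=ClassificationThresholds(**raw.get("thresholds", {})),
            seed=raw.get("seed", 0),
        )
        cfg.simulation.n_genes = cfg.n_genes
        return cfg

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "normalization": self.normalization,
            "simulation": dataclasses.asdict(self.simulation),
            "mixture": dataclasses.asdict(self.mixture),
            "peak_params": dataclasses.asdict(self.peak_params),
            "thresholds": dataclasses.asdict(self.thresholds),
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute the full chain; returns the run manifest (also written as JSON).

    Stage failures abort with the stage name prepended to the error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }
    sim_seed, mix_seed, _, _ = _stage_seeds(config.seed)
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.simulation, n_genes=config.n_genes,
                                      seed=sim_seed)
        mixture = dataclasses.replace(config.mixture, seed=mix_seed)
        annotation = simulate.generate_annotation(sim_cfg)
        truth = simulate.plant_truth(annotation, sim_cfg)
        nor, pv = simulate.simulate_arrays(annotation, truth, mixture, sim_cfg)
        write_annotation(annotation, out / "annotation.tsv")
        simulate.write_truth(truth, out / "truth.tsv")
        manifest["stages"][stage] = {
            "n_genes": int(config.n_genes),
            "n_probes": len(nor),
            "planted": truth["true_class"].value_counts().to_dict(),
        }
        logger.info("simulate: %d genes, %d probes", config.n_genes, len(nor))

        stage = "normalize"
        nor = normalize(nor, config.normalization)
        pv = normalize(pv, config.normalization)
        write_profile(nor, out / "profile_nor.tsv")
        write_profile(pv, out / "profile_pv.tsv")
        manifest["stages"][stage] = {"method": config.normalization}

        stage = "call_peaks"
        peaks = {}
        for label, prof in (("nor", nor), ("pv", pv)):
            ws = scan_windows(prof, config.peak_params)
            peaks[label] = call_peaks(ws, config.peak_params)
            write_peaks(peaks[label], out / f"peaks_{label}.tsv")
            write_bed(peaks[label].assign(
                name=[f"peak_{label}_{i}" for i in range(len(peaks[label]))]),
                out / f"peaks_{label}.bed", score_col="peakscore")
        manifest["stages"][stage] = {
            "n_peaks_nor": len(peaks["nor"]),
            "n_peaks_pv": len(peaks["pv"]),
            "params": dataclasses.asdict(config.peak_params),
        }
        logger.info("call_peaks: %d Nor peaks, %d PV peaks",
                    len(peaks["nor"]), len(peaks["pv"]))

        stage = "classify"
        scores = differential.assign_promoter_scores(
            peaks["nor"], peaks["pv"], annotation)
        calls = differential.classify_promoters(scores, config.thresholds)
        genes = differential.summarize_genes(calls)
        proportions, histogram = differential.tabulate(calls)
        differential.write_calls(calls, out / "promoter_calls.tsv")
        differential.write_calls(genes, out / "gene_calls.tsv", float_cols=())
        proportions.to_csv(out / "class_proportions.tsv", sep="\t", index=False)
        histogram.to_csv(out / "peakscore_histogram.tsv", sep="\t", index=False)
        class_counts = calls["klass"].value_counts().to_dict()
        manifest["stages"][stage] = {
            "n_promoters": len(calls),
            "n_scored": int(proportions["n_scored"].iloc[0]),
            "promoter_classes": {k: int(v) for k, v in class_counts.items()},
            "gene_classes": {k: int(v) for k, v in
                             genes["klass"].value_counts().to_dict().items()},
        }
        logger.info("classify: %s", class_counts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
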