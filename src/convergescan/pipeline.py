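"""End-to-end orchestration: filter -> average -> RER -> scan -> reports.

A :class:`RunConfig` (typically loaded from YAML) names the inputs and the
analysis parameters; :func:`run_all` executes the stages, writes TSV/newick
outputs plus a machine-readable manifest, and is byte-deterministic given
the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrich import enrich_gene_sets, read_gene_sets
from .rer import FilterCriteria, RateMatrix, compute_rer, estimate_average_tree, filter_trees
from .scan import ConvergentRateScan, ForegroundSpec
from .simulate import SimulationConfig, simulate_element_trees, write_truth
from .trees import read_element_trees, read_master_tree, write_element_trees

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs and parameters for a full scan run.

    Either ``trees``/``master``/``foreground`` paths are given, or a
    ``simulate`` block generates the batch.  Defaults follow the published
    settings: FDR 0.15, direction threshold 0.5, 10,000 permutations,
    filters (10 species / 2 foreground / 80% zero-length).
    """

    out_dir: str = "results"
    master: str | None = None
    trees: str | None = None
    foreground: str | None = None  # one taxon per line
    gene_sets: str | None = None
    simulate: dict | None = None
    min_species: int = 10
    min_foreground: int = 2
    zero_fraction: float = 0.80
    scale: bool = False
    n_perm: int = 10000
    fdr: float = 0.15
    direction_threshold: float = 0.5
    permute: str = "dataset"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for key in ("master", "trees", "foreground"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"config requires {key!r} (or a simulate block)")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{key} file not found: {value}")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise FileNotFoundError(f"gene_sets file not found: {self.gene_sets}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
            stage = "simulate"
            sim = simulate_element_trees(sim_cfg)
            master = sim.master
            trees = sim.trees
            foreground = list(sim.foreground)
            write_element_trees(trees, master, out / "trees.tsv")
            write_truth(sim, out / "truth.tsv")
            (out / "master.nwk").write_text(master.to_newick() + "\n")
            (out / "foreground.txt").write_text("\n".join(foreground) + "\n")
            batch_rejections = []
        else:
            master = read_master_tree(config.master)
            trees, batch_rejections = read_element_trees(config.trees, master)
            foreground = [
                line.strip()
                for line in Path(config.foreground).read_text().splitlines()
                if line.strip()
            ]

        stage = "filter"
        criteria = FilterCriteria(
            min_species=config.min_species,
            min_foreground=config.min_foreground,
            zero_fraction=config.zero_fraction,
        )
        retained, filter_log = filter_trees(trees, foreground, criteria)
        if not retained:
            raise ValueError("no trees survive filtering")
        rejections = [r.__dict__ for r in batch_rejections + filter_log]
        pd.DataFrame(rejections, columns=["element_id", "rule", "detail"]).to_csv(
            out / "rejections.tsv", sep="\t", index=False
        )

        stage = "average"
        matrix = RateMatrix.from_trees(retained, master)
        avg_master = estimate_average_tree(matrix)
        (out / "average_tree.nwk").write_text(avg_master.to_newick() + "\n")

        stage = "rer"
        rer = compute_rer(matrix, avg_master, scale=config.scale)
        rer.to_tsv(out / "rer.tsv", out / "rer.json")

        stage = "scan"
        model = ConvergentRateScan(
            rer,
            ForegroundSpec(species=frozenset(foreground)),
            direction_threshold=config.direction_threshold,
            fdr=config.fdr,
        )
        results = model.fit(
            n_perm=config.n_perm, seed=config.seed, permute=config.permute
        )
        results.to_tsv(out / "scan.tsv")
        (out / "summary.txt").write_text(results.summary() + "\n")

        if config.gene_sets is not None:
            stage = "enrich"
            sets = read_gene_sets(config.gene_sets)
            hits = list(results.accelerated.index)
            frame = enrich_gene_sets(hits, list(results.frame.index), sets)
            frame.to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_species": config.min_species,
            "min_foreground": config.min_foreground,
            "zero_fraction": config.zero_fraction,
            "scale": config.scale,
            "n_perm": config.n_perm,
            "fdr": config.fdr,
            "direction_threshold": config.direction_threshold,
            "permute": config.permute,
        },
        "simulate": config.simulate,
        "inputs": {
            key: {"path": str(getattr(config, key)), "sha256": _sha256(Path(getattr(config, key)))}
            for key in ("master", "trees", "foreground", "gene_sets")
            if getattr(config, key) is not None
        },
        "n_elements_scored": int(len(results.frame)),
        "foreground": sorted(foreground),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
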