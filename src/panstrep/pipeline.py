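"""Configured pipeline: simulate -> stats -> pangenome -> rarefy -> ani -> tree.

A single YAML config file drives the run; every block mirrors the parameter
set of its module and is schema-checked (unknown keys rejected) before any
stage executes.  Stage outputs are written into a temporary area inside the
output directory and promoted atomically; a JSON manifest records the tool
version, a hash of the effective config, the global seed, and every output
path, so that identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .ani import AniParams, ani_matrix
from .homology import HomologyThresholds, ScoringScheme
from .pangenome import StrainGeneSet, build_pan_pool, partition_counts
from .phylo import neighbor_joining, presence_matrix, profile_distance, write_distance_tsv
from .rarefaction import fit_core_decay, fit_pan_growth, rarefy
from .simulate import SimulationParams, simulate_genome_fasta, simulate_pangenome, write_gff3
from .stats import feature_summary, FeatureSummary

logger = logging.getLogger("panstrep")

_KNOWN_TOP = {"simulate", "homology", "pangenome", "rarefaction", "ani", "tree", "seed", "log_level", "stages"}
_KNOWN_BLOCK_KEYS = {
    "simulate": {
        "n_strains", "n_core", "dispensable_spec", "n_specific_per_strain",
        "gene_length_range", "divergence", "paralog_rate", "alphabet", "write_genomes",
    },
    "homology": {"bcr_min", "identity_min", "min_len", "alphabet"},
    "pangenome": {"search_all_members", "prefilter"},
    "rarefaction": {"n_perm"},
    "ani": {"fragment_bp", "min_identity_pct", "min_coverage", "reciprocal"},
    "tree": {"metric", "midpoint_root"},
}

_STAGE_ORDER = ["simulate", "stats", "pangenome", "rarefy", "ani", "tree"]
_STAGE_DEPS = {
    "stats": ["simulate"],
    "pangenome": ["simulate"],
    "rarefy": ["pangenome"],
    "ani": ["simulate"],
    "tree": ["pangenome"],
}


@dataclass
class PipelineConfig:
    raw: dict
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(_STAGE_ORDER))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for block, keys in _KNOWN_BLOCK_KEYS.items():
            if block in raw and raw[block] is not None:
                bad = set(raw[block]) - keys
                if bad:
                    raise ValueError(f"unknown key(s) in '{block}' block: {sorted(bad)}")
        stages = raw.get("stages") or list(_STAGE_ORDER)
        bad_stages = set(stages) - set(_STAGE_ORDER)
        if bad_stages:
            raise ValueError(f"unknown stage(s): {sorted(bad_stages)}")
        cfg = cls(
            raw=raw,
            seed=int(raw.get("seed", 0)),
            stages=[s for s in _STAGE_ORDER if s in stages],
            log_level=str(raw.get("log_level", "INFO")),
        )
        cfg.simulation_params()  # validate eagerly
        return cfg

    def block(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    def simulation_params(self) -> SimulationParams:
        blk = self.block("simulate")
        blk.pop("write_genomes", None)
        if "dispensable_spec" in blk:
            blk["dispensable_spec"] = tuple(tuple(x) for x in blk["dispensable_spec"])
        if "gene_length_range" in blk:
            blk["gene_length_range"] = tuple(blk["gene_length_range"])
        return SimulationParams(seed=self.seed, **blk)

    def scoring(self) -> ScoringScheme:
        alphabet = self.block("homology").get("alphabet", self.block("simulate").get("alphabet", "nucleotide"))
        return ScoringScheme.protein() if alphabet == "protein" else ScoringScheme.nucleotide()

    def thresholds(self) -> HomologyThresholds:
        blk = self.block("homology")
        alphabet = blk.pop("alphabet", "nucleotide")
        base = HomologyThresholds.for_alphabet(alphabet)
        return HomologyThresholds(
            bcr_min=blk.get("bcr_min", base.bcr_min),
            identity_min=blk.get("identity_min", base.identity_min),
            min_len=blk.get("min_len", base.min_len),
        )

    def ani_params(self) -> AniParams:
        return AniParams(**self.block("ani"))

    def config_hash(self) -> str:
        payload = json.dumps({"config": self.raw, "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, outdir / "run.log")

    for stage in config.stages:
        for dep in _STAGE_DEPS.get(stage, []):
            if dep not in config.stages:
                raise ValueError(f"stage '{stage}' requires stage '{dep}' in the run")

    t0 = time.time()
    manifest: dict = {
        "tool": "panstrep",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        logger.info("stage %s: start", stage)
        tmp = outdir / f".tmp-{stage}"
        if tmp.exists():
            shutil.rmtree(tmp)
        tmp.mkdir(parents=True)
        outputs = _RUNNERS[stage](config, tmp, state)
        final_dir = outdir / stage
        if final_dir.exists():
            shutil.rmtree(final_dir)
        os.replace(tmp, final_dir)
        manifest["stages"][stage] = {
            "outputs": [str(final_dir / name) for name in outputs],
        }
        logger.info("stage %s: done (%d outputs)", stage, len(outputs))
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _setup_logging(level: str, logfile: Path) -> None:
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    logger.handlers = [logging.StreamHandler()]
    fh = logging.FileHandler(logfile, mode="w")
    logger.addHandler(fh)


def _run_simulate(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    params = config.simulation_params()
    strains, truth = simulate_pangenome(params)
    state["strains"], state["truth"] = strains, truth
    outputs = []
    for strain in strains:
        name = f"{strain.strain_id}.genes.fasta"
        strain.to_fasta(tmp / name)
        outputs.append(name)
    truth.write_tsv(tmp / "truth.tsv")
    outputs.append("truth.tsv")
    if config.block("simulate").get("write_genomes", True):
        state["genomes"] = {}
        state["gene_coords"] = {}
        for i, strain in enumerate(strains):
            genome, coords = simulate_genome_fasta(strain, seed=config.seed + 10_000 + i)
            state["genomes"][strain.strain_id] = genome
            state["gene_coords"][strain.strain_id] = coords
            gname = f"{strain.strain_id}.genome.fasta"
            with open(tmp / gname, "w") as fh:
                fh.write(f">{strain.strain_id}\n")
                for j in range(0, len(genome), 70):
                    fh.write(genome[j : j + 70] + "\n")
            write_gff3(coords, strain.strain_id, tmp / f"{strain.strain_id}.gff3")
            outputs += [gname, f"{strain.strain_id}.gff3"]
    return outputs


def _run_stats(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    genomes = state.get("genomes") or {}
    rows = []
    for strain_id, genome in genomes.items():
        coords = [(s, e) for _, s, e in state["gene_coords"][strain_id]]
        rows.append((strain_id, feature_summary(genome, coords)))
    with open(tmp / "feature_summary.tsv", "w") as fh:
        fh.write("strain_id\t" + FeatureSummary.tsv_header() + "\n")
        for strain_id, summary in rows:
            fh.write(strain_id + "\t" + summary.tsv_row() + "\n")
    return ["feature_summary.tsv"]


def _run_pangenome(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    blk = config.block("pangenome")
    result = build_pan_pool(
        state["strains"],
        thresholds=config.thresholds(),
        scoring=config.scoring(),
        search_all_members=blk.get("search_all_members", False),
        prefilter=blk.get("prefilter", True),
    )
    state["pangenome"] = result
    result.write_clusters_tsv(tmp / "clusters.tsv")
    result.write_summary_json(tmp / "partition.json")
    result.write_flower_tsv(tmp / "flower.tsv")
    return ["clusters.tsv", "partition.json", "flower.tsv"]


def _run_rarefy(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    result = state["pangenome"]
    n_perm = config.block("rarefaction").get("n_perm", 200)
    curve = rarefy(result, n_perm=n_perm, seed=config.seed)
    curve.write_tsv(tmp / "curve.tsv")
    fit_core_decay(curve).to_json(tmp / "core_fit.json")
    fit_pan_growth(curve).to_json(tmp / "pan_fit.json")
    return ["curve.tsv", "core_fit.json", "pan_fit.json"]


def _run_ani(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    genomes = state.get("genomes")
    if not genomes:
        raise ValueError("ani stage requires simulated genomes (simulate.write_genomes)")
    mat, results = ani_matrix(genomes, config.ani_params())
    mat.to_csv(tmp / "ani_matrix.tsv", sep="\t")
    for res in results:
        res.to_json(tmp / f"ani_{res.genome_a}_{res.genome_b}.json")
    state["ani_matrix"] = mat
    return ["ani_matrix.tsv"] + [f"ani_{r.genome_a}_{r.genome_b}.json" for r in results]


def _run_tree(config: PipelineConfig, tmp: Path, state: dict) -> List[str]:
    result = state["pangenome"]
    blk = config.block("tree")
    matrix = presence_matrix(result)
    d = profile_distance(matrix, metric=blk.get("metric", "jaccard"))
    tree = neighbor_joining(d)
    if blk.get("midpoint_root", False):
        tree = tree.midpoint_rooted()
    tree.write(tmp / "gene_family_tree.nwk")
    write_distance_tsv(d, tmp / "profile_distance.tsv")
    return ["gene_family_tree.nwk", "profile_distance.tsv"]


_RUNNERS = {
    "simulate": _run_simulate,
    "stats": _run_stats,
    "pangenome": _run_pangenome,
    "rarefy": _run_rarefy,
    "ani": _run_ani,
    "tree": _run_tree,
}
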