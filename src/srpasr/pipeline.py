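"""End-to-end pipeline: replicate ASR, consensus, composition, null, features.

A run is described by one declarative config (YAML on disk, or a plain dict);
inputs are either real files (alignment + tree + optional clusters) or a
synthetic scenario generated in-run.  All randomness flows from one master
seed, with fixed per-stage offsets, so a rerun with the same config and seed
is byte-identical; the run directory name is derived from the config hash and
seed rather than wall-clock time for the same reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import call_sequence, reconstruct, threshold_sweep
from .composition import (DEFAULT_CHRONOLOGY, composition_summary, count_residues,
                          depletion_test, pairwise_identity_stats)
from .errors import DomainError, SrpAsrError
from .evomodel import wag_model
from .protfeat import classify_localization, isoelectric_point, mean_hydropathy
from .resample import (ClusterSet, cluster_sequences, consensus, parse_cluster_file,
                       replicated_asr, write_cluster_file)
from .seqio import Alignment, read_fasta_alignment, read_newick, ungapped_length, write_fasta
from .simulate import (SimulationScenario, depleted_root_freqs,
                       null_reconstruction_distribution, overlay_gaps, simulate_alignment,
                       simulate_tree)
from .tree import PhyloTree
from .trim import TrimParams, gap_fraction, trim_alignment

logger = logging.getLogger("srpasr")

# fixed per-stage seed offsets (documented contract: results independent of
# execution order; all seeds stay below 2**31)
_OFF_CLUSTER = 101
_OFF_REPLICATES = 202
_OFF_NULL = 303
_OFF_SCENARIO = 404


@dataclass
class PipelineConfig:
    alignment: Optional[str] = None
    tree: Optional[str] = None
    clusters: str = "auto"          # path | "auto"
    soft_max: int = 5
    node: str = "root"
    thresholds: tuple[int, ...] = (10, 50, 90)
    n_replicates: int = 100
    n_sims: int = 100
    null_gap_threshold: int = 10
    late_aa: str = "CHFMYW"
    seed: int = 0
    out: str = "runs"
    scenario: Optional[dict] = None  # used when alignment/tree are absent
    log_level: str = "INFO"

    def __post_init__(self):
        self.thresholds = tuple(int(t) for t in self.thresholds)
        if any(not 1 <= t <= 99 for t in self.thresholds):
            raise DomainError(f"thresholds {self.thresholds} outside [1, 99]")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if self.alignment is None and self.scenario is None:
            self.scenario = {}
        for path_attr in ("alignment", "tree"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise DomainError(f"{path_attr} path {p!r} does not exist")
        if self.clusters != "auto" and not Path(self.clusters).exists():
            raise DomainError(f"clusters path {self.clusters!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except SrpAsrError as exc:
                raise SrpAsrError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis graph; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    model = wag_model()
    run_dir = Path(config.out) / f"run_{config.digest()}_seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.digest(),
                      "seed": config.seed, "version": __version__,
                      "outputs": []}

    def declare(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(run_dir)))
        return path

    # -- inputs -------------------------------------------------------------
    if config.alignment is not None:
        alignment = read_fasta_alignment(config.alignment)
        tree = read_newick(config.tree)
    else:
        scen = SimulationScenario(seed=config.seed + _OFF_SCENARIO,
                                  **(config.scenario or {}))
        tree = simulate_tree(scen)
        sim, root_seq = simulate_alignment(tree, model, scen.length,
                                           root_freqs=scen.root_freqs,
                                           seed=scen.seed)
        alignment = overlay_gaps(sim, scen.gap_template) if scen.gap_template else sim
        write_fasta(declare(run_dir / "synthetic_alignment.fasta"), alignment)
        (declare(run_dir / "synthetic_tree.nwk")).write_text(tree.to_newick() + "\n")
        write_fasta(declare(run_dir / "synthetic_true_root.fasta"),
                    [("true_root", root_seq)])

    if config.clusters == "auto":
        clusters = cluster_sequences(alignment, config.soft_max,
                                     seed=config.seed + _OFF_CLUSTER)
        write_cluster_file(declare(run_dir / "clusters.txt"), clusters)
    else:
        clusters = parse_cluster_file(config.clusters)
        clusters.check_against(alignment)

    # -- replicate ASR + consensus -----------------------------------------
    sets, cons = _run_replicates(alignment, tree, model, clusters, config)
    for t in config.thresholds:
        recs = [(f"replicate_{i + 1:03d}", s) for i, s in enumerate(sets[t].sequences)]
        recs.append((f"consensus_t{t}", cons[t].sequence))
        write_fasta(declare(run_dir / f"replicates_t{t}.fasta"), recs)
    write_fasta(declare(run_dir / "consensus.fasta"),
                [(f"{config.node}_t{t}", cons[t].sequence) for t in config.thresholds])

    lengths = pd.DataFrame(
        [{"threshold": t,
          "mean_ungapped": float(np.mean([ungapped_length(s) for s in sets[t].sequences])),
          "sd_ungapped": float(np.std([ungapped_length(s) for s in sets[t].sequences], ddof=1))
          if len(sets[t].sequences) > 1 else 0.0,
          "consensus_ungapped": ungapped_length(cons[t].sequence)}
         for t in config.thresholds])
    lengths.to_csv(declare(run_dir / "reconstruction_lengths.tsv"), sep="\t", index=False)

    # -- threshold sweep on the full-data profile ---------------------------
    profile = _full_profile(alignment, tree, model, config)
    occupancy = threshold_sweep(profile)
    pd.DataFrame({"column": np.arange(len(occupancy)),
                  "occupancy": occupancy,
                  "gap_posterior": profile.gap_posterior,
                  "top_residue": [call_sequence(profile, 50).sequence[c]
                                  for c in range(len(occupancy))]}
                 ).to_csv(declare(run_dir / "threshold_sweep.tsv"), sep="\t", index=False)

    # -- composition + null + depletion test --------------------------------
    comp = composition_summary(list(alignment), DEFAULT_CHRONOLOGY, groupby="sequence")
    comp.to_csv(declare(run_dir / "composition.tsv"), sep="\t", index=False)

    nulls = _run_null(tree, alignment, model, clusters, config)
    null_df = pd.DataFrame({aa: nd.counts for aa, nd in nulls.items()})
    null_df.to_csv(declare(run_dir / "null_distribution.tsv"), sep="\t", index=False)

    obs_seq = cons[min(config.thresholds)].sequence
    rows = []
    for aa, nd in nulls.items():
        obs = count_residues(obs_seq, {aa})
        if nd.n_sims >= 20:
            p, z = depletion_test(obs, nd)
        else:  # too few simulations for a meaningful empirical p
            p, z = float("nan"), None
        rows.append({"residue": aa, "observed": obs,
                     "null_mean": float(nd.counts.mean()),
                     "null_sd": float(nd.counts.std(ddof=1)),
                     "p": p, "z": z if z is not None else float("nan")})
    pd.DataFrame(rows).to_csv(declare(run_dir / "depletion_test.tsv"), sep="\t", index=False)

    # -- feature report ------------------------------------------------------
    feats = []
    for t in config.thresholds:
        seq = cons[t].sequence.replace("-", "")
        if not seq:
            continue
        h = mean_hydropathy(seq)
        pi, ok = isoelectric_point(seq)
        feats.append({"sequence": f"{config.node}_t{t}", "length": len(seq),
                      "mean_hydropathy": h, "localization": classify_localization(h),
                      "pI": pi, "pI_converged": ok})
    pd.DataFrame(feats).to_csv(declare(run_dir / "features.tsv"), sep="\t", index=False)

    # -- alignment statistics ------------------------------------------------
    pid, ppos = pairwise_identity_stats(alignment) if len(alignment) <= 200 else (float("nan"),) * 2
    trim_params = TrimParams.defaults_for(len(alignment), gap_allowance="all",
                                          max_nonconserved_stretch=100, min_block_length=2)
    try:
        trimmed = trim_alignment(alignment, trim_params)
        trimmed_gap = gap_fraction(trimmed.trimmed)
        trimmed_cols = len(trimmed.kept_columns)
    except DomainError:
        trimmed_gap, trimmed_cols = float("nan"), 0
    pd.DataFrame([{"n_records": len(alignment), "n_columns": alignment.n_columns,
                   "gap_fraction": gap_fraction(alignment),
                   "pairwise_identity": pid, "pairwise_positive": ppos,
                   "trimmed_columns": trimmed_cols,
                   "trimmed_gap_fraction": trimmed_gap}]
                 ).to_csv(declare(run_dir / "alignment_stats.tsv"), sep="\t", index=False)

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return run_dir


@_stage("replicated_asr")
def _run_replicates(alignment, tree, model, clusters, config):
    for r in range(config.n_replicates):
        logger.debug("replicate %d seed %d", r, config.seed + _OFF_REPLICATES + r)
    return replicated_asr(alignment, tree, model, clusters, node_id=config.node,
                          thresholds=config.thresholds, n=config.n_replicates,
                          seed=config.seed + _OFF_REPLICATES)


@_stage("full_profile")
def _full_profile(alignment, tree, model, config):
    return reconstruct(tree, alignment, model, node_id=config.node)


@_stage("null_distribution")
def _run_null(tree, alignment, model, clusters, config):
    return null_reconstruction_distribution(
        tree, alignment, model, clusters, node_id=config.node,
        amino_acids=config.late_aa, n_sims=config.n_sims,
        gap_threshold=config.null_gap_threshold, seed=config.seed + _OFF_NULL)
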