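"""End-to-end analysis pipeline with a run manifest and stage caching.

Stages run in dependency order: QC -> diversity -> distances/trees ->
PCA -> LD/Ne -> FST scan. Each stage's parameters and input checksums
are hashed; a stage whose hash matches the manifest from a previous run
is skipped and its outputs reused. LD pair enumeration is the one
potentially slow stage, which is what makes the cache worthwhile.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import common_high_maf_subset, diversity_table
from .distance import ibs_distance, nei_distance, neighbor_joining, \
    write_newick
from .fst import build_regions, call_outliers, overlap_annotation, \
    overlap_counts, per_snp_fst, read_annotation_bed, regions_to_bed
from .io_plink import read_panel
from .ldne import bin_ld, fit_ld_decay, ne_trajectory, pairwise_r2
from .panel import GenotypePanel, PanelError, QCConfig, apply_qc
from .pca import pca

logger = logging.getLogger(__name__)

STAGES = ("qc", "diversity", "distance", "pca", "ldne", "fst")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    input_prefix: str
    input_format: str = "bed"
    group_map: str | None = None          # TSV individual_id -> group
    out_dir: str = "popscan_out"
    seed: int = 0
    # QC
    min_snp_call_rate: float = 0.900
    min_maf: float = 0.050
    min_sample_call_rate: float = 0.900
    # diversity
    diversity_maf: float = 0.200
    diversity_reference_groups: list[str] | None = None  # [group_a, group_b]
    # LD / Ne
    ld_populations: list[str] | None = None  # default: all
    ld_bin_kb: int = 200
    ld_max_mb: int = 20
    ne_k: float = 4.0
    ne_alpha: float = 1.0
    ne_t_min: int = 3
    ne_t_max: int = 100
    morgans_per_bp: float = 1e-8
    # FST
    fst_quantile: float = 0.99
    fst_flank_kb: int = 200
    annotation_beds: dict[str, str] = field(default_factory=dict)
    n_autosomes: int = 18
    pca_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PanelError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        fmt_files = {"bed": (".bed", ".bim", ".fam"),
                     "ped": (".ped", ".map")}[self.input_format]
        for ext in fmt_files:
            p = Path(self.input_prefix).with_suffix(ext)
            if not p.exists():
                raise PanelError(f"missing input file {p}")
        if self.group_map and not Path(self.group_map).exists():
            raise PanelError(f"missing group map {self.group_map}")
        for name, path in self.annotation_beds.items():
            if not Path(path).exists():
                raise PanelError(f"missing annotation BED {name}: {path}")
        if not 0 < self.fst_quantile < 1:
            raise PanelError("fst_quantile must be in (0, 1)")
        if self.ne_t_min < 1 or self.ne_t_max < self.ne_t_min:
            raise PanelError("invalid Ne generation range")


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(config: RunConfig, stage: str, extra: dict) -> str:
    payload = {"stage": stage, "version": __version__,
               "config": {k: v for k, v in vars(config).items()},
               **extra}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


class PipelineRun:
    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        self.executed: list[str] = []
        self.skipped: list[str] = []

    def _input_hashes(self) -> dict:
        exts = {"bed": (".bed", ".bim", ".fam"),
                "ped": (".ped", ".map")}[self.config.input_format]
        hashes = {
            ext: _file_hash(Path(self.config.input_prefix).with_suffix(ext))
            for ext in exts}
        if self.config.group_map:
            hashes["group_map"] = _file_hash(Path(self.config.group_map))
        return hashes

    def _fresh(self, stage: str, key: str,
               outputs: list[Path] | None = None) -> bool:
        """A stage is fresh when its key matches and its recorded
        outputs (which may be a data-dependent subset of the declared
        ones) still exist on disk."""
        rec = self.manifest.get(stage)
        if rec is None or rec.get("key") != key:
            return False
        return all(Path(p).exists() for p in rec.get("outputs", []))

    def _record(self, stage: str, key: str, outputs: list[Path]) -> None:
        self.manifest[stage] = {
            "key": key,
            "outputs": [str(p) for p in outputs if p.exists()]}
        self.manifest["version"] = __version__
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    # ------------------------------------------------------------ run

    def run(self) -> Path:
        cfg = self.config
        in_hashes = self._input_hashes()

        panel = read_panel(cfg.input_prefix, format=cfg.input_format)
        grouping = None
        if cfg.group_map:
            gm = pd.read_csv(cfg.group_map, sep="\t", header=None,
                             names=["individual_id", "group"], dtype=str)
            grouping = dict(zip(gm["individual_id"], gm["group"]))

        # ---- QC
        stage = "qc"
        qc_out = self.out / "qc_report.tsv"
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, [qc_out]):
            self.skipped.append(stage)
            qc_panel, _ = apply_qc(panel, QCConfig(
                cfg.min_snp_call_rate, cfg.min_maf, cfg.min_sample_call_rate))
        else:
            try:
                qc_panel, report = apply_qc(panel, QCConfig(
                    cfg.min_snp_call_rate, cfg.min_maf,
                    cfg.min_sample_call_rate))
            except PanelError as exc:
                raise PanelError(f"stage qc failed: {exc}") from exc
            report.to_frame().to_csv(qc_out, sep="\t", index=False)
            self._record(stage, key, [qc_out])
            self.executed.append(stage)

        auto = qc_panel.autosome_markers(cfg.n_autosomes)

        # ---- diversity
        stage = "diversity"
        div_out = self.out / "diversity.tsv"
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, [div_out]):
            self.skipped.append(stage)
        else:
            markers = None
            if cfg.diversity_reference_groups:
                ga, gb = cfg.diversity_reference_groups
                labels = (qc_panel.samples["individual_id"].map(grouping)
                          if grouping else qc_panel.samples["population"])
                idx_a = np.flatnonzero((labels == ga).to_numpy())
                idx_b = np.flatnonzero((labels == gb).to_numpy())
                markers = common_high_maf_subset(
                    qc_panel, idx_a, idx_b, cfg.diversity_maf)
            diversity_table(qc_panel, markers,
                            maf_threshold=cfg.diversity_maf
                            ).to_csv(div_out, sep="\t", index=False)
            self._record(stage, key, [div_out])
            self.executed.append(stage)

        # ---- distances + trees
        stage = "distance"
        outs = [self.out / "ibs_distance.tsv", self.out / "nei_distance.tsv",
                self.out / "individual_tree.nwk",
                self.out / "population_tree.nwk"]
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, outs):
            self.skipped.append(stage)
        else:
            dm_ind = ibs_distance(qc_panel)
            dm_ind.write_tsv(outs[0])
            dm_pop = nei_distance(qc_panel)
            dm_pop.write_tsv(outs[1])
            if len(dm_ind.labels) >= 3:
                write_newick(neighbor_joining(dm_ind), outs[2])
            if len(dm_pop.labels) >= 3 and np.isfinite(dm_pop.values).all():
                write_newick(neighbor_joining(dm_pop), outs[3])
            self._record(stage, key, outs)
            self.executed.append(stage)

        # ---- PCA
        stage = "pca"
        outs = [self.out / "pca_coordinates.tsv",
                self.out / "pca_contributions.tsv"]
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, outs):
            self.skipped.append(stage)
        else:
            res = pca(qc_panel, markers=auto, k=cfg.pca_k)
            res.to_frame(qc_panel.samples).to_csv(outs[0], sep="\t",
                                                  index=False)
            pd.DataFrame({
                "component": np.arange(1, len(res.contributions) + 1),
                "eigenvalue": res.eigenvalues,
                "contribution": res.contributions,
            }).to_csv(outs[1], sep="\t", index=False)
            self._record(stage, key, outs)
            self.executed.append(stage)

        # ---- LD / Ne per population
        stage = "ldne"
        pops = cfg.ld_populations or \
            qc_panel.samples["population"].unique().tolist()
        outs = []
        for pop in pops:
            outs += [self.out / f"ld_bins_{pop}.tsv",
                     self.out / f"ld_fit_{pop}.json",
                     self.out / f"ne_trajectory_{pop}.tsv"]
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, outs):
            self.skipped.append(stage)
        else:
            for pop in pops:
                idx = qc_panel.samples_of(pop)
                sub = qc_panel.subset(sample_idx=idx, marker_idx=auto)
                pairs = pairwise_r2(
                    sub, max_distance_bp=cfg.ld_max_mb * 1_000_000)
                bins = bin_ld(pairs, bin_width_bp=cfg.ld_bin_kb * 1000,
                              max_bp=cfg.ld_max_mb * 1_000_000)
                bins.write_tsv(self.out / f"ld_bins_{pop}.tsv")
                fit = fit_ld_decay(bins)
                (self.out / f"ld_fit_{pop}.json").write_text(json.dumps({
                    "a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d,
                    "r_squared_of_fit": fit.r_squared_of_fit,
                    "converged": fit.converged}, indent=2))
                traj = ne_trajectory(
                    fit, t_min=cfg.ne_t_min, t_max=cfg.ne_t_max,
                    k=cfg.ne_k, alpha=cfg.ne_alpha,
                    morgans_per_bp=cfg.morgans_per_bp)
                traj.to_csv(self.out / f"ne_trajectory_{pop}.tsv",
                            sep="\t", index=False)
            self._record(stage, key, outs)
            self.executed.append(stage)

        # ---- FST scan
        stage = "fst"
        outs = [self.out / "fst.tsv", self.out / "selection_regions.bed"]
        if cfg.annotation_beds:
            outs += [self.out / "annotation_overlaps.tsv",
                     self.out / "annotation_counts.tsv"]
        key = _stage_key(cfg, stage, {"inputs": in_hashes})
        if self._fresh(stage, key, outs):
            self.skipped.append(stage)
        else:
            auto_panel = qc_panel.subset(marker_idx=auto)
            res = per_snp_fst(auto_panel, grouping=grouping)
            res = call_outliers(res, quantile=cfg.fst_quantile)
            res.write_tsv(outs[0])
            regions = build_regions(res, flank_bp=cfg.fst_flank_kb * 1000)
            regions_to_bed(regions, outs[1])
            if cfg.annotation_beds:
                ann = []
                for kind, path in cfg.annotation_beds.items():
                    ann.extend(read_annotation_bed(path, kind=kind))
                ov = overlap_annotation(regions, ann)
                ov.to_csv(outs[2], sep="\t", index=False)
                overlap_counts(ov).to_csv(outs[3], sep="\t", index=False)
            self._record(stage, key, outs)
            self.executed.append(stage)

        return self.out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    return PipelineRun(config).run()
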