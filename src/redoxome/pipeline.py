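"""End-to-end orchestration: simulate/load → quantify → differential call →
hotspot ranking → domain mapping → motif analysis, with full provenance.

A run is driven by a single :class:`RunConfig`; every output table, the
effective configuration and a machine-readable stage report land in the
output directory.  Runs are deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import differential, motif, quantify
from .errors import ConfigError
from .io import (
    DomainAnnotation,
    PlexDesign,
    ProteinDb,
    read_domain_annotation,
    read_fasta,
    read_plex_design,
    read_psm_table,
    write_fasta,
    write_plex_design,
    write_psm_table,
    write_table,
)
from .simulate import SimConfig, generate_experiment, generate_null_experiment


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Either ``simulate`` is set (synthetic mode) or the three input paths
    are (real-data mode); ``domain_path`` is optional in both."""

    out_dir: str | Path
    simulate: SimConfig | None = None
    null_model: bool = False
    psm_path: str | Path | None = None
    design_path: str | Path | None = None
    fasta_path: str | Path | None = None
    domain_path: str | Path | None = None
    alpha: float = 0.05
    rel_min: float = 0.25
    top_frac: float = 0.15
    min_reps: int = 2
    window: int = 6
    background: str = "detected"   # "detected" | "proteome"
    normalize: bool = False

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("psm_path", "design_path", "fasta_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"non-simulate mode requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")
        if self.domain_path is not None and not Path(self.domain_path).exists():
            raise ConfigError(f"domain_path does not exist: {self.domain_path}")
        if self.background not in ("detected", "proteome"):
            raise ConfigError(
                f"background must be 'detected' or 'proteome', got "
                f"{self.background!r}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.top_frac <= 1:
            raise ConfigError("top_frac must lie in (0, 1]")
        if self.min_reps < 2:
            raise ConfigError("min_reps must be ≥ 2")


@dataclass
class RunReport:
    """Counts and artefacts of every pipeline stage."""

    n_psms: int = 0
    n_psms_excluded_multi_cys: int = 0
    n_sites_quantified: int = 0
    n_sites_tested: int = 0
    n_sites_called: int = 0
    fraction_called: float = 0.0
    n_over_100_percent: int = 0
    top_proteins: list[dict] = field(default_factory=list)
    n_motif_significant_cells: int = 0
    motif_threshold: float = 0.0
    manifest: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _effective_config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    for k in ("psm_path", "design_path", "fasta_path", "domain_path"):
        if d[k] is not None:
            d[k] = str(d[k])
    return d


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and write all outputs under ``cfg.out_dir``.

    Outputs: plex_design.tsv / proteins.fasta / psm_table.tsv / truth.tsv
    (synthetic mode), site_quant_{oxidized,total}.tsv,
    oxidation_profile.tsv, differential.tsv, protein_ranks.tsv,
    domain_map.tsv (if annotated), motif_cells.tsv, motif_pwm.tsv,
    run_report.json, effective_config.json.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    manifest = report.manifest

    # ---- inputs ----
    annot: DomainAnnotation | None = None
    if cfg.simulate is not None:
        gen = generate_null_experiment if cfg.null_model else generate_experiment
        db, designs, psms, truth = gen(cfg.simulate)
        write_fasta(db, out / "proteins.fasta")
        write_plex_design(designs, out / "plex_design.tsv")
        channels = [e.channel_id for e in designs[0].entries]
        write_psm_table(psms, out / "psm_table.tsv", channels=channels)
        write_table(truth.as_frame(), out / "truth.tsv")
        manifest.update(
            proteins="proteins.fasta",
            plex_design="plex_design.tsv",
            psm_table="psm_table.tsv",
            truth="truth.tsv",
        )
    else:
        db = read_fasta(cfg.fasta_path)
        designs = read_plex_design(cfg.design_path)
        psms = read_psm_table(cfg.psm_path, db)
    if cfg.domain_path is not None:
        annot = read_domain_annotation(cfg.domain_path, db)
    report.n_psms = len(psms)

    # ---- quantification ----
    sites = quantify.aggregate_psms_to_sites(psms, designs)
    if cfg.normalize:
        sites = quantify.median_center_channels(sites)
    report.n_psms_excluded_multi_cys = sites.n_excluded_multi_cys
    report.n_sites_quantified = len(sites.site_ids)
    write_table(sites.oxidized, out / "site_quant_oxidized.tsv", index=True)
    write_table(sites.total, out / "site_quant_total.tsv", index=True)
    manifest["site_quant_oxidized"] = "site_quant_oxidized.tsv"
    manifest["site_quant_total"] = "site_quant_total.tsv"

    profile = quantify.compute_oxidation_percent(sites)
    report.n_over_100_percent = profile.n_over_100
    profile = quantify.filter_quantified_sites(profile, min_reps=cfg.min_reps)
    write_table(profile.values, out / "oxidation_profile.tsv", index=True)
    manifest["oxidation_profile"] = "oxidation_profile.tsv"

    # ---- differential calling ----
    results = differential.test_all_sites(profile)
    results = differential.call_increased_oxidation(
        results, alpha=cfg.alpha, rel_min=cfg.rel_min, top_frac=cfg.top_frac
    )
    report.n_sites_tested = len(results)
    report.n_sites_called = int(results["called"].sum())
    report.fraction_called = differential.called_fraction(results)
    write_table(results.reset_index(), out / "differential.tsv")
    manifest["differential"] = "differential.tsv"

    ranks = differential.rank_proteins(results)
    write_table(ranks, out / "protein_ranks.tsv")
    manifest["protein_ranks"] = "protein_ranks.tsv"
    report.top_proteins = ranks.head(10).to_dict(orient="records")

    called_ids = sorted(results.index[results["called"]])
    if annot is not None:
        domain_map, _counts = differential.map_sites_to_domains(called_ids, annot)
        write_table(domain_map, out / "domain_map.tsv")
        manifest["domain_map"] = "domain_map.tsv"

    # ---- motif analysis ----
    if called_ids:
        fg = motif.extract_flanks(called_ids, db, w=cfg.window)
        if cfg.background == "detected":
            bg_ids = sorted(results.index)
        else:
            bg_ids = sorted(
                f"{acc}:{i + 1}"
                for acc, seq in db.records.items()
                for i, ch in enumerate(seq)
                if ch == "C"
            )
        bg = motif.extract_flanks(bg_ids, db, w=cfg.window)
        mres = motif.build_motif_result(fg, bg, alpha=cfg.alpha)
        report.n_motif_significant_cells = int(mres.cells["significant"].sum())
        report.motif_threshold = mres.threshold
        write_table(mres.cells, out / "motif_cells.tsv")
        write_table(
            mres.pwm.reset_index(), out / "motif_pwm.tsv"
        )
        manifest["motif_cells"] = "motif_cells.tsv"
        manifest["motif_pwm"] = "motif_pwm.tsv"

    # ---- provenance ----
    with open(out / "effective_config.json", "w") as fh:
        json.dump(_effective_config_dict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["effective_config"] = "effective_config.json"
    manifest["run_report"] = "run_report.json"
    return report
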