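"""Coupling of the three stages into the multi-scale case study.

One pass of the pipeline runs: ventilator waveform -> airway-tree
pressures -> per-airway wall strain -> cellular-automata inflammation,
then feeds the accumulated fibrosis back into the wall materials
(stiffening) and re-solves the tissue stage. The default case study
follows three lower airways — labelled G4-1, G6 and G7 by (generation,
branch index) — and reports pressures, strains before and after the
inflammatory episode, inflammation traces, and the fold changes that let
the immune response be compared with the compliance change it causes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_ca, organ_flow, tissue_mech
from .cell_ca import CAParams, EnsembleSummary, Lattice, StrainInput
from .fixtures import load_morphology

log = logging.getLogger("ventilam")

UNRESOLVED = -1  # sentinel for a trace that never returns to zero


@dataclass
class SimulationConfig:
    """All knobs of the three stages plus the coupling parameters."""

    # organ block
    tidal_volume_ml: float = 420.0
    t_in_s: float = 0.4
    t_ex_s: float = 2.0
    max_generation: int = 7
    air_viscosity: float = organ_flow.AIR_VISCOSITY
    outlet_pressure_pa: float = 0.0
    n_time_samples: int = 200
    # tissue block
    epithelium_mu_pa: float = tissue_mech.EPITHELIUM_MU
    inner_middle_ratio: float = tissue_mech.INNER_MIDDLE_RATIO
    asm_e_pa: float = tissue_mech.ASM_E
    asm_nu: float = 0.45
    foundation_k: float = tissue_mech.FOUNDATION_K
    n_radial_nodes: int = 200
    # cellular block
    ca: CAParams = field(default_factory=CAParams)
    lattice_width: int = 100
    lattice_height: int = 100
    ca_steps: int = 10000
    # coupling
    airways: tuple[str, ...] = ("G4-1", "G6", "G7")
    feedback_alpha: float = 5.0
    n_replicates: int = 5
    master_seed: int = 0
    morphology_path: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.feedback_alpha < 0:
            raise ValueError("feedback alpha must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ca = CAParams(**raw.pop("ca", {}))
        return cls(ca=ca, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def parse_airway_label(label: str) -> tuple[int, int]:
    """'G4-1' -> (generation 4, branch 1); 'G6' -> (6, 0)."""
    m = re.fullmatch(r"G(\d+)(?:-(\d+))?", label)
    if not m:
        raise ValueError(f"cannot parse airway label {label!r}")
    return int(m.group(1)), int(m.group(2) or 0)


@dataclass
class AirwayResult:
    label: str
    gn: int
    peak_pressure_pa: float
    strain_pre: float
    strain_post: float
    fibrosis_fraction: float
    peak_dead: float
    peak_step: int
    resolution_step: int
    mu_epithelium_pre: float
    mu_epithelium_post: float
    ensemble: EnsembleSummary


@dataclass
class CaseStudyReport:
    config_hash: str
    master_seed: int
    airways: list[AirwayResult]
    immune_fold_change: float   # highest-strain peak over lowest active peak
    strain_fold_change: float   # largest pre/post strain ratio across airways

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "immune_fold_change": self.immune_fold_change,
            "strain_fold_change": self.strain_fold_change,
            "airways": [{k: v for k, v in dataclasses.asdict(a).items()
                         if k != "ensemble"} for a in self.airways],
        }


def summarize_response(dead_trace: np.ndarray) -> dict:
    """Peak value, peak step, resolution step and area under the curve.

    The peak step is the first argmax; the resolution step is the first
    step after the peak at which the dead count is zero (``UNRESOLVED``
    if it never returns to zero). An all-zero trace has peak 0 and
    resolution step 0.
    """
    dead = np.asarray(dead_trace, dtype=float)
    if dead.size == 0:
        raise ValueError("empty trace")
    peak = float(dead.max())
    peak_step = int(dead.argmax())
    after = np.nonzero(dead[peak_step:] == 0)[0]
    resolution = int(peak_step + after[0]) if after.size else UNRESOLVED
    return {"peak": peak, "peak_step": peak_step, "resolution_step": resolution,
            "auc": float(np.trapezoid(dead))}


def sustained_zero_step(dead_trace: np.ndarray, threshold: float = 0.5) -> int:
    """First step from which the (possibly ensemble-mean) dead count stays
    below ``threshold`` for the rest of the trace; ``UNRESOLVED`` if none."""
    dead = np.asarray(dead_trace, dtype=float)
    above = np.nonzero(dead >= threshold)[0]
    if above.size == 0:
        return 0
    last = int(above[-1])
    return UNRESOLVED if last == dead.size - 1 else last + 1


def compute_strains(cfg: SimulationConfig):
    """Organ + tissue stages: peak pressures and epithelial strains per
    selected airway, plus the objects needed for the feedback pass."""
    morph = load_morphology(cfg.morphology_path)
    tree = organ_flow.build_airway_tree(morph, cfg.max_generation, cfg.air_viscosity)
    wave = organ_flow.VentilatorWaveform(tidal_volume=cfg.tidal_volume_ml * 1e-6,
                                         t_in=cfg.t_in_s, t_ex=cfg.t_ex_s)
    profile = organ_flow.pressure_profile(tree, wave, cfg.outlet_pressure_pa,
                                          cfg.n_time_samples)
    peaks = profile.peak_pressures()
    materials = tissue_mech.default_materials(cfg.epithelium_mu_pa,
                                              cfg.inner_middle_ratio,
                                              cfg.asm_e_pa, cfg.asm_nu)
    sections = tissue_mech.wall_sections(morph, materials, cfg.foundation_k)
    gns = [parse_airway_label(a)[0] for a in cfg.airways]
    for gn in gns:
        if gn > tree.max_gn:
            raise ValueError(f"selected airway generation {gn} exceeds the tree depth {tree.max_gn}")
    peak_by_gn = {gn: float(peaks[gn]) for gn in gns}
    strains = tissue_mech.strain_for_airways(peak_by_gn, sections, cfg.n_radial_nodes)
    return morph, tree, profile, sections, peak_by_gn, strains


def run_case_study(cfg: SimulationConfig) -> CaseStudyReport:
    """Execute the full multi-scale pass over the selected airways."""
    log.info("case study: seed=%d hash=%s", cfg.master_seed, cfg.config_hash())
    morph, tree, profile, sections, peaks, strains = compute_strains(cfg)
    lattice = Lattice(width=cfg.lattice_width, height=cfg.lattice_height)
    results = []
    for label in cfg.airways:
        gn, _branch = parse_airway_label(label)
        strain = StrainInput(level=strains[gn])
        ens = cell_ca.run_ensemble(strain, cfg.ca, n_steps=cfg.ca_steps,
                                   n_reps=cfg.n_replicates,
                                   seed=cfg.master_seed + gn, lattice=lattice)
        summary = summarize_response(ens.mean_dead)
        fib_frac = float(ens.mean_fibrosis[-1]) / (lattice.width * lattice.height)
        # fibrosis -> stiffening feedback on both Neo-Hookean layers
        section = sections[gn]
        new_layers = tuple(
            dataclasses.replace(
                layer,
                material=tissue_mech.stiffen(layer.material, fib_frac, cfg.feedback_alpha))
            if isinstance(layer.material, tissue_mech.MaterialNeoHookean) else layer
            for layer in section.layers)
        stiffened = dataclasses.replace(section, layers=new_layers)
        post = tissue_mech.solve_wall(stiffened, peaks[gn], n_nodes=cfg.n_radial_nodes)
        results.append(AirwayResult(
            label=label, gn=gn, peak_pressure_pa=peaks[gn],
            strain_pre=strains[gn], strain_post=post.epithelial_strain,
            fibrosis_fraction=fib_frac,
            peak_dead=summary["peak"], peak_step=summary["peak_step"],
            resolution_step=sustained_zero_step(ens.mean_dead),
            mu_epithelium_pre=section.layers[0].material.mu,
            mu_epithelium_post=new_layers[0].material.mu,
            ensemble=ens))
        log.info("%s: P=%.3f Pa strain=%.3e peak_dead=%.1f fibrosis=%.3f",
                 label, peaks[gn], strains[gn], summary["peak"], fib_frac)
    peaks_dead = [r.peak_dead for r in results]
    active = sorted((v for v in peaks_dead if v > 0), reverse=True)
    immune_fold = active[0] / max(active[-1], 1.0) if active else 0.0
    strain_fold = max((r.strain_pre / r.strain_post if r.strain_post > 0 else 1.0)
                      for r in results)
    report = CaseStudyReport(config_hash=cfg.config_hash(),
                             master_seed=cfg.master_seed, airways=results,
                             immune_fold_change=immune_fold,
                             strain_fold_change=strain_fold)
    if cfg.outdir:
        write_outputs(cfg, report, profile)
    return report


def write_outputs(cfg: SimulationConfig, report: CaseStudyReport,
                  profile: organ_flow.PressureProfile) -> None:
    """CSV tables, JSON report and figure analogues under cfg.outdir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# ventilam config_hash={report.config_hash} seed={report.master_seed}\n"
    with open(out / "pressures.csv", "w") as f:
        f.write(header)
        profile.to_frame().to_csv(f, index=False)
    rows = pd.DataFrame([{k: v for k, v in dataclasses.asdict(a).items()
                          if k != "ensemble"} for a in report.airways])
    with open(out / "airways.csv", "w") as f:
        f.write(header)
        rows.to_csv(f, index=False)
    for a in report.airways:
        tr = pd.DataFrame({"step": np.arange(a.ensemble.mean_dead.size),
                           "mean_dead": a.ensemble.mean_dead,
                           "std_dead": a.ensemble.std_dead,
                           "mean_fibrosis": a.ensemble.mean_fibrosis})
        with open(out / f"trace_{a.label}.csv", "w") as f:
            f.write(header)
            tr.to_csv(f, index=False)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _plots(out, report, profile)


def _plots(out: Path, report: CaseStudyReport,
           profile: organ_flow.PressureProfile) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for gn in range(profile.pressures.shape[0]):
        ax.plot(profile.times, profile.pressures[gn], label=f"G{gn}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("lumen pressure (Pa)")
    ax.legend(ncol=2, fontsize=7)
    fig.savefig(out / "pressures.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = [a.label for a in report.airways]
    ax.bar(labels, [a.strain_pre for a in report.airways], width=0.4, label="pre")
    ax.bar(np.arange(len(labels)) + 0.4, [a.strain_post for a in report.airways],
           width=0.4, label="post-feedback")
    ax.set_ylabel("epithelial hoop strain")
    ax.legend()
    fig.savefig(out / "strains.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for a in report.airways:
        ax.plot(a.ensemble.mean_dead, label=a.label)
    ax.set_xlabel("CA step")
    ax.set_ylabel("dead epithelial cells (ensemble mean)")
    ax.legend()
    fig.savefig(out / "inflammation.png", dpi=120)
    plt.close(fig)
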