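"""End-to-end orchestration: config, synthetic or file inputs, reports.

:func:`run_pipeline` takes a :class:`RunConfig` and produces, for every
complex, the Fe–reactive-atom distance series, its summary, a detachment
call and a substrate-likelihood call, plus a variant-vs-reference comparison
and effect call for every non-reference allele of each ligand. Results come
back as dataframes and are optionally written as TSV + JSON reports (with
per-series TSVs and plots) that regenerate byte-identically for the same
config and seed.

:func:`run_conservation` covers the sequence side: conservation of a
reference-mapped alignment column plus strict and relaxed heme-motif scans
of the ungapped reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .conservation_msa import read_msa, map_position, column_conservation, ungap, \
    scan_heme_motif, relaxed_motif_scan
from .discriminant_stats import (
    DETACHMENT_THRESHOLD_NM,
    DETACHMENT_WINDOW_PS,
    MINOR_MARGIN_NM,
    PROBE_MARGIN_NM,
    call_substrate,
    call_variant_effect,
    detect_detachment,
    summarize,
)
from .errors import ConfigError
from .geometry_engine import (
    DistanceSeries,
    distance_series,
    rmsd_series,
    write_series_tsv,
)
from .structure_io import LigandSpec, calpha_indices, select_atoms, \
    find_heme_iron, select_reactive_atom, read_model_trajectory
from .synthetic_data import scenario_presets, simulate_distance_series

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryInput:
    """One trajectory file plus the metadata needed to analyse it."""

    path: str
    ligand: str  # ligand label, e.g. "OTA"
    res_name: str  # ligand residue name in the file
    reactive_atom: str
    allele: str
    dt_ps: float = 10.0


@dataclass
class RunConfig:
    """Validated run configuration (see :meth:`from_toml` for the file layout)."""

    seed: int = 0
    out_dir: str | None = None
    scenarios: list[str] = field(default_factory=lambda: ["all"])
    trajectories: list[TrajectoryInput] = field(default_factory=list)
    n_frames: int = 5000
    dt_ps: float = 10.0
    alpha: float = 0.05
    t_mode: str = "student"
    burn_in_ps: float = 0.0
    ess_correction: bool = False
    detachment_threshold_nm: float = DETACHMENT_THRESHOLD_NM
    detachment_window_ps: float = DETACHMENT_WINDOW_PS
    reference_allele: str = "*1"
    probe_ligands: list[str] = field(default_factory=lambda: ["dextromethorphan", "bufuralol"])
    probe_margin_nm: float = PROBE_MARGIN_NM
    minor_margin_nm: float = MINOR_MARGIN_NM
    effect_calls: bool = True
    make_plots: bool = False

    def validate(self) -> None:
        if self.t_mode not in ("student", "welch"):
            raise ConfigError(f"t_mode must be 'student' or 'welch', got {self.t_mode!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not self.scenarios and not self.trajectories:
            raise ConfigError("no inputs: give scenarios and/or trajectories")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Read a TOML run-config; unknown keys are errors (fail fast)."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        trajectories = [
            TrajectoryInput(**t) if isinstance(t, dict) else t
            for t in raw.get("trajectories", [])
        ]
        cfg = cls(**{**raw, "trajectories": trajectories})
        cfg.validate()
        return cfg

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # Only analysis-relevant fields: where reports land (out_dir) and
        # whether plots are drawn must not change the hash.
        payload = {k: v for k, v in self.as_dict().items()
                   if k not in ("out_dir", "make_plots")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ComplexResult:
    label: str
    ligand: str
    allele: str
    series: DistanceSeries
    rmsd: dict[str, Any] = field(default_factory=dict)


@dataclass
class ReportBundle:
    complexes: pd.DataFrame
    effects: pd.DataFrame
    meta: dict[str, Any]
    series: dict[str, DistanceSeries]


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def _collect_synthetic(config: RunConfig) -> list[ComplexResult]:
    presets = scenario_presets()
    if config.scenarios == ["all"]:
        selected = presets
    else:
        by_name = {p.name: p for p in presets}
        missing = [s for s in config.scenarios if s not in by_name]
        if missing:
            raise ConfigError(f"unknown scenario presets: {missing}")
        selected = [by_name[s] for s in config.scenarios]
    seeds = _child_seeds(config.seed, len(selected))
    results = []
    for preset, child_seed in zip(selected, seeds):
        series = simulate_distance_series(
            preset.ou, config.n_frames, config.dt_ps, seed=child_seed,
            label=preset.name,
        )
        results.append(
            ComplexResult(
                label=preset.name, ligand=preset.ligand, allele=preset.allele,
                series=series,
            )
        )
    return results


def _collect_trajectories(config: RunConfig) -> list[ComplexResult]:
    results = []
    for tin in config.trajectories:
        label = f"{tin.ligand}:{tin.allele}"
        traj = read_model_trajectory(tin.path, dt_ps=tin.dt_ps)
        s = traj.structure
        lig = LigandSpec(tin.res_name, tin.reactive_atom, tin.ligand)
        fe = find_heme_iron(s)
        ra = select_reactive_atom(s, lig)
        series = distance_series(traj, ra, fe, label=label)
        rmsd: dict[str, Any] = {}
        ca = calpha_indices(s)
        if ca.size >= 3 and traj.n_frames >= 2:
            rmsd["protein_calpha"] = rmsd_series(
                traj, ca, ca, selection_label="protein_calpha"
            )
            lig_idx = select_atoms(s, res_name=tin.res_name)
            rmsd["ligand"] = rmsd_series(
                traj, lig_idx, ca, selection_label="ligand"
            )
        results.append(
            ComplexResult(label=label, ligand=tin.ligand, allele=tin.allele,
                          series=series, rmsd=rmsd)
        )
    return results


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full distance-discriminant analysis for a configuration."""
    config.validate()
    complexes = _collect_synthetic(config) if config.scenarios else []
    complexes += _collect_trajectories(config)
    if not complexes:
        raise ConfigError("configuration produced no complexes")
    alleles_present = {c.allele for c in complexes}
    if config.effect_calls and config.reference_allele not in alleles_present:
        raise ConfigError(
            f"variant-effect calls requested but reference allele "
            f"{config.reference_allele!r} is not among the inputs"
        )

    analysed: dict[str, DistanceSeries] = {}
    for c in complexes:
        series = c.series
        if config.burn_in_ps > 0:
            series = series.after(series.times_ps[0] + config.burn_in_ps)
        analysed[c.label] = series

    summaries = {lbl: summarize(s, ess_correction=config.ess_correction)
                 for lbl, s in analysed.items()}

    # Probe envelope from the probe ligands' reference-allele complexes.
    probe_means = [
        summaries[c.label].mean_nm
        for c in complexes
        if c.ligand in config.probe_ligands and c.allele == config.reference_allele
    ]

    rows = []
    for c in complexes:
        s = analysed[c.label]
        summ = summaries[c.label]
        span = float(s.times_ps[-1] - s.times_ps[0])
        if span >= config.detachment_window_ps:
            event = detect_detachment(
                s, config.detachment_threshold_nm, config.detachment_window_ps
            )
            onset = event.onset_ps
        else:
            onset = None
            logger.warning("%s: series shorter than detachment window; skipped", c.label)
        sub_label = None
        if probe_means:
            sub_label = call_substrate(
                summ, probe_means, config.probe_margin_nm, config.minor_margin_nm
            ).label
        rows.append(
            {
                "label": c.label,
                "ligand": c.ligand,
                "allele": c.allele,
                "mean_nm": summ.mean_nm,
                "se_nm": summ.se_nm,
                "sd_nm": summ.sd_nm,
                "n_frames": summ.n_frames,
                "substrate_call": sub_label,
                "detachment_onset_ps": onset,
                "seed": config.seed,
            }
        )
    complexes_df = pd.DataFrame(rows)

    effect_rows = []
    if config.effect_calls:
        by_ligand: dict[str, dict[str, ComplexResult]] = {}
        for c in complexes:
            by_ligand.setdefault(c.ligand, {})[c.allele] = c
        for ligand, alleles in sorted(by_ligand.items()):
            if config.reference_allele not in alleles:
                logger.warning("%s: no %s complex; effect calls skipped",
                               ligand, config.reference_allele)
                continue
            ref_series = analysed[alleles[config.reference_allele].label]
            for allele, c in sorted(alleles.items()):
                if allele == config.reference_allele:
                    continue
                call = call_variant_effect(
                    analysed[c.label], ref_series,
                    alpha=config.alpha, mode=config.t_mode,
                )
                effect_rows.append(
                    {
                        "ligand": ligand,
                        "allele": allele,
                        "reference": config.reference_allele,
                        "delta_nm": call.delta_nm,
                        "t_stat": call.comparison.t_stat,
                        "df": call.comparison.df,
                        "p_value": call.comparison.p_value,
                        "significant": call.comparison.significant,
                        "effect_call": call.label,
                    }
                )
    effects_df = pd.DataFrame(
        effect_rows,
        columns=["ligand", "allele", "reference", "delta_nm", "t_stat", "df",
                 "p_value", "significant", "effect_call"],
    )

    meta = {
        "tool": "hemedist",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "t_mode": config.t_mode,
        "burn_in_ps": config.burn_in_ps,
        "ess_correction": config.ess_correction,
        "detachment_threshold_nm": config.detachment_threshold_nm,
        "detachment_window_ps": config.detachment_window_ps,
        "probe_margin_nm": config.probe_margin_nm,
        "minor_margin_nm": config.minor_margin_nm,
        "probe_envelope_nm": max(probe_means) if probe_means else None,
        "n_complexes": len(complexes),
    }
    bundle = ReportBundle(
        complexes=complexes_df, effects=effects_df, meta=meta, series=analysed
    )
    if config.out_dir is not None:
        _write_reports(bundle, config)
    return bundle


def _write_reports(bundle: ReportBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.complexes.to_csv(out / "complexes.tsv", sep="\t", index=False,
                            float_format="%.6f")
    bundle.effects.to_csv(out / "effects.tsv", sep="\t", index=False,
                          float_format="%.6g")
    report = {
        "meta": bundle.meta,
        "complexes": bundle.complexes.to_dict(orient="records"),
        "effects": bundle.effects.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    for label, s in bundle.series.items():
        safe = label.replace("*", "star").replace(":", "_")
        write_series_tsv(s, series_dir / f"{safe}.tsv")
    if config.make_plots:
        _plot_series(bundle, out / "plots")


def _plot_series(bundle: ReportBundle, plot_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for label, s in bundle.series.items():
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(s.times_ps / 1000.0, s.values_nm, lw=0.5)
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("Fe–reactive-atom distance (nm)")
        ax.set_title(label)
        fig.tight_layout()
        safe = label.replace("*", "star").replace(":", "_")
        fig.savefig(plot_dir / f"{safe}.png", dpi=120)
        plt.close(fig)


def run_conservation(
    msa_path: str | Path,
    ref_id: str,
    ref_position: int,
    format: str = "fasta",
    relaxed_plus_two: set[str] = frozenset({"A", "S", "K"}),
    count_gaps: bool = False,
) -> dict[str, Any]:
    """Conservation at a reference-mapped column plus heme-motif scans.

    Returns the :class:`ConservationReport` for the column holding the
    reference's ``ref_position``-th residue, together with strict and
    relaxed heme-motif hits over the ungapped reference sequence.
    """
    msa = read_msa(msa_path, format=format)
    msa.ref_id = ref_id
    if ref_id not in {r for r, _ in msa.records}:
        raise ConfigError(f"reference id {ref_id!r} not present in alignment")
    column = map_position(msa, ref_position)
    report = column_conservation(msa, column, count_gaps=count_gaps)
    ref_ungapped = ungap(msa.reference()[1])
    return {
        "conservation": report,
        "strict_motif_hits": scan_heme_motif(ref_ungapped),
        "relaxed_motif_hits": relaxed_motif_scan(ref_ungapped, set(relaxed_plus_two)),
    }
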