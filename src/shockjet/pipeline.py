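"""End-to-end orchestration: simulate -> jet features -> filter -> stats
-> structural comparison -> kinematics, with a paper-style summary report.

Every stage consumes the previous stage's in-memory products; the summary
report collects shot accounting (hits, filtered hits, indexed), per-run
and pooled rates, median per-image resolutions per data set, the binned
resolution-vs-probe-energy table, merged-data quality metrics, the
structural-comparison block and the kinematics block, together with the
package version and a hash of the effective configuration.  Runs are
deterministic given the seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import diffraction_stats as ds
from . import jet_imaging as ji
from . import shock_kinematics as sk
from . import shot_filtering as sf
from . import structural_comparison as sc
from . import synthio

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Stage parameters for a full synthetic analysis run."""

    sim: synthio.SimulationConfig = field(default_factory=synthio.SimulationConfig)
    # diffraction-stats stage
    snr_threshold: float = 4.0
    n_energy_bins: int = 6
    stats_n_images: int = 60
    stats_d_min: float = 2.5
    stats_obs_fraction: float = 0.2
    stats_noise_sd_single: float = 0.10
    stats_noise_sd_pump_probe: float = 0.20
    wilson_b_single: float = 47.4
    wilson_b_pump_probe: float = 59.0
    stats_n_res_bins: int = 10
    # structural-comparison stage
    n_boot: int = 100
    compare_n_images: int = 50
    compare_noise_sd: float = 0.1
    compare_compaction: float = 0.995
    compare_amplitude: float = 0.15
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = synthio.SimulationConfig(**sim)
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _filter_shots(shots, gt, cfg: PipelineConfig) -> pd.DataFrame:
    """Apply the three acceptance filters; one row per shot with flags."""
    sim = cfg.sim
    noise_keep = sf.diode_noise_filter(
        np.array([sf.trace_noise_std(s.trace_unmasked) for s in shots])
    )

    pp_ids = [s.shot_id for s in shots if s.mode == "pump_probe"]
    leak_keep_all = np.ones(len(shots), dtype=bool)
    if pp_ids:
        pump_arrival = synthio.PUMP_ARRIVAL_NS
        signals = np.array(
            [sf.pump_window_signal(shots[i].trace_masked, pump_arrival) for i in pp_ids]
        )
        keep = sf.pump_leakage_filter(signals)
        for i, k in zip(pp_ids, keep):
            leak_keep_all[i] = k

    features = {
        s.shot_id: ji.extract_jet_features(s.jet_image, sim.um_per_px)
        for s in shots
        if s.mode == "pump_probe"
    }
    run_of = {s.shot_id: s.run for s in shots}
    morph = (
        sf.morphology_filter(
            features,
            run_of,
            pump_position_um=sim.pump_position_um,
            probe_position_um=sim.probe_position_um,
        )
        if features
        else {}
    )

    rows = []
    for i, s in enumerate(shots):
        reasons = []
        if not noise_keep[i]:
            reasons.append("noisy_trace")
        if not leak_keep_all[i]:
            reasons.append("pump_leakage")
        if s.shot_id in morph:
            reasons.extend(morph[s.shot_id].reasons)
        rows.append(
            {
                "shot_id": s.shot_id,
                "run": s.run,
                "mode": s.mode,
                "pump_energy": s.pump_energy,
                "probe_energy": s.probe_energy,
                "hit": s.hit,
                "indexed": s.indexed,
                "passed_filter": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def _resolution_block(shots, table: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Per-image resolution statistics on filtered, indexed shots."""
    res = {}
    sel = table[table["indexed"] & table["passed_filter"]]
    per_image = {}
    for sid in sel["shot_id"]:
        r = ds.image_resolution(shots[sid].peaks, cfg.snr_threshold)
        if r is not None:
            per_image[sid] = r
    sub = sel[sel["shot_id"].isin(per_image)].copy()
    sub["resolution"] = sub["shot_id"].map(per_image)

    out = {"median_resolution": {}, "binned": {}}
    energies = sub["probe_energy"].to_numpy()
    if energies.size:
        edges = np.linspace(energies.min(), energies.max() + 1e-9, cfg.n_energy_bins + 1)
    for mode, grp in sub.groupby("mode"):
        out["median_resolution"][mode] = float(grp["resolution"].median())
        out["binned"][mode] = ds.bin_by_probe_energy(
            grp["probe_energy"].to_numpy(), grp["resolution"].to_numpy(), edges
        )
    out["n_used"] = {m: int(n) for m, n in sub.groupby("mode").size().items()}
    return out


def _merged_metrics_block(cfg: PipelineConfig) -> dict:
    """Table-1 style merged-data metrics for both emulated data sets.

    The pump-probe data set carries a larger planted Wilson B (disorder)
    and a larger per-observation noise level than the single-pulse set,
    mirroring the observed degradation of merged-data quality.
    """
    out = {}
    specs = {
        "single": (cfg.wilson_b_single, cfg.stats_noise_sd_single, 11),
        "pump_probe": (cfg.wilson_b_pump_probe, cfg.stats_noise_sd_pump_probe, 12),
    }
    for name, (b_iso, noise_sd, sub_seed) in specs.items():
        ref = synthio.wilson_intensities(
            d_min=cfg.stats_d_min, b_iso=b_iso, dispersion=True, seed=cfg.seed
        )
        obs = synthio.generate_reflection_observations(
            ref,
            n_images=cfg.stats_n_images,
            scale_sd=0.1,
            noise_sd=noise_sd,
            seed=cfg.seed * 1000 + sub_seed,
            obs_fraction=cfg.stats_obs_fraction,
        )
        merged = ds.merge(obs)
        metrics = ds.half_set_metrics(obs, n_bins=cfg.stats_n_res_bins, seed=cfg.seed)
        out[name] = {
            "n_images": cfg.stats_n_images,
            "n_unique": int(len(merged.records)),
            "multiplicity": float(merged.records["multiplicity"].mean()),
            "completeness_pct": ds.completeness(merged),
            "wilson_b": ds.wilson_b(merged),
            "auto_resolution_cutoff": ds.auto_resolution_cutoff(
                obs, n_bins=cfg.stats_n_res_bins
            ),
            **{k: v for k, v in metrics["overall"].items()},
            "per_bin": metrics["per_bin"],
        }
    return out


def _compare_block(cfg: PipelineConfig) -> dict:
    """Structural comparison of an unshocked vs shocked model pair."""
    reference = synthio.make_reference_model(seed=cfg.seed)
    # single-pulse structure: no shock, observation noise only
    pair_a = synthio.generate_structure_pair(
        reference,
        displacement_amplitude=0.0,
        compaction=1.0,
        noise_sd=cfg.compare_noise_sd,
        n_images=cfg.compare_n_images,
        seed=cfg.seed * 1000 + 21,
    )
    # pump-probe structure: planted correlated field + compaction
    pair_b = synthio.generate_structure_pair(
        reference,
        displacement_amplitude=cfg.compare_amplitude,
        compaction=cfg.compare_compaction,
        noise_sd=cfg.compare_noise_sd,
        n_images=cfg.compare_n_images,
        seed=cfg.seed * 1000 + 22,
    )
    ens_a = sc.bootstrap_ensemble(
        pair_a.observations, n_boot=cfg.n_boot, seed=cfg.seed * 1000 + 23
    )
    ens_b = sc.bootstrap_ensemble(
        pair_b.observations, n_boot=cfg.n_boot, seed=cfg.seed * 1000 + 24
    )
    model_a = pair_a.perturbed.with_coords(ens_a.mean_xyz)
    model_b = pair_b.perturbed.with_coords(ens_b.mean_xyz)
    report = sc.compare_report(model_a, model_b, ens_a, ens_b)
    report.pop("per_residue_relative_sum")
    report["true_compaction"] = pair_b.compaction
    report["bootstrap_n_boot"] = cfg.n_boot
    return report


def _kinematics_block(cfg: PipelineConfig) -> dict:
    sim = cfg.sim
    g = sk.ShockGeometry(sim.pump_probe_delay, sim.beam_offset, sim.jet_speed)
    return {
        "delay_ns": sim.pump_probe_delay,
        "offset_um": sim.beam_offset,
        "jet_speed_mps": sim.jet_speed,
        "effective_delay_ns": sk.effective_delay(g),
        "equivalent_rep_rate_mhz": sk.equivalent_rep_rate(g),
        "shock_travel_distance_um": sk.shock_travel_distance(g),
    }


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run all stages on a synthetic experiment; returns the summary report."""
    cfg = cfg or PipelineConfig()
    shots, gt = synthio.generate_shot_series(
        dataclasses.replace(cfg.sim, seed=cfg.sim.seed or cfg.seed)
    )
    table = _filter_shots(shots, gt, cfg)
    rates = sf.rate_report(table)

    exclusion_counts: dict[str, int] = {}
    for rs in table["reasons"]:
        for r in filter(None, rs.split(";")):
            exclusion_counts[r] = exclusion_counts.get(r, 0) + 1

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "counts": {
            "n_shots": int(len(table)),
            "n_hits": int(table["hit"].sum()),
            "n_filtered_hits": int((table["hit"] & table["passed_filter"]).sum()),
            "n_indexed": int(
                (table["indexed"] & table["passed_filter"]).sum()
            ),
            "exclusions_by_reason": exclusion_counts,
        },
        "rates": {
            "pooled": rates["pooled"],
            "average": rates["average"],
            "per_run": rates["per_run"],
        },
        "rates_by_mode": {
            mode: sf.rate_report(grp)["pooled"]
            for mode, grp in table.groupby("mode")
        },
        "resolution": _resolution_block(shots, table, cfg),
        "merged_metrics": _merged_metrics_block(cfg),
        "structural_comparison": _compare_block(cfg),
        "kinematics": _kinematics_block(cfg),
    }
    report["shot_table"] = table
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def render_report(report: dict, outdir, formats: tuple[str, ...] = ("json", "tsv"),
                  plots: bool = False) -> list[Path]:
    """Write the summary report as JSON (always) plus TSV tables and
    optional diagnostic plots.  Returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt not in ("json", "tsv"):
            raise ValueError(f"unknown report format {fmt!r}")

    path = out / "summary.json"
    with open(path, "w") as f:
        json.dump(_jsonable(report), f, indent=2)
    written.append(path)

    if "tsv" in formats:
        tables = {
            "per_run_rates.tsv": report["rates"]["per_run"],
            "shot_table.tsv": report.get("shot_table"),
        }
        for mode, binned in report.get("resolution", {}).get("binned", {}).items():
            tables[f"resolution_bins_{mode}.tsv"] = binned
        for name, blk in report.get("merged_metrics", {}).items():
            tables[f"merged_bins_{name}.tsv"] = blk.get("per_bin")
        for fname, df in tables.items():
            if isinstance(df, pd.DataFrame):
                p = out / fname
                df.to_csv(p, sep="\t", index=False)
                written.append(p)

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        per_run = report["rates"]["per_run"]
        fig, ax = plt.subplots()
        ax.plot(per_run["run"], per_run["hit_rate"], "o")
        ax.set_xlabel("run")
        ax.set_ylabel("hit rate")
        p = out / "hit_rate_per_run.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
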