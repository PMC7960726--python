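"""Synthetic X-ray pump-probe experiment with known ground truth.

Every downstream stage of the pipeline (jet-image analysis, shot
filtering, diffraction statistics, structural comparison) is exercised
on data produced here, so each generated artefact carries a ground-truth
record: planted gaps, jet widths, noisy diode traces, pump leakage,
abnormal jet morphology, per-shot true resolution, planted displacement
fields and compaction factors.

The emulated experiment: a ~5 um liquid microjet at ~50 m/s carries
microcrystals through two X-ray foci.  The pump pulse (mean energy
0.03 mJ) strikes first; after 122.5 ns a probe pulse, displaced 5 um
upstream, records diffraction.  Pump and probe pulse energies are
strongly anti-correlated (a property of the accelerator's two-bunch
mode), modelled as a truncated bivariate normal.  The per-image true
resolution follows a monotone phenomenology:

    d_true = d_base - s * (E_probe - <E_probe>) + c * E_pump,

floored at the optics-limited best resolution — more probe signal
improves resolution, pump-induced shock damage degrades it.  No physical
shock model is claimed; the functional form is the simplest one that
lets the binned-resolution and null-effect analyses be tested.

All randomness flows from a single seed through named substreams
(energies, traces, jets, peaks, reflections, structures), so identical
seed and configuration give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .diffraction_stats import ReflectionObservations, unique_reflections
from .shot_filtering import DiodeTrace
from .structural_comparison import CoordinateObservations, StructureModel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ShotRecord",
    "render_jet_image",
    "generate_shot_series",
    "wilson_intensities",
    "generate_reflection_observations",
    "make_reference_model",
    "generate_structure_pair",
    "write_series",
]

# substream labels -> indices mixed with the master seed
_STREAMS = {"energies": 1, "traces": 2, "jets": 3, "peaks": 4,
            "reflections": 5, "structures": 6}

DEFAULT_CELL = (55.7, 158.1, 67.7, 90.0, 90.0, 90.0)
DEFAULT_SPACE_GROUP = "P212121"


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pump-probe experiment.

    Defaults reproduce the study conditions: jet diameter 5 um at
    50 m/s, 122.5 ns delay with a 5 um upstream probe offset, pump pulse
    energy 0.03 +/- 0.02 mJ (truncated at zero), strongly anti-correlated
    pump/probe energies, a 19% base crystal-hit probability and a damage
    coefficient sized so the observed median resolution drop among
    surviving hits is ~0.3 A (shock-damaged crystals are preferentially
    lost from the hit pool, which biases surviving hits to low pump
    energy).
    """

    n_shots: int = 2000
    n_runs: int = 10
    mode_fraction_pump_probe: float = 0.7
    jet_speed: float = 50.0          # m/s
    jet_diameter: float = 5.0        # um
    pump_probe_delay: float = 122.5  # ns
    beam_offset: float = 5.0         # um, probe upstream of pump
    pump_energy_mean: float = 0.03   # mJ
    pump_energy_sd: float = 0.02     # mJ
    probe_energy_mean: float = 0.87  # mJ
    probe_energy_sd: float = 0.2     # mJ
    energy_anticorrelation: float = -0.7
    hit_probability_base: float = 0.19
    hit_suppression_energy: float = 0.08   # mJ; P(survive) = exp(-E_pump/this)
    damage_coefficient: float = 12.0       # A per mJ of pump energy
    signal_coefficient: float = 0.5        # A per mJ of probe energy
    base_resolution: float = 3.0           # A at the mean probe energy
    best_resolution: float = 2.5           # A, optics/crystal floor
    indexing_probability: float = 0.235
    probe_gap_probability: float = 0.7
    noise_trace_fraction: float = 0.05
    pump_leak_fraction: float = 0.05
    abnormal_jet_fraction: float = 0.05
    # imaging geometry
    um_per_px: float = 0.11
    image_height_px: int = 220
    image_width_px: int = 96
    pump_row_px: int = 160
    wiggle_amplitude_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = [
            "mode_fraction_pump_probe", "hit_probability_base",
            "indexing_probability", "probe_gap_probability",
            "noise_trace_fraction", "pump_leak_fraction",
            "abnormal_jet_fraction",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        positive = [
            "jet_speed", "jet_diameter", "pump_probe_delay",
            "pump_energy_mean", "pump_energy_sd", "probe_energy_mean",
            "probe_energy_sd", "hit_suppression_energy", "base_resolution",
            "best_resolution", "um_per_px",
        ]
        for name in positive:
            v = getattr(self, name)
            if not np.isfinite(v) or not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not np.isfinite(self.energy_anticorrelation) or not (
            -1.0 <= self.energy_anticorrelation <= 0.0
        ):
            raise ValueError(
                "energy_anticorrelation must lie in [-1, 0], got "
                f"{self.energy_anticorrelation}"
            )
        for name in ("damage_coefficient", "signal_coefficient", "beam_offset"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_shots < 1:
            raise ValueError(f"n_shots must be >= 1, got {self.n_shots}")

    @property
    def probe_row_px(self) -> int:
        return self.pump_row_px - int(round(self.beam_offset / self.um_per_px))

    @property
    def pump_position_um(self) -> float:
        return self.pump_row_px * self.um_per_px

    @property
    def probe_position_um(self) -> float:
        return self.probe_row_px * self.um_per_px


@dataclass
class GroundTruth:
    """Per-shot truth for the generated series (one record per shot)."""

    crystal_present: np.ndarray
    destroyed_by_pump: np.ndarray
    is_hit: np.ndarray
    trace_noisy: np.ndarray
    pump_leaked: np.ndarray
    abnormal_jet: list          # None or a type label per shot
    gaps_um: list               # list of (start, end) per shot
    jet_width_um: np.ndarray
    true_resolution: np.ndarray  # NaN for non-hits
    pump_position_um: float
    probe_position_um: float


@dataclass
class ShotRecord:
    """One X-ray event: energies, traces, jet image, peak list, flags."""

    shot_id: int
    run: int
    mode: str                   # "pump_probe" | "single"
    pump_energy: float
    probe_energy: float
    trace_unmasked: DiodeTrace
    trace_masked: DiodeTrace
    jet_image: np.ndarray
    peaks: pd.DataFrame         # columns d, I, sigma
    hit: bool
    indexed: bool


def render_jet_image(
    width_px: int,
    height_px: int,
    jet_axis_column: float,
    jet_width_px: float,
    gaps: list[tuple[int, int]] | None = None,
    breakup_row: int | None = None,
    wiggle_amplitude: float = 0.0,
    wiggle_wavelength: float = 60.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw a dark jet on a bright background as an 8-bit grayscale image.

    The jet axis is vertical; rows increase downstream.  Rows inside gap
    intervals take the background value; downstream of ``breakup_row``
    the continuous jet is replaced by short droplets.  Overlapping gap
    intervals are rejected.
    """
    if jet_width_px < 1:
        raise ValueError(f"jet_width_px must be >= 1, got {jet_width_px}")
    gaps = sorted(gaps or [])
    for (a1, b1), (a2, b2) in zip(gaps, gaps[1:]):
        if b1 > a2:
            raise ValueError(f"overlapping gap intervals ({a1},{b1}) and ({a2},{b2})")
    for a, b in gaps:
        if not (0 <= a < b <= height_px):
            raise ValueError(f"gap ({a},{b}) outside image of height {height_px}")

    rng = np.random.default_rng(seed)
    img = rng.normal(228.0, 4.0, size=(height_px, width_px))
    phase = rng.uniform(0, 2 * np.pi)
    half = jet_width_px / 2.0

    droplet_len, droplet_period = 5, 14
    for r in range(height_px):
        in_gap = any(a <= r < b for a, b in gaps)
        if in_gap:
            continue
        if breakup_row is not None and r >= breakup_row:
            if (r - breakup_row) % droplet_period >= droplet_len:
                continue
        centre = jet_axis_column + wiggle_amplitude * np.sin(
            2 * np.pi * r / wiggle_wavelength + phase
        )
        c0 = int(round(centre - half))
        c1 = int(round(centre + half))
        c0, c1 = max(c0, 0), min(c1, width_px)
        img[r, c0:c1] = rng.normal(45.0, 4.0, size=max(c1 - c0, 0))
    return np.clip(img, 0, 255).astype(np.uint8)


def _draw_energies(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Anti-correlated (pump, probe) energies, truncated at zero by redraw."""
    rho = cfg.energy_anticorrelation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    pump = np.empty(n)
    probe = np.empty(n)
    filled = 0
    while filled < n:
        z = rng.standard_normal((2, n - filled))
        zz = chol @ z
        p = cfg.pump_energy_mean + cfg.pump_energy_sd * zz[0]
        q = cfg.probe_energy_mean + cfg.probe_energy_sd * zz[1]
        ok = (p > 0) & (q > 0)
        m = int(ok.sum())
        pump[filled : filled + m] = p[ok]
        probe[filled : filled + m] = q[ok]
        filled += m
    return pump, probe


# diode-trace geometry (ns)
TRACE_DT_NS = 0.5
TRACE_N_SAMPLES = 600
TRACE_PRE_WINDOW = (0, 100)       # 50 ns before any pulse
PUMP_ARRIVAL_NS = 75.0
_PULSE_SIGMA_NS = 1.0
_VOLTS_PER_MJ = 10.0
_CLEAN_NOISE_V = 0.01
_NOISY_FACTOR = 10.0
_LEAK_AMP_V = 1.5


def _make_trace(
    rng: np.random.Generator,
    pump_amp: float,
    probe_amp: float,
    probe_arrival_ns: float,
    noisy: bool,
) -> DiodeTrace:
    t = np.arange(TRACE_N_SAMPLES) * TRACE_DT_NS
    noise_sd = _CLEAN_NOISE_V * (_NOISY_FACTOR if noisy else 1.0)
    v = rng.normal(0.0, noise_sd, size=TRACE_N_SAMPLES)
    for amp, arrival in ((pump_amp, PUMP_ARRIVAL_NS), (probe_amp, probe_arrival_ns)):
        if amp > 0:
            v += amp * np.exp(-0.5 * ((t - arrival) / _PULSE_SIGMA_NS) ** 2)
    return DiodeTrace(v, TRACE_DT_NS, TRACE_PRE_WINDOW)


def _make_peaks(
    rng: np.random.Generator,
    is_hit: bool,
    d_true: float,
    probe_ratio: float,
) -> pd.DataFrame:
    if is_hit:
        lam = 40.0 * max(probe_ratio, 0.45)
        n = max(int(rng.poisson(lam)), 10)
        # d sampled uniform in 1/d^3 between 20 A and the true limit
        s3 = rng.uniform(20.0**-3, d_true**-3, size=n)
        d = s3 ** (-1.0 / 3.0)
        snr = 4.0 * (d / d_true) ** 3 * rng.lognormal(0.0, 0.25, size=n)
    else:
        # spurious/background peaks only; by definition below the hit threshold
        n = min(int(rng.poisson(3.0)), 9)
        d = rng.uniform(3.0, 20.0, size=n)
        snr = rng.exponential(2.0, size=n)
    return pd.DataFrame({"d": d, "I": snr, "sigma": np.ones(n)})


_ABNORMAL_TYPES = ("over_wide", "upstream_gap", "upstream_breakup", "no_gaps")


def generate_shot_series(config: SimulationConfig) -> tuple[list[ShotRecord], GroundTruth]:
    """Generate a full series of synthetic shots with ground truth.

    Runs are homogeneous in mode: the first ``round(n_runs * fraction)``
    runs are pump-probe, the rest single-pulse.  Single-pulse shots draw
    their probe energy from the same marginal law as pump-probe shots
    (and carry zero pump energy), so a zero damage coefficient yields
    identical resolution distributions in the two modes.
    """
    cfg = config
    rng_e = _stream(cfg.seed, "energies")
    rng_t = _stream(cfg.seed, "traces")
    rng_j = _stream(cfg.seed, "jets")
    rng_p = _stream(cfg.seed, "peaks")

    n = cfg.n_shots
    n_pp_runs = int(round(cfg.n_runs * cfg.mode_fraction_pump_probe))
    runs = (np.arange(n) * cfg.n_runs) // n
    is_pp = runs < n_pp_runs

    pump, probe = _draw_energies(cfg, n, rng_e)
    pump = np.where(is_pp, pump, 0.0)

    probe_arrival = PUMP_ARRIVAL_NS + cfg.pump_probe_delay
    jet_width_px = cfg.jet_diameter / cfg.um_per_px
    gap_half_px = max(int(round(1.2 / cfg.um_per_px)), 2)  # ~2.4 um gaps
    axis_col = cfg.image_width_px / 2.0

    noisy = rng_t.random(n) < cfg.noise_trace_fraction
    leaked = is_pp & (rng_t.random(n) < cfg.pump_leak_fraction)

    # Abnormal jets are planted stratified per run, cycling through the
    # morphology types, so every run's width statistics see contamination.
    abnormal_type = np.full(n, None, dtype=object)
    for r in range(cfg.n_runs):
        idx = np.flatnonzero(runs == r)
        k = int(round(cfg.abnormal_jet_fraction * idx.size))
        if k:
            chosen = np.sort(rng_j.choice(idx, size=k, replace=False))
            for j, sid in enumerate(chosen):
                abnormal_type[sid] = _ABNORMAL_TYPES[j % len(_ABNORMAL_TYPES)]
    crystal = rng_p.random(n) < cfg.hit_probability_base
    survived = np.where(
        is_pp, rng_p.random(n) < np.exp(-pump / cfg.hit_suppression_energy), True
    )
    is_hit = crystal & survived
    indexed = is_hit & (rng_p.random(n) < cfg.indexing_probability)

    d_true = np.maximum(
        cfg.base_resolution
        - cfg.signal_coefficient * (probe - cfg.probe_energy_mean)
        + cfg.damage_coefficient * pump,
        cfg.best_resolution,
    )
    d_true = np.where(is_hit, d_true, np.nan)

    shots: list[ShotRecord] = []
    gt_gaps: list = []
    gt_width = np.empty(n)

    for i in range(n):
        mode = "pump_probe" if is_pp[i] else "single"

        # --- jet geometry -------------------------------------------------
        abnormal = abnormal_type[i]
        # small natural width variation; abnormal jets are grossly wider
        width_px = jet_width_px * (1.0 + rng_j.normal(0.0, 0.015))
        breakup_row = None
        gap_rows: list[tuple[int, int]] = []
        if is_pp[i]:
            gap_rows.append((cfg.pump_row_px - gap_half_px, cfg.pump_row_px + gap_half_px))
            if rng_j.random() < cfg.probe_gap_probability:
                gap_rows.append(
                    (cfg.probe_row_px - gap_half_px, cfg.probe_row_px + gap_half_px)
                )
        else:
            gap_rows.append((cfg.probe_row_px - gap_half_px, cfg.probe_row_px + gap_half_px))
        if abnormal is not None:
            if abnormal == "over_wide":
                width_px = jet_width_px * 1.8
            elif abnormal == "upstream_gap":
                # pre-existing discontinuity well upstream of the probe
                up_row = cfg.probe_row_px - int(6.0 / cfg.um_per_px)
                gap_rows.append((up_row - gap_half_px, up_row + gap_half_px))
            elif abnormal == "upstream_breakup":
                breakup_row = max(cfg.probe_row_px - int(10.0 / cfg.um_per_px), 12)
                gap_rows = []
            elif abnormal == "no_gaps":
                gap_rows = []
        gap_rows = sorted(gap_rows)
        img = render_jet_image(
            cfg.image_width_px,
            cfg.image_height_px,
            axis_col,
            width_px,
            gaps=gap_rows,
            breakup_row=breakup_row,
            wiggle_amplitude=cfg.wiggle_amplitude_px,
            seed=int(rng_j.integers(2**31)),
        )
        gt_gaps.append(
            [(a * cfg.um_per_px, b * cfg.um_per_px) for a, b in gap_rows]
        )
        gt_width[i] = width_px * cfg.um_per_px

        # --- diode traces --------------------------------------------------
        unmasked = _make_trace(
            rng_t,
            pump_amp=_VOLTS_PER_MJ * pump[i],
            probe_amp=_VOLTS_PER_MJ * probe[i],
            probe_arrival_ns=probe_arrival,
            noisy=bool(noisy[i]),
        )
        masked = _make_trace(
            rng_t,
            pump_amp=_LEAK_AMP_V if leaked[i] else 0.0,
            probe_amp=_VOLTS_PER_MJ * probe[i],
            probe_arrival_ns=probe_arrival,
            noisy=bool(noisy[i]),
        )
        masked.masked = True

        # --- peak list -----------------------------------------------------
        peaks = _make_peaks(
            rng_p, bool(is_hit[i]), float(d_true[i]) if is_hit[i] else 3.0,
            probe[i] / cfg.probe_energy_mean,
        )

        shots.append(
            ShotRecord(
                shot_id=i,
                run=int(runs[i]),
                mode=mode,
                pump_energy=float(pump[i]),
                probe_energy=float(probe[i]),
                trace_unmasked=unmasked,
                trace_masked=masked,
                jet_image=img,
                peaks=peaks,
                hit=bool(is_hit[i]),
                indexed=bool(indexed[i]),
            )
        )

    gt = GroundTruth(
        crystal_present=crystal,
        destroyed_by_pump=crystal & ~survived,
        is_hit=is_hit,
        trace_noisy=noisy,
        pump_leaked=leaked,
        abnormal_jet=list(abnormal_type),
        gaps_um=gt_gaps,
        jet_width_um=gt_width,
        true_resolution=d_true,
        pump_position_um=cfg.pump_position_um,
        probe_position_um=cfg.probe_position_um,
    )
    return shots, gt


def wilson_intensities(
    cell=DEFAULT_CELL,
    space_group: str = DEFAULT_SPACE_GROUP,
    d_min: float = 2.5,
    d_max: float = 30.0,
    b_iso: float = 47.4,
    base_intensity: float = 1e4,
    dispersion: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference intensities I = I0 * exp(-2*B*(1/(2d))^2) on the unique list.

    With ``dispersion`` set, each intensity is additionally multiplied by
    a unit-mean exponential variate (acentric Wilson statistics);
    otherwise intensities follow the smooth Wilson envelope exactly, so a
    planted B is recoverable to numerical precision.
    """
    cellg = gemmi.UnitCell(*cell) if not isinstance(cell, gemmi.UnitCell) else cell
    hkls = sorted(unique_reflections(cellg, space_group, d_min, d_max))
    d = np.array([cellg.calculate_d(h) for h in hkls])
    inten = base_intensity * np.exp(-2.0 * b_iso * (0.5 / d) ** 2)
    if dispersion:
        rng = _stream(seed, "reflections")
        inten = inten * rng.exponential(1.0, size=inten.size)
    df = pd.DataFrame(hkls, columns=["h", "k", "l"])
    df["I"] = inten
    df["d"] = d
    return df


def generate_reflection_observations(
    model_intensities: pd.DataFrame,
    n_images: int,
    scale_sd: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
    obs_fraction: float = 0.3,
    cell=DEFAULT_CELL,
    space_group: str = DEFAULT_SPACE_GROUP,
    relative_noise: bool = True,
) -> ReflectionObservations:
    """Per-image observations of a reference intensity list.

    Each image observes a random subset (``obs_fraction``) of the unique
    reflections through a multiplicative per-image scale
    exp(N(0, scale_sd)) with additive Gaussian noise; observed indices
    are pushed through a random point-group symmetry operation (random
    sign combination, valid under mmm) so that merging must reduce them
    back to the asymmetric unit.  Noise is relative (sd = noise_sd * I)
    by default.  At scale_sd = noise_sd = 0 every observation equals the
    reference intensity exactly.
    """
    if n_images < 2:
        raise ValueError(f"n_images must be >= 2 (half-set split), got {n_images}")
    if (model_intensities["I"] <= 0).any():
        raise ValueError("model intensities must be positive")
    rng = _stream(seed, "reflections")
    hkl = model_intensities[["h", "k", "l"]].to_numpy(dtype=int)
    itrue = model_intensities["I"].to_numpy(dtype=float)
    n_ref = len(itrue)
    frames = []
    for img in range(n_images):
        sel = rng.random(n_ref) < obs_fraction
        if not sel.any():
            sel[rng.integers(n_ref)] = True
        m = int(sel.sum())
        scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd > 0 else 1.0
        sd = noise_sd * (itrue[sel] if relative_noise else 1.0)
        iobs = scale * itrue[sel] + (rng.normal(0.0, 1.0, size=m) * sd if noise_sd > 0 else 0.0)
        signs = rng.integers(0, 2, size=(m, 3)) * 2 - 1  # mmm sign combos
        frames.append(
            pd.DataFrame(
                {
                    "h": hkl[sel, 0] * signs[:, 0],
                    "k": hkl[sel, 1] * signs[:, 1],
                    "l": hkl[sel, 2] * signs[:, 2],
                    "I": iobs,
                    "sigma": np.where(sd > 0, sd, 1.0),
                    "image_id": img,
                }
            )
        )
    return ReflectionObservations(
        pd.concat(frames, ignore_index=True), cell, space_group
    )


def make_reference_model(
    chain_lengths: tuple[int, ...] = (141, 146, 141, 146),
    seed: int = 0,
) -> StructureModel:
    """Synthetic C-alpha-only tetramer used as the comparison reference.

    Four helical chains (alpha-helix geometry: 1.5 A rise, 100 deg turn,
    2.3 A radius) arranged around a central channel — a cartoon of a
    haemoglobin-like tetramer (2 x 141 + 2 x 146 = 574 residues), with a
    small coordinate jitter so the geometry is non-degenerate.
    """
    rng = _stream(seed, "structures")
    chains = "ABCDEFGH"[: len(chain_lengths)]
    offsets = [(14.0, 14.0, 0.0), (-14.0, 14.0, 6.0), (-14.0, -14.0, 0.0), (14.0, -14.0, 6.0)]
    rows = []
    for ci, (chain, n_res) in enumerate(zip(chains, chain_lengths)):
        ox, oy, oz = offsets[ci % len(offsets)]
        i = np.arange(n_res)
        theta = np.deg2rad(100.0) * i          # local helix turn
        phi = 2 * np.pi * i / n_res            # superhelical path, closes on itself
        major = 11.0 + 2.3 * np.cos(theta)
        x = ox + major * np.cos(phi) + rng.normal(0, 0.2, n_res)
        y = oy + major * np.sin(phi) + rng.normal(0, 0.2, n_res)
        z = oz + 2.3 * np.sin(theta) + 4.0 * np.sin(2 * phi) + rng.normal(0, 0.2, n_res)
        for j in range(n_res):
            rows.append(
                {
                    "chain": chain,
                    "resnum": j + 1,
                    "resname": "ALA",
                    "atom": "CA",
                    "x": x[j],
                    "y": y[j],
                    "z": z[j],
                    "b": 30.0,
                    "occ": 1.0,
                }
            )
    return StructureModel(pd.DataFrame(rows), DEFAULT_CELL, DEFAULT_SPACE_GROUP)


@dataclass
class StructurePairTruth:
    """Perturbed model plus the planted truth behind it."""

    perturbed: StructureModel
    observations: CoordinateObservations
    true_field: np.ndarray       # (n_atoms, 3) planted displacement
    compaction: float
    noise_sd: float


def _correlated_field(
    model: StructureModel,
    amplitude: float,
    period_res: float,
    n_modes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth sequence-correlated vector field: low-frequency sinusoids
    of the residue index, independent phases per chain/component/mode."""
    atoms = model.atoms
    field = np.zeros((len(atoms), 3))
    if amplitude == 0:
        return field
    for chain, idx in atoms.groupby("chain").groups.items():
        i = np.arange(len(idx), dtype=float)
        for comp in range(3):
            for mode in range(1, n_modes + 1):
                phase = rng.uniform(0, 2 * np.pi)
                field[np.asarray(idx), comp] += (
                    amplitude / n_modes
                ) * np.sin(2 * np.pi * mode * i / period_res + phase)
    return field


def generate_structure_pair(
    reference: StructureModel,
    displacement_amplitude: float = 0.15,
    displacement_period_res: float = 40.0,
    n_modes: int = 2,
    compaction: float = 0.995,
    noise_sd: float = 0.1,
    n_images: int = 50,
    seed: int = 0,
) -> StructurePairTruth:
    """Perturbed copy of a reference model plus per-image observations.

    The perturbed model is the reference scaled by ``compaction`` about
    its centroid plus a smooth, sequence-correlated displacement field
    (sinusoids of the residue index with period ``displacement_period_res``
    residues).  Per-image coordinate observations add i.i.d. Gaussian
    noise of ``noise_sd`` A to each coordinate — the input contract of
    the bootstrap uncertainty estimator, whose per-coordinate sampling SD
    is then exactly noise_sd / sqrt(n_images).
    """
    if not 0.9 < compaction < 1.1:
        raise ValueError(f"compaction must lie in (0.9, 1.1), got {compaction}")
    if len(reference.atoms) == 0:
        raise ValueError("empty reference model")
    rng = _stream(seed, "structures")
    xyz = reference.coords(None)
    centroid = xyz.mean(axis=0)
    field = _correlated_field(
        reference, displacement_amplitude, displacement_period_res, n_modes, rng
    )
    perturbed_xyz = centroid + compaction * (xyz - centroid) + field
    perturbed = reference.with_coords(perturbed_xyz)
    obs = perturbed_xyz[None, :, :] + rng.normal(
        0.0, noise_sd, size=(n_images, len(xyz), 3)
    )
    observations = CoordinateObservations(
        coords=obs, image_ids=list(range(n_images)), template=perturbed
    )
    return StructurePairTruth(
        perturbed=perturbed,
        observations=observations,
        true_field=field,
        compaction=compaction,
        noise_sd=noise_sd,
    )


def write_series(shots: list[ShotRecord], gt: GroundTruth, outdir) -> None:
    """Write a generated series to disk (TSV/PNG/HDF5/JSON)."""
    import h5py
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(outdir)
    (out / "jets").mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "shot_id": [s.shot_id for s in shots],
            "run": [s.run for s in shots],
            "mode": [s.mode for s in shots],
            "pump_energy_mj": [s.pump_energy for s in shots],
            "probe_energy_mj": [s.probe_energy for s in shots],
            "n_peaks": [len(s.peaks) for s in shots],
            "hit": [s.hit for s in shots],
            "indexed": [s.indexed for s in shots],
        }
    )
    table.to_csv(out / "shots.tsv", sep="\t", index=False)

    peak_rows = []
    for s in shots:
        p = s.peaks.copy()
        p.insert(0, "shot_id", s.shot_id)
        peak_rows.append(p)
    pd.concat(peak_rows, ignore_index=True).to_csv(
        out / "peaks.tsv", sep="\t", index=False
    )

    with h5py.File(out / "traces.h5", "w") as f:
        f.create_dataset(
            "unmasked", data=np.stack([s.trace_unmasked.samples for s in shots])
        )
        f.create_dataset(
            "masked", data=np.stack([s.trace_masked.samples for s in shots])
        )
        f.attrs["dt_ns"] = TRACE_DT_NS
        f.attrs["pre_pulse_window"] = TRACE_PRE_WINDOW

    for s in shots:
        iio.imwrite(out / "jets" / f"shot_{s.shot_id:06d}.png", s.jet_image)

    truth = {
        "crystal_present": gt.crystal_present.tolist(),
        "destroyed_by_pump": gt.destroyed_by_pump.tolist(),
        "is_hit": gt.is_hit.tolist(),
        "trace_noisy": gt.trace_noisy.tolist(),
        "pump_leaked": gt.pump_leaked.tolist(),
        "abnormal_jet": gt.abnormal_jet,
        "gaps_um": gt.gaps_um,
        "jet_width_um": gt.jet_width_um.tolist(),
        "true_resolution": [
            None if not np.isfinite(v) else float(v) for v in gt.true_resolution
        ],
        "pump_position_um": gt.pump_position_um,
        "probe_position_um": gt.probe_position_um,
    }
    with open(out / "ground_truth.json", "w") as f:
        json.dump(truth, f)
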