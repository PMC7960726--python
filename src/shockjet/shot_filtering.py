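"""Shot-acceptance rules and hit/indexing accounting.

Three independent filters decide whether a recorded X-ray event enters
the analysis:

* **diode noise** — the pre-pulse standard deviation of the photodiode
  voltage trace must not exceed the clean-population mean plus three of
  its standard deviations (the clean population itself is estimated
  robustly by median/MAD trimming, since it is circularly defined);
* **pump leakage** — on pump-probe shots the Fe-foil-masked diode must
  show no pump-pulse signal: the integrated pump-window signal must stay
  below the all-shot mean plus 1.5 standard deviations;
* **jet morphology** — the projected jet width must lie within one
  standard deviation of the run median, one or two explosion gaps must be
  visible, and the jet must be fully continuous upstream of the pumped
  segment so a shock can propagate to the probed region.

A diffraction image is a crystal hit when it contains at least 10 peaks.
Hit rates are counted over all shots; indexing rates over filtered hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .jet_imaging import JetFeatures

__all__ = [
    "DiodeTrace",
    "FilterDecision",
    "trace_noise_std",
    "diode_noise_filter",
    "pump_window_signal",
    "pump_leakage_filter",
    "morphology_filter",
    "classify_hit",
    "rate_report",
]

HIT_PEAK_THRESHOLD = 10


@dataclass
class DiodeTrace:
    """Fast-photodiode voltage trace for one shot.

    ``pre_pulse_window`` is a half-open (start, end) sample-index range
    that ends before the first pulse arrives; ``masked`` marks the diode
    covered with an Fe foil (blind to the above-edge pump photons unless
    the pump photon energy leaks below the edge).
    """

    samples: np.ndarray
    dt_ns: float
    pre_pulse_window: tuple[int, int]
    masked: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        a, b = self.pre_pulse_window
        if not (0 <= a < b <= len(self.samples)):
            raise ValueError(f"pre_pulse_window {self.pre_pulse_window} outside trace")


@dataclass
class FilterDecision:
    """Outcome of the acceptance rules for one shot."""

    shot_id: int | str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def trace_noise_std(trace: DiodeTrace) -> float:
    """Population SD of the voltage over the pre-pulse window (volts)."""
    a, b = trace.pre_pulse_window
    if b - a < 8:
        raise ValueError(f"pre-pulse window has {b - a} samples; need >= 8")
    return float(np.std(trace.samples[a:b]))  # ddof=0 by convention


def diode_noise_filter(
    traces: list[DiodeTrace] | np.ndarray, n_sigma: float = 3.0
) -> np.ndarray:
    """Keep flags for the electronic-noise rule over a shot population.

    Two passes: (1) the clean ("noise-less") population is the set of
    per-shot noise SDs within 3 scaled MADs of their median; (2) a shot
    is excluded when its noise SD is strictly greater than
    ``mean(clean) + n_sigma * SD(clean)``.

    Accepts either DiodeTrace objects or a precomputed array of noise SDs.
    """
    if isinstance(traces, np.ndarray):
        sds = np.asarray(traces, dtype=float)
    else:
        sds = np.array([trace_noise_std(t) for t in traces])
    if len(sds) < 50:
        raise ValueError(f"need >= 50 shots for population statistics, got {len(sds)}")
    med = np.median(sds)
    mad = np.median(np.abs(sds - med)) * 1.4826
    clean = sds[np.abs(sds - med) <= 3.0 * mad] if mad > 0 else sds[sds == med]
    if clean.size == 0:
        raise ValueError("no clean traces identified; population estimate impossible")
    threshold = clean.mean() + n_sigma * clean.std()
    keep = ~(sds > threshold)  # strict >: a shot exactly at threshold is kept
    if not keep.any():
        raise ValueError("all traces excluded; population estimate impossible")
    return keep


def pump_window_signal(
    trace: DiodeTrace, pump_arrival_ns: float, half_window_ns: float = 3.0
) -> float:
    """Integrated signal (V*ns) in a window around the pump arrival time.

    The half-window defaults to three times a 1 ns effective diode
    response so the whole pulse response is captured at the trace's
    sampling interval.
    """
    t = np.arange(len(trace.samples)) * trace.dt_ns
    sel = np.abs(t - pump_arrival_ns) <= half_window_ns
    if not sel.any():
        raise ValueError("pump window lies outside the trace")
    return float(np.trapezoid(trace.samples[sel], dx=trace.dt_ns))


def pump_leakage_filter(
    masked_pump_signals: np.ndarray, n_sigma: float = 1.5
) -> np.ndarray:
    """Keep flags for the pump-leakage rule over all pump-probe shots.

    A shot is kept when its masked-diode pump-window signal is strictly
    below ``mean + n_sigma * SD`` over all shots.  A zero-variance
    population shows no leakage contrast, so everything is kept.
    """
    s = np.asarray(masked_pump_signals, dtype=float)
    if s.size == 0:
        raise ValueError("empty signal population")
    sd = s.std()
    if sd == 0:
        return np.ones(s.size, dtype=bool)
    return s < s.mean() + n_sigma * sd


def morphology_filter(
    features: dict[int | str, JetFeatures | None],
    run_of: dict[int | str, int],
    pump_position_um: float,
    probe_position_um: float | None = None,
    position_tol_um: float = 3.0,
    min_run_size: int = 20,
) -> dict[int | str, FilterDecision]:
    """Jet-shape acceptance per shot, with run-relative width statistics.

    Pass criteria: projected width within one (population) SD of the run
    median; one or two gaps (pump, or pump and probe); and no gap or
    break-up upstream of the pump position other than the probe-pulse gap
    (a probe gap, at ``probe_position_um`` within ``position_tol_um``, is
    expected and does not need to exist).  Missing or jet-free images
    fail with reason ``no_jet``.
    """
    ids = list(features)
    widths_by_run: dict[int, list[float]] = {}
    for sid in ids:
        f = features[sid]
        if f is not None and not f.no_jet:
            widths_by_run.setdefault(run_of[sid], []).append(f.projected_width_um)

    run_stats = {}
    for run, ws in widths_by_run.items():
        if len(ws) < min_run_size:
            raise ValueError(
                f"run {run} has {len(ws)} usable shots; need >= {min_run_size} "
                "for stable median/SD"
            )
        arr = np.asarray(ws)
        run_stats[run] = (float(np.median(arr)), float(arr.std()))

    decisions: dict[int | str, FilterDecision] = {}
    for sid in ids:
        f = features[sid]
        reasons: list[str] = []
        if f is None or f.no_jet:
            decisions[sid] = FilterDecision(sid, ["no_jet"])
            continue
        med, sd = run_stats[run_of[sid]]
        if abs(f.projected_width_um - med) > sd:
            reasons.append("abnormal_width")
        if f.n_gaps not in (1, 2):
            reasons.append("wrong_gap_count")
        else:
            upstream_ok = True
            for start, end in f.gaps_um:
                centre = 0.5 * (start + end)
                if centre >= pump_position_um - position_tol_um:
                    continue  # at or downstream of the pumped segment
                is_probe_gap = (
                    probe_position_um is not None
                    and abs(centre - probe_position_um) <= position_tol_um
                )
                if not is_probe_gap:
                    upstream_ok = False
            limit = pump_position_um - position_tol_um
            if probe_position_um is not None:
                limit = min(limit, probe_position_um - position_tol_um)
            if f.breakup_um is not None and f.breakup_um < limit:
                upstream_ok = False
            if not upstream_ok:
                reasons.append("discontinuous_upstream")
        decisions[sid] = FilterDecision(sid, reasons)
    return decisions


def classify_hit(peak_list) -> bool:
    """A diffraction image is a crystal hit iff it has >= 10 peaks."""
    return len(peak_list) >= HIT_PEAK_THRESHOLD


def rate_report(shots: pd.DataFrame) -> dict:
    """Per-run and pooled hit/indexing rates.

    Parameters
    ----------
    shots:
        One row per shot with columns ``run``, ``hit`` (bool),
        ``indexed`` (bool) and ``passed_filter`` (bool).  Hit rates count
        all shots; indexing rates count indexed images among *filtered*
        hits only.

    Returns
    -------
    dict with ``per_run`` (DataFrame), ``pooled`` and ``average`` blocks.
    Rates are fractions in [0, 1]; undefined rates (zero denominator) are
    reported as None.
    """
    required = {"run", "hit", "indexed", "passed_filter"}
    missing = required - set(shots.columns)
    if missing:
        raise ValueError(f"shot table missing columns: {sorted(missing)}")

    rows = []
    for run, grp in shots.groupby("run"):
        n_shots = len(grp)
        if n_shots == 0:
            continue
        n_hits = int(grp["hit"].sum())
        filtered_hits = grp[grp["hit"] & grp["passed_filter"]]
        n_filtered = len(filtered_hits)
        n_indexed = int(filtered_hits["indexed"].sum())
        rows.append(
            {
                "run": run,
                "n_shots": n_shots,
                "n_hits": n_hits,
                "n_filtered_hits": n_filtered,
                "n_indexed": n_indexed,
                "hit_rate": n_hits / n_shots,
                "indexing_rate": n_indexed / n_filtered if n_filtered else None,
            }
        )
    per_run = pd.DataFrame(rows)
    if per_run.empty:
        raise ValueError("no non-empty runs")

    pooled_shots = int(per_run["n_shots"].sum())
    pooled_hits = int(per_run["n_hits"].sum())
    pooled_filtered = int(per_run["n_filtered_hits"].sum())
    pooled_indexed = int(per_run["n_indexed"].sum())
    idx_rates = per_run["indexing_rate"].dropna()
    return {
        "per_run": per_run,
        "pooled": {
            "n_shots": pooled_shots,
            "n_hits": pooled_hits,
            "n_filtered_hits": pooled_filtered,
            "n_indexed": pooled_indexed,
            "hit_rate": pooled_hits / pooled_shots,
            "indexing_rate": pooled_indexed / pooled_filtered if pooled_filtered else None,
        },
        "average": {
            "hit_rate": float(per_run["hit_rate"].mean()),
            "indexing_rate": float(idx_rates.mean()) if len(idx_rates) else None,
        },
    }
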