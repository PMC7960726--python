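"""Per-image resolution and merged-intensity quality statistics.

The quality of serial-crystallography data is summarised two ways:

* per diffraction image — the best resolution among indexed peaks with a
  signal-to-noise ratio I/sigma(I) >= 4, optionally binned by probe pulse
  energy to separate signal effects from damage effects;
* per merged data set — half-data-set agreement metrics (Rsplit, CC1/2
  and the derived CC*), mean I/sigma(I), completeness against the full
  symmetry-unique reflection list, Wilson B, and an automatic
  high-resolution cutoff at the bin where mean I/sigma(I) falls to 1.0.

Observations are merged without scaling or partiality correction:
the merged intensity of a unique reflection is the unweighted mean of its
observations.  Symmetry handling (reduction to the reciprocal-space
asymmetric unit, systematic absences of screw axes) is delegated to
gemmi.  Resolution bins are equal-volume in 1/d^3 unless stated
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ReflectionObservations",
    "MergedSet",
    "image_resolution",
    "bin_by_probe_energy",
    "equalize_energy_distributions",
    "merge",
    "half_set_metrics",
    "cc_star",
    "completeness",
    "unique_reflections",
    "wilson_b",
    "auto_resolution_cutoff",
]

OBS_COLUMNS = ["h", "k", "l", "I", "sigma", "image_id"]


def _as_cell(cell) -> gemmi.UnitCell:
    if isinstance(cell, gemmi.UnitCell):
        return cell
    return gemmi.UnitCell(*cell)


@dataclass
class ReflectionObservations:
    """Per-image reflection observations (h, k, l, I, sigma, image_id)."""

    df: pd.DataFrame
    cell: gemmi.UnitCell
    space_group: str = "P212121"

    def __post_init__(self) -> None:
        self.cell = _as_cell(self.cell)
        missing = set(OBS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")

    @property
    def n_images(self) -> int:
        return self.df["image_id"].nunique()

    def to_text(self, path) -> None:
        self.df[OBS_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_text(cls, path, cell, space_group="P212121") -> "ReflectionObservations":
        return cls(pd.read_csv(path, sep="\t"), cell, space_group)


@dataclass
class MergedSet:
    """Merged unique reflections with multiplicities and d-spacings."""

    records: pd.DataFrame  # h k l I sigma multiplicity d
    cell: gemmi.UnitCell
    space_group: str

    @property
    def d_min(self) -> float:
        return float(self.records["d"].min())

    @property
    def d_max(self) -> float:
        return float(self.records["d"].max())


def image_resolution(peak_list, snr_threshold: float = 4.0) -> float | None:
    """Best (minimum) d among peaks with I/sigma(I) >= threshold, in A.

    ``peak_list`` is a DataFrame or record array with columns ``d``,
    ``I`` and ``sigma``.  Returns None when no peak qualifies.
    """
    if len(peak_list) == 0:
        raise ValueError("empty peak list")
    d = np.asarray(peak_list["d"], dtype=float)
    snr = np.asarray(peak_list["I"], dtype=float) / np.asarray(
        peak_list["sigma"], dtype=float
    )
    ok = snr >= snr_threshold
    if not ok.any():
        return None
    return float(d[ok].min())


def bin_by_probe_energy(
    probe_energies: np.ndarray, resolutions: np.ndarray, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Median per-image resolution binned by probe pulse energy.

    Returns one row per bin with ``n``, ``median_resolution`` and the
    error of the mean (sample SD / sqrt(n); None when n < 2).  Empty bins
    are reported with n = 0 and no statistics.
    """
    e = np.asarray(probe_energies, dtype=float)
    r = np.asarray(resolutions, dtype=float)
    if e.shape != r.shape:
        raise ValueError("energies and resolutions must have equal length")
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (e >= lo) & (e < hi)
        vals = r[sel]
        rows.append(
            {
                "e_lo": lo,
                "e_hi": hi,
                "n": int(sel.sum()),
                "median_resolution": float(np.median(vals)) if vals.size else None,
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size >= 2
                else None,
            }
        )
    return pd.DataFrame(rows)


def equalize_energy_distributions(
    energies_a: np.ndarray,
    energies_b: np.ndarray,
    bin_edges: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample both sets so their binned energy histograms match.

    Within each bin both sets are randomly subsampled, without
    replacement, to the smaller of the two bin counts.  Returns positional
    index arrays into the two inputs (sorted, so relative order is kept).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(energies_a, dtype=float)
    b = np.asarray(energies_b, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    keep_a: list[np.ndarray] = []
    keep_b: list[np.ndarray] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ia = np.flatnonzero((a >= lo) & (a < hi))
        ib = np.flatnonzero((b >= lo) & (b < hi))
        m = min(ia.size, ib.size)
        if m == 0:
            continue
        keep_a.append(np.sort(rng.choice(ia, size=m, replace=False)))
        keep_b.append(np.sort(rng.choice(ib, size=m, replace=False)))
    cat = lambda parts: np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
    return cat(keep_a), cat(keep_b)


def _to_asu(df: pd.DataFrame, space_group: str) -> pd.DataFrame:
    sg = gemmi.SpaceGroup(space_group)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    out = np.empty_like(hkl)
    cache: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    for i, (h, k, l) in enumerate(map(tuple, hkl)):
        key = (h, k, l)
        if key not in cache:
            cache[key] = tuple(asu.to_asu(key, ops)[0])
        out[i] = cache[key]
    df = df.copy()
    df[["h", "k", "l"]] = out
    return df


def merge(observations: ReflectionObservations) -> MergedSet:
    """Merge observations to unique reflections (no scaling).

    Each observation is mapped to the reciprocal-space asymmetric unit of
    the space group's point group; the merged intensity is the unweighted
    mean, sigma is the sample SD of the observations divided by
    sqrt(multiplicity) (NaN for multiplicity 1), and multiplicities are
    recorded so that their sum equals the number of observations merged.
    """
    df = _to_asu(observations.df, observations.space_group)
    grouped = df.groupby(["h", "k", "l"])["I"]
    rec = grouped.agg(I="mean", multiplicity="size", sd=lambda x: x.std(ddof=1))
    rec = rec.reset_index()
    rec["sigma"] = rec["sd"] / np.sqrt(rec["multiplicity"])
    rec = rec.drop(columns="sd")
    cell = observations.cell
    rec["d"] = [
        cell.calculate_d((int(h), int(k), int(l)))
        for h, k, l in rec[["h", "k", "l"]].to_numpy()
    ]
    return MergedSet(rec, cell, observations.space_group)


def _volume_bin_edges(d_max: float, d_min: float, n_bins: int) -> np.ndarray:
    """Bin edges in d, equal-volume in 1/d^3, from low to high resolution."""
    s3 = np.linspace(d_max**-3, d_min**-3, n_bins + 1)
    return s3 ** (-1.0 / 3.0)


def _assign_volume_bins(d: np.ndarray, edges_d: np.ndarray) -> np.ndarray:
    # edges_d decreases in d; in 1/d^3 the edges increase monotonically
    s3 = 1.0 / d**3
    idx = np.searchsorted(edges_d**-3.0, s3, side="right") - 1
    return np.clip(idx, 0, len(edges_d) - 2)


def _merged_snr(records: pd.DataFrame) -> np.ndarray:
    """Per-reflection I/sigma of a merged set; NaN where sigma is unusable."""
    sigma = records["sigma"].to_numpy()
    ok = np.isfinite(sigma) & (sigma > 0)
    return np.where(ok, records["I"].to_numpy() / np.where(ok, sigma, 1.0), np.nan)


def cc_star(cc_half: float) -> float:
    """CC* = sqrt(2*CC1/2 / (1 + CC1/2)); NaN for CC1/2 <= 0."""
    if cc_half is None or not np.isfinite(cc_half) or cc_half <= 0:
        return float("nan")
    return math.sqrt(2.0 * cc_half / (1.0 + cc_half))


def _pair_metrics(i1: np.ndarray, i2: np.ndarray) -> dict:
    denom = 0.5 * float(np.sum(i1 + i2))
    rsplit = (
        100.0 * float(np.sum(np.abs(i1 - i2))) / denom / math.sqrt(2.0)
        if denom != 0
        else float("nan")
    )
    if i1.size >= 2 and np.std(i1) > 0 and np.std(i2) > 0:
        cc = float(np.corrcoef(i1, i2)[0, 1])
    elif i1.size >= 2 and np.array_equal(i1, i2):
        cc = 1.0
    else:
        cc = float("nan")
    return {"rsplit_pct": rsplit, "cc_half": cc, "cc_star": cc_star(cc)}


def half_set_metrics(
    observations: ReflectionObservations, n_bins: int = 10, seed: int = 0
) -> dict:
    """Half-data-set agreement metrics: Rsplit, CC1/2, CC*, mean I/sigma.

    Whole images are randomly assigned to two half sets (seeded); each
    half is merged independently and compared on the reflections present
    in both halves.  Rsplit = 2^(-1/2) * sum|I1 - I2| / (0.5*sum(I1+I2)),
    in percent; CC1/2 is the Pearson correlation of the half-set merged
    intensities; CC* = sqrt(2*CC1/2/(1+CC1/2)).  Mean I/sigma(I) comes
    from the full merged set.  Returned dict has ``overall`` and a
    ``per_bin`` DataFrame over equal-volume resolution bins; bins where a
    half has no common reflections carry NaN metrics.
    """
    images = np.asarray(sorted(observations.df["image_id"].unique()))
    if images.size < 2:
        raise ValueError(f"need >= 2 images for a half-set split, got {images.size}")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(images.size) % 2
    half_of = dict(zip(images.tolist(), assignment))
    mask = observations.df["image_id"].map(half_of).to_numpy() == 0

    halves = []
    for m in (mask, ~mask):
        sub = ReflectionObservations(
            observations.df[m], observations.cell, observations.space_group
        )
        halves.append(merge(sub).records.set_index(["h", "k", "l"]))
    full = merge(observations)

    joined = halves[0].join(halves[1], lsuffix="_1", rsuffix="_2", how="inner")
    if joined.empty:
        raise ValueError("half sets share no reflections")
    i1 = joined["I_1"].to_numpy()
    i2 = joined["I_2"].to_numpy()
    d = joined["d_1"].to_numpy()

    fullrec = full.records
    snr = _merged_snr(fullrec)

    overall = _pair_metrics(i1, i2)
    overall["mean_i_over_sigma"] = float(np.nanmean(snr)) if np.isfinite(snr).any() else None
    overall["n_common"] = int(joined.shape[0])

    edges = _volume_bin_edges(float(d.max()), float(d.min()), n_bins)
    idx = _assign_volume_bins(d, edges)
    idx_full = _assign_volume_bins(fullrec["d"].to_numpy(), edges)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        row = {
            "d_lo": float(edges[b]),
            "d_hi": float(edges[b + 1]),
            "n_common": int(sel.sum()),
        }
        if sel.any():
            row.update(_pair_metrics(i1[sel], i2[sel]))
        else:
            row.update({"rsplit_pct": np.nan, "cc_half": np.nan, "cc_star": np.nan})
        fsel = (idx_full == b) & np.isfinite(snr)
        row["mean_i_over_sigma"] = float(np.mean(snr[fsel])) if fsel.any() else np.nan
        rows.append(row)
    return {"overall": overall, "per_bin": pd.DataFrame(rows)}


def unique_reflections(
    cell, space_group: str, d_min: float, d_max: float = float("inf")
) -> set[tuple[int, int, int]]:
    """All symmetry-unique reflections with d in [d_min, d_max].

    Enumerates the non-negative index grid, keeps indices inside gemmi's
    reciprocal-space asymmetric unit of the point group, and drops
    systematic absences (e.g. odd axial reflections on 2_1 screw axes).
    """
    if not d_min > 0 or d_min >= d_max:
        raise ValueError(f"invalid d limits [{d_min}, {d_max}]")
    cell = _as_cell(cell)
    sg = gemmi.SpaceGroup(space_group)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    out = set()
    for h in range(hmax + 1):
        for k in range(kmax + 1):
            for l in range(lmax + 1):
                if h == k == l == 0:
                    continue
                hkl = (h, k, l)
                if not asu.is_in(hkl):
                    continue
                if ops.is_systematically_absent(hkl):
                    continue
                d = cell.calculate_d(hkl)
                if d_min <= d <= d_max:
                    out.add(hkl)
    return out


def completeness(
    merged: MergedSet, d_limits: tuple[float, float] | None = None
) -> float:
    """Observed fraction (%) of the symmetry-unique reflection list.

    ``d_limits`` is (d_max, d_min), low to high resolution; defaults to
    the merged set's own range.
    """
    if d_limits is None:
        d_max, d_min = merged.d_max, merged.d_min
    else:
        d_max, d_min = d_limits
        if d_min >= d_max:
            raise ValueError(f"inverted d limits ({d_max}, {d_min})")
    expected = unique_reflections(merged.cell, merged.space_group, d_min, d_max)
    rec = merged.records
    inrange = rec[(rec["d"] >= d_min) & (rec["d"] <= d_max)]
    observed = set(map(tuple, inrange[["h", "k", "l"]].to_numpy()))
    if not expected:
        raise ValueError("no unique reflections in the requested range")
    return 100.0 * len(observed & expected) / len(expected)


def wilson_b(
    merged: MergedSet, fit_d_max: float = 4.5, n_bins: int = 20
) -> float:
    """Overall Wilson B (A^2) from the slope of ln<I> vs (1/(2d))^2.

    Mean intensities are taken in equal-width bins of s^2 = (sin(theta)/
    lambda)^2 = (1/(2d))^2 over reflections with d < ``fit_d_max`` (the
    low-resolution non-Wilson regime is excluded).  With I proportional
    to exp(-2B*s^2) the fitted slope equals -2B.  Bins with non-positive
    mean intensity are skipped; fewer than 3 usable bins is an error.
    """
    rec = merged.records
    sel = rec["d"] < fit_d_max
    if sel.sum() < 3:
        raise ValueError("too few reflections inside the Wilson fit range")
    d = rec.loc[sel, "d"].to_numpy()
    inten = rec.loc[sel, "I"].to_numpy()
    s2 = (0.5 / d) ** 2
    edges = np.linspace(s2.min(), s2.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, s2, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        mean_i = inten[m].mean()
        if mean_i <= 0:
            continue
        xs.append(s2[m].mean())
        ys.append(math.log(mean_i))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable Wilson bins; need >= 3")
    slope = np.polyfit(np.asarray(xs), np.asarray(ys), 1)[0]
    return float(-slope / 2.0)


def auto_resolution_cutoff(
    observations: ReflectionObservations, n_bins: int = 20
) -> float:
    """Automatic high-resolution limit from binned merged I/sigma(I).

    The merged data are divided into ``n_bins`` equal-volume resolution
    bins; walking from low to high resolution, the cutoff is the inner
    (high-resolution) d edge of the last bin whose mean I/sigma(I) is
    still > 1.0 before the first bin that fails — a first-crossing rule,
    even if later bins recover.  If every bin passes, the overall d_min
    is returned; if the first bin already fails, there is no usable data
    and an error is raised.
    """
    full = merge(observations)
    rec = full.records
    d = rec["d"].to_numpy()
    edges = _volume_bin_edges(float(d.max()), float(d.min()), n_bins)
    idx = _assign_volume_bins(d, edges)
    snr = _merged_snr(rec)
    for b in range(n_bins):
        m = (idx == b) & np.isfinite(snr)
        mean_snr = float(np.mean(snr[m])) if m.any() else float("nan")
        if not (mean_snr > 1.0):
            if b == 0:
                raise ValueError(
                    "lowest-resolution bin already has mean I/sigma <= 1.0; "
                    "no usable data"
                )
            return float(edges[b])  # inner edge of the last passing bin
    return float(d.min())
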