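"""Comparison of atomic models: displacement fields, distance-difference
matrices, radius of gyration, RMSD and bootstrap coordinate errors.

Two isomorphous crystal structures of the same protein are compared on
their common C-alpha atoms (paired by chain id and residue number — no
sequence alignment, since the models describe the same molecule).  The
distance-difference matrix D_ij = d_ij(B) - d_ij(A) is invariant under
rigid motion of either model and so needs no superposition; displacement
vectors are reported after a Kabsch least-squares superposition by
default.

Coordinate uncertainties come from bootstrap resampling: the image pool
behind a structure is resampled with replacement, a structure is
obtained from each resample by a pluggable ``refine_engine`` (the
shipped surrogate engine takes the per-atom mean of per-image coordinate
observations), and the standard deviation over the ensemble estimates
the coordinate error.  Atoms of a reference model further than two sigma
from the ensemble mean are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "PairedCA",
    "Superposition",
    "BootstrapEnsemble",
    "CoordinateObservations",
    "pair_models",
    "superpose",
    "displacement_field",
    "distance_difference_matrix",
    "radius_of_gyration",
    "surrogate_refine_engine",
    "bootstrap_ensemble",
    "compare_report",
]

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "x", "y", "z", "b", "occ"]


@dataclass
class StructureModel:
    """Atomic model as a flat atom table plus cell metadata.

    ``atoms`` columns: chain, resnum, resname, atom, x, y, z, b, occ.
    (chain, resnum, atom) keys must be unique and coordinates finite.
    """

    atoms: pd.DataFrame
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) == 0:
            raise ValueError("empty structure")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ValueError("non-finite coordinates")
        if self.atoms.duplicated(subset=["chain", "resnum", "atom"]).any():
            raise ValueError("duplicate (chain, resnum, atom) keys")

    def coords(self, atom_name: str | None = "CA") -> np.ndarray:
        df = self.atoms if atom_name is None else self.atoms[self.atoms["atom"] == atom_name]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = np.asarray(xyz, dtype=float)
        return StructureModel(atoms, self.cell, self.space_group)

    @classmethod
    def from_pdb(cls, path) -> "StructureModel":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        rows = []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append(
                        {
                            "chain": chain.name,
                            "resnum": res.seqid.num,
                            "resname": res.name,
                            "atom": atom.name,
                            "x": atom.pos.x,
                            "y": atom.pos.y,
                            "z": atom.pos.z,
                            "b": atom.b_iso,
                            "occ": atom.occ,
                        }
                    )
        cell = st.cell
        return cls(
            pd.DataFrame(rows),
            (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
            st.spacegroup_hm or None,
        )

    def to_pdb(self, path) -> None:
        st = gemmi.Structure()
        st.name = "model"
        if self.cell is not None:
            st.cell = gemmi.UnitCell(*self.cell)
        if self.space_group:
            st.spacegroup_hm = self.space_group
        model = gemmi.Model("1")
        for chain_name, chain_df in self.atoms.groupby("chain", sort=False):
            chain = gemmi.Chain(str(chain_name))
            for resnum, res_df in chain_df.groupby("resnum", sort=False):
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(resnum), " ")
                res.name = str(res_df["resname"].iloc[0])
                for _, row in res_df.iterrows():
                    atom = gemmi.Atom()
                    atom.name = str(row["atom"])
                    atom.pos = gemmi.Position(row["x"], row["y"], row["z"])
                    atom.b_iso = float(row["b"])
                    atom.occ = float(row["occ"])
                    atom.element = gemmi.Element("C")
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.write_pdb(str(path))


@dataclass
class PairedCA:
    """C-alpha atoms common to two models, ordered chain-then-residue."""

    keys: list[tuple[str, int]]
    xyz_a: np.ndarray
    xyz_b: np.ndarray
    unmatched_a: list[tuple[str, int]] = field(default_factory=list)
    unmatched_b: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.keys)


def pair_models(a: StructureModel, b: StructureModel) -> PairedCA:
    """Match C-alpha atoms of two models by (chain, residue number)."""

    def ca_map(m: StructureModel) -> dict[tuple[str, int], np.ndarray]:
        ca = m.atoms[m.atoms["atom"] == "CA"]
        return {
            (str(r["chain"]), int(r["resnum"])): np.array([r["x"], r["y"], r["z"]])
            for _, r in ca.iterrows()
        }

    ma, mb = ca_map(a), ca_map(b)
    common = sorted(set(ma) & set(mb))
    if not common:
        raise ValueError(
            "models share no (chain, residue) C-alpha keys; check chain naming"
        )
    return PairedCA(
        keys=common,
        xyz_a=np.array([ma[k] for k in common]),
        xyz_b=np.array([mb[k] for k in common]),
        unmatched_a=sorted(set(ma) - set(mb)),
        unmatched_b=sorted(set(mb) - set(ma)),
    )


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def superpose(paired: PairedCA) -> Superposition:
    """Kabsch least-squares rigid superposition of B onto A.

    Only proper rotations (det = +1) are allowed; a mirror image cannot
    be superposed away.  Requires >= 3 non-collinear pairs.
    """
    if paired.n_pairs < 3:
        raise ValueError(f"need >= 3 pairs for superposition, got {paired.n_pairs}")
    a = paired.xyz_a
    b = paired.xyz_b
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry; superposition undefined")
    rot, _ = Rotation.align_vectors(a0, b0)  # proper rotation by construction
    r = rot.as_matrix()
    t = ca - cb @ r.T
    moved = b @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=r, translation=t, rmsd=rmsd)


def displacement_field(
    paired: PairedCA, superpose_first: bool = True, arrow_scale: float = 10.0
) -> pd.DataFrame:
    """Per-residue displacement vectors B - A, with scaled export copies.

    ``arrow_scale`` multiplies the exported arrow columns for
    visualisation only; every statistic uses the unscaled vectors.
    """
    b = paired.xyz_b
    if superpose_first:
        b = superpose(paired).apply(b)
    vec = b - paired.xyz_a
    out = pd.DataFrame(
        {
            "chain": [k[0] for k in paired.keys],
            "resnum": [k[1] for k in paired.keys],
            "dx": vec[:, 0],
            "dy": vec[:, 1],
            "dz": vec[:, 2],
        }
    )
    out["norm"] = np.linalg.norm(vec, axis=1)
    for c in ("dx", "dy", "dz"):
        out[f"{c}_scaled"] = out[c] * arrow_scale
    return out


def distance_difference_matrix(paired: PairedCA) -> dict:
    """Changes in all pairwise C-alpha distances between two models.

    Returns ``absolute`` (D_ij = d_ij(B) - d_ij(A), A), the ``relative``
    form D_ij / d_ij(A), and the per-residue sum of relative changes —
    negative sums indicate local compaction.  Distances are invariant
    under rigid motion, so no superposition is involved.
    """
    da = squareform(pdist(paired.xyz_a))
    db = squareform(pdist(paired.xyz_b))
    diff = db - da
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(da > 0, diff / da, 0.0)
    np.fill_diagonal(rel, 0.0)
    return {
        "absolute": diff,
        "relative": rel,
        "per_residue_relative_sum": rel.sum(axis=1),
        "keys": paired.keys,
    }


def radius_of_gyration(
    model: StructureModel, selection: str | None = "CA", mass_weighted: bool = False
) -> float:
    """Rg = sqrt(sum w_i |r_i - rbar|^2 / sum w_i), uniform weights by default.

    Occupancies are used as weights when ``mass_weighted`` is set (the
    atom table carries no element masses; occupancy is the only per-atom
    weight available and is what matters for partially occupied sites).
    """
    df = model.atoms if selection is None else model.atoms[model.atoms["atom"] == selection]
    if len(df) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    w = df["occ"].to_numpy(dtype=float) if mass_weighted else np.ones(len(df))
    centre = np.average(xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((xyz - centre) ** 2, axis=1), weights=w)))


@dataclass
class CoordinateObservations:
    """Per-image coordinate observations of one set of atoms.

    ``coords`` has shape (n_images, n_atoms, 3); ``image_ids`` labels the
    first axis; ``template`` maps atoms back to a StructureModel.
    """

    coords: np.ndarray
    image_ids: list
    template: StructureModel

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (m, n_atoms, 3), got {self.coords.shape}")
        if len(self.image_ids) != self.coords.shape[0]:
            raise ValueError("image_ids length mismatch")


def surrogate_refine_engine(
    pool: CoordinateObservations, image_ids: list
) -> StructureModel:
    """Reference refine engine: per-atom mean of the drawn observations.

    Stands in for a crystallographic refinement program in the bootstrap
    contract: it maps a multiset of image ids to a structure.
    """
    index = {iid: i for i, iid in enumerate(pool.image_ids)}
    rows = [index[i] for i in image_ids]
    return pool.template.with_coords(pool.coords[rows].mean(axis=0))


@dataclass
class BootstrapEnsemble:
    mean_xyz: np.ndarray  # (n_atoms, 3)
    sd_xyz: np.ndarray  # (n_atoms, 3) per-coordinate SD
    n_boot: int
    seed: int
    resampled_ids: list[list]
    template: StructureModel

    @property
    def atom_sd(self) -> np.ndarray:
        """Scalar per-atom coordinate error, sqrt(sx^2 + sy^2 + sz^2)."""
        return np.sqrt(np.sum(self.sd_xyz**2, axis=1))

    def two_sigma_check(self, reference: StructureModel, atom_name: str | None = None) -> dict:
        """Flag reference atoms > 2*SD from the ensemble mean.

        Distances are per-atom displacement norms compared against twice
        the scalar per-atom SD.  With zero ensemble spread the check is
        degenerate and reported as such.
        """
        ref = reference.coords(atom_name)
        if ref.shape != self.mean_xyz.shape:
            raise ValueError("reference does not match the ensemble atom set")
        dist = np.linalg.norm(ref - self.mean_xyz, axis=1)
        sd = self.atom_sd
        degenerate = bool(np.all(sd < 1e-12))  # zero-spread ensemble
        with np.errstate(divide="ignore", invalid="ignore"):
            outside = dist > 2.0 * sd
        return {
            "outside_2sigma": outside,
            "fraction_within": float(1.0 - outside.mean()) if not degenerate else 1.0,
            "degenerate": degenerate,
        }


def bootstrap_ensemble(
    pool: CoordinateObservations,
    refine_engine=surrogate_refine_engine,
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Bootstrap coordinate-uncertainty estimate over an image pool.

    Each of ``n_boot`` resamples draws images with replacement from the
    pool until the original pool size is reached; ``refine_engine`` turns
    each resample into a structure.  The per-atom SD over the ensemble is
    the coordinate-error estimate.  An engine failure on a resample is
    retried once with a fresh draw, then raised.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    rng = np.random.default_rng(seed)
    m = len(pool.image_ids)
    ids = list(pool.image_ids)
    members = []
    drawn: list[list] = []
    for _ in range(n_boot):
        for attempt in (0, 1):
            sample = [ids[i] for i in rng.integers(0, m, size=m)]
            try:
                model = refine_engine(pool, sample)
                break
            except Exception:
                if attempt == 1:
                    raise
        members.append(model.coords(None))
        drawn.append(sample)
    stack = np.stack(members)
    return BootstrapEnsemble(
        mean_xyz=stack.mean(axis=0),
        sd_xyz=stack.std(axis=0),
        n_boot=n_boot,
        seed=seed,
        resampled_ids=drawn,
        template=pool.template,
    )


def compare_report(
    a: StructureModel,
    b: StructureModel,
    ensemble_a: BootstrapEnsemble | None = None,
    ensemble_b: BootstrapEnsemble | None = None,
    superpose_first: bool = True,
) -> dict:
    """Structured comparison of two models (optionally with ensembles).

    Reports the C-alpha RMSD after superposition, the mean per-atom
    displacement, each model's radius of gyration, the total and
    per-residue sums of relative C-alpha distance changes (negative total
    = net compaction), and — when ensembles are supplied — the count of
    residues whose displacement exceeds twice their bootstrap coordinate
    error.
    """
    paired = pair_models(a, b)
    sup = superpose(paired) if superpose_first else None
    disp = displacement_field(paired, superpose_first=superpose_first)
    ddm = distance_difference_matrix(paired)
    rmsd = sup.rmsd if sup is not None else float(
        np.sqrt(np.mean(np.sum((paired.xyz_b - paired.xyz_a) ** 2, axis=1)))
    )
    report = {
        "n_pairs": paired.n_pairs,
        "rmsd": rmsd,
        "mean_displacement": float(disp["norm"].mean()),
        "rg_a": radius_of_gyration(a),
        "rg_b": radius_of_gyration(b),
        "total_relative_distance_change": float(ddm["per_residue_relative_sum"].sum()),
        "net_compaction": bool(ddm["per_residue_relative_sum"].sum() < 0),
        "per_residue_relative_sum": ddm["per_residue_relative_sum"],
        "unmatched_a": paired.unmatched_a,
        "unmatched_b": paired.unmatched_b,
    }
    if ensemble_a is not None and ensemble_b is not None:
        err = np.sqrt(ensemble_a.atom_sd**2 + ensemble_b.atom_sd**2)
        # ensembles must be on the paired CA set for this comparison
        if err.shape[0] == paired.n_pairs:
            significant = disp["norm"].to_numpy() > 2.0 * err
            report["n_displacements_above_2sigma"] = int(significant.sum())
            report["mean_coordinate_error"] = float(err.mean())
    return report
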