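"""Solvent-accessible surface, surface values, and patch detection.

The pipeline is: (1) a Shrake–Rupley dot-surface SASA with the probe radius
and dot density of the screening protocol; (2) per-point hydrophobic and
Coulombic electrostatic values; (3) thresholding and single-linkage
clustering of surface points into hydrophobic / positive / negative patches
with a minimum-area filter; (4) per-residue patch-area contributions
(res_hyd / res_pos / res_neg / res_ASA) that drive mutant design.

Default thresholds: hydrophobic value >= 0.09 kcal/mol, |potential| >=
30 kcal/mol/e, minimum patch area 30 Å², probe radius 1.8 Å, 960 dots per
atom. The hydrophobic value of a surface point is the (shifted Black–Mould)
scale value of its owner residue; the electrostatic value is a Coulomb sum
over formal charges with a distance-dependent dielectric (4r by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import StructureModel
from .tables import (
    CDR_REGIONS,
    CHARGE_SITE_ATOM,
    FORMAL_CHARGES_PH6,
    HYDROPHOBICITY_SCALE,
)

COULOMB_CONSTANT = 332.06  # kcal·Å/(mol·e²)


@dataclass(frozen=True)
class PatchParams:
    """Thresholds and discretisation settings for patch analysis."""

    hydrophobic_cutoff: float = 0.09   # kcal/mol, on the shipped scale
    charge_cutoff: float = 30.0        # kcal/mol/e
    min_area: float = 30.0             # Å²
    probe_radius: float = 1.8          # Å
    points_per_atom: int = 960
    adjacency_radius: float | None = None  # Å; None -> auto from dot density

    def __post_init__(self) -> None:
        for name in ("hydrophobic_cutoff", "charge_cutoff", "min_area",
                     "probe_radius", "points_per_atom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SurfaceCloud:
    """Retained solvent-accessible dots with per-point annotations.

    Arrays are parallel: ``positions`` (n, 3) Å, ``owner_atom`` (n,),
    ``owner_residue`` (n,), ``area_weight`` (n,) Å². Value arrays are filled
    by :func:`assign_surface_values`.
    """

    positions: np.ndarray
    owner_atom: np.ndarray
    owner_residue: np.ndarray
    area_weight: np.ndarray
    hydrophobic_value: np.ndarray | None = None
    electrostatic_value: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SasaResult:
    atom_sasa: np.ndarray       # Å² per atom
    residue_sasa: np.ndarray    # Å² per residue
    cloud: SurfaceCloud

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


@dataclass
class SurfacePatch:
    patch_class: str                      # hydrophobic | positive | negative
    point_indices: np.ndarray             # indices into the cloud
    area: float                           # Å²
    residue_shares: dict[int, float]      # residue index -> Å²
    near_cdr: bool = False


@dataclass
class ResidueContribution:
    residue_index: int
    res_asa: float
    res_hyd: float = 0.0
    res_pos: float = 0.0
    res_neg: float = 0.0


def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _atom_frames(coords: np.ndarray) -> np.ndarray:
    """Per-atom rotation matrices built from molecule-intrinsic vectors.

    The dot lattice on each atom is oriented by the centroid→atom direction
    and the direction to the atom's nearest neighbour (ties broken by atom
    index). Both vectors rotate with the molecule, so the retained dot set
    — and hence SASA and patch areas — is equivariant under rigid motion.
    """
    n = len(coords)
    frames = np.tile(np.eye(3), (n, 1, 1))
    if n < 2:
        return frames
    centroid = coords.mean(axis=0)
    tree = cKDTree(coords)
    _, nn = tree.query(coords, k=2)
    for i in range(n):
        v1 = coords[i] - centroid
        v2 = coords[int(nn[i, 1])] - coords[i]
        e3 = v1 if np.linalg.norm(v1) > 1e-8 else v2
        norm3 = np.linalg.norm(e3)
        if norm3 < 1e-8:
            continue
        e3 = e3 / norm3
        e1 = v2 - np.dot(v2, e3) * e3
        norm1 = np.linalg.norm(e1)
        if norm1 < 1e-8:
            # collinear fallback: any perpendicular (not rotation-equivariant,
            # but only reachable for degenerate collinear inputs)
            e1 = np.cross(e3, np.eye(3)[np.argmin(np.abs(e3))])
            norm1 = np.linalg.norm(e1)
        e1 = e1 / norm1
        e2 = np.cross(e3, e1)
        frames[i] = np.column_stack((e1, e2, e3))
    return frames


def compute_sasa(model: StructureModel, params: PatchParams | None = None) -> SasaResult:
    """Shrake–Rupley dot SASA.

    Dots are placed on each atom's expanded sphere (vdW + probe); a dot is
    retained iff it lies outside every other atom's expanded sphere. Atom
    SASA is the retained fraction times the expanded-sphere area; each
    retained dot carries ``area_weight = sphere_area / points_per_atom``.
    """
    params = params or PatchParams()
    n_atoms = len(model.atoms)
    if n_atoms == 0:
        raise ValueError("cannot compute SASA of an empty model")

    coords = model.coords()
    radii = model.radii() + params.probe_radius
    sphere = unit_sphere_points(params.points_per_atom)
    frames = _atom_frames(coords)
    owner_res = model.atom_residue_indices()

    tree = cKDTree(coords)
    max_r = radii.max()

    atom_sasa = np.zeros(n_atoms)
    kept_pos: list[np.ndarray] = []
    kept_atom: list[np.ndarray] = []
    kept_weight: list[np.ndarray] = []

    for i in range(n_atoms):
        pts = coords[i] + radii[i] * (sphere @ frames[i].T)
        # candidate occluders: any atom whose expanded sphere could reach
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        keep = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            keep &= d2 > radii[j] ** 2
        sphere_area = 4.0 * np.pi * radii[i] ** 2
        w = sphere_area / params.points_per_atom
        atom_sasa[i] = keep.sum() * w
        if keep.any():
            kept_pos.append(pts[keep])
            kept_atom.append(np.full(int(keep.sum()), i, dtype=int))
            kept_weight.append(np.full(int(keep.sum()), w))

    if kept_pos:
        positions = np.vstack(kept_pos)
        owner_atom = np.concatenate(kept_atom)
        weights = np.concatenate(kept_weight)
    else:
        positions = np.empty((0, 3))
        owner_atom = np.empty(0, dtype=int)
        weights = np.empty(0)

    residue_sasa = np.zeros(len(model.residues))
    np.add.at(residue_sasa, owner_res, atom_sasa)

    cloud = SurfaceCloud(
        positions=positions,
        owner_atom=owner_atom,
        owner_residue=owner_res[owner_atom] if len(owner_atom) else owner_atom,
        area_weight=weights,
    )
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa, cloud=cloud)


def formal_charge_sites(
    model: StructureModel,
    charge_map: dict[str, float] | None = None,
    include_termini: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate formal charges: (positions (m,3), charges (m,) in e).

    Side-chain charges sit on a named atom per residue type (NZ for Lys, CZ
    for Arg, ...), falling back to CA and then to the residue's first atom —
    the fallback covers one-bead synthetic structures. Termini add +1/−1 on
    the first/last residue of each chain when ``include_termini``.
    """
    charge_map = FORMAL_CHARGES_PH6 if charge_map is None else charge_map
    atoms_by_res: dict[int, list] = {}
    for atom in model.atoms:
        atoms_by_res.setdefault(atom.residue_index, []).append(atom)

    positions: list[tuple[float, float, float]] = []
    charges: list[float] = []

    def site_position(res_index: int, aa: str):
        atoms = atoms_by_res.get(res_index, [])
        if not atoms:
            return None
        preferred = CHARGE_SITE_ATOM.get(aa)
        for want in (preferred, "CA"):
            if want is None:
                continue
            for a in atoms:
                if a.name == want:
                    return a.coordinates
        return atoms[0].coordinates

    for i, res in enumerate(model.residues):
        q = charge_map.get(res.amino_acid, 0.0)
        if q != 0.0:
            pos = site_position(i, res.amino_acid)
            if pos is not None:
                positions.append(pos)
                charges.append(q)
        if include_termini and res.is_terminal:
            pos = site_position(i, res.amino_acid)
            if pos is not None:
                # first residue of the chain carries the amino terminus
                chain_members = [
                    j for j, r in enumerate(model.residues)
                    if r.chain_id == res.chain_id
                ]
                positions.append(pos)
                charges.append(+1.0 if i == chain_members[0] else -1.0)

    if not positions:
        return np.empty((0, 3)), np.empty(0)
    return np.asarray(positions, dtype=float), np.asarray(charges, dtype=float)


def assign_surface_values(
    cloud: SurfaceCloud,
    model: StructureModel,
    hydrophobicity_scale: dict[str, float] | None = None,
    charge_map: dict[str, float] | None = None,
    dielectric: float | str = "4r",
    include_termini: bool = True,
) -> SurfaceCloud:
    """Fill per-point hydrophobic and electrostatic values in place.

    Hydrophobic value: the owner residue's entry in ``hydrophobicity_scale``
    (kcal/mol on the shipped shifted scale). Electrostatic value: Coulomb
    sum k·q_i/(ε·d_i) in kcal/mol/e; ``dielectric`` is either the string
    "4r" (distance-dependent ε = 4d) or a constant number.
    """
    scale = HYDROPHOBICITY_SCALE if hydrophobicity_scale is None else hydrophobicity_scale

    hyd = np.empty(len(cloud))
    for i, res_idx in enumerate(cloud.owner_residue):
        aa = model.residues[int(res_idx)].amino_acid
        if aa not in scale:
            raise KeyError(f"no hydrophobicity scale entry for residue {aa!r}")
        hyd[i] = scale[aa]

    sites, charges = formal_charge_sites(model, charge_map, include_termini)
    elec = np.zeros(len(cloud))
    if len(sites) and len(cloud):
        # pairwise distances points x charge sites
        d = np.linalg.norm(
            cloud.positions[:, None, :] - sites[None, :, :], axis=2
        )
        d = np.maximum(d, 1e-6)
        if dielectric == "4r":
            eps = 4.0 * d
        else:
            eps = float(dielectric) * np.ones_like(d)
        elec = (COULOMB_CONSTANT * charges[None, :] / (eps * d)).sum(axis=1)

    cloud.hydrophobic_value = hyd
    cloud.electrostatic_value = elec
    return cloud


def _auto_adjacency(cloud: SurfaceCloud, params: PatchParams) -> float:
    if params.adjacency_radius is not None:
        return params.adjacency_radius
    if len(cloud) == 0:
        return 1.0
    # scaled to dot density so clustering is resolution-independent
    return 1.9 * float(np.sqrt(cloud.area_weight.mean()))


def _cluster(points: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage clusters: labels for each point (Euclidean <= radius)."""
    if len(points) == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(points)
    if len(pairs) == 0:
        return np.arange(n)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def detect_patches(
    cloud: SurfaceCloud,
    params: PatchParams | None = None,
    model: StructureModel | None = None,
) -> list[SurfacePatch]:
    """Threshold surface points and cluster them into patches.

    Classes are computed independently: a point may belong to a hydrophobic
    and one charge patch, but positive/negative are mutually exclusive by
    sign. Thresholds are inclusive (>=). Clusters below ``min_area`` are
    dropped. If ``model`` carries region annotations, ``near_cdr`` is set
    when any contributing residue lies in a CDR.
    """
    params = params or PatchParams()
    if cloud.hydrophobic_value is None or cloud.electrostatic_value is None:
        raise ValueError("assign_surface_values must run before detect_patches")

    radius = _auto_adjacency(cloud, params)
    masks = {
        "hydrophobic": cloud.hydrophobic_value >= params.hydrophobic_cutoff,
        "positive": cloud.electrostatic_value >= params.charge_cutoff,
        "negative": cloud.electrostatic_value <= -params.charge_cutoff,
    }

    patches: list[SurfacePatch] = []
    for patch_class, mask in masks.items():
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        labels = _cluster(cloud.positions[idx], radius)
        for lab in np.unique(labels):
            members = idx[labels == lab]
            area = float(cloud.area_weight[members].sum())
            if area < params.min_area:
                continue
            shares: dict[int, float] = {}
            for m in members:
                r = int(cloud.owner_residue[m])
                shares[r] = shares.get(r, 0.0) + float(cloud.area_weight[m])
            near = False
            if model is not None:
                near = any(
                    model.residues[r].region in CDR_REGIONS for r in shares
                )
            patches.append(
                SurfacePatch(
                    patch_class=patch_class,
                    point_indices=members,
                    area=area,
                    residue_shares=shares,
                    near_cdr=near,
                )
            )
    return patches


def residue_patch_contributions(
    patches: list[SurfacePatch], sasa: SasaResult
) -> list[ResidueContribution]:
    """Per-residue patch-area contributions (res_hyd/res_pos/res_neg)."""
    contribs = [
        ResidueContribution(residue_index=i, res_asa=float(a))
        for i, a in enumerate(sasa.residue_sasa)
    ]
    attr = {"hydrophobic": "res_hyd", "positive": "res_pos", "negative": "res_neg"}
    for patch in patches:
        name = attr[patch.patch_class]
        for res_idx, share in patch.residue_shares.items():
            c = contribs[res_idx]
            setattr(c, name, getattr(c, name) + share)
    return contribs


@dataclass
class PatchSummary:
    total_area: dict[str, float] = field(default_factory=dict)
    patch_count: dict[str, int] = field(default_factory=dict)
    near_cdr_count: dict[str, int] = field(default_factory=dict)


def save_surface_plot(cloud: SurfaceCloud, path, value: str = "electrostatic") -> None:
    """3-D scatter of surface dots coloured by their assigned value.

    A quick visual of the hydrophobic or electrostatic surface distribution;
    not a continuous potential map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = (
        cloud.electrostatic_value if value == "electrostatic" else cloud.hydrophobic_value
    )
    if values is None:
        raise ValueError("assign_surface_values must run before plotting")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    p = ax.scatter(
        cloud.positions[:, 0], cloud.positions[:, 1], cloud.positions[:, 2],
        c=values, s=2, cmap="coolwarm",
    )
    label = "potential (kcal/mol/e)" if value == "electrostatic" else "hydrophobicity (kcal/mol)"
    fig.colorbar(p, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def patch_summary(patches: list[SurfacePatch], model: StructureModel) -> PatchSummary:
    """Per-class totals: summed area, patch count, count touching CDRs."""
    summary = PatchSummary(
        total_area={c: 0.0 for c in ("hydrophobic", "positive", "negative")},
        patch_count={c: 0 for c in ("hydrophobic", "positive", "negative")},
        near_cdr_count={c: 0 for c in ("hydrophobic", "positive", "negative")},
    )
    for patch in patches:
        near = patch.near_cdr or any(
            model.residues[r].region in CDR_REGIONS for r in patch.residue_shares
        )
        summary.total_area[patch.patch_class] += patch.area
        summary.patch_count[patch.patch_class] += 1
        if near:
            summary.near_cdr_count[patch.patch_class] += 1
    return summary
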