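"""Structure and sequence I/O.

Reads PDB files (via gemmi) into a light-weight in-memory model carrying the
per-residue annotations (chain role, CDR/framework region, terminal flag)
that the patch and descriptor stages consume. Antibody numbering itself is
not computed here: region assignments come from a user-supplied table
(chain_id, start, end, region), typically derived from a Kabat annotation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .tables import DEFAULT_VDW_RADIUS, THREE_TO_ONE, VDW_RADII

VALID_REGIONS = {
    "CDR-H1", "CDR-H2", "CDR-H3", "CDR-L1", "CDR-L2", "CDR-L3",
    "FWR-H", "FWR-L", "constant", "unassigned",
}


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no usable ATOM records."""


class RegionOverlapError(ValueError):
    """Raised when two region ranges claim the same residue."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int
    coordinates: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    position_label: str
    amino_acid: str
    region: str = "unassigned"
    is_terminal: bool = False


@dataclass
class StructureModel:
    """Atoms plus residue-level annotations for one protein model.

    ``chain_roles`` maps chain id to one of ``VH``, ``VL`` or ``other`` so
    downstream descriptor code can locate the variable domains.
    """

    atoms: list[AtomRecord]
    residues: list[ResidueRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.residues)
        for atom in self.atoms:
            if not 0 <= atom.residue_index < n:
                raise ValueError(
                    f"atom {atom.serial} references residue {atom.residue_index} "
                    f"outside 0..{n - 1}"
                )
        roles = [r for r in self.chain_roles.values() if r in ("VH", "VL")]
        if roles.count("VH") > 1 or roles.count("VL") > 1:
            raise ValueError("at most one chain may carry each of the VH/VL roles")

    # -- array views used by the surface stage ------------------------------
    def coords(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def atom_residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def chain_for_role(self, role: str) -> str:
        for cid, r in self.chain_roles.items():
            if r == role:
                return cid
        raise KeyError(f"no chain annotated with role {role!r}")


def read_structure(
    path: str | Path,
    radius_table: dict[str, float] | None = None,
    include_hetero: bool = False,
) -> StructureModel:
    """Parse the first model of a PDB file into a :class:`StructureModel`.

    Waters and hetero groups are excluded by default; only altloc '' or 'A'
    atoms are kept and occupancy is ignored. Van der Waals radii come from
    ``radius_table`` (element symbol, upper case); unknown elements get
    1.7 Å with a warning.
    """
    radius_table = radius_table or VDW_RADII
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            if res.het_flag == "H" and res.name != "MSE" and not include_hetero:
                continue
            aa = THREE_TO_ONE.get(res.name)
            if aa is None:
                warnings.warn(
                    f"nonstandard residue {res.name} mapped to X", stacklevel=2
                )
                aa = "X"
            elif res.name == "MSE":
                warnings.warn("MSE mapped to M", stacklevel=2)
            label = f"{res.seqid.num}{res.seqid.icode}".strip()
            res_index = len(residues)
            residues.append(
                ResidueRecord(chain.name, label, aa)
            )
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                elem = atom.element.name.upper()
                if elem not in radius_table:
                    warnings.warn(
                        f"unknown element {elem!r}: using default radius "
                        f"{DEFAULT_VDW_RADIUS} Å",
                        stacklevel=2,
                    )
                radius = radius_table.get(elem, DEFAULT_VDW_RADIUS)
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=elem,
                        residue_index=res_index,
                        coordinates=(atom.pos.x, atom.pos.y, atom.pos.z),
                        vdw_radius=radius,
                    )
                )

    # drop residues that contributed no atoms (e.g. pure-altloc-B artifacts)
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")
    return StructureModel(atoms=atoms, residues=residues)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model back out as fixed-width PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    from .tables import ONE_TO_THREE

    for res_index, res in enumerate(model.residues):
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        gres.name = ONE_TO_THREE.get(res.amino_acid, "UNK")
        num = "".join(ch for ch in res.position_label if ch.isdigit() or ch == "-")
        icode = res.position_label[len(num):]
        gres.seqid = gemmi.SeqId(int(num), icode or " ")
        for atom in model.atoms:
            if atom.residue_index != res_index:
                continue
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element.capitalize())
            ga.pos = gemmi.Position(*atom.coordinates)
            ga.occ = 1.0
            gres.add_atom(ga)
        chains[res.chain_id].add_residue(gres)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def read_region_map(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read a region annotation CSV with header chain_id,start,end,region."""
    rows: list[tuple[str, str, str, str]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                (row["chain_id"], row["start"], row["end"], row["region"])
            )
    return rows


def annotate_regions(
    model: StructureModel,
    region_map: list[tuple[str, str, str, str]],
    chain_roles: dict[str, str] | None = None,
) -> StructureModel:
    """Assign CDR/FWR regions from (chain, start_label, end_label, region) rows.

    Ranges are inclusive and interpreted by file order within the chain (so
    insertion codes behave as in the source numbering). Residues covered by
    no range stay ``unassigned``; the first and last residue of each chain
    are flagged terminal. Overlapping ranges raise
    :class:`RegionOverlapError`.
    """
    chain_ids = model.chain_ids()
    by_chain: dict[str, list[int]] = {cid: [] for cid in chain_ids}
    for i, res in enumerate(model.residues):
        by_chain[res.chain_id].append(i)

    assigned: dict[int, str] = {}
    for chain_id, start, end, region in region_map:
        if chain_id not in by_chain:
            raise KeyError(f"region map references unknown chain {chain_id!r}")
        if region not in VALID_REGIONS:
            raise ValueError(f"unknown region label {region!r}")
        labels = [model.residues[i].position_label for i in by_chain[chain_id]]
        try:
            lo = labels.index(str(start))
            hi = labels.index(str(end))
        except ValueError as exc:
            raise KeyError(
                f"range {start}-{end} not found in chain {chain_id}"
            ) from exc
        if hi < lo:
            lo, hi = hi, lo
        for i in by_chain[chain_id][lo : hi + 1]:
            if i in assigned and assigned[i] != region:
                res = model.residues[i]
                raise RegionOverlapError(
                    f"residue {res.chain_id}{res.position_label} assigned both "
                    f"{assigned[i]} and {region}"
                )
            assigned[i] = region

    new_residues: list[ResidueRecord] = []
    for cid in chain_ids:
        idx = by_chain[cid]
        for i in idx:
            res = model.residues[i]
            new_residues.append(
                replace(
                    res,
                    region=assigned.get(i, "unassigned"),
                    is_terminal=(i == idx[0] or i == idx[-1]),
                )
            )
    # by_chain preserves file order so new_residues aligns with model.residues
    order = [i for cid in chain_ids for i in by_chain[cid]]
    reordered = [None] * len(new_residues)
    for pos, i in enumerate(order):
        reordered[i] = new_residues[pos]
    return StructureModel(
        atoms=model.atoms,
        residues=reordered,  # type: ignore[arg-type]
        chain_roles=dict(chain_roles or model.chain_roles),
    )


def extract_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain in residue (file) order."""
    seq = [r.amino_acid for r in model.residues if r.chain_id == chain_id]
    if not seq:
        raise KeyError(f"chain {chain_id!r} not present in model")
    return "".join(seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence} (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )
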