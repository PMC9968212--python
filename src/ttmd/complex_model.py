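"""Protein–ligand complex representation and chemical feature perception.

A :class:`ComplexModel` holds the protein and ligand atoms of one complex
together with the per-residue ordering that fixes the layout of the
interaction fingerprint (one block of 8 interaction-class slots per protein
residue, in ``residue_order``).  Feature perception annotates atoms with the
properties the fingerprint needs: hydrogen-bond donor/acceptor character,
formal-charge class, hydrophobicity, aromatic rings and metals.

Protein typing uses a fixed per-residue-name lookup appropriate for
physiological pH (Lys/Arg cationic, Asp/Glu anionic, His neutral with both
ring nitrogens donor+acceptor).  Ligand aromaticity and formal charges are
taken verbatim from the input file's bond/charge blocks and never
re-perceived, so constructed inputs behave exactly as declared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "AromaticRing",
    "ComplexModel",
    "Frame",
    "parse_complex",
    "perceive_features",
    "load_trajectory",
    "write_complex",
]

#: elements treated as protein-bound metals
METAL_ELEMENTS = {"ZN", "MG", "MN", "FE", "CA", "CU", "NI", "CO", "CD", "NA", "K"}

HALOGENS = {"F", "CL", "BR", "I"}

#: residue names stripped from protein input (solvent/ions handled elsewhere)
_SOLVENT_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}

# --- protein feature lookup (standard amino acids, pH ~7.4) -----------------

_SIDECHAIN_DONORS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

_CATIONIC = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
_ANIONIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

#: canonical aromatic ring atom names of the standard residues
_RESIDUE_RINGS = {
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}


@dataclass
class AtomRecord:
    """One atom of the complex with its perceived chemical roles."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # Å, shape (3,)
    residue_key: tuple  # (chain, resnum, icode, resname)
    is_protein: bool
    formal_charge_class: str = "neutral"  # neutral | cationic | anionic
    is_hydrophobic: bool = False
    is_hbond_donor_heavy: bool = False
    is_hbond_acceptor: bool = False
    is_metal: bool = False
    attached_hydrogens: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")
        if self.is_metal and (self.is_hbond_donor_heavy or self.is_hbond_acceptor):
            raise ValueError(f"atom {self.serial}: a metal is neither donor nor acceptor")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class AromaticRing:
    """A planar aromatic ring: member atoms, centroid and unit normal."""

    member_serials: tuple
    centroid: np.ndarray
    normal: np.ndarray
    owner: object  # protein residue_key or the string "ligand"

    def __post_init__(self):
        if len(self.member_serials) < 5:
            raise ValueError("aromatic ring needs >= 5 members")
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
            raise ValueError("ring normal must be a unit vector")


def ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and best-fit plane unit normal of a ring's member coordinates."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # smallest principal axis of the member cloud = plane normal
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    n = np.linalg.norm(normal)
    if not np.isfinite(n) or n == 0:
        raise ValueError("degenerate (collinear) ring geometry")
    return centroid, normal / n


@dataclass
class ComplexModel:
    """Protein + ligand atoms, residue ordering, rings and ligand bonds."""

    protein_atoms: list
    ligand_atoms: list
    residue_order: list
    rings: list = field(default_factory=list)
    ligand_bonds: list = field(default_factory=list)  # (serial, serial) pairs
    ligand_aromatic_serials: set = field(default_factory=set)
    perceived: bool = False

    def __post_init__(self):
        if len(set(self.residue_order)) != len(self.residue_order):
            raise ValueError("duplicate residue keys in residue_order")
        order = set(self.residue_order)
        for a in self.protein_atoms:
            if a.residue_key not in order:
                raise ValueError(f"protein atom {a.serial} residue not in residue_order")
        if not any(a.is_heavy for a in self.ligand_atoms):
            raise ValueError("ligand has no heavy atoms")
        serials = [a.serial for a in self.protein_atoms + self.ligand_atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials")

    @property
    def r(self) -> int:
        """Number of protein residues (fingerprint has r × 8 slots)."""
        return len(self.residue_order)

    @property
    def residue_index(self) -> dict:
        return {key: i for i, key in enumerate(self.residue_order)}

    def atom_by_serial(self, serial: int) -> AtomRecord:
        for a in self.protein_atoms:
            if a.serial == serial:
                return a
        for a in self.ligand_atoms:
            if a.serial == serial:
                return a
        raise KeyError(serial)

    def reference_frame(self, temperature: float = 300.0) -> "Frame":
        """Frame holding the model's own coordinates."""
        return Frame(
            index=0,
            time=0.0,
            temperature_set=temperature,
            coords_protein=np.array([a.coords for a in self.protein_atoms]),
            coords_ligand=np.array([a.coords for a in self.ligand_atoms]),
        )


@dataclass
class Frame:
    """Coordinates of one trajectory frame, congruent with a ComplexModel."""

    index: int
    time: float  # ps
    temperature_set: float  # K
    coords_protein: np.ndarray
    coords_ligand: np.ndarray

    def __post_init__(self):
        self.coords_protein = np.asarray(self.coords_protein, dtype=float)
        self.coords_ligand = np.asarray(self.coords_ligand, dtype=float)
        if self.time < 0:
            raise ValueError("frame time must be >= 0")

    def check_congruent(self, model: ComplexModel) -> None:
        if self.coords_protein.shape != (len(model.protein_atoms), 3):
            raise ValueError("protein coordinate array does not match model")
        if self.coords_ligand.shape != (len(model.ligand_atoms), 3):
            raise ValueError("ligand coordinate array does not match model")


# --------------------------------------------------------------------------
# parsing


def _element_from_pdb(name: str, elem_field: str) -> str:
    if elem_field and elem_field.strip():
        return elem_field.strip().upper()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {name!r}")
    two = stripped[:2].upper()
    if two in METAL_ELEMENTS or two in {"CL", "BR"}:
        return two
    return stripped[0].upper()


def _parse_pdb_protein(path) -> tuple[list, list]:
    """Read ATOM/HETATM records, keeping highest-occupancy altlocs."""
    records = []  # (serial, name, altloc, resname, chain, resnum, icode, xyz, occ, elem)
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            resname = line[17:20].strip()
            if resname in _SOLVENT_RESNAMES:
                continue
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            chain = line[21].strip()
            resnum = int(line[22:26])
            icode = line[26].strip()
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            try:
                occ = float(line[54:60])
            except (ValueError, IndexError):
                occ = 1.0
            elem = line[76:78] if len(line) >= 78 else ""
            records.append((serial, name, altloc, resname, chain, resnum, icode, xyz, occ, elem))
    if not records:
        raise ValueError(f"no ATOM/HETATM records in {path}")

    # altloc resolution: per (residue, atom name) keep the highest occupancy
    best = {}
    order = []
    for rec in records:
        key = (rec[4], rec[5], rec[6], rec[3], rec[1])  # chain,resnum,icode,resname,name
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec[8] > best[key][8]:
            best[key] = rec

    atoms = []
    residue_order = []
    for key in order:
        serial, name, _alt, resname, chain, resnum, icode, xyz, _occ, elem = best[key]
        rk = (chain, resnum, icode, resname)
        element = _element_from_pdb(name, elem)
        is_metal = element in METAL_ELEMENTS and resname.upper() not in _SIDECHAIN_DONORS
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                coords=xyz,
                residue_key=rk,
                is_protein=True,
                is_metal=is_metal and resname.upper() == element,
            )
        )
        if rk not in residue_order:
            residue_order.append(rk)
    return atoms, residue_order


def _parse_ligand_rdkit(path) -> tuple[list, list, set]:
    from rdkit import Chem

    path = str(path)
    if path.lower().endswith(".mol2"):
        mol = Chem.MolFromMol2File(path, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromMolFile(path, sanitize=False, removeHs=False)
    if mol is None:
        raise ValueError(f"unreadable ligand file: {path}")
    try:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    except Exception:
        pass  # constructed fixtures need no valence model
    conf = mol.GetConformer()
    atoms, bonds, aromatic = [], [], set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        element = atom.GetSymbol().upper()
        if not element:
            raise ValueError(f"ligand atom {idx} has no element")
        charge = atom.GetFormalCharge()
        atoms.append(
            AtomRecord(
                serial=idx,
                name=f"{element}{idx}",
                element=element,
                coords=np.array([pos.x, pos.y, pos.z]),
                residue_key=("L", 1, "", "LIG"),
                is_protein=False,
                formal_charge_class=(
                    "cationic" if charge > 0 else "anionic" if charge < 0 else "neutral"
                ),
            )
        )
        if atom.GetIsAromatic():
            aromatic.add(idx)
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        if bond.GetIsAromatic():
            aromatic.add(bond.GetBeginAtomIdx())
            aromatic.add(bond.GetEndAtomIdx())
    return atoms, bonds, aromatic


def parse_complex(protein_file, ligand_file) -> ComplexModel:
    """Parse a protein PDB and a ligand SDF/MOL2 into a ComplexModel.

    Residue order follows file order; ligand atom serials are offset past
    the protein's so serials stay unique.  Protein hydrogens are attached to
    their heavy atom by distance (≤ 1.2 Å within the same residue), ligand
    hydrogens by the file's bonds.
    """
    protein_atoms, residue_order = _parse_pdb_protein(protein_file)
    if not residue_order:
        raise ValueError("zero protein residues")
    lig_atoms, lig_bonds, lig_aromatic = _parse_ligand_rdkit(ligand_file)
    if not any(a.is_heavy for a in lig_atoms):
        raise ValueError("zero ligand heavy atoms")

    offset = max(a.serial for a in protein_atoms) + 1
    for a in lig_atoms:
        a.serial += offset
    lig_bonds = [(i + offset, j + offset) for i, j in lig_bonds]
    lig_aromatic = {i + offset for i in lig_aromatic}

    model = ComplexModel(
        protein_atoms=protein_atoms,
        ligand_atoms=lig_atoms,
        residue_order=residue_order,
        ligand_bonds=lig_bonds,
        ligand_aromatic_serials=lig_aromatic,
    )
    _attach_protein_hydrogens(model)
    _attach_ligand_hydrogens(model)
    return model


def _attach_protein_hydrogens(model: ComplexModel, dmax: float = 1.2) -> None:
    heavies = [a for a in model.protein_atoms if a.is_heavy]
    hydros = [a for a in model.protein_atoms if not a.is_heavy]
    if not hydros:
        return
    tree = cKDTree(np.array([a.coords for a in heavies]))
    for h in hydros:
        cand = tree.query_ball_point(h.coords, dmax)
        # closest heavy atom in the same residue
        cand = [i for i in cand if heavies[i].residue_key == h.residue_key]
        if not cand:
            continue
        best = min(cand, key=lambda i: np.linalg.norm(heavies[i].coords - h.coords))
        heavies[best].attached_hydrogens.append(h.serial)


def _attach_ligand_hydrogens(model: ComplexModel) -> None:
    by_serial = {a.serial: a for a in model.ligand_atoms}
    for i, j in model.ligand_bonds:
        ai, aj = by_serial.get(i), by_serial.get(j)
        if ai is None or aj is None:
            continue
        if ai.is_heavy and not aj.is_heavy:
            ai.attached_hydrogens.append(j)
        elif aj.is_heavy and not ai.is_heavy:
            aj.attached_hydrogens.append(i)


# --------------------------------------------------------------------------
# feature perception


def _infer_protein_bonds(model: ComplexModel, dmax: float = 1.9) -> dict:
    """Heavy-atom adjacency of the protein inferred from distances."""
    heavies = [a for a in model.protein_atoms if a.is_heavy and not a.is_metal]
    coords = np.array([a.coords for a in heavies])
    adj = {a.serial: set() for a in heavies}
    if len(heavies) >= 2:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(dmax):
            adj[heavies[i].serial].add(heavies[j].serial)
            adj[heavies[j].serial].add(heavies[i].serial)
    return adj


def _hydrophobic_flags(atoms, adjacency, by_serial) -> None:
    for a in atoms:
        if not a.is_heavy or a.is_metal:
            continue
        el = a.element.upper()
        if el != "C" and el not in HALOGENS:
            continue
        neighbours = [by_serial[s] for s in adjacency.get(a.serial, ()) if s in by_serial]
        heavy_nb = [n for n in neighbours if n.is_heavy]
        a.is_hydrophobic = all(
            n.element.upper() == "C" or n.element.upper() in HALOGENS for n in heavy_nb
        )


def perceive_features(model: ComplexModel, rules: dict | None = None) -> ComplexModel:
    """Annotate donor/acceptor/charge/hydrophobic flags and detect rings.

    Protein flags come from the per-residue-name lookup table (overridable via
    ``rules`` with keys ``donors``, ``acceptors``, ``cationic``, ``anionic``
    mapping resname → atom-name sets).  Ligand flags are derived from the
    input file's elements, bonds and formal charges only.
    """
    rules = rules or {}
    donors = {**_SIDECHAIN_DONORS, **rules.get("donors", {})}
    acceptors = {**_SIDECHAIN_ACCEPTORS, **rules.get("acceptors", {})}
    cationic = {**_CATIONIC, **rules.get("cationic", {})}
    anionic = {**_ANIONIC, **rules.get("anionic", {})}

    for a in model.protein_atoms:
        if a.is_metal or not a.is_heavy:
            continue
        resname = a.residue_key[3].upper()
        name = a.name.upper()
        if name == "N" and resname != "PRO":
            a.is_hbond_donor_heavy = True
        if name in ("O", "OXT"):
            a.is_hbond_acceptor = True
        if name in donors.get(resname, ()):
            a.is_hbond_donor_heavy = True
        if name in acceptors.get(resname, ()):
            a.is_hbond_acceptor = True
        if name in cationic.get(resname, ()):
            a.formal_charge_class = "cationic"
        if name in anionic.get(resname, ()):
            a.formal_charge_class = "anionic"

    # hydrophobicity from bonded environment (protein: distance-inferred bonds)
    protein_adj = _infer_protein_bonds(model)
    by_serial_p = {a.serial: a for a in model.protein_atoms}
    _hydrophobic_flags(model.protein_atoms, protein_adj, by_serial_p)

    lig_adj = {a.serial: set() for a in model.ligand_atoms}
    by_serial_l = {a.serial: a for a in model.ligand_atoms}
    for i, j in model.ligand_bonds:
        if i in lig_adj and j in lig_adj:
            lig_adj[i].add(j)
            lig_adj[j].add(i)
    _hydrophobic_flags(model.ligand_atoms, lig_adj, by_serial_l)

    for a in model.ligand_atoms:
        if not a.is_heavy:
            continue
        el = a.element.upper()
        has_h = bool(a.attached_hydrogens)
        if el in ("N", "O", "S") and has_h:
            a.is_hbond_donor_heavy = True
        if a.formal_charge_class != "cationic":
            if el == "O":
                a.is_hbond_acceptor = True
            elif el == "N" and not has_h:
                a.is_hbond_acceptor = True

    model.rings = _perceive_rings(model, lig_adj, by_serial_l)
    model.perceived = True
    return model


def _perceive_rings(model: ComplexModel, lig_adj: dict, by_serial_l: dict) -> list:
    rings = []
    # protein: canonical ring atoms of His/Phe/Tyr/Trp
    by_res: dict = {}
    for a in model.protein_atoms:
        by_res.setdefault(a.residue_key, {})[a.name.upper()] = a
    for rk, atoms in by_res.items():
        for names in _RESIDUE_RINGS.get(rk[3].upper(), ()):
            if all(n in atoms for n in names):
                members = [atoms[n] for n in names]
                centroid, normal = ring_geometry([m.coords for m in members])
                rings.append(
                    AromaticRing(
                        member_serials=tuple(m.serial for m in members),
                        centroid=centroid,
                        normal=normal,
                        owner=rk,
                    )
                )
    # ligand: 5/6-cycles whose atoms are flagged aromatic in the input
    heavy_graph = nx.Graph()
    for s, nbrs in lig_adj.items():
        if not by_serial_l[s].is_heavy:
            continue
        heavy_graph.add_node(s)
        for t in nbrs:
            if by_serial_l[t].is_heavy:
                heavy_graph.add_edge(s, t)
    for cycle in nx.cycle_basis(heavy_graph):
        if len(cycle) in (5, 6) and all(s in model.ligand_aromatic_serials for s in cycle):
            coords = [by_serial_l[s].coords for s in cycle]
            centroid, normal = ring_geometry(coords)
            rings.append(
                AromaticRing(
                    member_serials=tuple(cycle),
                    centroid=centroid,
                    normal=normal,
                    owner="ligand",
                )
            )
    return rings


# --------------------------------------------------------------------------
# trajectory I/O


def load_trajectory(model: ComplexModel, topology, trajectory, window_metadata) -> list:
    """Load frames with MDAnalysis, tagging each with its window temperature.

    ``window_metadata`` is a sequence of ``{"temperature": K, "n_frames": int}``
    mappings consumed in order; their frame counts must sum to the trajectory
    length.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(trajectory))
    n_model = len(model.protein_atoms) + len(model.ligand_atoms)
    if len(u.atoms) != n_model:
        raise ValueError(f"trajectory has {len(u.atoms)} atoms, model has {n_model}")
    if len(u.trajectory) == 0:
        raise ValueError("empty trajectory")

    temps = []
    for meta in window_metadata:
        temps.extend([float(meta["temperature"])] * int(meta["n_frames"]))
    if len(temps) != len(u.trajectory):
        raise ValueError(
            f"window metadata covers {len(temps)} frames, trajectory has {len(u.trajectory)}"
        )

    n_p = len(model.protein_atoms)
    frames = []
    for i, ts in enumerate(u.trajectory):
        pos = ts.positions.astype(float)
        frames.append(
            Frame(
                index=i,
                time=float(ts.time) if ts.time is not None else float(i),
                temperature_set=temps[i],
                coords_protein=pos[:n_p],
                coords_ligand=pos[n_p:],
            )
        )
    return frames


def write_complex(model: ComplexModel, protein_path, ligand_path) -> None:
    """Write the model as a PDB (protein) and SDF (ligand) pair."""
    with open(protein_path, "w") as fh:
        for a in model.protein_atoms:
            chain, resnum, icode, resname = a.residue_key
            record = "HETATM" if a.is_metal else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"{record}{a.serial:>5d} {name:<4s}{'':1s}{resname:<3s} "
                f"{chain:1s}{resnum:>4d}{icode:1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")

    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    serial_to_idx = {}
    for a in model.ligand_atoms:
        atom = Chem.Atom(a.element.capitalize())
        charge = {"cationic": 1, "anionic": -1, "neutral": 0}[a.formal_charge_class]
        atom.SetFormalCharge(charge)
        atom.SetNoImplicit(True)
        if a.serial in model.ligand_aromatic_serials:
            atom.SetIsAromatic(True)
        serial_to_idx[a.serial] = mol.AddAtom(atom)
    for i, j in model.ligand_bonds:
        aromatic = (
            i in model.ligand_aromatic_serials
            and j in model.ligand_aromatic_serials
            and model.atom_by_serial(i).is_heavy
            and model.atom_by_serial(j).is_heavy
        )
        mol.AddBond(
            serial_to_idx[i],
            serial_to_idx[j],
            Chem.BondType.AROMATIC if aromatic else Chem.BondType.SINGLE,
        )
    conf = Chem.Conformer(mol.GetNumAtoms())
    for a in model.ligand_atoms:
        conf.SetAtomPosition(serial_to_idx[a.serial], Point3D(*a.coords))
    mol.AddConformer(conf)
    with Chem.SDWriter(str(ligand_path)) as writer:
        writer.SetKekulize(False)
        writer.write(mol.GetMol())
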