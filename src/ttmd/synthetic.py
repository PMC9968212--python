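"""Synthetic complexes and toy dynamics with known unbinding ground truth.

``make_fixture_complex`` builds a protein–ligand complex that realises a
declared set of native interactions — one geometry template per interaction
class — with every declared contact strictly inside its detection threshold
and nothing else anywhere near one.  ``SyntheticBackend`` then evolves the
ligand with a deliberately simple stochastic model: each native interaction
survives a frame at temperature T with logistic probability
``p_i(T) = 1 / (1 + exp((T − T_i) / sharpness))`` around its characteristic
temperature ``T_i``; a lost interaction's ligand moiety is displaced far
outside detection range, and once a whole window passes with no interaction
intact the ligand is marked dissociated.  This gives the titration protocol
a testbed whose stability ordering is known by construction.

Geometry notes: protein aromatic sites use histidine rings and the ligand
ring is a plain benzene, so ring stacking generates no incidental
hydrophobic contacts (every His ring atom borders a nitrogen and is
therefore non-hydrophobic under the bonded-environment rule); sites are
spaced 16 Å apart along the x axis so interactions never cross-talk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .complex_model import AtomRecord, ComplexModel, Frame, perceive_features
from .fingerprint import InteractionClass

__all__ = [
    "SyntheticLigandSpec",
    "SyntheticPoseSet",
    "SyntheticBackend",
    "make_fixture_complex",
    "make_pose_set",
    "synth_run_window",
    "write_frames_dcd",
    "write_topology_pdb",
]

SITE_SPACING = 16.0  # Å between interaction sites along x
FAR_Y = 25.0  # y offset of residues that host no interaction
DISPLACE_Y = -10.0  # y shift applied to a lost ligand moiety
JITTER = 0.1  # per-coordinate jitter of intact moieties (max displacement < 0.2 Å)


@dataclass
class SyntheticLigandSpec:
    """Ground truth for one synthetic pose.

    ``native_interactions`` is a list of ``(InteractionClass, residue_index)``
    pairs (the geometry template is implied by the class); each interaction
    has its own characteristic temperature at which its survival probability
    is 1/2.
    """

    native_interactions: list
    characteristic_temperatures: list
    sharpness: float = 5.0
    rebind_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.characteristic_temperatures) != len(self.native_interactions):
            raise ValueError("one characteristic temperature per interaction required")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")
        if not 0.0 <= self.rebind_probability <= 1.0:
            raise ValueError("rebind_probability must be in [0, 1]")

    def retention_probability(self, temperature: float) -> np.ndarray:
        t = np.asarray(self.characteristic_temperatures, dtype=float)
        return 1.0 / (1.0 + np.exp((temperature - t) / self.sharpness))

    def median_characteristic_temperature(self) -> float:
        return float(np.median(self.characteristic_temperatures))


@dataclass
class SyntheticPoseSet:
    """Poses sharing one complex topology, with their true stability order."""

    poses: list  # [(pose_id, SyntheticLigandSpec), ...]
    model: ComplexModel
    reference_frame: Frame
    true_stability_order: list  # pose ids, most stable first


# --------------------------------------------------------------------------
# fixture construction


class _Builder:
    def __init__(self):
        self.protein_atoms = []
        self.ligand_atoms = []
        self.ligand_bonds = []
        self.ligand_aromatic = set()
        self._p_serial = 0
        self._l_serial = 10000

    def add_p(self, name, element, xyz, residue_key, is_metal=False, attach_to=None):
        self._p_serial += 1
        a = AtomRecord(
            serial=self._p_serial, name=name, element=element,
            coords=np.asarray(xyz, float), residue_key=residue_key,
            is_protein=True, is_metal=is_metal,
        )
        self.protein_atoms.append(a)
        if attach_to is not None:
            attach_to.attached_hydrogens.append(a.serial)
        return a

    def add_l(self, element, xyz, charge=0, aromatic=False, attach_to=None):
        self._l_serial += 1
        a = AtomRecord(
            serial=self._l_serial, name=f"{element}{self._l_serial - 10000}",
            element=element, coords=np.asarray(xyz, float),
            residue_key=("L", 1, "", "LIG"), is_protein=False,
            formal_charge_class="cationic" if charge > 0 else "anionic" if charge < 0 else "neutral",
        )
        self.ligand_atoms.append(a)
        if aromatic:
            self.ligand_aromatic.add(a.serial)
        if attach_to is not None:
            self.ligand_bonds.append((attach_to.serial, a.serial))
            if not a.is_heavy:
                attach_to.attached_hydrogens.append(a.serial)
        return a

    def bond_l(self, a, b, aromatic=False):
        self.ligand_bonds.append((a.serial, b.serial))
        if aromatic:
            self.ligand_aromatic.update((a.serial, b.serial))


def _backbone(b: _Builder, rk, x, y):
    # carbonyl O off the z=0 plane keeps backbone sets non-collinear,
    # which the RMSD superposition needs
    b.add_p("N", "N", (x, y, 0.0), rk)
    b.add_p("CA", "C", (x + 1.5, y, 0.0), rk)
    b.add_p("C", "C", (x + 3.0, y, 0.0), rk)
    b.add_p("O", "O", (x + 4.2, y, 0.8), rk)


def _ring_coords(centroid, normal, radius, n):
    """n points on a circle around centroid in the plane orthogonal to normal."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = 2 * np.pi * np.arange(n) / n
    return [np.asarray(centroid) + radius * (np.cos(t) * u + np.sin(t) * v) for t in angles]


def _add_benzene(b: _Builder, centroid, normal):
    """Carbons-only aromatic 6-ring; returns its atoms (any is a link point)."""
    coords = _ring_coords(centroid, normal, 1.39, 6)
    atoms = [b.add_l("C", c, aromatic=True) for c in coords]
    for i in range(6):
        b.bond_l(atoms[i], atoms[(i + 1) % 6], aromatic=True)
    return atoms


def _add_his_ring(b: _Builder, rk, centroid, normal):
    names = ["CG", "ND1", "CE1", "NE2", "CD2"]  # canonical adjacency order
    elements = ["C", "N", "C", "N", "C"]
    for name, el, c in zip(names, elements, _ring_coords(centroid, normal, 1.15, 5)):
        b.add_p(name, el, c, rk)


def _build_site(b: _Builder, cls: InteractionClass, rk, x: float):
    """Place one interaction site; returns the ligand moiety's atoms."""
    if cls == InteractionClass.HYDROPHOBIC:
        # ALA CB over a ligand methyl carbon, 3.5 Å apart
        b.add_p("N", "N", (x - 1.45, 5.0, 0.0), rk)
        b.add_p("CA", "C", (x, 5.0, 0.0), rk)
        b.add_p("C", "C", (x + 1.45, 5.0, 0.0), rk)
        b.add_p("O", "O", (x + 2.65, 5.0, 0.8), rk)
        b.add_p("CB", "C", (x, 3.5, 0.0), rk)
        return [b.add_l("C", (x, 0.0, 0.0))]

    if cls == InteractionClass.AROMATIC_FACE_TO_FACE:
        _backbone(b, rk, x, 7.0)
        _add_his_ring(b, rk, (x, 3.6, 0.0), (0.0, 1.0, 0.0))
        return _add_benzene(b, (x, 0.0, 0.0), (0.0, 1.0, 0.0))

    if cls == InteractionClass.AROMATIC_EDGE_TO_FACE:
        _backbone(b, rk, x, 8.0)
        _add_his_ring(b, rk, (x, 4.5, 0.0), (0.0, 1.0, 0.0))
        tilt = np.deg2rad(75.0)
        return _add_benzene(b, (x, 0.0, 0.0), (np.sin(tilt), np.cos(tilt), 0.0))

    if cls == InteractionClass.HBOND_PROTEIN_DONOR:
        # backbone N–H donating to a ligand ether-type oxygen, N···O 2.9 Å
        n = b.add_p("N", "N", (x, 2.9, 0.0), rk)
        b.add_p("H", "H", (x, 1.9, 0.0), rk, attach_to=n)
        b.add_p("CA", "C", (x + 1.45, 2.9, 0.0), rk)
        b.add_p("C", "C", (x + 2.9, 2.9, 0.0), rk)
        b.add_p("O", "O", (x + 2.9, 4.13, 0.0), rk)
        o = b.add_l("O", (x, 0.0, 0.0))
        b.add_l("C", (x, -1.43, 0.0), attach_to=o)
        return [o]

    if cls == InteractionClass.HBOND_PROTEIN_ACCEPTOR:
        # ligand N–H donating to a backbone carbonyl oxygen, N···O 2.9 Å
        b.add_p("O", "O", (x, 2.9, 0.0), rk)
        b.add_p("C", "C", (x, 4.13, 0.0), rk)
        b.add_p("CA", "C", (x + 1.45, 4.13, 0.0), rk)
        b.add_p("N", "N", (x + 2.9, 4.13, 0.0), rk)
        n = b.add_l("N", (x, 0.0, 0.0))
        h = b.add_l("H", (x, 1.0, 0.0), attach_to=n)
        b.add_l("C", (x, -1.43, 0.0), attach_to=n)
        return [n, h]

    if cls == InteractionClass.SALTBRIDGE_PROTEIN_POSITIVE:
        _backbone(b, rk, x, 7.0)
        b.add_p("NZ", "N", (x, 3.4, 0.0), rk)
        o = b.add_l("O", (x, 0.0, 0.0), charge=-1)
        b.add_l("C", (x, -1.43, 0.0), attach_to=o)
        return [o]

    if cls == InteractionClass.SALTBRIDGE_PROTEIN_NEGATIVE:
        _backbone(b, rk, x, 7.5)
        b.add_p("OD1", "O", (x, 3.4, 0.0), rk)
        b.add_p("CG", "C", (x, 4.6, 0.0), rk)
        b.add_p("OD2", "O", (x + 1.1, 5.2, 0.0), rk)
        n = b.add_l("N", (x, 0.0, 0.0), charge=1)
        h = b.add_l("H", (x - 0.8, -0.6, 0.0), attach_to=n)
        b.add_l("C", (x + 1.0, -1.0, 0.0), attach_to=n)
        return [n, h]

    if cls == InteractionClass.METAL_IONIC:
        b.add_p("ZN", "ZN", (x, 2.2, 0.0), rk, is_metal=True)
        o = b.add_l("O", (x, 0.0, 0.0), charge=-1)
        b.add_l("C", (x, -1.43, 0.0), attach_to=o)
        return [o]

    raise ValueError(f"no geometry template for {cls}")


_RESNAME_FOR_CLASS = {
    InteractionClass.HYDROPHOBIC: "ALA",
    InteractionClass.AROMATIC_FACE_TO_FACE: "HIS",
    InteractionClass.AROMATIC_EDGE_TO_FACE: "HIS",
    InteractionClass.HBOND_PROTEIN_DONOR: "GLY",
    InteractionClass.HBOND_PROTEIN_ACCEPTOR: "GLY",
    InteractionClass.SALTBRIDGE_PROTEIN_POSITIVE: "LYS",
    InteractionClass.SALTBRIDGE_PROTEIN_NEGATIVE: "ASP",
    InteractionClass.METAL_IONIC: "ZN",
}


@dataclass
class _Fixture:
    model: ComplexModel
    reference_frame: Frame
    moiety_rows: list  # per interaction, ligand row indices to displace on loss
    spec: SyntheticLigandSpec


def _build_fixture(spec: SyntheticLigandSpec, n_residues: int) -> _Fixture:
    interactions = [(InteractionClass(c), int(i)) for c, i in spec.native_interactions]
    referenced = [i for _, i in interactions]
    if len(set(referenced)) != len(referenced):
        raise ValueError("infeasible geometry packing: one interaction site per residue")
    if referenced and max(referenced) >= n_residues:
        raise ValueError("n_residues must cover every referenced residue index")
    if n_residues < 1:
        raise ValueError("need at least one residue")

    by_residue = dict((i, c) for c, i in interactions)
    b = _Builder()
    moiety_atoms_by_residue = {}
    for i in range(n_residues):
        x = SITE_SPACING * i
        if i in by_residue:
            cls = by_residue[i]
            rk = ("A", i + 1, "", _RESNAME_FOR_CLASS[cls])
            n0 = len(b.ligand_atoms)
            _build_site(b, cls, rk, x)
            moiety_atoms_by_residue[i] = b.ligand_atoms[n0:]
        else:
            rk = ("A", i + 1, "", "GLY")
            _backbone(b, rk, x, FAR_Y)

    if not b.ligand_atoms:
        # a ligand must exist even for an interaction-free spec
        b.add_l("C", (0.0, FAR_Y * -1, 0.0))

    # chain the moieties with carbon–carbon bonds between their link carbons
    def _link_carbon(atoms):
        return next(a for a in atoms if a.is_heavy and a.element == "C")

    ordered = sorted(moiety_atoms_by_residue)
    for a_i, b_i in zip(ordered, ordered[1:]):
        b.bond_l(
            _link_carbon(moiety_atoms_by_residue[a_i]),
            _link_carbon(moiety_atoms_by_residue[b_i]),
        )

    residue_order = []
    for a in b.protein_atoms:
        if a.residue_key not in residue_order:
            residue_order.append(a.residue_key)
    model = ComplexModel(
        protein_atoms=b.protein_atoms,
        ligand_atoms=b.ligand_atoms,
        residue_order=residue_order,
        ligand_bonds=b.ligand_bonds,
        ligand_aromatic_serials=b.ligand_aromatic,
    )
    perceive_features(model)

    # ligand rows belonging to each interaction's moiety (displaced on loss)
    serial_to_row = {a.serial: r for r, a in enumerate(model.ligand_atoms)}
    moiety_rows = [
        sorted(serial_to_row[a.serial] for a in moiety_atoms_by_residue[res_i])
        for (_cls, res_i) in interactions
    ]

    return _Fixture(
        model=model,
        reference_frame=model.reference_frame(),
        moiety_rows=moiety_rows,
        spec=spec,
    )


def make_fixture_complex(spec: SyntheticLigandSpec, n_residues: int):
    """Build a complex realising the spec's declared interactions exactly.

    Returns ``(model, reference_frame)``; the model is already perceived.
    Deterministic: the layout depends only on the declared interactions.
    """
    fx = _build_fixture(spec, n_residues)
    return fx.model, fx.reference_frame


# --------------------------------------------------------------------------
# toy dynamics


@dataclass
class _SynthState:
    fixture: _Fixture
    dissociated: bool = False
    t0_ps: float = 0.0
    frame_offset: int = 0


class SyntheticBackend:
    """Dynamics backend producing logistic-decay trajectories for a fixture."""

    def __init__(self, spec: SyntheticLigandSpec, n_residues: int):
        self.fixture = _build_fixture(spec, n_residues)
        self.model = self.fixture.model
        self.reference_frame = self.fixture.reference_frame

    def run_window(self, state, temperature, duration_ns, stride_ps, seed):
        if not isinstance(state, _SynthState):
            state = _SynthState(fixture=self.fixture)
        return synth_run_window(state, temperature, duration_ns, stride_ps, seed)


def synth_run_window(state: _SynthState, temperature: float, duration_ns: float,
                     stride_ps: float, seed: int):
    """Generate one window of toy dynamics; returns ``(frames, end_state)``.

    Per frame each native interaction is intact independently with its
    logistic retention probability (or the rebind probability once the
    ligand has dissociated).  Intact moieties keep template geometry with
    sub-0.2 Å jitter; lost ones are displaced far beyond detection range.
    """
    fx = state.fixture
    spec = fx.spec
    rng = np.random.default_rng(seed)
    n_frames = max(1, int(round(duration_ns * 1000.0 / stride_ps)))
    p = spec.retention_probability(temperature)
    n_int = len(fx.moiety_rows)

    ref_lig = fx.reference_frame.coords_ligand
    ref_prot = fx.reference_frame.coords_protein
    frames = []
    any_intact_in_window = False
    for f in range(n_frames):
        if n_int:
            if state.dissociated:
                intact = rng.random(n_int) < spec.rebind_probability
            else:
                intact = rng.random(n_int) < p
        else:
            intact = np.zeros(0, dtype=bool)
        if intact.any():
            any_intact_in_window = True
        coords = ref_lig.copy()
        for i, rows in enumerate(fx.moiety_rows):
            jitter = rng.uniform(-JITTER, JITTER, size=(len(rows), 3))
            coords[rows] += jitter
            if not intact[i]:
                coords[rows, 1] += DISPLACE_Y
        frames.append(
            Frame(
                index=state.frame_offset + f,
                time=state.t0_ps + (f + 1) * stride_ps,
                temperature_set=temperature,
                coords_protein=ref_prot,
                coords_ligand=coords,
            )
        )

    end = _SynthState(
        fixture=fx,
        dissociated=state.dissociated or (n_int > 0 and not any_intact_in_window),
        t0_ps=state.t0_ps + n_frames * stride_ps,
        frame_offset=state.frame_offset + n_frames,
    )
    return frames, end


# --------------------------------------------------------------------------
# pose sets


DEFAULT_POSE_INTERACTIONS = (
    (InteractionClass.HYDROPHOBIC, 1),
    (InteractionClass.HBOND_PROTEIN_DONOR, 3),
    (InteractionClass.HBOND_PROTEIN_ACCEPTOR, 5),
    (InteractionClass.SALTBRIDGE_PROTEIN_POSITIVE, 7),
)


def make_pose_set(
    n_poses: int,
    n_residues: int = 9,
    temperature_spread: float = 30.0,
    seed: int = 0,
    base_temperature: float = 320.0,
    sharpness: float = 5.0,
) -> SyntheticPoseSet:
    """Poses sharing one topology but differing in characteristic temperatures.

    Pose ``k`` (0-based) centres its interaction temperatures at
    ``base_temperature + k * temperature_spread`` with small seeded
    per-interaction offsets, so the true stability order is by construction
    the reverse pose order (later poses unbind hotter, hence are more
    stable and should earn lower MS).
    """
    if n_poses < 2:
        raise ValueError("need at least 2 poses")
    if temperature_spread == 0:
        warnings.warn("all poses share one characteristic temperature; the true "
                      "stability order is undefined", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    interactions = list(DEFAULT_POSE_INTERACTIONS)
    poses = []
    for k in range(n_poses):
        centre = base_temperature + k * temperature_spread
        offsets = rng.uniform(-5.0, 5.0, size=len(interactions))
        spec = SyntheticLigandSpec(
            native_interactions=interactions,
            characteristic_temperatures=(centre + offsets).tolist(),
            sharpness=sharpness,
            seed=int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % 2**31),
        )
        poses.append((f"pose{k + 1}", spec))

    model, ref = make_fixture_complex(poses[0][1], n_residues)
    order = sorted(
        poses,
        key=lambda p: -p[1].median_characteristic_temperature(),
    )
    return SyntheticPoseSet(
        poses=poses,
        model=model,
        reference_frame=ref,
        true_stability_order=[pid for pid, _ in order],
    )


# --------------------------------------------------------------------------
# real-format I/O for fixtures


def write_topology_pdb(model: ComplexModel, path) -> None:
    """Combined protein+ligand PDB usable as an MDAnalysis topology."""
    with open(path, "w") as fh:
        serial = 0
        for a in model.protein_atoms + model.ligand_atoms:
            serial += 1
            chain, resnum, icode, resname = a.residue_key
            record = "ATOM  " if a.is_protein and not a.is_metal else "HETATM"
            name = a.name[:4]
            name = name if len(name) == 4 else f" {name:<3s}"
            fh.write(
                f"{record}{serial:>5d} {name:<4s}{'':1s}{resname:<3s} "
                f"{chain:1s}{resnum:>4d}{icode:1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element[:2]:>2s}\n"
            )
        fh.write("END\n")


def write_frames_dcd(model: ComplexModel, frames, path) -> None:
    """Write frames as a DCD trajectory congruent with the model's atoms."""
    import MDAnalysis as mda

    n_atoms = len(model.protein_atoms) + len(model.ligand_atoms)
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=n_atoms) as writer:
        for frame in frames:
            u.atoms.positions = np.vstack([frame.coords_protein, frame.coords_ligand])
            writer.write(u.atoms)
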