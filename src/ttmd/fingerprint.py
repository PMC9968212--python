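"""Protein–ligand interaction fingerprints and the IFP_CS scoring function.

Eight interaction classes are detected per trajectory frame and encoded as
an integer vector of length r × 8 (r protein residues, fixed ordering, one
8-slot block per residue).  A frame is scored against the reference complex
by cosine similarity of the two count vectors multiplied by −1, so scores
run from −1 (the native binding mode is fully conserved) to 0 (every
reference interaction has been lost).  The zero score doubles as the
protocol's early-termination signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .complex_model import ComplexModel, Frame, ring_geometry

__all__ = [
    "InteractionClass",
    "InteractionGeometryConfig",
    "InteractionFingerprint",
    "FrameScore",
    "detect_interactions",
    "build_fingerprint",
    "cosine_similarity",
    "ifp_cs_score",
    "window_mean_ifpcs",
    "fingerprint_frame",
]

log = logging.getLogger(__name__)


class InteractionClass(IntEnum):
    """The 8 fingerprint slots, in their fixed encoding order."""

    HYDROPHOBIC = 0
    AROMATIC_FACE_TO_FACE = 1
    AROMATIC_EDGE_TO_FACE = 2
    HBOND_PROTEIN_DONOR = 3
    HBOND_PROTEIN_ACCEPTOR = 4
    SALTBRIDGE_PROTEIN_POSITIVE = 5
    SALTBRIDGE_PROTEIN_NEGATIVE = 6
    METAL_IONIC = 7


N_CLASSES = len(InteractionClass)
assert N_CLASSES == 8


@dataclass(frozen=True)
class InteractionGeometryConfig:
    """Geometric detection thresholds (Å / degrees), ODDT-compatible defaults."""

    hydrophobic_dmax: float = 4.0
    hbond_dmax: float = 3.5  # donor heavy -- acceptor heavy
    hbond_angle_min: float = 130.0  # donor–H···acceptor
    saltbridge_dmax: float = 4.0
    ring_centroid_dmax: float = 5.0
    face_angle_max: float = 30.0
    edge_angle_range: tuple = (60.0, 90.0)
    metal_dmax: float = 3.0

    def __post_init__(self):
        for name in ("hydrophobic_dmax", "hbond_dmax", "saltbridge_dmax",
                     "ring_centroid_dmax", "metal_dmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for angle in (self.hbond_angle_min, self.face_angle_max, *self.edge_angle_range):
            if not 0 <= angle <= 180:
                raise ValueError("angles must lie in [0, 180] degrees")


@dataclass
class InteractionFingerprint:
    """Integer count vector of length r × 8; slot(residue i, class c) = i*8 + c."""

    counts: np.ndarray
    residue_order: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.residue_order) * N_CLASSES,):
            raise ValueError("fingerprint length must be r × 8")
        if np.any(self.counts < 0):
            raise ValueError("fingerprint counts must be non-negative")

    @property
    def r(self) -> int:
        return len(self.residue_order)

    def count(self, residue_index: int, cls: InteractionClass) -> int:
        return int(self.counts[residue_index * N_CLASSES + int(cls)])

    def nonzero_slots(self) -> set:
        return set(np.flatnonzero(self.counts).tolist())


@dataclass
class FrameScore:
    """IFP_CS of one frame against the run's reference fingerprint."""

    ifp_cs: float
    frame_index: int
    temperature: float

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.ifp_cs <= 1e-9:
            raise ValueError(f"IFP_CS out of range: {self.ifp_cs}")


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the path a–b–c, in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _planes_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring normals folded into [0, 90] degrees."""
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def detect_interactions(
    model: ComplexModel,
    frame: Frame,
    cfg: InteractionGeometryConfig | None = None,
) -> list:
    """Detect all protein–ligand interaction instances in one frame.

    Returns ``[(residue_key, InteractionClass), ...]`` with one tuple per
    qualifying atom pair or ring pair.  An atom pair that qualifies as a salt
    bridge (cationic–anionic) is counted only as a salt bridge, never
    additionally as a hydrogen bond.  Hydrogen-bond geometry uses the
    donor–H···acceptor angle when the donor's hydrogens are recorded and
    degrades to the heavy-atom distance alone when they are not.
    """
    if not model.perceived:
        raise ValueError("model features not perceived; call perceive_features first")
    cfg = cfg or InteractionGeometryConfig()
    frame.check_congruent(model)

    p_atoms = model.protein_atoms
    l_atoms = model.ligand_atoms
    p_xyz = frame.coords_protein
    l_xyz = frame.coords_ligand
    coords_of = {}
    for a, xyz in zip(p_atoms, p_xyz):
        coords_of[a.serial] = xyz
    for a, xyz in zip(l_atoms, l_xyz):
        coords_of[a.serial] = xyz

    p_heavy = [(i, a) for i, a in enumerate(p_atoms) if a.is_heavy]
    l_heavy = [(i, a) for i, a in enumerate(l_atoms) if a.is_heavy]
    if not p_heavy or not l_heavy:
        return []
    dmat = np.linalg.norm(
        p_xyz[[i for i, _ in p_heavy], None, :] - l_xyz[None, [i for i, _ in l_heavy], :],
        axis=-1,
    )

    found = []
    max_cut = max(
        cfg.hydrophobic_dmax, cfg.hbond_dmax, cfg.saltbridge_dmax, cfg.metal_dmax
    )
    cand = np.argwhere(dmat <= max_cut)

    def _hbond_geometry_ok(donor, acceptor) -> bool:
        hs = [coords_of[s] for s in donor.attached_hydrogens if s in coords_of]
        if not hs:
            log.debug("donor %s has no recorded hydrogens; distance-only H-bond test", donor.serial)
            return True
        d_xyz, a_xyz = coords_of[donor.serial], coords_of[acceptor.serial]
        return any(_angle_deg(d_xyz, h, a_xyz) >= cfg.hbond_angle_min for h in hs)

    for pi, li in cand:
        pa = p_heavy[pi][1]
        la = l_heavy[li][1]
        d = dmat[pi, li]
        rk = pa.residue_key

        if pa.is_metal:
            if d <= cfg.metal_dmax and (
                la.formal_charge_class == "anionic" or la.is_hbond_acceptor
            ):
                found.append((rk, InteractionClass.METAL_IONIC))
            continue

        salt_pair = False
        if d <= cfg.saltbridge_dmax:
            if pa.formal_charge_class == "cationic" and la.formal_charge_class == "anionic":
                found.append((rk, InteractionClass.SALTBRIDGE_PROTEIN_POSITIVE))
                salt_pair = True
            elif pa.formal_charge_class == "anionic" and la.formal_charge_class == "cationic":
                found.append((rk, InteractionClass.SALTBRIDGE_PROTEIN_NEGATIVE))
                salt_pair = True

        if d <= cfg.hydrophobic_dmax and pa.is_hydrophobic and la.is_hydrophobic:
            found.append((rk, InteractionClass.HYDROPHOBIC))

        if not salt_pair and d <= cfg.hbond_dmax:
            if pa.is_hbond_donor_heavy and la.is_hbond_acceptor and _hbond_geometry_ok(pa, la):
                found.append((rk, InteractionClass.HBOND_PROTEIN_DONOR))
            if la.is_hbond_donor_heavy and pa.is_hbond_acceptor and _hbond_geometry_ok(la, pa):
                found.append((rk, InteractionClass.HBOND_PROTEIN_ACCEPTOR))

    # aromatic ring pairs (geometry recomputed from the frame's coordinates)
    p_rings = [r for r in model.rings if r.owner != "ligand"]
    l_rings = [r for r in model.rings if r.owner == "ligand"]
    for pr in p_rings:
        c1, n1 = ring_geometry([coords_of[s] for s in pr.member_serials])
        for lr in l_rings:
            c2, n2 = ring_geometry([coords_of[s] for s in lr.member_serials])
            if np.linalg.norm(c1 - c2) > cfg.ring_centroid_dmax:
                continue
            theta = _planes_angle_deg(n1, n2)
            if theta <= cfg.face_angle_max:
                found.append((pr.owner, InteractionClass.AROMATIC_FACE_TO_FACE))
            elif cfg.edge_angle_range[0] <= theta <= cfg.edge_angle_range[1]:
                found.append((pr.owner, InteractionClass.AROMATIC_EDGE_TO_FACE))

    return found


def build_fingerprint(interactions, residue_order, r: int | None = None) -> InteractionFingerprint:
    """Accumulate interaction instances into the r × 8 count vector."""
    r = len(residue_order) if r is None else r
    index = {key: i for i, key in enumerate(residue_order)}
    counts = np.zeros(r * N_CLASSES, dtype=np.int64)
    for residue_key, cls in interactions:
        if residue_key not in index:
            raise KeyError(f"unknown residue key {residue_key!r}")
        counts[index[residue_key] * N_CLASSES + int(cls)] += 1
    return InteractionFingerprint(counts=counts, residue_order=list(residue_order))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two count vectors; 0 if either is all-zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    naa, nbb = float(np.dot(a, a)), float(np.dot(b, b))
    if naa == 0.0 or nbb == 0.0:
        return 0.0
    # sqrt of the product keeps the self-similarity of a vector exactly 1
    return min(1.0, float(np.dot(a, b)) / float(np.sqrt(naa * nbb)))


def ifp_cs_score(reference: InteractionFingerprint, query: InteractionFingerprint) -> float:
    """−cosine(reference, query): −1 = native mode conserved, 0 = fully lost."""
    if reference.residue_order != query.residue_order:
        raise ValueError("reference and query fingerprints use different residue orders")
    if not reference.counts.any():
        raise ValueError("all-zero reference fingerprint: pose has no detectable native interactions")
    return -cosine_similarity(reference.counts, query.counts)


def fingerprint_frame(
    model: ComplexModel, frame: Frame, cfg: InteractionGeometryConfig | None = None
) -> InteractionFingerprint:
    """Convenience: detect interactions in a frame and build its fingerprint."""
    return build_fingerprint(detect_interactions(model, frame, cfg), model.residue_order)


def window_mean_ifpcs(scores) -> float:
    """Arithmetic mean of per-frame IFP_CS scores over one temperature window."""
    if len(scores) == 0:
        raise ValueError("empty window")
    return float(np.mean([s.ifp_cs for s in scores]))
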