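"""D6 double-ring coordinate builder for the toroidal particle.

Builds a coarse pseudo-atom model of the double hexameric toroid: six
monomer placeholders per ring at a common radius, two rings stacked head
to head (the lower ring is the upper ring flipped by a two-fold rotation)
and staggered by a configurable angle. By construction the model is
exactly invariant under the D6 point group generated by the 6-fold axis
(z) and the in-plane two-fold that exchanges the rings.

Monomers are placeholders only: each is a small fixed set of pseudo-atoms
whose envelope reproduces the particle's outer diameter, height and
channel; no side-chain or backbone model is implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ToroidSpec", "ToroidModel", "build_d6_toroid", "d6_transforms", "write_pdb"]

_CHAINS = "ABCDEFGHIJKL"


@dataclass(frozen=True)
class ToroidSpec:
    """Geometric description of the double-ring particle (angstroms/degrees)."""

    n_per_ring: int = 6
    rings: int = 2
    outer_diameter: float = 65.0
    height: float = 55.0
    channel_diameter: float = 15.0
    inter_ring_gap: float = 5.0
    stagger_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.n_per_ring < 2:
            raise ValueError("need at least 2 monomers per ring")
        if self.rings != 2:
            raise ValueError("only the double-ring arrangement is supported")
        for name in ("outer_diameter", "height", "channel_diameter", "inter_ring_gap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.channel_diameter >= self.outer_diameter:
            raise ValueError("channel diameter must be smaller than outer diameter")
        if self.inter_ring_gap >= self.height:
            raise ValueError("inter-ring gap must be smaller than particle height")

    @property
    def ring_radius(self) -> float:
        """Monomer-center radius: midway between channel and outer wall."""
        return (self.outer_diameter + self.channel_diameter) / 4.0

    @property
    def monomer_radial_halfwidth(self) -> float:
        return (self.outer_diameter - self.channel_diameter) / 4.0

    @property
    def monomer_half_height(self) -> float:
        return (self.height - self.inter_ring_gap) / 4.0

    @property
    def ring_z(self) -> float:
        """|z| of each ring's monomer centers."""
        return self.inter_ring_gap / 2.0 + self.monomer_half_height


@dataclass(frozen=True)
class ToroidModel:
    """Labelled pseudo-atom coordinates (angstroms, principal axis = z)."""

    coords: np.ndarray  # (n_atoms, 3)
    chain_ids: tuple[str, ...]  # per atom, A-L
    spec: ToroidSpec

    @property
    def n_chains(self) -> int:
        return len(set(self.chain_ids))


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # two-fold rotation about x


def _monomer_template(spec: ToroidSpec) -> np.ndarray:
    """Pseudo-atoms of one monomer, local frame centered on the monomer.

    Deliberately asymmetric so the only exact symmetries of the assembled
    particle are the ones imposed by construction.
    """
    wr = spec.monomer_radial_halfwidth
    hz = spec.monomer_half_height
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [wr, 0.0, 0.0],
            [-wr, 0.0, 0.0],
            [0.0, 0.0, hz],
            [0.0, 0.0, -hz],
            [0.3 * wr, 0.55 * wr, 0.35 * hz],
        ]
    )


def build_d6_toroid(spec: ToroidSpec = ToroidSpec()) -> ToroidModel:
    """Build the 12-chain double-ring model.

    Upper-ring monomer k sits at azimuth k*(360/n), z = +ring_z; the lower
    ring is the upper ring rotated by 180 deg about x (head-to-head
    packing) and then rotated about z by the stagger angle.
    """
    base = _monomer_template(spec) + np.array([spec.ring_radius, 0.0, spec.ring_z])
    step = 360.0 / spec.n_per_ring
    coords, chains = [], []
    for k in range(spec.n_per_ring):  # upper ring: chains A..F
        coords.append(base @ _rot_z(k * step).T)
        chains.extend(_CHAINS[k] * len(base))
    flipped = base @ _FLIP_X.T
    for k in range(spec.n_per_ring):  # lower ring: chains G..L
        coords.append(flipped @ _rot_z(k * step + spec.stagger_deg).T)
        chains.extend(_CHAINS[spec.n_per_ring + k] * len(base))
    return ToroidModel(
        coords=np.vstack(coords), chain_ids=tuple(chains), spec=spec
    )


def d6_transforms(spec: ToroidSpec = ToroidSpec()) -> list[np.ndarray]:
    """The 12 proper rotations of the particle's D6 group.

    Six powers of the principal C6 (rotation by 360/n about z) and six
    perpendicular two-folds C6^k * g, where g = R_z(stagger) * C2x is the
    ring-exchanging two-fold of the construction.
    """
    step = 360.0 / spec.n_per_ring
    g = _rot_z(spec.stagger_deg) @ _FLIP_X
    out = []
    for k in range(spec.n_per_ring):
        r = _rot_z(k * step)
        out.append(r)
        out.append(r @ g)
    return out


def symmetry_rmsd(model: ToroidModel, transform: np.ndarray) -> float:
    """RMSD between the model and its transform under nearest-point matching.

    A symmetry operation permutes the pseudo-atoms, so each transformed
    point is matched to its nearest original point before the RMSD.
    """
    from scipy.spatial import cKDTree

    moved = model.coords @ transform.T
    d, _ = cKDTree(model.coords).query(moved)
    return float(np.sqrt(np.mean(d**2)))


def write_pdb(model: ToroidModel, path) -> None:
    """Write the pseudo-atom model as PDB: chains A-L, one TER per chain."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model.coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(model.coords, dtype=np.float32)
    atoms.chain_id = np.array(list(model.chain_ids))
    atoms.res_id = np.array(
        [i % (n // model.n_chains) + 1 for i in range(n)], dtype=int
    )
    atoms.res_name = np.full(n, "UNK")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
    # biotite emits no chain terminators; add one TER per chain
    with open(path) as fh:
        lines = fh.read().splitlines()
    out, prev_chain = [], None
    for line in lines:
        if line.startswith("ATOM"):
            chain = line[21]
            if prev_chain is not None and chain != prev_chain:
                out.append("TER")
            prev_chain = chain
        out.append(line)
    if prev_chain is not None:
        out.append("TER")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
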