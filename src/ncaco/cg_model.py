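"""Coarse-grained five-bead protein model.

A residue is reduced to its four main-chain heavy atoms (N, CA, C, O) plus a
pseudo side-chain center of mass (SCM) for the 19 non-glycine amino acids.
The SCM is not read from a structure: it is reconstructed from the backbone
phi/psi torsions through a statistical lookup table (:class:`SCMTable`) that
stores, per (amino acid, phi-bin, psi-bin) cell, the average internal
coordinates of the true side-chain centroid observed in a structure database.

Torsion conventions: phi_i = C(i-1)-N(i)-CA(i)-C(i); psi_i =
N(i)-CA(i)-C(i)-N(i+1); omega_i = CA(i)-C(i)-N(i+1)-CA(i+1) (the peptide bond
between i and i+1). phi is undefined at the first residue, psi/omega at the
last; undefined entries are NaN. All angles live in (-180, 180] degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .geometry import dihedral, dihedral_batch, place_atom, wrap_angle

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = sorted(AA1_TO_3)          # 20 one-letter codes, alphabetical
NON_GLY = [a for a in AMINO_ACIDS if a != "G"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Ideal backbone geometry used for torsion-to-coordinate reconstruction
# (Engh-Huber-style averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7

SCM_BIN_WIDTH = 10.0
SCM_N_BINS = 36


@dataclass
class BackboneResidue:
    """One residue of the coarse-grained chain."""

    aa: str
    index: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    scm: Optional[np.ndarray] = None
    sidechain: Optional[np.ndarray] = None  # (k, 3) heavy atoms, derivation only

    def atoms(self, with_scm: bool = True):
        """Yield (role, coordinate) pairs for the residue's coarse-grained atoms."""
        yield "N", self.n
        yield "CA", self.ca
        yield "C", self.c
        yield "O", self.o
        if with_scm and self.scm is not None:
            yield "SCM", self.scm


@dataclass
class CGStructure:
    """An ordered single-chain coarse-grained structure."""

    residues: list
    id: str = ""

    def __len__(self):
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def copy(self) -> "CGStructure":
        return CGStructure(
            residues=[
                BackboneResidue(
                    r.aa, r.index,
                    r.n.copy(), r.ca.copy(), r.c.copy(), r.o.copy(),
                    None if r.scm is None else r.scm.copy(),
                    None if r.sidechain is None else r.sidechain.copy(),
                )
                for r in self.residues
            ],
            id=self.id,
        )


@dataclass
class TorsionSeries:
    """Per-residue phi/psi/omega, NaN where undefined (chain termini)."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __len__(self):
        return len(self.phi)


class StructureError(ValueError):
    pass


def read_structure(pdb_source, chain: Optional[str] = None, id: Optional[str] = None) -> CGStructure:
    """Read one chain of a PDB file into a :class:`CGStructure`.

    First MODEL only; altloc blank or 'A'; HETATM records ignored. Residues
    missing any of N/CA/C/O are dropped with a warning; fewer than three
    complete residues is a hard error. Side-chain heavy atoms are retained on
    each residue (``sidechain``) for SCM-table derivation.
    """
    st = gemmi.read_pdb(str(pdb_source))
    if len(st) == 0:
        raise StructureError(f"{pdb_source}: no models")
    model = st[0]
    if len(model) == 0:
        raise StructureError(f"{pdb_source}: no chains")
    gch = None
    if chain is None:
        gch = model[0]
    else:
        for c in model:
            if c.name == chain:
                gch = c
                break
        if gch is None:
            raise StructureError(f"{pdb_source}: chain {chain!r} not found")

    residues = []
    idx = 0
    for res in gch:
        if res.het_flag != "A" or res.name not in AA3_TO_1:
            continue
        coords = {}
        side = []
        for atom in res:
            if atom.altloc not in ("\x00", "", "A"):
                continue
            if atom.element.is_hydrogen:
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if atom.name in BACKBONE_ATOMS:
                coords[atom.name] = pos
            elif atom.name != "OXT":
                side.append(pos)
        if any(k not in coords for k in BACKBONE_ATOMS):
            logger.warning(
                "%s %s%d: incomplete backbone, residue dropped",
                pdb_source, res.name, res.seqid.num,
            )
            continue
        idx += 1
        residues.append(
            BackboneResidue(
                aa=AA3_TO_1[res.name],
                index=idx,
                n=coords["N"], ca=coords["CA"], c=coords["C"], o=coords["O"],
                sidechain=np.array(side) if side else None,
            )
        )
    if len(residues) < 3:
        raise StructureError(
            f"{pdb_source}: only {len(residues)} complete residues (need >= 3)"
        )
    label = id if id is not None else str(pdb_source)
    return CGStructure(residues=residues, id=label)


def write_structure(structure: CGStructure, path, write_sidechain: bool = True) -> None:
    """Write a CGStructure as a single-chain PDB file (backbone + side-chain atoms)."""
    st = gemmi.Structure()
    st.name = structure.id or "cg"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = AA1_TO_3[r.aa]
        res.seqid = gemmi.SeqId(r.index, " ")
        for name, pos in zip(BACKBONE_ATOMS, (r.n, r.ca, r.c, r.o)):
            at = gemmi.Atom()
            at.name = name
            at.pos = gemmi.Position(*pos)
            at.element = gemmi.Element(elements[name])
            res.add_atom(at)
        if write_sidechain and r.sidechain is not None:
            for k, pos in enumerate(r.sidechain):
                at = gemmi.Atom()
                at.name = "CB" if k == 0 else f"S{k}"
                at.pos = gemmi.Position(*pos)
                at.element = gemmi.Element("C")
                res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def compute_torsions(structure: CGStructure) -> TorsionSeries:
    """Backbone phi/psi/omega of a structure; NaN at undefined terminal entries."""
    L = len(structure)
    if L < 2:
        raise StructureError("need at least 2 residues for torsions")
    res = structure.residues
    N = np.array([r.n for r in res])
    CA = np.array([r.ca for r in res])
    C = np.array([r.c for r in res])
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    omega = np.full(L, np.nan)
    phi[1:] = dihedral_batch(C[:-1], N[1:], CA[1:], C[1:])
    psi[:-1] = dihedral_batch(N[:-1], CA[:-1], C[:-1], N[1:])
    omega[:-1] = dihedral_batch(CA[:-1], C[:-1], N[1:], CA[1:])
    return TorsionSeries(phi=phi, psi=psi, omega=omega)


def torsion_bin(angle: float, width: float, n_bins: int) -> int:
    """Half-open [lo, hi) binning of a degree angle over [-180, 180); +180 -> last bin."""
    b = int(math.floor((angle + 180.0) / width))
    if b == n_bins:  # exactly +180
        b = n_bins - 1
    if b < 0 or b >= n_bins:
        raise ValueError(f"angle {angle} out of range")
    return b


@dataclass
class SCMTable:
    """(19 aa x 36 phi-bins x 36 psi-bins) table of mean SCM internal coordinates.

    Cells hold (mean CA-SCM bond length, mean N-CA-SCM angle, circular-mean
    pseudo dihedral about the N-CA axis with C as reference, occupancy count).
    Zero-occupancy cells are flagged by count == 0.
    """

    length: np.ndarray   # (19, 36, 36)
    angle: np.ndarray
    dih: np.ndarray
    count: np.ndarray    # int

    aa_order: tuple = tuple(NON_GLY)

    @classmethod
    def empty(cls) -> "SCMTable":
        shape = (len(NON_GLY), SCM_N_BINS, SCM_N_BINS)
        return cls(
            length=np.zeros(shape), angle=np.zeros(shape),
            dih=np.zeros(shape), count=np.zeros(shape, dtype=int),
        )

    def aa_index(self, aa: str) -> int:
        return self.aa_order.index(aa)

    def lookup(self, aa: str, phi: float, psi: float):
        """Internal coordinates for (aa, phi, psi); falls back to the nearest
        occupied cell by torus distance when the exact cell is empty."""
        ai = self.aa_index(aa)
        pb = torsion_bin(phi, SCM_BIN_WIDTH, SCM_N_BINS)
        sb = torsion_bin(psi, SCM_BIN_WIDTH, SCM_N_BINS)
        if self.count[ai, pb, sb] > 0:
            return self.length[ai, pb, sb], self.angle[ai, pb, sb], self.dih[ai, pb, sb]
        occ = np.argwhere(self.count[ai] > 0)
        if len(occ) == 0:
            raise StructureError(f"SCM table has no observations for {aa}")
        dp = np.minimum(np.abs(occ[:, 0] - pb), SCM_N_BINS - np.abs(occ[:, 0] - pb))
        ds = np.minimum(np.abs(occ[:, 1] - sb), SCM_N_BINS - np.abs(occ[:, 1] - sb))
        d2 = dp * dp + ds * ds
        # ties: lower phi-bin then lower psi-bin (occ is in lexicographic order)
        best = occ[np.argmin(d2)]
        logger.warning(
            "SCM cell (%s, %d, %d) empty; falling back to (%d, %d)",
            aa, pb, sb, best[0], best[1],
        )
        return (
            self.length[ai, best[0], best[1]],
            self.angle[ai, best[0], best[1]],
            self.dih[ai, best[0], best[1]],
        )


def scm_internal_coords(res: BackboneResidue, scm: np.ndarray):
    """(bond, angle, dihedral) of an SCM position relative to the residue backbone."""
    bond = float(np.linalg.norm(scm - res.ca))
    from .geometry import bond_angle
    ang = bond_angle(res.n, res.ca, scm)
    dih = dihedral(res.c, res.n, res.ca, scm)
    return bond, ang, dih


def scm_from_internal(res: BackboneResidue, bond: float, angle: float, dih: float) -> np.ndarray:
    """Place an SCM from internal coordinates (inverse of :func:`scm_internal_coords`)."""
    return place_atom(res.c, res.n, res.ca, bond, angle, dih)


def true_scm(res: BackboneResidue) -> Optional[np.ndarray]:
    """Unweighted heavy-atom centroid of the residue's side chain (None for GLY/absent)."""
    if res.aa == "G" or res.sidechain is None or len(res.sidechain) == 0:
        return None
    return res.sidechain.mean(axis=0)


def derive_scm_table(structures: Iterable[CGStructure]) -> SCMTable:
    """Accumulate SCM internal coordinates into the (aa, phi-bin, psi-bin) grid.

    Dihedrals are averaged circularly; length and angle arithmetically. GLY
    contributes nothing; residues with undefined phi or psi are skipped.
    """
    structures = list(structures)
    if not structures:
        raise StructureError("empty structure database")
    shape = (len(NON_GLY), SCM_N_BINS, SCM_N_BINS)
    s_len = np.zeros(shape)
    s_ang = np.zeros(shape)
    s_sin = np.zeros(shape)
    s_cos = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    aa_idx = {a: i for i, a in enumerate(NON_GLY)}
    for st in structures:
        tor = compute_torsions(st)
        for i, res in enumerate(st.residues):
            if res.aa == "G":
                continue
            scm = true_scm(res)
            if scm is None:
                continue
            if math.isnan(tor.phi[i]) or math.isnan(tor.psi[i]):
                continue
            bond, ang, dih = scm_internal_coords(res, scm)
            if math.isnan(dih):
                continue
            ai = aa_idx[res.aa]
            pb = torsion_bin(tor.phi[i], SCM_BIN_WIDTH, SCM_N_BINS)
            sb = torsion_bin(tor.psi[i], SCM_BIN_WIDTH, SCM_N_BINS)
            s_len[ai, pb, sb] += bond
            s_ang[ai, pb, sb] += ang
            s_sin[ai, pb, sb] += math.sin(math.radians(dih))
            s_cos[ai, pb, sb] += math.cos(math.radians(dih))
            count[ai, pb, sb] += 1
    table = SCMTable.empty()
    occ = count > 0
    table.length[occ] = s_len[occ] / count[occ]
    table.angle[occ] = s_ang[occ] / count[occ]
    table.dih[occ] = wrap_angle(np.degrees(np.arctan2(s_sin[occ], s_cos[occ])))
    table.count = count
    return table


def place_scm(structure: CGStructure, table: SCMTable, torsions: Optional[TorsionSeries] = None) -> CGStructure:
    """Attach a pseudo SCM to every non-GLY residue with defined phi/psi.

    Returns a new structure; GLY and torsion-undefined terminal residues get
    no SCM. Empty cells fall back to the nearest occupied cell (with warning).
    """
    out = structure.copy()
    tor = torsions if torsions is not None else compute_torsions(out)
    for i, res in enumerate(out.residues):
        res.scm = None
        if res.aa == "G":
            continue
        if math.isnan(tor.phi[i]) or math.isnan(tor.psi[i]):
            continue
        bond, ang, dih = table.lookup(res.aa, tor.phi[i], tor.psi[i])
        res.scm = scm_from_internal(res, bond, ang, dih)
    return out


def _place_oxygen(ca, c, n_next):
    """Carbonyl O in the peptide plane, externally bisecting CA-C and N(next)-C."""
    u = ca - c
    u /= np.linalg.norm(u)
    v = n_next - c
    v /= np.linalg.norm(v)
    d = -(u + v)
    d /= np.linalg.norm(d)
    return c + BOND_C_O * d


def rebuild_backbone(sequence: str, torsions: TorsionSeries, id: str = "rebuilt") -> CGStructure:
    """Build N/CA/C/O coordinates from a torsion series with ideal bond geometry.

    The chain is seeded at the origin; ``compute_torsions`` of the result
    reproduces the input torsions at every defined position. The carbonyl O
    is placed in the peptide plane; the last residue uses a virtual next N at
    psi = 180 so its O is still defined.
    """
    L = len(sequence)
    if len(torsions) != L:
        raise StructureError("sequence/torsion length mismatch")
    if L < 2:
        raise StructureError("need at least 2 residues")
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # seed residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(L - 1):
        psi = torsions.psi[i]
        omega = torsions.omega[i]
        phi_next = torsions.phi[i + 1]
        if any(math.isnan(x) for x in (psi, omega, phi_next)):
            raise StructureError(f"undefined torsion in non-terminal window at residue {i+1}")
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
    residues = []
    for i, aa in enumerate(sequence):
        if i < L - 1:
            o = _place_oxygen(CA[i], C[i], N[i + 1])
        else:
            virt_n = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, 180.0)
            o = _place_oxygen(CA[i], C[i], virt_n)
        residues.append(BackboneResidue(aa=aa, index=i + 1, n=N[i], ca=CA[i], c=C[i], o=o))
    return CGStructure(residues=residues, id=id)
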