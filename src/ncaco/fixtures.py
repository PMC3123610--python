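"""Synthetic inputs for every stage of the pipeline.

These generators build micro structure databases (helices, sheets, perturbed
coils) with single pseudo-C-beta side chains, near-native decoy sets by
fragment-replacement torsion perturbation, and dialect-valid PSIPRED
``.ss2`` / PSI-BLAST PSSM / DSSP files — enough to derive every table and
exercise every reader without any download. They are geometric scaffolds,
not physically realistic proteins: side chains are a single bead, sheet
fixtures join rigidly placed strands, and profiles encode the input sequence
directly. Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cg_model import (
    BackboneResidue,
    CGStructure,
    NON_GLY,
    TorsionSeries,
    compute_torsions,
    rebuild_backbone,
)
from .geometry import kabsch_superpose, place_atom, rmsd, wrap_angle

# ideal pseudo-C-beta internal coordinates (bond CA-CB, angle N-CA-CB,
# dihedral about N-CA with C as reference)
CB_BOND = 1.53
CB_ANGLE = 110.5
CB_DIHEDRAL = -122.6

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

# Fixture chains use a reduced amino-acid alphabet. The statistical shortest
# contact distances are per atom-type pair; at micro-database scale a full
# 20-letter alphabet leaves most of the 99x99 pair minima estimated from a
# handful of draws (so the estimated "minimum" sits near a typical distance
# and compact structures register spurious clashes). Five letters keep every
# pair densely sampled while still exercising the aa-specific tables.
FIXTURE_ALPHABET = "ACDEF"


@dataclass
class FixtureSpec:
    n_structures: int = 20
    length_range: Tuple[int, int] = (8, 16)
    helix_fraction: float = 0.4
    sheet_fraction: float = 0.3
    coil_fraction: float = 0.3
    perturbation: float = 15.0        # degrees
    seed: int = 0

    def __post_init__(self):
        total = self.helix_fraction + self.sheet_fraction + self.coil_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("secondary-structure fractions must sum to 1")
        if self.length_range[0] < 6:
            raise ValueError("lengths must be >= 6")


def _default_sequence(n: int, offset: int = 0) -> str:
    return "".join(FIXTURE_ALPHABET[(offset + i) % len(FIXTURE_ALPHABET)] for i in range(n))


def attach_pseudo_cb(structure: CGStructure) -> CGStructure:
    """Attach a single pseudo-C-beta side-chain bead to every non-GLY residue."""
    out = structure.copy()
    for res in out.residues:
        if res.aa == "G":
            continue
        cb = place_atom(res.c, res.n, res.ca, CB_BOND, CB_ANGLE, CB_DIHEDRAL)
        res.sidechain = cb[None, :]
    return out


def _uniform_torsions(n: int, phi: float, psi: float, omega: float = 180.0) -> TorsionSeries:
    return TorsionSeries(
        phi=np.full(n, phi), psi=np.full(n, psi), omega=np.full(n, omega)
    )


def gen_ideal_helix(n: int, sequence: Optional[str] = None, id: str = "helix") -> CGStructure:
    """Ideal alpha helix (phi -57, psi -47, omega 180) with pseudo-CB side chains."""
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    seq = sequence or _default_sequence(n)
    st = rebuild_backbone(seq, _uniform_torsions(n, HELIX_PHI, HELIX_PSI), id=id)
    return attach_pseudo_cb(st)


def gen_beta_sheet(
    strand_len: int = 5,
    n_strands: int = 2,
    parallel: bool = True,
    spacing: float = 4.8,
    id: str = "sheet",
) -> CGStructure:
    """Multi-strand sheet scaffold: extended strands rigidly placed side by
    side at the given CA-CA spacing, joined by two interpolated loop residues.

    Antiparallel sheets alternate strand direction. The junction geometry is
    synthetic (loops are interpolated, not physically folded) but CA-level
    strand pairing and full backbone atoms are well-defined.
    """
    if strand_len < 3:
        raise ValueError("strands need at least 3 residues")
    strand_t = _uniform_torsions(strand_len, STRAND_PHI, STRAND_PSI)
    proto = rebuild_backbone(_default_sequence(strand_len), strand_t, id="strand")
    # principal axis of the prototype strand
    ca = proto.ca_coords()
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)

    residues: List[BackboneResidue] = []
    idx = 0
    offset_dir = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(offset_dir) < 1e-6:
        offset_dir = np.cross(axis, [0.0, 1.0, 0.0])
    offset_dir /= np.linalg.norm(offset_dir)
    prev_tail = None
    for s in range(n_strands):
        shift = s * spacing * offset_dir
        reverse = (not parallel) and (s % 2 == 1)
        strand_res = []
        for r in proto.residues:
            strand_res.append(
                BackboneResidue(
                    aa=r.aa, index=0,
                    n=r.n + shift, ca=r.ca + shift, c=r.c + shift, o=r.o + shift,
                )
            )
        if reverse:
            # residue order runs backwards in space; CA geometry is what matters
            strand_res = list(reversed(strand_res))
        if prev_tail is not None:
            # two loop residues interpolated between strand ends
            a = prev_tail
            b = strand_res[0].ca
            for k in (1, 2):
                t = k / 3.0
                pos = a + t * (b - a)
                idx += 1
                residues.append(
                    BackboneResidue(
                        aa="G", index=idx,
                        n=pos + np.array([-0.5, 0.0, 0.3]),
                        ca=pos,
                        c=pos + np.array([0.5, 0.0, 0.3]),
                        o=pos + np.array([0.5, 0.0, 1.5]),
                    )
                )
        for r in strand_res:
            idx += 1
            residues.append(
                BackboneResidue(aa=r.aa, index=idx, n=r.n, ca=r.ca, c=r.c, o=r.o)
            )
        prev_tail = residues[-1].ca
    return attach_pseudo_cb(CGStructure(residues=residues, id=id))


def gen_coil(n: int, rng: np.random.Generator, perturbation: float = 15.0,
             id: str = "coil") -> CGStructure:
    """Perturbed coil: torsions sampled around broad Ramachandran basins."""
    basins = np.array([[-57.0, -47.0], [-120.0, 120.0], [-75.0, 150.0]])
    choice = rng.integers(len(basins), size=n)
    phi = basins[choice, 0] + rng.normal(0.0, perturbation, size=n)
    psi = basins[choice, 1] + rng.normal(0.0, perturbation, size=n)
    t = TorsionSeries(phi=wrap_angle(phi), psi=wrap_angle(psi), omega=np.full(n, 180.0))
    seq = "".join(
        FIXTURE_ALPHABET[k] for k in rng.integers(0, len(FIXTURE_ALPHABET), size=n)
    )
    return attach_pseudo_cb(rebuild_backbone(seq, t, id=id))


def gen_structure_db(spec: FixtureSpec) -> List[CGStructure]:
    """Seeded mixture of helices, sheets, and coils with side chains.

    Construction labels (helix/sheet/coil) are recorded in each structure id.
    """
    rng = np.random.default_rng(spec.seed)
    kinds = (
        ["helix"] * round(spec.n_structures * spec.helix_fraction)
        + ["sheet"] * round(spec.n_structures * spec.sheet_fraction)
    )
    kinds += ["coil"] * (spec.n_structures - len(kinds))
    db = []
    for k, kind in enumerate(kinds):
        n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if kind == "helix":
            phi = wrap_angle(HELIX_PHI + rng.normal(0, spec.perturbation / 3, size=n))
            psi = wrap_angle(HELIX_PSI + rng.normal(0, spec.perturbation / 3, size=n))
            t = TorsionSeries(phi=phi, psi=psi, omega=np.full(n, 180.0))
            seq = _default_sequence(n, offset=int(rng.integers(len(FIXTURE_ALPHABET))))
            st = attach_pseudo_cb(rebuild_backbone(seq, t, id=f"helix_{k}"))
        elif kind == "sheet":
            st = gen_beta_sheet(
                strand_len=max(3, n // 2 - 1),
                n_strands=2,
                parallel=bool(rng.integers(2)),
                id=f"sheet_{k}",
            )
        else:
            st = gen_coil(n, rng, spec.perturbation, id=f"coil_{k}")
        db.append(st)
    return db


def gen_decoys(
    native: CGStructure,
    n: int,
    magnitude: float,
    rng: np.random.Generator,
    n_replacements: Optional[int] = None,
) -> List[dict]:
    """Near-native decoys by fragment-replacement torsion perturbation.

    Each decoy perturbs the phi/psi/omega of a few random triplets by
    Gaussian noise of the given magnitude (degrees), then rebuilds the
    backbone. Returns dicts with the structure and its CA-RMSD / TM-score to
    the native.
    """
    from .assembly import tm_score

    L = len(native)
    if L < 9:
        raise ValueError("native too short for fragment-replacement decoys")
    tor = compute_torsions(native)
    base = np.column_stack([tor.phi, tor.psi, tor.omega])
    base[np.isnan(base)] = 180.0
    n_rep = n_replacements if n_replacements is not None else max(1, L // 6)
    native_ca = native.ca_coords()
    out = []
    for k in range(n):
        arr = base.copy()
        if magnitude > 0:
            for p in rng.integers(0, L - 2, size=n_rep):
                arr[p : p + 3] += rng.normal(0.0, magnitude, size=(3, 3))
        arr = wrap_angle(arr)
        st = rebuild_backbone(native.sequence, _torsions_to_series(arr), id=f"decoy_{k}")
        st = attach_pseudo_cb(st)
        out.append(
            {
                "structure": st,
                "rmsd": rmsd(st.ca_coords(), native_ca),
                "tm_score": tm_score(st.ca_coords(), native_ca),
            }
        )
    return out


def _torsions_to_series(arr: np.ndarray) -> TorsionSeries:
    return TorsionSeries(phi=arr[:, 0].copy(), psi=arr[:, 1].copy(), omega=arr[:, 2].copy())


SS2_HEADER = "# PSIPRED VFORMAT (PSIPRED V4.0)\n\n"


def gen_profile_files(
    sequence: str,
    ss: str,
    noise: float,
    rng: np.random.Generator,
    ss2_path,
    pssm_path,
) -> None:
    """Write dialect-valid .ss2 and PSI-BLAST ASCII PSSM files for a sequence.

    At noise 0 the SS labels and the dominant profile signal exactly encode
    the inputs; noise mixes in uniform probability mass.
    """
    from .fragments import PSSM_ALPHABET

    if len(sequence) != len(ss):
        raise ValueError("sequence and SS must have equal length")
    order = {"C": 3, "H": 4, "E": 5}
    with open(ss2_path, "w") as fh:
        fh.write(SS2_HEADER)
        for i, (aa, s) in enumerate(zip(sequence, ss), start=1):
            probs = np.full(3, noise / 3.0)
            probs[order[s] - 3] += 1.0 - noise
            if noise > 0:
                probs = probs + rng.uniform(0, noise / 10.0, size=3)
            probs = probs / probs.sum()
            fh.write(f"{i:4d} {aa} {s}  {probs[0]:6.3f} {probs[1]:6.3f} {probs[2]:6.3f}\n")

    with open(pssm_path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed, weighted ...\n")
        fh.write("            " + "   ".join(PSSM_ALPHABET) + "  " +
                 "   ".join(PSSM_ALPHABET) + "\n")
        for i, aa in enumerate(sequence, start=1):
            j = PSSM_ALPHABET.index(aa)
            lods = np.full(20, -1, dtype=int)
            lods[j] = 7
            freq = np.zeros(20)
            freq[j] = 100.0 * (1.0 - noise)
            if noise > 0:
                extra = rng.uniform(0, 1, size=20)
                extra = noise * 100.0 * extra / extra.sum()
                freq = freq + extra
            freq_i = np.round(freq).astype(int)
            row = (
                f"{i:5d} {aa}  "
                + " ".join(f"{v:3d}" for v in lods)
                + "  "
                + " ".join(f"{v:3d}" for v in freq_i)
                + "  0.50 1.00\n"
            )
            fh.write(row)


def gen_dssp_file(sequence: str, ss: str, path) -> None:
    """Write a minimal classic-format DSSP file carrying the given labels.

    The labels may use the full DSSP alphabet (H/G/I/E/T/S/B/blank).
    """
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition (synthetic fixture) ====\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        for i, (aa, s) in enumerate(zip(sequence, ss), start=1):
            label = s if s != "C" else " "
            fh.write(f"{i:5d}{i:5d} A {aa}  {label}\n")
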