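"""Evaluation of the four energy terms, the combined score, and decoy metrics.

E_tot = E_con + a*E_trp + b*E_sol + c*E_beta (+ w_clash*E_clash in assembly
mode, with E_clash = N_clash, the number of atom pairs closer than their
statistical shortest contact distance). Default weights a = b = c = 1; use
:func:`optimize_weights` to re-fit them on decoy sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cg_model import CGStructure, compute_torsions
from .geometry import bond_angle, vec_angle
from .potentials import (
    DEFAULT_D_CUT,
    MIN_PAIR_SEPARATION,
    PotentialTables,
    beta_bin_index,
    contact_numbers,
    iter_triplet_windows,
    structure_atoms,
)

logger = logging.getLogger(__name__)

BETA_MIN_CENTER_SEPARATION = 3   # |i-j| >= 3 for candidate triplet centers


class ScoringError(ValueError):
    pass


@dataclass
class WeightSet:
    """Relative weights of E_trp, E_sol, E_beta and the assembly clash term."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    w_clash: float = 1.0


@dataclass
class EnergyBreakdown:
    e_con: float
    e_trp: float
    e_sol: float
    e_beta: float
    e_clash: float
    e_tot: float

    def recombine(self, weights: WeightSet, with_clash: bool = False,
                  beta_multiplier: float = 1.0) -> float:
        """Re-evaluate the linear combination without rescoring the terms."""
        tot = (
            self.e_con
            + weights.a * self.e_trp
            + weights.b * self.e_sol
            + weights.c * beta_multiplier * self.e_beta
        )
        if with_clash:
            tot += weights.w_clash * self.e_clash
        return tot


@dataclass
class BetaPair:
    i: int
    j: int
    pattern: str                      # "parallel" | "antiparallel"
    distances: Tuple[float, float, float]


def _check_scm(structure: CGStructure) -> None:
    L = len(structure)
    for k, res in enumerate(structure.residues):
        if res.aa != "G" and res.scm is None and 0 < k < L - 1:
            raise ScoringError(
                f"residue {res.index} ({res.aa}) has no SCM; run place_scm first"
            )


from .potentials import ALPHABET

_IS_SCM = np.array([role == "SCM" for _, role in ALPHABET.types])


def _contact_pair_arrays(structure: CGStructure, backbone_only: bool = False):
    coords, tidx, ridx = structure_atoms(structure, backbone_only=backbone_only)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    sep = np.abs(ridx[:, None] - ridx[None, :])
    mask = np.triu(sep >= MIN_PAIR_SEPARATION, k=1)
    ii, jj = np.nonzero(mask)
    return tidx[ii], tidx[jj], d[ii, jj]


def score_contact(structure: CGStructure, contact, _pairs=None) -> float:
    """Sum of pair energies over all atom pairs inside their contact shell."""
    _check_scm(structure)
    ta, tb, d = _pairs if _pairs is not None else _contact_pair_arrays(structure)
    r = contact.r_min[ta, tb]
    sel = (d >= r) & (d <= contact.lam * r)
    return float(contact.energy[ta[sel], tb[sel]].sum())


def score_triplet(structure: CGStructure, triplet, torsions=None) -> float:
    """Sum of triplet-torsion energies over all defined overlapping windows."""
    if len(structure) < 3:
        raise ScoringError("need at least 3 residues for triplet scoring")
    return float(
        sum(triplet.energy(t, b) for t, b in iter_triplet_windows(structure, torsions))
    )


def score_solvation(structure: CGStructure, solvation) -> float:
    """Sum over residues of the burial energy at each residue's contact count."""
    ca = structure.ca_coords()
    ks = contact_numbers(ca, solvation.radius)
    return float(sum(solvation.lookup(res.aa, int(k)) for res, k in zip(structure.residues, ks)))


def detect_beta_pairs(ca: np.ndarray, d_cut: float = DEFAULT_D_CUT) -> List[BetaPair]:
    """Triplet-center pairs with strand-pairing distance patterns.

    Candidate centers i < j with j - i >= 3 and full triplets in range.
    Parallel requires d(i-1,j-1), d(i,j), d(i+1,j+1) all < d_cut;
    antiparallel requires d(i-1,j+1), d(i,j), d(i+1,j-1) all < d_cut. When
    both patterns hold, the one with the smaller mean distance wins.
    """
    ca = np.asarray(ca, float)
    L = len(ca)
    pairs: List[BetaPair] = []
    if L < 3:
        return pairs
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    centers_i, centers_j = np.nonzero(np.triu(d < d_cut, k=BETA_MIN_CENTER_SEPARATION))
    for i, j in zip(centers_i, centers_j):
        if i < 1 or j > L - 2:
            continue
        par = (d[i - 1, j - 1], d[i, j], d[i + 1, j + 1])
        anti = (d[i - 1, j + 1], d[i, j], d[i + 1, j - 1])
        par_ok = all(x < d_cut for x in par)
        anti_ok = all(x < d_cut for x in anti)
        if par_ok and anti_ok:
            if np.mean(par) <= np.mean(anti):
                pairs.append(BetaPair(int(i), int(j), "parallel", par))
            else:
                pairs.append(BetaPair(int(i), int(j), "antiparallel", anti))
        elif par_ok:
            pairs.append(BetaPair(int(i), int(j), "parallel", par))
        elif anti_ok:
            pairs.append(BetaPair(int(i), int(j), "antiparallel", anti))
    return pairs


def beta_features(ca: np.ndarray, i: int, j: int) -> Optional[Tuple[float, float, float, float]]:
    """(alpha1, alpha2, beta, gamma) in degrees for a pair of triplet centers.

    alpha1/alpha2 are the virtual bond angles at the two centers; gamma is the
    angle between the first-leg vectors CA(i-1)->CA(i) and CA(j-1)->CA(j);
    beta is the angle between the in-plane vectors P_i and P_j, where P_k
    points from the midpoint of CA(k-1), CA(k+1) to CA(k). Returns None (with
    warning) for a collinear triplet, whose plane is undefined.
    """
    a1 = bond_angle(ca[i - 1], ca[i], ca[i + 1])
    a2 = bond_angle(ca[j - 1], ca[j], ca[j + 1])
    gamma = vec_angle(ca[i] - ca[i - 1], ca[j] - ca[j - 1])
    p_i = ca[i] - 0.5 * (ca[i - 1] + ca[i + 1])
    p_j = ca[j] - 0.5 * (ca[j - 1] + ca[j + 1])
    ni = p_i[0] ** 2 + p_i[1] ** 2 + p_i[2] ** 2
    nj = p_j[0] ** 2 + p_j[1] ** 2 + p_j[2] ** 2
    if ni < 1e-18 or nj < 1e-18:
        logger.warning("collinear triplet at centers (%d, %d); pair skipped", i, j)
        return None
    beta = vec_angle(p_i, p_j)
    return a1, a2, beta, gamma


def score_beta(structure: CGStructure, beta_table) -> float:
    """Sum of propensity energies over detected strand pairs (0 when none)."""
    ca = structure.ca_coords()
    total = 0.0
    for pair in detect_beta_pairs(ca, beta_table.d_cut):
        feats = beta_features(ca, pair.i, pair.j)
        if feats is None:
            continue
        total += beta_table.lookup(*feats)
    return float(total)


def count_clashes(structure: CGStructure, r_min: np.ndarray, _pairs=None) -> Tuple[int, int]:
    """(backbone-backbone clash count, all-atom clash count incl. SCM).

    A pair clashes when its distance falls below the statistical shortest
    contact distance; the same residue-separation rule as contact counting.
    """
    ta, tb, d = _pairs if _pairs is not None else _contact_pair_arrays(structure)
    clash = d < r_min[ta, tb]
    n_all = int(clash.sum())
    bb = ~(_IS_SCM[ta] | _IS_SCM[tb])
    n_bb = int((clash & bb).sum())
    return n_bb, n_all


def score_total(
    structure: CGStructure,
    tables: PotentialTables,
    weights: Optional[WeightSet] = None,
    with_clash: bool = False,
    beta_multiplier: float = 1.0,
) -> EnergyBreakdown:
    """All four terms plus their exact linear combination."""
    weights = weights or WeightSet()
    pairs = _contact_pair_arrays(structure)
    e_con = score_contact(structure, tables.contact, _pairs=pairs)
    e_trp = score_triplet(structure, tables.triplet)
    e_sol = score_solvation(structure, tables.solvation)
    e_beta = score_beta(structure, tables.beta)
    if with_clash:
        _, n_clash = count_clashes(structure, tables.contact.r_min, _pairs=pairs)
        e_clash = float(n_clash)
    else:
        e_clash = 0.0
    bd = EnergyBreakdown(e_con=e_con, e_trp=e_trp, e_sol=e_sol,
                         e_beta=e_beta, e_clash=e_clash, e_tot=0.0)
    bd.e_tot = bd.recombine(weights, with_clash=with_clash, beta_multiplier=beta_multiplier)
    return bd


@dataclass
class DecoyEvaluation:
    native: EnergyBreakdown
    decoys: List[EnergyBreakdown]
    rank: int
    z_score: Optional[float]


def zscore(native_energy: float, decoy_energies) -> Optional[float]:
    """(E_native - mean decoy energy) / population sigma of the decoy energies.

    None when the decoy spread is zero (undefined Z).
    """
    e = np.asarray(decoy_energies, float)
    sigma = float(e.std())
    if sigma == 0.0:
        return None
    return float((native_energy - e.mean()) / sigma)


def evaluate_decoys(
    native: CGStructure,
    decoys: Sequence[CGStructure],
    tables: PotentialTables,
    weights: Optional[WeightSet] = None,
) -> DecoyEvaluation:
    """Native rank and Z-score against a decoy set.

    Rank counts decoys with strictly lower energy (native wins ties). The
    Z-score uses the population standard deviation of the decoy energies,
    native excluded; a zero spread flags the Z-score as undefined (None).
    """
    if len(decoys) < 2:
        raise ScoringError("need at least 2 decoys for a defined spread")
    nb = score_total(native, tables, weights)
    dbs = [score_total(d, tables, weights) for d in decoys]
    energies = np.array([d.e_tot for d in dbs])
    rank = 1 + int((energies < nb.e_tot).sum())
    z = zscore(nb.e_tot, energies)   # population sigma, native excluded
    return DecoyEvaluation(native=nb, decoys=dbs, rank=rank, z_score=z)


def optimize_weights(
    decoy_sets: Sequence[Tuple[CGStructure, Sequence[CGStructure]]],
    tables: PotentialTables,
    grid: Optional[dict] = None,
) -> WeightSet:
    """Deterministic grid search minimizing mean normalized rank + mean Z.

    ``grid`` maps 'a'/'b'/'c' to candidate value sequences. Ties break by
    lower mean Z, then lexicographically smaller (a, b, c).
    """
    if not decoy_sets:
        raise ScoringError("need at least one decoy set")
    grid = grid or {"a": (0.5, 1.0, 2.0), "b": (0.5, 1.0, 2.0), "c": (0.5, 1.0, 2.0)}
    points = list(itertools.product(grid["a"], grid["b"], grid["c"]))
    if not points:
        raise ScoringError("empty weight grid")

    # Pre-score terms once; the combination is linear in the weights.
    prescored = []
    for native, decoys in decoy_sets:
        nb = score_total(native, tables, WeightSet())
        dbs = [score_total(d, tables, WeightSet()) for d in decoys]
        prescored.append((nb, dbs))

    best = None
    degenerate = True
    for a, b, c in points:
        w = WeightSet(a=a, b=b, c=c)
        ranks, zs = [], []
        for nb, dbs in prescored:
            e_nat = nb.recombine(w)
            e_dec = np.array([d.recombine(w) for d in dbs])
            ranks.append((1 + (e_dec < e_nat).sum()) / (len(e_dec) + 1))
            sigma = e_dec.std()
            if sigma > 0:
                zs.append((e_nat - e_dec.mean()) / sigma)
                degenerate = False
            else:
                zs.append(0.0)
        cost = float(np.mean(ranks) + np.mean(zs))
        key = (cost, float(np.mean(zs)), (a, b, c))
        if best is None or key < best[0]:
            best = (key, w)
    if degenerate:
        logger.warning("optimize_weights: flat cost surface (all decoys equal native?)")
    return best[1]
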