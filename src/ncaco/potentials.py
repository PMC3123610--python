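"""Derivation of the four statistical potentials from a structure database.

The pairwise contact and triplet-torsion terms use a mu-potential,

    E(N, N', mu) = -ln( mu * (N + 1/2) / ((1 - mu) * (N' + 1/2)) ),

where N counts observed events (contacts of an atom-type pair; occurrences of
a residue triplet in one torsion bin), N' counts the complementary events, and
the single global scalar mu in (0, 1) is chosen so that the observation-
weighted net interaction  sum_classes N~ * E(N, N', mu)  vanishes. The net sum
is strictly decreasing in mu, so bisection finds the unique root. With rare
contacts (N << N') the root sits close to 1.

The solvation term is a Boltzmann inverse of residue burial statistics,
E_ak = -ln(N_ak / E[N_ak]) with E[N_ak] = N_a * N_k / N_total, where k is the
number of other residues whose CA lies within 12.5 A. The beta-propensity
term is -ln(N_bin / Nbar) over a 4x4x6x6 grid of strand-pair geometry
features with Nbar the global per-bin mean. For these two tables only empty
cells are pseudo-counted, so expectation-matched counts give exactly zero
energy.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .cg_model import AMINO_ACIDS, CGStructure, SCMTable, compute_torsions, torsion_bin

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 1.9
COVALENT_FLOOR = 2.2          # A; shorter pairs may be covalently linked
SOLVATION_RADIUS = 12.5       # A, CA-CA
DEFAULT_D_CUT = 5.6           # A, beta-pair detection
TRP_N_BINS = 12
TRP_BIN_WIDTH = 30.0
PSEUDO = 0.5
MIN_PAIR_SEPARATION = 2       # |i-j| >= 2 for contact/clash counting

ROLES_GLY = ("N", "CA", "C", "O")
ROLES_FULL = ("N", "CA", "C", "O", "SCM")

# beta-feature bin edges (degrees); upper edge 180 closed into the last bin
ALPHA_EDGES = (0.0, 90.0, 120.0, 150.0, 180.0)
BETA_GAMMA_EDGES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


class DerivationError(ValueError):
    pass


@dataclass(frozen=True)
class AtomTypeAlphabet:
    """The 99 coarse-grained atom types: (aa, role), GLY has no SCM."""

    types: Tuple[Tuple[str, str], ...]
    index: Dict[Tuple[str, str], int]

    def __len__(self):
        return len(self.types)


def build_alphabet() -> AtomTypeAlphabet:
    types = []
    for aa in AMINO_ACIDS:
        roles = ROLES_GLY if aa == "G" else ROLES_FULL
        for role in roles:
            types.append((aa, role))
    types = tuple(types)
    return AtomTypeAlphabet(types=types, index={t: i for i, t in enumerate(types)})


ALPHABET = build_alphabet()


def structure_atoms(structure: CGStructure, with_scm: bool = True, backbone_only: bool = False):
    """Flatten a structure into (coords, type indices, residue indices) arrays."""
    coords, tidx, ridx = [], [], []
    for i, res in enumerate(structure.residues):
        for role, pos in res.atoms(with_scm=with_scm and not backbone_only):
            if backbone_only and role == "SCM":
                continue
            coords.append(pos)
            tidx.append(ALPHABET.index[(res.aa, role)])
            ridx.append(i)
    return np.array(coords), np.array(tidx), np.array(ridx)


def _pair_mask(ridx: np.ndarray, min_sep: int) -> np.ndarray:
    """Upper-triangular mask of atom pairs with residue separation >= min_sep."""
    sep = np.abs(ridx[:, None] - ridx[None, :])
    mask = sep >= min_sep
    return np.triu(mask, k=1)


def derive_min_distances(structures: Iterable[CGStructure]) -> np.ndarray:
    """Statistical shortest contact distance r_min per atom-type pair.

    The smallest inter-residue distance strictly greater than 2.2 A observed
    anywhere in the database; symmetric; pairs never observed are filled with
    the median of observed values.
    """
    structures = list(structures)
    if not structures:
        raise DerivationError("empty structure database")
    n = len(ALPHABET)
    rmin = np.full((n, n), np.inf)
    for st in structures:
        coords, tidx, ridx = structure_atoms(st)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        mask = _pair_mask(ridx, min_sep=1) & (d > COVALENT_FLOOR)
        ii, jj = np.nonzero(mask)
        a = np.minimum(tidx[ii], tidx[jj])
        b = np.maximum(tidx[ii], tidx[jj])
        np.minimum.at(rmin, (a, b), d[ii, jj])
    rmin = np.minimum(rmin, rmin.T)
    iu = np.triu_indices(n)
    observed = np.isfinite(rmin[iu])
    if not observed.any():
        raise DerivationError("no inter-residue distances above the covalent floor")
    # Unobserved type pairs take the smallest observed r_min: r_min is a
    # lower bound on approach distance, and a pair the database never shows
    # must not clash (or shell) more readily than every pair it does show.
    fill = float(np.min(rmin[iu][observed]))
    rmin[~np.isfinite(rmin)] = fill
    return rmin


def count_contacts(
    structures: Iterable[CGStructure], r_min: np.ndarray, lam: float = DEFAULT_LAMBDA
) -> Tuple[np.ndarray, np.ndarray]:
    """Count contacts / non-contacts per atom-type pair.

    A pair of atoms from residues with |i-j| >= 2 is a contact iff
    r_min <= d <= lam * r_min (boundaries inclusive); every considered pair
    that is not a contact counts as a non-contact.
    """
    if lam <= 1.0:
        raise DerivationError("lambda must exceed 1")
    n = len(ALPHABET)
    N = np.zeros((n, n))
    Nn = np.zeros((n, n))
    for st in structures:
        coords, tidx, ridx = structure_atoms(st)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        mask = _pair_mask(ridx, MIN_PAIR_SEPARATION)
        ii, jj = np.nonzero(mask)
        a = np.minimum(tidx[ii], tidx[jj])
        b = np.maximum(tidx[ii], tidx[jj])
        r = r_min[a, b]
        dc = d[ii, jj]
        is_contact = (dc >= r) & (dc <= lam * r)
        np.add.at(N, (a[is_contact], b[is_contact]), 1.0)
        np.add.at(Nn, (a[~is_contact], b[~is_contact]), 1.0)
    N = N + np.triu(N, 1).T
    Nn = Nn + np.triu(Nn, 1).T
    return N, Nn


def mu_energy(N, Nn, mu):
    """The mu-potential energy for pseudo-counted (N, N') at a given mu."""
    N = np.asarray(N, float) + PSEUDO
    Nn = np.asarray(Nn, float) + PSEUDO
    return -np.log(mu * N / ((1.0 - mu) * Nn))


def net_interaction(N, Nn, mu) -> float:
    """Observation-weighted net interaction sum over all classes."""
    Np = np.asarray(N, float) + PSEUDO
    return float(np.sum(Np * mu_energy(N, Nn, mu)))


def solve_mu(N, Nn, tol: float = 1e-6) -> float:
    """Bisection for the mu in (0,1) at which the net interaction vanishes."""
    N = np.asarray(N, float).ravel()
    Nn = np.asarray(Nn, float).ravel()
    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo = net_interaction(N, Nn, lo)
    f_hi = net_interaction(N, Nn, hi)
    if not (f_lo > 0 > f_hi):
        raise DerivationError(
            f"degenerate count table: net interaction has no sign change "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = net_interaction(N, Nn, mid)
        if f == 0.0:
            return mid
        if f > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 4 * np.finfo(float).eps * mid:
            break
    mu = 0.5 * (lo + hi)
    if abs(net_interaction(N, Nn, mu)) > max(tol, 1e-6):
        logger.warning("solve_mu: residual net interaction %.3g", net_interaction(N, Nn, mu))
    return mu


@dataclass
class ContactPotential:
    r_min: np.ndarray        # (99, 99)
    energy: np.ndarray       # (99, 99)
    counts: np.ndarray
    noncounts: np.ndarray
    lam: float
    mu: float


def derive_contact_potential(
    structures: Iterable[CGStructure],
    r_min: Optional[np.ndarray] = None,
    lam: float = DEFAULT_LAMBDA,
    high_res_structures: Optional[Iterable[CGStructure]] = None,
) -> ContactPotential:
    """Full contact-potential derivation: r_min, counts, global mu, energies."""
    structures = list(structures)
    if r_min is None:
        src = list(high_res_structures) if high_res_structures is not None else structures
        r_min = derive_min_distances(src)
    N, Nn = count_contacts(structures, r_min, lam)
    iu = np.triu_indices(len(ALPHABET))
    mu = solve_mu(N[iu], Nn[iu])
    energy = mu_energy(N, Nn, mu)
    return ContactPotential(r_min=r_min, energy=energy, counts=N, noncounts=Nn, lam=lam, mu=mu)


def triplet_bin(psi_prev: float, phi: float, psi: float, phi_next: float) -> int:
    """Flat index over the 12^4 grid of (psi_{i-1}, phi_i, psi_i, phi_{i+1})."""
    idx = 0
    for a in (psi_prev, phi, psi, phi_next):
        idx = idx * TRP_N_BINS + torsion_bin(a, TRP_BIN_WIDTH, TRP_N_BINS)
    return idx


def iter_triplet_windows(structure: CGStructure, torsions=None):
    """Yield (triplet sequence, bin index) for every window with defined dihedrals."""
    tor = torsions if torsions is not None else compute_torsions(structure)
    seq = structure.sequence
    for i in range(1, len(seq) - 1):
        quad = (tor.psi[i - 1], tor.phi[i], tor.psi[i], tor.phi[i + 1])
        if any(math.isnan(x) for x in quad):
            continue
        yield seq[i - 1 : i + 2], triplet_bin(*quad)


@dataclass
class TripletTorsionPotential:
    """Sparse mu-potential over (residue triplet, torsion bin) classes."""

    counts: Dict[Tuple[str, int], float]
    totals: Dict[str, float]
    mu: float

    def energy(self, triplet: str, bin_index: int) -> float:
        n = self.counts.get((triplet, bin_index), 0.0)
        total = self.totals.get(triplet, 0.0)
        return float(mu_energy(n, total - n, self.mu))

    @property
    def default_energy(self) -> float:
        """Energy returned for a triplet never seen in the database."""
        return float(mu_energy(0.0, 0.0, self.mu))


def derive_triplet_potential(structures: Iterable[CGStructure]) -> TripletTorsionPotential:
    structures = list(structures)
    if not structures:
        raise DerivationError("empty structure database")
    counts: Dict[Tuple[str, int], float] = {}
    totals: Dict[str, float] = {}
    for st in structures:
        for trp, b in iter_triplet_windows(st):
            counts[(trp, b)] = counts.get((trp, b), 0.0) + 1.0
            totals[trp] = totals.get(trp, 0.0) + 1.0
    if not counts:
        raise DerivationError("no triplet windows with defined dihedrals")
    N = np.array([v for v in counts.values()])
    Nn = np.array([totals[t] - v for (t, _), v in counts.items()])
    mu = solve_mu(N, Nn)
    return TripletTorsionPotential(counts=counts, totals=totals, mu=mu)


@dataclass
class SolvationPotential:
    """E_ak over 20 amino acids x contact-number k in [0, k_max]."""

    energy: np.ndarray       # (20, k_max+1)
    counts: np.ndarray       # N_ak
    n_a: np.ndarray
    n_k: np.ndarray
    n_total: float
    radius: float = SOLVATION_RADIUS

    @property
    def k_max(self) -> int:
        return self.energy.shape[1] - 1

    def lookup(self, aa: str, k: int) -> float:
        if k > self.k_max:
            logger.warning("solvation contact count %d beyond k_max=%d; clamped", k, self.k_max)
            k = self.k_max
        return float(self.energy[AMINO_ACIDS.index(aa), k])


def contact_numbers(ca: np.ndarray, radius: float = SOLVATION_RADIUS) -> np.ndarray:
    """Per-residue count of other residues with CA-CA distance < radius."""
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return (d < radius).sum(axis=1)


def solvation_energies_from_counts(n_ak: np.ndarray, n_a: np.ndarray, n_k: np.ndarray, n_total: float) -> np.ndarray:
    """E_ak = -ln(N_ak / (N_a N_k / N_total)); empty cells pseudo-counted only."""
    expected = np.outer(n_a, n_k) / n_total if n_total > 0 else np.zeros_like(n_ak, dtype=float)
    e = np.zeros_like(n_ak, dtype=float)
    nz = n_ak > 0
    with np.errstate(divide="ignore"):
        e[nz] = -np.log(n_ak[nz] / expected[nz])
    zero = ~nz
    e[zero] = -np.log(PSEUDO / (expected[zero] + PSEUDO))
    return e


def derive_solvation_potential(
    structures: Iterable[CGStructure], radius: float = SOLVATION_RADIUS
) -> SolvationPotential:
    structures = list(structures)
    if not structures:
        raise DerivationError("empty structure database")
    per_struct = []
    k_max = 0
    for st in structures:
        k = contact_numbers(st.ca_coords(), radius)
        per_struct.append((st, k))
        k_max = max(k_max, int(k.max()))
    n_ak = np.zeros((len(AMINO_ACIDS), k_max + 1))
    for st, k in per_struct:
        for res, ki in zip(st.residues, k):
            n_ak[AMINO_ACIDS.index(res.aa), int(ki)] += 1
    n_a = n_ak.sum(axis=1)
    n_k = n_ak.sum(axis=0)
    n_total = float(n_ak.sum())
    energy = solvation_energies_from_counts(n_ak, n_a, n_k, n_total)
    return SolvationPotential(
        energy=energy, counts=n_ak, n_a=n_a, n_k=n_k, n_total=n_total, radius=radius
    )


def _feature_bin(value: float, edges) -> int:
    """Half-open bins [lo, hi); the top edge is closed into the last bin."""
    for b in range(len(edges) - 1):
        if edges[b] <= value < edges[b + 1]:
            return b
    if value == edges[-1]:
        return len(edges) - 2
    raise ValueError(f"feature {value} outside [{edges[0]}, {edges[-1]}]")


def beta_bin_index(alpha1: float, alpha2: float, beta: float, gamma: float) -> Tuple[int, int, int, int]:
    return (
        _feature_bin(alpha1, ALPHA_EDGES),
        _feature_bin(alpha2, ALPHA_EDGES),
        _feature_bin(beta, BETA_GAMMA_EDGES),
        _feature_bin(gamma, BETA_GAMMA_EDGES),
    )


@dataclass
class BetaPropensityTable:
    """-ln(N_bin / Nbar) over the 4x4x6x6 grid of strand-pair features."""

    energy: np.ndarray    # (4, 4, 6, 6)
    counts: np.ndarray
    d_cut: float = DEFAULT_D_CUT

    def lookup(self, alpha1: float, alpha2: float, beta: float, gamma: float) -> float:
        return float(self.energy[beta_bin_index(alpha1, alpha2, beta, gamma)])


def beta_energies_from_counts(counts: np.ndarray) -> np.ndarray:
    nbar = counts.sum() / counts.size
    e = np.zeros_like(counts, dtype=float)
    nz = counts > 0
    e[nz] = -np.log(counts[nz] / nbar)
    e[~nz] = -np.log(PSEUDO / (nbar + PSEUDO))
    return e


def derive_beta_table(
    structures: Iterable[CGStructure], d_cut: float = DEFAULT_D_CUT
) -> BetaPropensityTable:
    """Count strand-pair feature bins over the database and invert to energies."""
    from .scorer import beta_features, detect_beta_pairs  # shared routines

    structures = list(structures)
    if not structures:
        raise DerivationError("empty structure database")
    counts = np.zeros((4, 4, 6, 6))
    n_pairs = 0
    for st in structures:
        ca = st.ca_coords()
        for pair in detect_beta_pairs(ca, d_cut):
            feats = beta_features(ca, pair.i, pair.j)
            if feats is None:
                continue
            counts[beta_bin_index(*feats)] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise DerivationError(
            "no strand pairs detected in the database; include sheet-containing structures"
        )
    return BetaPropensityTable(energy=beta_energies_from_counts(counts), counts=counts, d_cut=d_cut)


@dataclass
class PotentialTables:
    """The full derived table set used by the scorer."""

    scm: SCMTable
    contact: ContactPotential
    triplet: TripletTorsionPotential
    solvation: SolvationPotential
    beta: BetaPropensityTable
    provenance: dict = field(default_factory=dict)


class TableFormatError(ValueError):
    pass


_FORMAT_VERSION = 1


def _tables_payload(tables: PotentialTables) -> dict:
    return {
        "scm": {
            "length": tables.scm.length.tolist(),
            "angle": tables.scm.angle.tolist(),
            "dih": tables.scm.dih.tolist(),
            "count": tables.scm.count.tolist(),
        },
        "contact": {
            "r_min": tables.contact.r_min.tolist(),
            "energy": tables.contact.energy.tolist(),
            "counts": tables.contact.counts.tolist(),
            "noncounts": tables.contact.noncounts.tolist(),
            "lambda": tables.contact.lam,
            "mu": tables.contact.mu,
        },
        "triplet": {
            "counts": [[t, b, v] for (t, b), v in sorted(tables.triplet.counts.items())],
            "totals": sorted(tables.triplet.totals.items()),
            "mu": tables.triplet.mu,
        },
        "solvation": {
            "energy": tables.solvation.energy.tolist(),
            "counts": tables.solvation.counts.tolist(),
            "n_a": tables.solvation.n_a.tolist(),
            "n_k": tables.solvation.n_k.tolist(),
            "n_total": tables.solvation.n_total,
            "radius": tables.solvation.radius,
        },
        "beta": {
            "energy": tables.beta.energy.tolist(),
            "counts": tables.beta.counts.tolist(),
            "d_cut": tables.beta.d_cut,
        },
    }


def save_tables(tables: PotentialTables, path) -> None:
    """Serialize all five tables to one JSON archive with a checksummed payload."""
    payload = json.dumps(_tables_payload(tables), sort_keys=True)
    digest = hashlib.sha256(payload.encode()).hexdigest()
    doc = {
        "format": "ncaco-tables",
        "version": _FORMAT_VERSION,
        "provenance": tables.provenance,
        "sha256": digest,
        "payload": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_tables(path) -> PotentialTables:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise TableFormatError(f"unreadable table archive {path}: {exc}") from exc
    if doc.get("format") != "ncaco-tables" or doc.get("version") != _FORMAT_VERSION:
        raise TableFormatError(f"{path}: not an ncaco table archive (or wrong version)")
    payload = doc["payload"]
    if hashlib.sha256(payload.encode()).hexdigest() != doc.get("sha256"):
        raise TableFormatError(f"{path}: checksum mismatch")
    data = json.loads(payload)
    scm = SCMTable(
        length=np.array(data["scm"]["length"]),
        angle=np.array(data["scm"]["angle"]),
        dih=np.array(data["scm"]["dih"]),
        count=np.array(data["scm"]["count"], dtype=int),
    )
    c = data["contact"]
    contact = ContactPotential(
        r_min=np.array(c["r_min"]), energy=np.array(c["energy"]),
        counts=np.array(c["counts"]), noncounts=np.array(c["noncounts"]),
        lam=c["lambda"], mu=c["mu"],
    )
    t = data["triplet"]
    triplet = TripletTorsionPotential(
        counts={(trp, int(b)): v for trp, b, v in t["counts"]},
        totals=dict(t["totals"]),
        mu=t["mu"],
    )
    s = data["solvation"]
    solvation = SolvationPotential(
        energy=np.array(s["energy"]), counts=np.array(s["counts"]),
        n_a=np.array(s["n_a"]), n_k=np.array(s["n_k"]),
        n_total=s["n_total"], radius=s["radius"],
    )
    b = data["beta"]
    beta = BetaPropensityTable(
        energy=np.array(b["energy"]), counts=np.array(b["counts"]), d_cut=b["d_cut"]
    )
    return PotentialTables(
        scm=scm, contact=contact, triplet=triplet, solvation=solvation, beta=beta,
        provenance=doc.get("provenance", {}),
    )


def derive_all_tables(
    structures: Iterable[CGStructure],
    high_res_structures: Optional[Iterable[CGStructure]] = None,
    lam: float = DEFAULT_LAMBDA,
    d_cut: float = DEFAULT_D_CUT,
) -> PotentialTables:
    """One-call derivation of the complete table set from raw structures.

    ``structures`` must retain side-chain heavy atoms: the SCM table is
    derived first, SCMs are then placed on every chain, and the four
    potentials are counted on the SCM-placed database. ``high_res_structures``
    (if given) stands in for the high-resolution set used only for r_min.
    """
    from .cg_model import derive_scm_table, place_scm

    structures = list(structures)
    scm_table = derive_scm_table(structures)
    placed = [place_scm(s, scm_table) for s in structures]
    if high_res_structures is not None:
        placed_hr = [place_scm(s, scm_table) for s in high_res_structures]
    else:
        placed_hr = placed
    r_min = derive_min_distances(placed_hr)
    contact = derive_contact_potential(placed, r_min=r_min, lam=lam)
    triplet = derive_triplet_potential(placed)
    solvation = derive_solvation_potential(placed)
    beta = derive_beta_table(placed, d_cut=d_cut)
    prov = {
        "n_structures": len(structures),
        "lambda": lam,
        "d_cut": d_cut,
        "mu_contact": contact.mu,
        "mu_triplet": triplet.mu,
    }
    return PotentialTables(
        scm=scm_table, contact=contact, triplet=triplet,
        solvation=solvation, beta=beta, provenance=prov,
    )
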