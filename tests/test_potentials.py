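import math

import numpy as np
import pytest

from ncaco.cg_model import place_scm
from ncaco.fixtures import FixtureSpec, gen_ideal_helix, gen_structure_db
from ncaco.potentials import (
    ALPHABET,
    COVALENT_FLOOR,
    DerivationError,
    PSEUDO,
    beta_energies_from_counts,
    build_alphabet,
    count_contacts,
    derive_all_tables,
    derive_min_distances,
    derive_solvation_potential,
    derive_triplet_potential,
    load_tables,
    mu_energy,
    net_interaction,
    save_tables,
    solvation_energies_from_counts,
    solve_mu,
    structure_atoms,
)

# ---------------------------------------------------------------- alphabet

def test_alphabet_structure():
    ab = build_alphabet()
    assert len(ab) == 99
    gly = [t for t in ab.types if t[0] == "G"]
    assert [r for _, r in gly] == ["N", "CA", "C", "O"]
    for aa in set(a for a, _ in ab.types) - {"G"}:
        assert sum(1 for a, _ in ab.types if a == aa) == 5


# ---------------------------------------------------------------- r_min / contacts

def brute_force_atoms(structure):
    out = []
    for i, res in enumerate(structure.residues):
        for role, pos in res.atoms():
            out.append((i, (res.aa, role), np.asarray(pos)))
    return out


def brute_force_rmin(structures):
    n = len(ALPHABET)
    rmin = np.full((n, n), np.inf)
    for st in structures:
        atoms = brute_force_atoms(st)
        for i, (ri, ti, pi) in enumerate(atoms):
            for j, (rj, tj, pj) in enumerate(atoms):
                if j <= i or ri == rj:
                    continue
                d = float(np.linalg.norm(pi - pj))
                if d <= COVALENT_FLOOR:
                    continue
                a, b = ALPHABET.index[ti], ALPHABET.index[tj]
                rmin[a, b] = min(rmin[a, b], d)
                rmin[b, a] = rmin[a, b]
    return rmin


@pytest.fixture(scope="module")
def placed_micro(tables, micro_db):
    return [place_scm(s, tables.scm) for s in micro_db[:3]]


def test_rmin_matches_bruteforce(placed_micro):
    db = placed_micro[:2]
    got = derive_min_distances(db)
    want = brute_force_rmin(db)
    observed = np.isfinite(want)
    assert np.allclose(got[observed], want[observed])
    assert np.allclose(got, got.T)
    assert (got > COVALENT_FLOOR).all()


def test_contact_counts_match_bruteforce(placed_micro):
    db = placed_micro[:2]
    rmin = derive_min_distances(db)
    lam = 1.9
    N, Nn = count_contacts(db, rmin, lam)
    bN = np.zeros_like(N)
    bNn = np.zeros_like(Nn)
    for st in db:
        atoms = brute_force_atoms(st)
        for i, (ri, ti, pi) in enumerate(atoms):
            for j, (rj, tj, pj) in enumerate(atoms):
                if j <= i or abs(ri - rj) < 2:
                    continue
                a, b = ALPHABET.index[ti], ALPHABET.index[tj]
                d = float(np.linalg.norm(pi - pj))
                r = rmin[a, b]
                # the pair defining r_min re-measures at d == r up to one ulp;
                # make the oracle's inclusive lower boundary float-tolerant
                if r - 1e-9 <= d <= lam * r:
                    bN[a, b] += 1
                    if a != b:
                        bN[b, a] += 1
                else:
                    bNn[a, b] += 1
                    if a != b:
                        bNn[b, a] += 1
    assert np.array_equal(N, bN)
    assert np.array_equal(Nn, bNn)


def test_contact_boundaries():
    """Contact predicate is inclusive at r_min and at lambda * r_min."""
    r = 3.0
    lam = 1.9
    assert r <= 3.0 <= lam * r
    assert not (r <= 5.71 <= lam * r)   # just above 1.9 * 3.0


def test_count_contacts_rejects_bad_lambda(placed_micro):
    rmin = derive_min_distances(placed_micro[:1])
    with pytest.raises(DerivationError):
        count_contacts(placed_micro[:1], rmin, 0.9)


# ---------------------------------------------------------------- mu solving

def test_solve_mu_engineered_half():
    """Counts built so the net interaction vanishes at exactly mu = 0.5."""
    # two classes with equal pseudo-counted N and log-ratios that cancel
    n1, nn1 = 3.0, 7.0
    n2 = 3.0
    nn2 = (n1 + PSEUDO) ** 2 / (nn1 + PSEUDO) - PSEUDO
    mu = solve_mu(np.array([n1, n2]), np.array([nn1, nn2]))
    assert mu == pytest.approx(0.5, abs=1e-6)
    # oracle: dense grid scan locates the same root
    grid = np.linspace(1e-4, 1 - 1e-4, 20001)
    nets = [net_interaction(np.array([n1, n2]), np.array([nn1, nn2]), m) for m in grid]
    root = grid[int(np.argmin(np.abs(nets)))]
    assert mu == pytest.approx(root, abs=1e-4)


def test_solve_mu_symmetric_classes_zero_energy():
    """Identical classes: the net vanishes exactly where each energy is zero."""
    N = np.array([4.0, 4.0])
    Nn = np.array([9.0, 9.0])
    mu = solve_mu(N, Nn)
    assert np.allclose(mu_energy(N, Nn, mu), 0.0, atol=1e-9)
    assert mu == pytest.approx((9.0 + PSEUDO) / (4.0 + 9.0 + 2 * PSEUDO), abs=1e-9)


def test_net_zero_invariant_on_derived_tables(tables):
    iu = np.triu_indices(99)
    assert abs(net_interaction(
        tables.contact.counts[iu], tables.contact.noncounts[iu], tables.contact.mu
    )) < 1e-6
    N = np.array(list(tables.triplet.counts.values()))
    Nn = np.array([tables.triplet.totals[t] - v for (t, _), v in tables.triplet.counts.items()])
    assert abs(net_interaction(N, Nn, tables.triplet.mu)) < 1e-6


def test_contact_energy_symmetric(tables):
    assert np.allclose(tables.contact.energy, tables.contact.energy.T)
    assert np.allclose(tables.contact.r_min, tables.contact.r_min.T)


def test_contact_energy_matches_formula_on_counts(tables):
    """Independent reimplementation of the energy form on the stored counts."""
    c = tables.contact
    want = -np.log(c.mu * (c.counts + 0.5) / ((1 - c.mu) * (c.noncounts + 0.5)))
    assert np.allclose(c.energy, want)


# ---------------------------------------------------------------- triplet potential

def test_triplet_dominant_bin_is_negative_and_minimal():
    """The heavily-populated bin of a triplet gets a negative, minimal energy."""
    from ncaco.cg_model import TorsionSeries, rebuild_backbone

    helix = gen_ideal_helix(10, sequence="A" * 10)     # 7 windows in one bin
    n = 5
    t = TorsionSeries(phi=np.full(n, 180.0), psi=np.full(n, 180.0), omega=np.full(n, 180.0))
    extended = rebuild_backbone("A" * n, t)            # 3 windows in another bin
    pot = derive_triplet_potential([helix, extended])
    bins = {b: v for (trp, b), v in pot.counts.items()}
    b_major = max(bins, key=bins.get)
    e_major = pot.energy("AAA", b_major)
    assert e_major < 0
    others = [pot.energy("AAA", b) for b in bins if b != b_major]
    assert all(e_major < e for e in others)
    # hand oracle: direct formula on the window counts (8 helix vs 3 extended)
    assert bins[b_major] == 8.0 and pot.totals["AAA"] == 11.0
    mu = pot.mu
    want = -math.log(mu * 8.5 / ((1 - mu) * 3.5))
    assert e_major == pytest.approx(want, abs=1e-12)


def test_triplet_unseen_returns_default(tables):
    e = tables.triplet.energy("WWW", 0)
    assert e == pytest.approx(tables.triplet.default_energy)
    assert math.isfinite(e)


def test_triplet_uniform_counts_equal_energies():
    pot = derive_triplet_potential([gen_ideal_helix(10, sequence="A" * 10)])
    # manufacture uniform occupancy over three bins
    pot.counts = {("AAA", 0): 5.0, ("AAA", 1): 5.0, ("AAA", 2): 5.0}
    pot.totals = {"AAA": 15.0}
    es = {pot.energy("AAA", b) for b in range(3)}
    assert len(es) == 1


# ---------------------------------------------------------------- solvation

def test_solvation_expectation_identity():
    """Counts exactly at their expectation give identically zero energies."""
    n_a = np.array([10.0, 20.0, 30.0])
    n_k = np.array([30.0, 30.0])
    n_total = 60.0
    n_ak = np.outer(n_a, n_k) / n_total
    e = solvation_energies_from_counts(n_ak, n_a, n_k, n_total)
    assert np.all(e == 0.0)


def test_solvation_double_expectation_is_minus_ln2():
    n_a = np.array([40.0])
    n_k = np.array([10.0, 30.0])
    n_total = 40.0
    expected = np.outer(n_a, n_k) / n_total
    n_ak = 2.0 * expected
    e = solvation_energies_from_counts(n_ak, n_a, n_k, n_total)
    assert np.allclose(e, -math.log(2.0))


def test_solvation_counts_match_bruteforce(micro_db):
    db = micro_db[:2]
    pot = derive_solvation_potential(db)
    # brute-force recount
    from ncaco.cg_model import AMINO_ACIDS

    n_ak = np.zeros_like(pot.counts)
    for st in db:
        ca = st.ca_coords()
        for i, res in enumerate(st.residues):
            k = sum(
                1 for j in range(len(ca))
                if j != i and np.linalg.norm(ca[i] - ca[j]) < 12.5
            )
            n_ak[AMINO_ACIDS.index(res.aa), k] += 1
    assert np.array_equal(pot.counts, n_ak)
    assert pot.n_total == n_ak.sum()


def test_solvation_k_clamp(tables):
    k_max = tables.solvation.k_max
    assert tables.solvation.lookup("A", k_max + 5) == tables.solvation.lookup("A", k_max)


# ---------------------------------------------------------------- beta table

def test_beta_uniform_counts_zero_energy():
    counts = np.full((4, 4, 6, 6), 3.0)
    assert np.all(beta_energies_from_counts(counts) == 0.0)


def test_beta_single_bin_minus_ln576():
    counts = np.zeros((4, 4, 6, 6))
    counts[1, 2, 3, 4] = 576.0
    e = beta_energies_from_counts(counts)
    assert e[1, 2, 3, 4] == pytest.approx(-math.log(576.0))


def test_beta_table_counts_match_bruteforce(micro_db):
    """Single-structure bin counts equal an independent feature recount."""
    from ncaco.potentials import beta_bin_index, derive_beta_table
    from ncaco.scorer import detect_beta_pairs

    sheet = next(s for s in micro_db if s.id.startswith("sheet"))
    table = derive_beta_table([sheet])
    ca = sheet.ca_coords()
    pairs = detect_beta_pairs(ca, table.d_cut)
    assert pairs, "sheet fixture must contain strand pairs"

    def oracle_features(i, j):
        def ang(u, v):
            c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            return math.degrees(math.acos(np.clip(c, -1, 1)))

        a1 = ang(ca[i - 1] - ca[i], ca[i + 1] - ca[i])
        a2 = ang(ca[j - 1] - ca[j], ca[j + 1] - ca[j])
        gamma = ang(ca[i] - ca[i - 1], ca[j] - ca[j - 1])
        p_i = ca[i] - 0.5 * (ca[i - 1] + ca[i + 1])
        p_j = ca[j] - 0.5 * (ca[j - 1] + ca[j + 1])
        if np.linalg.norm(p_i) < 1e-9 or np.linalg.norm(p_j) < 1e-9:
            return None
        return a1, a2, ang(p_i, p_j), gamma

    counts = np.zeros((4, 4, 6, 6))
    for p in pairs:
        feats = oracle_features(p.i, p.j)
        if feats is not None:
            counts[beta_bin_index(*feats)] += 1
    assert np.array_equal(table.counts, counts)


# ---------------------------------------------------------------- serialization

def test_tables_roundtrip(tables, tmp_path):
    path = tmp_path / "t.ncaco"
    save_tables(tables, path)
    back = load_tables(path)
    assert np.array_equal(back.contact.energy, tables.contact.energy)
    assert np.array_equal(back.scm.length, tables.scm.length)
    assert back.triplet.counts == tables.triplet.counts
    assert back.triplet.mu == tables.triplet.mu
    assert np.array_equal(back.solvation.energy, tables.solvation.energy)
    assert np.array_equal(back.beta.energy, tables.beta.energy)


def test_tables_truncated_file_errors(tables, tmp_path):
    from ncaco.potentials import TableFormatError

    path = tmp_path / "t.ncaco"
    save_tables(tables, path)
    data = path.read_text()
    path.write_text(data[: len(data) // 2])
    with pytest.raises(TableFormatError):
        load_tables(path)


def test_tables_derivation_deterministic(micro_db, tmp_path):
    a = derive_all_tables(micro_db[:4])
    b = derive_all_tables(micro_db[:4])
    pa, pb = tmp_path / "a", tmp_path / "b"
    save_tables(a, pa)
    save_tables(b, pb)
    assert pa.read_bytes() == pb.read_bytes()
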