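"""Fragment-assembly folding guided by the coarse-grained score.

The protocol: start from an extended chain (all torsions 180 degrees),
randomize every triplet from the fragment library, then run simulated
annealing in which a random triplet's phi/psi/omega are replaced by a random
library candidate and the move is accepted by a Metropolis criterion,
r < exp(-dE / (k * T * factor)), with the temperature lowered linearly from
2000 to 300 over the run. A proposal whose backbone clash count exceeds L/3
is rejected outright; the clash count enters the energy as E_clash. The
escape factor grows once more than 200 consecutive rejections accumulate
(factor = 1 + (Nr - 200)/divisor) and the run stops early when it passes the
run's stop threshold (11.0 / 6.0 / 3.5 for the three iterations). The
E_beta weight oscillates as |sin(pi * Tn / 1000)| to let sheets form and
dissolve periodically. Models are selected by SPICKER-style centroid
clustering on pairwise TM-scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cg_model import CGStructure, TorsionSeries, compute_torsions, place_scm, rebuild_backbone
from .geometry import transform_of
from .potentials import PotentialTables
from .scorer import EnergyBreakdown, WeightSet, count_clashes, score_total

logger = logging.getLogger(__name__)

BETA_PERIOD = 1000.0


class AssemblyError(ValueError):
    pass


@dataclass
class AnnealConfig:
    n_steps: int = 35000
    t_start: float = 2000.0
    t_end: float = 300.0
    nr_trigger: int = 200
    factor_divisor: float = 80.0
    factor_stop: float = 11.0
    k_boltz: float = 0.002      # calibration constant in exp(-dE/(k*T*factor))
    beta_period: float = BETA_PERIOD

    def temperature(self, step: int) -> float:
        if self.n_steps <= 1:
            return self.t_start
        frac = step / (self.n_steps - 1)
        return self.t_start + (self.t_end - self.t_start) * frac


# per-iteration escape-factor settings of the three-run protocol
RUN_FACTORS = ((80.0, 11.0), (160.0, 6.0), (320.0, 3.5))


def beta_weight(step: int, period: float = BETA_PERIOD) -> float:
    """Periodic multiplier of the E_beta weight: |sin(pi*Tn/period)|.

    0 at Tn = 0, maximal (1) at Tn = period/2, back to 0 at Tn = period.
    """
    return abs(math.sin(math.pi * step / period))


def init_extended(sequence: str) -> CGStructure:
    """Extended chain: all phi/psi/omega at 180 degrees."""
    if len(sequence) < 3:
        raise AssemblyError("sequence too short")
    L = len(sequence)
    t = TorsionSeries(phi=np.full(L, 180.0), psi=np.full(L, 180.0), omega=np.full(L, 180.0))
    return rebuild_backbone(sequence, t, id="extended")


def _full_torsion_array(structure: CGStructure) -> np.ndarray:
    """(L, 3) torsions with terminal undefined entries set to 180 for rebuilds."""
    tor = compute_torsions(structure)
    arr = np.column_stack([tor.phi, tor.psi, tor.omega])
    arr[np.isnan(arr)] = 180.0
    return arr


def _torsions_to_series(arr: np.ndarray) -> TorsionSeries:
    return TorsionSeries(phi=arr[:, 0].copy(), psi=arr[:, 1].copy(), omega=arr[:, 2].copy())


def randomize(
    structure: CGStructure,
    library,
    rng: np.random.Generator,
    r_min: Optional[np.ndarray] = None,
    max_tries: int = 50,
) -> CGStructure:
    """Replace every triplet's torsions, N- to C-terminus, from the library.

    When ``r_min`` is given, drawing is retried until the backbone clash count
    stays within the L/3 bound the annealer enforces (the least-clashed draw
    is returned, with a warning, if no draw satisfies it).
    """
    L = len(structure)
    if len(library.candidates) < L - 2:
        raise AssemblyError("library does not cover all triplet positions")

    def draw():
        arr = _full_torsion_array(structure)
        for p in range(L - 2):
            cands = library.candidates[p]
            if not cands:
                raise AssemblyError(f"no candidates at position {p}")
            c = cands[rng.integers(len(cands))]
            arr[p : p + 3] = c.torsions
        return rebuild_backbone(structure.sequence, _torsions_to_series(arr), id=structure.id)

    if r_min is None:
        return draw()
    from .scorer import count_clashes

    best_st, best_bb = None, None
    for _ in range(max_tries):
        st = draw()
        n_bb, _ = count_clashes(st, r_min)
        if n_bb <= L / 3.0:
            return st
        if best_bb is None or n_bb < best_bb:
            best_st, best_bb = st, n_bb
    logger.warning("randomize: no draw within the clash bound after %d tries "
                   "(best %d backbone clashes)", max_tries, best_bb)
    return best_st


def accept_move(delta: float, temperature: float, factor: float,
                k_boltz: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: always accept downhill; uphill with
    probability exp(-dE / (k * T * factor))."""
    if delta < 0.0:
        return True
    p = math.exp(-delta / (k_boltz * temperature * factor))
    return rng.random() < p


@dataclass
class TraceRecord:
    step: int
    temperature: float
    factor: float
    accepted: bool
    energy: float          # schedule-weighted energy of the current state
    energy_ref: float      # fixed-weight reference energy of the current state
    best_ref: float


def _evaluate(arr: np.ndarray, sequence: str, tables: PotentialTables,
              weights: WeightSet, structure_id: str = "model"):
    from .scorer import (_contact_pair_arrays, score_beta, score_contact,
                         score_solvation, score_triplet)

    st = rebuild_backbone(sequence, _torsions_to_series(arr), id=structure_id)
    # the torsions are known exactly (the rebuild is their inverse); flag the
    # terminal undefined entries rather than recomputing from coordinates
    tor = _torsions_to_series(arr)
    tor.phi[0] = math.nan
    tor.psi[-1] = math.nan
    tor.omega[-1] = math.nan
    st = place_scm(st, tables.scm, torsions=tor)
    pairs = _contact_pair_arrays(st)
    n_bb, n_all = count_clashes(st, tables.contact.r_min, _pairs=pairs)
    bd = EnergyBreakdown(
        e_con=score_contact(st, tables.contact, _pairs=pairs),
        e_trp=score_triplet(st, tables.triplet, torsions=tor),
        e_sol=score_solvation(st, tables.solvation),
        e_beta=score_beta(st, tables.beta),
        e_clash=float(n_all),
        e_tot=0.0,
    )
    bd.e_tot = bd.recombine(weights, with_clash=True, beta_multiplier=1.0)
    return st, bd, n_bb


def sa_run(
    structure: CGStructure,
    library,
    tables: PotentialTables,
    weights: WeightSet,
    config: AnnealConfig,
    rng: np.random.Generator,
) -> Tuple[CGStructure, EnergyBreakdown, List[TraceRecord]]:
    """One simulated-annealing trajectory of single-triplet replacements.

    Returns the best structure visited (by the fixed-weight reference energy,
    clash term included, beta multiplier 1), its energy breakdown, and the
    per-step trace. Early stop when the escape factor passes its threshold.
    """
    L = len(structure)
    seq = structure.sequence
    max_bb_clash = L / 3.0
    arr = _full_torsion_array(structure)
    cur_st, cur_bd, cur_bb = _evaluate(arr, seq, tables, weights, structure.id)
    best_arr = arr.copy()
    best_bd = cur_bd
    best_ref = cur_bd.recombine(weights, with_clash=True, beta_multiplier=1.0)
    trace: List[TraceRecord] = []
    nr = 0
    factor = 1.0
    for step in range(config.n_steps):
        T = config.temperature(step)
        mult = beta_weight(step, config.beta_period)
        pos = int(rng.integers(L - 2))
        cands = library.candidates[pos]
        cand = cands[rng.integers(len(cands))]
        prop = arr.copy()
        prop[pos : pos + 3] = cand.torsions
        prop_st, prop_bd, prop_bb = _evaluate(prop, seq, tables, weights, structure.id)
        accepted = False
        if prop_bb <= max_bb_clash:
            e_cur = cur_bd.recombine(weights, with_clash=True, beta_multiplier=mult)
            e_prop = prop_bd.recombine(weights, with_clash=True, beta_multiplier=mult)
            accepted = accept_move(e_prop - e_cur, T, factor, config.k_boltz, rng)
        if accepted:
            arr = prop
            cur_bd = prop_bd
            nr = 0
            factor = 1.0
            ref = cur_bd.recombine(weights, with_clash=True, beta_multiplier=1.0)
            if ref < best_ref:
                best_ref = ref
                best_arr = arr.copy()
                best_bd = cur_bd
        else:
            nr += 1
            if nr > config.nr_trigger:
                factor = 1.0 + (nr - config.nr_trigger) / config.factor_divisor
        trace.append(
            TraceRecord(
                step=step, temperature=T, factor=factor, accepted=accepted,
                energy=cur_bd.recombine(weights, with_clash=True, beta_multiplier=mult),
                energy_ref=cur_bd.recombine(weights, with_clash=True, beta_multiplier=1.0),
                best_ref=best_ref,
            )
        )
        if factor > config.factor_stop:
            logger.info("early stop at step %d (factor %.2f)", step, factor)
            break
    best_st = rebuild_backbone(seq, _torsions_to_series(best_arr), id=structure.id)
    best_st = place_scm(best_st, tables.scm)
    best_bd = replace(
        best_bd, e_tot=best_bd.recombine(weights, with_clash=True, beta_multiplier=1.0)
    )
    return best_st, best_bd, trace


def tm_score(model: CGStructure | np.ndarray, reference: CGStructure | np.ndarray) -> float:
    """Length-normalized TM-score of two equal-length CA traces.

    d0 = 1.24*(L-15)^(1/3) - 1.8 (floored at 0.5); iterative superposition
    extension seeded from windows of several lengths, keeping the best score.
    """
    m = model.ca_coords() if isinstance(model, CGStructure) else np.asarray(model, float)
    r = reference.ca_coords() if isinstance(reference, CGStructure) else np.asarray(reference, float)
    if len(m) != len(r):
        raise AssemblyError(f"length mismatch: {len(m)} vs {len(r)}")
    L = len(r)
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8 if L > 15 else 0.5
    d0 = max(d0, 0.5)

    def score_from(idx: np.ndarray) -> float:
        best = 0.0
        sel = idx
        for _ in range(20):
            if len(sel) < 3:
                break
            R, t = transform_of(m[sel], r[sel])
            moved = m @ R.T + t
            d = np.linalg.norm(moved - r, axis=1)
            s = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)
            best = max(best, s)
            d_cut = d0
            new = np.nonzero(d < d_cut)[0]
            while len(new) < 3:
                d_cut += 0.5
                new = np.nonzero(d < d_cut)[0]
            if len(new) == len(sel) and np.array_equal(new, sel):
                break
            sel = new
        return best

    best = 0.0
    lengths = sorted({L, max(L // 2, 4), max(L // 4, 4)}, reverse=True)
    for seg in lengths:
        for start in range(0, L - seg + 1):
            best = max(best, score_from(np.arange(start, start + seg)))
    return best


@dataclass
class Model:
    structure: CGStructure
    energy: EnergyBreakdown
    run_index: int
    seed: int


@dataclass
class ClusterResult:
    clusters: List[dict]            # {"centroid": idx, "members": [...]} by size desc
    cutoff: float
    top5: List[int]                 # indices of cluster centroids, biggest first


def _cluster_at(tm: np.ndarray, cutoff: float) -> List[dict]:
    n = len(tm)
    remaining = list(range(n))
    clusters = []
    while remaining:
        sub = tm[np.ix_(remaining, remaining)]
        neighbor_counts = (sub >= cutoff).sum(axis=1)  # includes self
        seed_local = int(np.argmax(neighbor_counts))   # ties -> lowest index
        centroid = remaining[seed_local]
        members = [remaining[k] for k in np.nonzero(sub[seed_local] >= cutoff)[0]]
        clusters.append({"centroid": centroid, "members": members})
        remaining = [k for k in remaining if k not in set(members)]
    clusters.sort(key=lambda c: (-len(c["members"]), c["centroid"]))
    return clusters


def cluster_models(
    ensemble: Sequence[Model],
    cutoff: float = 0.7,
    bounds: Tuple[float, float] = (0.3, 0.9),
    target_fraction: Tuple[float, float] = (0.2, 0.7),
    step: float = 0.05,
) -> ClusterResult:
    """SPICKER-style centroid clustering on pairwise TM-scores.

    The model with the most neighbors above the cutoff seeds a cluster, its
    members are removed, and the process repeats. The cutoff adapts within
    ``bounds`` until the biggest cluster holds 20-70% of the models; hitting
    a bound accepts the clustering with a warning.
    """
    if not ensemble:
        raise AssemblyError("empty ensemble")
    n = len(ensemble)
    cas = [m.structure.ca_coords() for m in ensemble]
    tm = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tm[i, j] = tm[j, i] = tm_score(cas[i], cas[j])

    lo, hi = bounds
    f_lo, f_hi = target_fraction
    cutoff = min(max(cutoff, lo), hi)
    for _ in range(100):
        clusters = _cluster_at(tm, cutoff)
        frac = len(clusters[0]["members"]) / n
        if f_lo <= frac <= f_hi:
            break
        if frac > f_hi and cutoff < hi - 1e-9:
            cutoff = min(cutoff + step, hi)      # stricter -> smaller clusters
        elif frac < f_lo and cutoff > lo + 1e-9:
            cutoff = max(cutoff - step, lo)
        else:
            logger.warning(
                "biggest-cluster fraction %.2f outside [%.2f, %.2f] at cutoff bound %.2f",
                frac, f_lo, f_hi, cutoff,
            )
            break
    top = [c["centroid"] for c in clusters[:5]]
    if len(ensemble) < 5:
        logger.warning("fewer than 5 models; returning all %d centroids", len(top))
    return ClusterResult(clusters=clusters, cutoff=cutoff, top5=top)


@dataclass
class PredictResult:
    best: Model
    top5: List[Model]
    ensembles: List[List[Model]]    # one ensemble per iteration
    cluster_results: List[ClusterResult]


def predict(
    sequence: str,
    library,
    tables: PotentialTables,
    weights: Optional[WeightSet] = None,
    config: Optional[AnnealConfig] = None,
    n_models_run1: int = 1000,
    n_models_per_seed: int = 200,
    seed: int = 0,
) -> PredictResult:
    """Three-iteration fold-and-select protocol.

    Iteration 1 runs ``n_models_run1`` independent annealing trajectories
    from randomized starts and clusters them; iterations 2 and 3 respawn
    ``n_models_per_seed`` trajectories from each of the previous top-5
    centroids with progressively gentler escape factors, recluster, and the
    final answer is the lowest-energy structure among the third run's top 5.
    """
    weights = weights or WeightSet()
    base = config or AnnealConfig()
    ss = np.random.SeedSequence(seed)
    ensembles: List[List[Model]] = []
    cluster_results: List[ClusterResult] = []
    extended = init_extended(sequence)
    starts: List[CGStructure] = []
    for run_idx, (divisor, stop) in enumerate(RUN_FACTORS):
        cfg = replace(base, factor_divisor=divisor, factor_stop=stop)
        if run_idx == 0:
            jobs = [(extended, True)] * n_models_run1
        else:
            jobs = [(s, False) for s in starts for _ in range(n_models_per_seed)]
        children = ss.spawn(len(jobs))
        models = []
        for k, ((start, do_randomize), child) in enumerate(zip(jobs, children)):
            rng = np.random.default_rng(child)
            if do_randomize:
                st = randomize(start, library, rng, r_min=tables.contact.r_min)
            else:
                st = start.copy()
            best_st, best_bd, _ = sa_run(st, library, tables, weights, cfg, rng)
            models.append(Model(structure=best_st, energy=best_bd,
                                run_index=run_idx, seed=k))
        cr = cluster_models(models)
        ensembles.append(models)
        cluster_results.append(cr)
        starts = [models[i].structure for i in cr.top5]
    final_models = [ensembles[-1][i] for i in cluster_results[-1].top5]
    best = min(final_models, key=lambda m: m.energy.e_tot)
    return PredictResult(best=best, top5=final_models, ensembles=ensembles,
                         cluster_results=cluster_results)
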