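"""Per-position three-residue torsion-template library for fragment assembly.

For each overlapping query triplet, every template triplet in the structure
database is scored by a profile-profile term,

    sum_{i=1..3} sum_{j=1..20} F_query(i, j) * P_template(i, j),

plus a secondary-structure agreement bonus (+1 per matched position, scaled
by a configurable weight), and the 25 best-scoring templates' phi/psi/omega
torsions are kept. Query profiles come from PSI-BLAST ASCII PSSM files
(frequency part), template log-odds from the same dialect; query secondary
structure from PSIPRED ``.ss2`` files, template secondary structure from
DSSP output mapped H/G/I -> H, E -> E, else -> C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .cg_model import CGStructure, compute_torsions

logger = logging.getLogger(__name__)

# PSI-BLAST PSSM column order
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
N_SELECT = 25
DEFAULT_SS_WEIGHT = 1.0
HOMOLOG_IDENTITY_THRESHOLD = 0.30


class ProfileFormatError(ValueError):
    pass


@dataclass
class SequenceProfile:
    """Per-position 20-vectors: frequencies for queries, log-odds for templates."""

    sequence: str
    frequencies: Optional[np.ndarray] = None   # (L, 20), rows sum to 1
    log_odds: Optional[np.ndarray] = None      # (L, 20)

    def __len__(self):
        return len(self.sequence)


def map_dssp_ss(labels: str) -> str:
    """Collapse DSSP 8-state labels to H/E/C (H, G, I -> H; E -> E; else C)."""
    return "".join("H" if c in "HGI" else ("E" if c == "E" else "C") for c in labels)


def read_ss2(path) -> Tuple[str, str]:
    """Parse a PSIPRED VFORMAT .ss2 file -> (sequence, SS string over {H,E,C})."""
    seq, ss = [], []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or "PSIPRED" not in lines[0]:
        raise ProfileFormatError(f"{path}: missing PSIPRED VFORMAT header")
    for line in lines[1:]:
        parts = line.split()
        if len(parts) < 6:
            continue
        seq.append(parts[1])
        ss.append(parts[2])
    if not seq:
        raise ProfileFormatError(f"{path}: no residue rows")
    return "".join(seq), "".join(ss)


def read_pssm(path) -> SequenceProfile:
    """Parse a PSI-BLAST ASCII PSSM: both the log-odds and frequency matrices.

    Query frequency rows (percentages) are renormalized after a small
    pseudo-count so degenerate all-zero rows cannot occur.
    """
    seq, lods, freqs = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    started = False
    for line in lines:
        parts = line.split()
        if not started:
            if len(parts) >= 40 and parts[0] == "A":
                started = True
            continue
        if len(parts) < 42 or not parts[0].isdigit():
            continue
        seq.append(parts[1])
        lods.append([float(x) for x in parts[2:22]])
        freqs.append([float(x) for x in parts[22:42]])
    if not started:
        raise ProfileFormatError(f"{path}: missing PSI-BLAST PSSM column header")
    if not seq:
        raise ProfileFormatError(f"{path}: no PSSM rows")
    freq = np.array(freqs) / 100.0 + 1e-6
    freq /= freq.sum(axis=1, keepdims=True)
    return SequenceProfile(sequence="".join(seq), frequencies=freq, log_odds=np.array(lods))


def read_dssp(path) -> Tuple[str, str]:
    """Parse classic DSSP output -> (sequence, mapped H/E/C string)."""
    seq, ss = [], []
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise ProfileFormatError(f"{path}: missing DSSP '#  RESIDUE' header")
    for line in lines[start:]:
        if len(line) < 17:
            continue
        aa = line[13]
        if aa == "!":   # chain break
            continue
        seq.append(aa)
        ss.append(line[16] if line[16] != " " else "C")
    if not seq:
        raise ProfileFormatError(f"{path}: no residue rows")
    return "".join(seq), map_dssp_ss("".join(ss))


def load_inputs(ss2_file=None, pssm_file=None, dssp_file=None) -> Tuple[SequenceProfile, str]:
    """Load query inputs (ss2 + PSSM) and/or template SS (DSSP).

    Returns (profile, secondary structure). For a query, pass ss2 + PSSM; for
    a template whose SS comes from DSSP, pass pssm_file + dssp_file.
    """
    profile = read_pssm(pssm_file) if pssm_file else None
    if ss2_file is not None:
        seq, ss = read_ss2(ss2_file)
    elif dssp_file is not None:
        seq, ss = read_dssp(dssp_file)
    else:
        raise ProfileFormatError("need an ss2 or a DSSP file for secondary structure")
    if profile is not None:
        if len(profile) != len(ss):
            raise ProfileFormatError(
                f"profile length {len(profile)} != secondary-structure length {len(ss)}"
            )
        if profile.sequence != seq:
            logger.warning("profile and SS sequences disagree; keeping profile sequence")
    else:
        profile = SequenceProfile(sequence=seq)
    return profile, ss


@dataclass
class FragmentTemplate:
    """A database chain available as a source of torsion triplets."""

    id: str
    sequence: str
    ss: str
    log_odds: np.ndarray            # (L, 20)
    torsions: np.ndarray            # (L, 3) phi/psi/omega, NaN undefined

    @classmethod
    def from_structure(cls, structure: CGStructure, ss: str,
                       log_odds: Optional[np.ndarray] = None) -> "FragmentTemplate":
        tor = compute_torsions(structure)
        t = np.column_stack([tor.phi, tor.psi, tor.omega])
        if log_odds is None:
            log_odds = np.zeros((len(structure), 20))
        return cls(id=structure.id, sequence=structure.sequence, ss=ss,
                   log_odds=log_odds, torsions=t)


@dataclass
class FragmentCandidate:
    source_id: str
    position: int                   # 0-based start of the template triplet
    torsions: np.ndarray            # (3, 3) phi/psi/omega per residue
    score: float


@dataclass
class FragmentLibrary:
    """Ranked candidate lists per query triplet start position (0-based)."""

    candidates: List[List[FragmentCandidate]]
    n_select: int = N_SELECT

    def __len__(self):
        return len(self.candidates)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (match 1,
    mismatch 0, gap -1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def exclude_homologs(
    templates: Sequence[FragmentTemplate], query_sequence: str,
    threshold: float = HOMOLOG_IDENTITY_THRESHOLD,
) -> List[FragmentTemplate]:
    """Drop templates with identity to the query strictly above the threshold."""
    kept = []
    for t in templates:
        ident = sequence_identity(query_sequence, t.sequence)
        if ident > threshold:
            logger.info("excluding homolog %s (identity %.1f%%)", t.id, 100 * ident)
            continue
        kept.append(t)
    return kept


def score_fragment(
    query: SequenceProfile, query_ss: str, q_pos: int,
    template: FragmentTemplate, t_pos: int,
    ss_weight: float = DEFAULT_SS_WEIGHT,
) -> float:
    """Profile-profile + secondary-structure score of one triplet pair."""
    fq = query.frequencies[q_pos : q_pos + 3]
    pt = template.log_odds[t_pos : t_pos + 3]
    profile_term = float((fq * pt).sum())
    ss_term = sum(
        1.0 for k in range(3) if query_ss[q_pos + k] == template.ss[t_pos + k]
    )
    return profile_term + ss_weight * ss_term


def build_library(
    query: SequenceProfile, query_ss: str,
    templates: Sequence[FragmentTemplate],
    n_select: int = N_SELECT,
    ss_weight: float = DEFAULT_SS_WEIGHT,
) -> FragmentLibrary:
    """Rank all template triplets per query position and keep the top 25.

    Template triplets must have all nine phi/psi/omega values defined, which
    excludes chain-terminal windows. Ties break by (template id, position).
    """
    if not templates:
        raise ValueError("empty template database")
    L = len(query)
    if L < 3:
        raise ValueError("query too short")
    # enumerate usable template triplets once
    pool = []
    for t in templates:
        Lt = len(t.sequence)
        for s in range(Lt - 2):
            win = t.torsions[s : s + 3]
            if np.isnan(win).any():
                continue
            pool.append((t, s))
    per_position: List[List[FragmentCandidate]] = []
    for p in range(L - 2):
        scored = []
        for t, s in pool:
            sc = score_fragment(query, query_ss, p, t, s, ss_weight)
            scored.append((-sc, t.id, s, t))
        scored.sort(key=lambda x: (x[0], x[1], x[2]))
        top = scored[:n_select]
        if len(top) < n_select:
            logger.warning(
                "position %d: only %d candidates available (wanted %d)",
                p, len(top), n_select,
            )
        per_position.append(
            [
                FragmentCandidate(
                    source_id=tid, position=s,
                    torsions=t.torsions[s : s + 3].copy(), score=-neg,
                )
                for neg, tid, s, t in top
            ]
        )
    return FragmentLibrary(candidates=per_position, n_select=n_select)


def save_library(library: FragmentLibrary, path) -> None:
    """Write the library as TSV: position, rank, score, source, 9 torsions."""
    with open(path, "w") as fh:
        fh.write("position\trank\tscore\tsource\tsource_pos\t"
                 "phi1\tpsi1\tomega1\tphi2\tpsi2\tomega2\tphi3\tpsi3\tomega3\n")
        for p, cands in enumerate(library.candidates):
            for r, c in enumerate(cands, start=1):
                tors = "\t".join(repr(float(x)) for x in c.torsions.ravel())
                fh.write(f"{p}\t{r}\t{c.score!r}\t{c.source_id}\t{c.position}\t{tors}\n")


def load_library(path) -> FragmentLibrary:
    per_position: Dict[int, List[FragmentCandidate]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position\t"):
            raise ProfileFormatError(f"{path}: not a fragment-library TSV")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            p = int(parts[0])
            cand = FragmentCandidate(
                source_id=parts[3], position=int(parts[4]),
                torsions=np.array([float(x) for x in parts[5:14]]).reshape(3, 3),
                score=float(parts[2]),
            )
            per_position.setdefault(p, []).append(cand)
    n = max(per_position) + 1 if per_position else 0
    return FragmentLibrary(candidates=[per_position.get(p, []) for p in range(n)])
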