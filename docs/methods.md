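# Methods

## Coarse-grained representation

A protein chain is reduced to the four main-chain heavy atoms per residue —
N, Cα, C, O — plus a pseudo side-chain center of mass (SCM) for the 19
non-glycine amino acids, giving 99 atom types in total (GLY contributes 4,
every other amino acid 5). The SCM is never read from an input structure: it
is reconstructed from backbone geometry alone. During table derivation the
true SCM of each residue is taken as the unweighted centroid of its
side-chain heavy atoms (hydrogens excluded; whether a mass-weighted centroid
was ever intended is unresolved in the source literature, so the unweighted
convention is fixed here and documented). Its internal coordinates — the
Cα–SCM pseudo bond length, the N–Cα–SCM pseudo angle, and a pseudo dihedral —
are accumulated into a 19 × 36 × 36 table indexed by amino acid and by φ/ψ
binned at 10°, and averaged per cell (circular mean for the dihedral, which
can straddle ±180°). Placement inverts the same transformation.

One geometric convention deserves note. A pseudo dihedral written over the
atom order N–C–Cα–SCM (axis C–Cα) is not a consistent Z-matrix partner for
the N–Cα–SCM angle: the two together admit two placement solutions. This
package therefore measures and applies the dihedral about the N–Cα axis with
C as the reference atom, i.e. dihedral(C, N, Cα, SCM), which together with
the stated angle and bond length determines the SCM uniquely and round-trips
exactly (singleton-occupancy cells reproduce their observation to < 1e-6 Å).

Torsions follow the IUPAC sign convention and live in (−180°, 180°]. Binning
is half-open [lo, hi) with exactly +180° assigned to the last bin, so every
defined angle maps to exactly one bin. φ is undefined at the first residue
and ψ/ω at the last; undefined entries are NaN, excluded from all statistics,
and such residues receive no SCM.

Backbone rebuilding from torsions uses fixed ideal geometry (Engh–Huber-style
averages): bonds N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles
N–Cα–C 111.2°, Cα–C–N 116.6°, C–N–Cα 121.7°. The carbonyl O is placed in the
peptide plane along the external bisector of the Cα–C and N(i+1)–C
directions; the last residue uses a virtual next N at ψ = 180°. Any fixed
geometry satisfies the torsion round-trip identity
`compute_torsions(rebuild_backbone(seq, t)) == t` (verified to 1e-6°).

## The four statistical potentials

**Contact term (E_con).** Two atoms of residues with |i−j| ≥ 2 are in
contact when their distance lies in [r_AB, λ·r_AB] (boundaries inclusive),
with λ = 1.9. r_AB is the statistical shortest contact distance of the
atom-type pair: the smallest inter-residue distance strictly above 2.2 Å
(the covalent-exclusion floor) observed in a high-resolution database. Type
pairs the database never exhibits are filled with the *minimum* observed
r_AB. A lower-bound statistic estimated from zero draws should be the most
permissive value available, not a typical one: at small database sizes a
median fill sits near ordinary packing distances and brands every compact
conformation a mass of phantom clashes, which breaks both clash punishment
and the contact shell. With a production-scale database the fill is
essentially never used. Bonded neighbours (|i−j| < 2) are excluded from
counting so the potential cannot reward mere chain connectivity.

**μ-potential form.** Contact and triplet energies share one family,

    E(N, N', μ) = −ln[ μ (N + ½) / ((1 − μ)(N' + ½)) ],

where N counts events, N' counts complementary events, and μ ∈ (0, 1) is a
single global scalar per table chosen so that the observation-weighted net
interaction Σ (N + ½) · E vanishes. The net sum is strictly decreasing in μ,
so bisection finds the unique root (|net| < 1e-6 afterwards; a closed form
exists and serves as an independent oracle in the tests). When events are
rare (N ≪ N', the realistic regime for contacts), the root sits close to 1.
The ½ pseudo-counts keep every energy finite; a pair never observed in
contact gets the large-but-finite value the formula yields at N = 0.

**Local conformation term (E_trp).** Every overlapping three-residue window
contributes the energy of its sequence triplet in the bin of the four
dihedrals (ψ_{i−1}, φ_i, ψ_i, φ_{i+1}), each binned at 30° into 12 bins
(12⁴ bins total). Counts are stored sparsely; N' for a bin is the triplet's
total occurrences minus the bin count. Unseen bins of a seen triplet and
entirely unseen triplets fall out of the same formula at N = 0 (an unseen
triplet scores the constant −ln[μ/(1−μ)]). The net-zero constraint is solved
over the observed (triplet, bin) classes; enumerating all 20³ × 12⁴ empty
classes would drown the statistic in pseudo-counts.

**Solvation term (E_sol).** At Cα resolution, a residue's burial is its
count k of other residues with Cα–Cα distance < 12.5 Å. With N_ak the number
of residues of amino acid a at burial k, E_ak = −ln(N_ak / Ê_ak) with
Ê_ak = N_a·N_k / N_total. Only empty cells are pseudo-counted
(−ln(½/(Ê+½))): this preserves the exact identities that expectation-matched
counts score identically zero and a cell at twice expectation scores −ln 2.
k_max is the largest burial observed; queries beyond it clamp (with a
warning).

**β-geometry term (E_beta).** Candidate strand pairings are pairs of
three-residue fragments with center separation |i−j| ≥ 3 (excluding helical
i,i+2 neighbours). A parallel pairing requires the three index-aligned Cα
distances (i−1↔j−1, i↔j, i+1↔j+1) all below d = 5.6 Å; antiparallel uses the
index-reversed pattern; if both hold, the pattern with the smaller mean
distance is kept, and each unordered pair is counted once. Four features are
computed: α1, α2 — the virtual bond angles at the two centers; γ — the angle
between the two first-leg vectors Cα_{i−1}→Cα_i and Cα_{j−1}→Cα_j; and β —
the angle between the in-plane vectors P_i and P_j, where P_k points from
the midpoint of Cα_{k−1}, Cα_{k+1} to Cα_k. This P construction is a
package convention: it lies in the fragment plane, is symmetric in the
flanking residues, and is undefined exactly when the fragment is collinear
(such pairs are skipped with a warning). Features are binned 4 × 4 × 6 × 6
(α bins 0–90, 90–120, 120–150, 150–180; β/γ six 30° bins over 0–180) and
E_bin = −ln(N_bin / N̄) with N̄ the global mean count over the 576 bins;
uniform occupancy scores identically zero, and empty bins are pseudo-counted
as in the solvation table.

## Combined score, decoy metrics, weights

E_tot = E_con + a·E_trp + b·E_sol + c·E_beta, plus w_clash·N_clash in
assembly mode, where N_clash counts all atom pairs (backbone + SCM, |i−j| ≥ 2)
closer than their r_AB. The combination is exactly linear in the weights.
Defaults are a = b = c = 1 and w_clash = 1; the published optimum for these
weights is not recoverable from available sources, so the defaults are
deliberately neutral and `optimize_weights` re-fits them on any decoy
collection by deterministic grid search minimizing mean normalized native
rank plus mean native Z-score (ties broken by lower Z, then lexicographic
weights).

Decoy discrimination reports the native rank Rn (1 + number of decoys with
strictly lower energy; the native wins ties) and the Z-score
(E_native − mean E_decoys)/σ(E_decoys) with the population (n-denominator)
standard deviation and the native excluded from mean and σ. Zero spread
flags the Z-score as undefined rather than raising.

## Fragment library

Query inputs are a PSIPRED `.ss2` file and a PSI-BLAST ASCII PSSM (the
frequency columns, renormalized after a 1e-6 pseudo-count, give F_query; the
log-odds columns give P_template for templates). Template secondary
structure comes from DSSP output mapped H/G/I→H, E→E, else C. Templates with
global-alignment identity to the query strictly above 30% are excluded
(alignment: match 1, mismatch 0, gap −1; identity = matches / alignment
length). Each query triplet is scored against every template triplet whose
nine φ/ψ/ω values are all defined:

    score = Σ_{i=1..3} Σ_{j=1..20} F_query(i,j) · P_template(i,j)
            + w_ss · #{i : q_i = t_i},

with w_ss = 1 by default (the secondary-structure bonus is exposed rather
than hard-coded because its published normalization is not recoverable). The
top 25 per position are kept, ties broken by (template id, position) for
bit-reproducibility; a shorter candidate list is kept whole with a warning.

## Folding protocol

Step 1 initializes an extended chain (all torsions 180°). Step 2 randomizes
every triplet from the library, N- to C-terminus; when the contact tables
are available the draw is retried (up to 50 times) until the backbone clash
bound below is met, so annealing never starts from a state it could not
itself accept. Step 3 runs simulated annealing: at each of n_steps (35,000
by default; desk-scale runs use hundreds) a random triplet position and a
random candidate are drawn, the chain is rebuilt, SCMs re-placed, and the
full score recomputed. Moves with ΔE < 0 are always accepted; uphill moves
with probability exp(−ΔE/(k·T·factor)), where T falls linearly from 2000 to
300 over the run and k (default 0.002) is a single calibration constant
scaling the temperature to the typical per-move |ΔE| on fixture-scale
energies — it is exposed in `AnnealConfig` and should be re-calibrated if
the tables change scale. A proposal whose backbone–backbone clash count
exceeds L/3 is rejected outright. After more than 200 consecutive rejections
the escape factor grows as 1 + (Nr − 200)/divisor and the run stops early
once it passes the run's stop threshold; the three protocol iterations use
(divisor, stop) = (80, 11), (160, 6), (320, 3.5), read uniformly as
exceed-threshold semantics. The E_beta weight is multiplied by
|sin(π·Tn/1000)|: zero at the start of each 1000-step period, maximal at
step 500 — sheets are encouraged, released, and re-encouraged periodically.
The best structure of a run is the minimum over visited states of the
reference energy (clash term on, β multiplier 1).

The full protocol runs three iterations: run 1 folds n₁ independent
randomized starts (1000 at production scale), clusters them, and keeps the
top-5 cluster centroids; runs 2 and 3 respawn n₂ trajectories (200 at
production scale) from each centroid with the gentler escape factors,
recluster, and the final model is the lowest-energy member of the third
run's top 5. All counts and step numbers are configuration, so desk-scale
smoke tests use (n₁, n₂, steps) in the tens-to-hundreds.

Model similarity uses the TM-score with d0 = 1.24·(L−15)^⅓ − 1.8 (floored at
0.5), computed by iterative superposition: seed windows of lengths L, L/2,
L/4 at every start, Kabsch superposition on the seed, then repeated
re-selection of residues within d0 and re-superposition, keeping the best
score over all seeds. Clustering is centroid-based: the model with the most
neighbours at or above the cutoff seeds a cluster, its members are removed,
and the process repeats; the cutoff starts at 0.7 and adapts in 0.05 steps
within [0.3, 0.9] until the biggest cluster holds 20–70% of the models,
accepting with a warning at a bound (an ensemble of near-identical models
legitimately pins the cutoff at 0.9 with one 100% cluster).

## Synthetic data

The fixture generators supply every input: micro structure databases
(ideal-to-perturbed helices, two-strand sheet scaffolds at 4.8 Å spacing,
Ramachandran-basin coils) with single pseudo-Cβ side-chain beads placed at
ideal geometry (bond 1.53 Å, angle 110.5°, dihedral −122.6°), fragment-
replacement decoy sets annotated with Cα-RMSD and TM-score to their native,
and dialect-valid `.ss2`/PSSM/DSSP files whose noise-0 content encodes the
input sequence and secondary structure exactly. Every generator is a pure
function of its parameters and seed.

Fixture chains draw from a reduced five-letter amino-acid alphabet (A, C, D,
E, F). The shortest-contact statistic is estimated per atom-type pair, and
with 20 letters a micro database sees most of the ~5000 pair minima only
once or twice, so the estimate sits near a typical distance rather than a
floor and every compact structure appears clash-ridden. Five letters keep
each pair densely sampled at a few hundred residues total while still
exercising amino-acid-specific tables. Consequences a user should keep in
mind: fixture-derived μ values sit near 0.3–0.6 rather than the ≈0.99 of
production-scale databases (contacts are not rare in tiny, compact
fixtures), and SCM tables cover only the fixture alphabet — scoring a
sequence outside it requires a table derived from a database containing
those amino acids. Sheet fixtures are geometric scaffolds: strands are
rigidly placed and joined by interpolated loops, so their inter-strand Cα
geometry is exact but their loop backbone is not physical. Passing tests on
these fixtures demonstrate correctness of the counting, normalization,
geometry, and optimization machinery — not biological accuracy of the
derived tables, which is a property of the input database.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk scale: a
16-structure database (~190 residues), 40-decoy discrimination sets, a
200-decoy energy/RMSD correlation, and ten 800-step annealing runs on a
20-residue helix target whose library mixes the target's own fragments with
random distractors. Brute-force oracles (exhaustive pair enumeration, grid
scans for μ, seed-window TM-score search) verify every statistic on ≤
8-residue toys. Tolerances: torsion round trips 1e-6°, SCM round trips
1e-6 Å, rigid-motion invariance 1e-9, net-interaction zero 1e-6. Boundary
conventions: contact shell inclusive at both ends; clash strictly below
r_AB; +180° in the last bin everywhere.

## Known limitations

Orientation-dependent interactions (explicit hydrogen-bond geometry) are
deliberately out of scope; the β term is their coarse, smoother stand-in.
Multi-chain complexes, insertion codes, and altlocs beyond 'A' are not
handled. The SCM model assumes side-chain conformation is determined by
backbone φ/ψ, which is an average-case statement only. Default weights
(a = b = c = 1) are neutral placeholders pending re-optimization on a real
decoy corpus. The annealing energy is fully recomputed per move; at
35,000 steps × 1000 trajectories on real targets an incremental-update
scheme would be the first optimization to add.
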