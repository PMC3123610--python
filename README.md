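# ncaco

A coarse-grained, knowledge-based scoring function for protein structures
that needs nothing beyond the main-chain atoms — N, Cα, C, O — of a model,
together with the full pipeline around it: deriving the statistical tables
from a structure database, discriminating native structures from decoys, and
de novo folding by fragment assembly under simulated annealing.

It is aimed at structural bioinformatics work where side chains are absent,
unreliable, or deliberately ignored: scoring backbone-only models, ranking
decoy sets, and quick exploratory folding of small targets.

## The score

A pseudo side-chain center of mass (SCM) is first rebuilt for every
non-glycine residue from a statistical table indexed by amino acid and
(φ, ψ), giving a five-bead residue model and 99 atom types. Four terms are
then combined linearly,

    E_tot = E_con + a·E_trp + b·E_sol + c·E_beta  (+ w·N_clash in assembly),

* **E_con** — pairwise atom–atom contacts. Atoms A, B are in contact when
  r_AB ≤ d ≤ λ·r_AB (λ = 1.9), with r_AB the statistical shortest contact
  distance (> 2.2 Å) of the type pair. Energies take the μ-potential form
  E = −ln[μN/((1−μ)N′)] with one global μ fixed by the condition that the
  database-wide net interaction is zero.
* **E_trp** — sequence-dependent local conformation of residue triplets over
  the four dihedrals (ψ_{i−1}, φ_i, ψ_i, φ_{i+1}), 12 bins of 30° each, same
  μ-potential form.
* **E_sol** — residue burial: E_ak = −ln(N_ak/Ê_ak), where k counts other
  residues with Cα–Cα < 12.5 Å and Ê_ak = N_a·N_k/N_total.
* **E_beta** — a Cα-level strand-pairing propensity: paired three-residue
  fragments (three inter-strand Cα distances < 5.6 Å, parallel or
  antiparallel pattern) are binned by four virtual angles (α1, α2, β, γ)
  into 4×4×6×6 bins, E = −ln(N_bin/N̄).

Decoy discrimination is reported as the native rank Rn and the Z-score
(E_native − ⟨E_decoy⟩)/σ(E_decoy). Folding replaces random triplet torsions
from a 25-per-position fragment-template library under a 2000 K → 300 K
annealing schedule with clash punishment and a periodically oscillating
β-weight, then selects models by TM-score centroid clustering over three
iterations. See `docs/methods.md` for every formula, convention, and default.

## Worked example

Everything below runs offline; the `make-fixtures` command generates a
synthetic micro database (PDB + `.ss2` + PSSM + DSSP files) in place of a
curated structure set.

```
$ ncaco make-fixtures --seed 3 --out fixdb
wrote 20 fixture structures to fixdb

$ ncaco derive-tables --db fixdb --out tables.ncaco
wrote tables.ncaco (mu_contact=0.636675, mu_triplet=0.603757)

$ ncaco score --tables tables.ncaco --pdb fixdb/helix_0.pdb
{
  "E_con": 70.94530246626968,
  "E_trp": 9.32216782331042,
  "E_sol": -0.5998717340797004,
  "E_beta": -29.000280155149596,
  "E_clash": 0.0,
  "E_tot": 50.66731840035081
}
```

The μ values printed by `derive-tables` are the net-zero normalizers of the
contact and triplet potentials (on production-scale databases, where
contacts are rare events, they sit near 0.99; on a 20-structure fixture set
contacts are common and μ lands near 0.6). In the score output, the negative
`E_beta` reflects the helix's favourable i,i+3 Cα geometry under the
fixture-derived propensity table; `E_clash` is 0 because the model has no
atom pair closer than its statistical minimum distance.

Folding a target from a fragment library:

```
$ ncaco build-frags --ss2 q.ss2 --pssm q.pssm --template-db fixdb --out frags.tsv
$ ncaco fold --tables tables.ncaco --frags frags.tsv --seq target.fasta \
        --models 20 --models-per-seed 5 --steps 2000 --seed 1 --out folded/
```

writes `best.pdb`, the top-5 cluster centroids, an energy TSV, and a
cluster-size report.

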