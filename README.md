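# lssr

Local structural similarity restraints (LSSR): plateauing penalties on the
differences between equivalent short-range interatomic distances, for
exploiting noncrystallographic symmetry (NCS) within a structure or
similarity to a fixed, previously determined target structure.

Given a restraint between atom pair (i, j) and its equivalent pair
(i′, j′), with `Δ = |r(i,j) − r(i′,j′)|`, the penalty is

```
V(Δ) = V_max · (1 − exp(−α·Δ²/σ²)),    α = ln(V_max / (V_max − 1))
```

which is close to harmonic below σ, equals 1.0 at Δ = σ, and is essentially
flat above 0.7 Å (defaults σ = 0.2 Å, V_max = 3), so genuine structural
differences carry a fixed, bounded cost. Restraints are set up for all
nonbonded and 1–4 atom pairs closer than 5.5 Å in either copy.

The package provides:

- **`lssr.structure`** — chain/residue/atom coordinate model; PDB and mmCIF
  reading (via Biopython), PDB writing, selection policies (waters and
  hydrogens removed, hetero groups kept, altloc handling).
- **`lssr.equivalence`** — automatic NCS chain-group detection (chains are
  related when more than 80% of residues with matching numbers share a
  residue name), atom matching by name/number, target-structure matching,
  and equivalent side-chain atom swapping (ASP/GLU/PHE/TYR/ARG; "plus" mode
  adds HIS/ASN/GLN quasi-symmetric flips).
- **`lssr.core`** — restraint enumeration (KD-tree candidate search, covalent
  1–2/1–3 exclusion), penalty/gradient evaluation, multi-copy weight
  adjustment `W/(N_chains − 1)`, TSV/JSON restraint-list serialization.
- **`lssr.pruning`** — plateau-ratio rule (residues whose summed penalty
  exceeds half the all-plateau maximum are dropped from the lists) and the
  optional relative gradient rule.
- **`lssr.analysis`** — pooled Δ histograms and per-atom contact comparison
  tables.
- **`lssr.fixtures`** — deterministic synthetic NCS fixtures, a toy
  restrained gradient-descent minimizer, and a finite-difference gradient
  oracle.
- **`lssr.cli`** — the `lssr` command.

## Command line

```sh
# generate a two-copy synthetic structure with a flipped PHE side chain
lssr fixture --residues 10 --chains 2 --noise-sd 0.05 --flip 3 --out demo.pdb

# full workflow: detect NCS, swap equivalent atoms, enumerate, prune, analyze
lssr build demo.pdb --mode autoncs --swap standard --out-dir demo_out

# restrain to a fixed target structure instead of internal NCS
lssr build refined.pdb --mode target --target high_res.pdb --out-dir out

# diagnostics
lssr analyze demo.pdb --out hist.tsv --plot hist.png
lssr report demo.pdb --chains A B --focus 2/OG
lssr minimize demo.pdb --steps 200 --out minimized.pdb
lssr check-gradients --seeds 5
```

`build` writes `restraints.tsv`/`.json`, `prune_report.*`, `swap_report.json`,
`delta_histogram.tsv`, `summary.txt`, `manifest.json` and a log. Exit status
3 means no NCS was detected in autoncs mode; 4 means the target structure did
not match.

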