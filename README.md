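# nmrscore

NMR-guided assessment of protein–protein complex models: chemical-shift-
perturbation (CSP) analysis of titration data, interface extraction from 3D
complex structures, coverage/error scoring of candidate models against
NMR-perturbed residue sets, interface features (buried area, polar vs
nonpolar contacts), and trajectory stability analysis (contact frequencies,
hydrogen bonds, receptor-aligned ligand RMSD, hierarchical clustering with
representative-structure selection).

## Layout

| module | what it does |
|---|---|
| `nmrscore.structio` | PDB/mmCIF reading, PDB writing, atom selection, Kabsch superposition, residue renumbering |
| `nmrscore.cspkit` | shift-table I/O (TSV + NMR-STAR subset), CSP = √(ΔδH² + (ΔδN/10)²), broadening detection, significance thresholds, perturbed sets, NOE restraint categorisation, mono-exponential relaxation fits, hetNOE |
| `nmrscore.interface` | interface residues at a 5 Å any-atom cutoff (hydrogens included), contact pairs with polarity, Shrake–Rupley SASA, buried area |
| `nmrscore.modelscore` | coverage C% / error E% (exact rationals, C+E = 100), C/E-ratio ranking, mutation concordance |
| `nmrscore.trajanalysis` | contact-frequency maps, H-bonds (3 Å donor–acceptor, ≤20° deviation from linearity), ligand RMSD series, frame clustering |
| `nmrscore.synthgen` | deterministic synthetic complexes, titrations, trajectories and decay curves with known ground truth |
| `nmrscore.benchmarks` | helpers for comparisons against deposited structures (local files only) |
| `nmrscore.cli` | `nmrscore` command-line entry point |

## CLI

```sh
nmrscore simulate complex --seed 7 -o out/            # synthetic fixture
nmrscore csp --apo apo.tsv --holo holo.tsv -o csp.json
nmrscore perturbed --csp csp.json --method trimmed_sd -o inmr.json
nmrscore interface --model m.pdb --chains-a A --chains-b B -o iface.tsv
nmrscore score --model m.pdb --perturbed-a a.json --perturbed-b b.json -o card.json
nmrscore rank card1.json card2.json -o ranked.json
nmrscore contacts --traj traj.pdb --chains-a A --chains-b B -o freq.tsv
nmrscore hbonds --traj traj.pdb --chains-a A --chains-b B -o hb.tsv
nmrscore rmsd --traj traj.pdb --receptor "chain A and backbone" \
         --ligand "chain B and backbone" --exclude 1-10 -o rmsd.tsv
nmrscore cluster --traj traj.pdb --selection "chain B" --align "chain A" -o clusters.json
```

Selection grammar: clauses joined by `and` — `chain A`, `resi 11-90`,
`name CA CB`, `backbone`, `heavy`, `hydrogen`, `all`.  Exit codes: 0 ok,
1 usage error, 2 data error.  Every command writes a `*.prov.json`
provenance block (inputs with SHA-256, parameters, seed, version).

Shift-table schema (TSV): columns `residue`, `res_type`, `dH`, `dN`,
optional `intensity`, `assigned`.

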