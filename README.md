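# consrank

Consensus contact-based scoring of protein–protein docking decoys.

## The problem

Docking programs produce large ensembles of candidate structures
("decoys") for a protein–protein complex, and picking the correct poses
out of a pool of mostly wrong ones — the *scoring* problem — remains an
open challenge. This package implements a pure consensus approach: no
physical energies, no statistical potentials. Models are ranked by how
well their intermolecular contacts match the contacts most frequently
realized across the whole ensemble, on the premise that independent
predictors converge on the correct interface far more often than on any
particular wrong one.

It is aimed at structural bioinformaticians who need to rank a directory
of multi-chain PDB models of the same complex — e.g. a blind-docking
scoring set — and submit or shortlist a small number of them.

## The method

For an ensemble of *n* consistently renumbered models, every
intermolecular residue contact (*k*, *l*) (any heavy-atom pair closer
than 5 Å across chains) has a conservation rate

```
CR_kl = (# models containing the contact) / n          (1/n ≤ CR_kl ≤ 1)
```

A model *i* with *M_i* contacts scores

```
S_i  = Σ CR_kl   over its contacts,        S̄_i = S_i / M_i
```

and models are ranked by the normalized score S̄. The score of the
top-ranked model — the **Maxscore** — measures how sharp the ensemble
consensus is, and is used as an a-priori reliability signal: when it
falls below ≈0.1 the consensus cannot be trusted.

Around this core the package assembles the full scoring workflow:

1. **Filter & renumber** (`model_io`): discard empty / single-chain /
   sequence-mismatched (identity < 90% or target coverage < 70%) /
   zero-contact models, and renumber every chain against the target
   sequences so contacts are comparable across models.
2. **Consensus ranking** (`scoring`): conservation rates, scores,
   ranking, consensus contact-map export.
3. **Contact-fingerprint clustering** (`clustering`): complete-linkage
   hierarchical clustering on pairwise Hamming distances between contact
   maps, cut with the maxclust rule at *t* = *n*/10 clusters; clusters
   numbered 0, 1, … by population; consensus re-scored inside each of the
   top 15 clusters.
4. **Interface analysis** (`interface`): contact count, buried
   solvent-accessible interface area (Shrake–Rupley, probe 1.4 Å), and
   steric clash count (heavy-atom pairs < 3 Å across chains).
5. **Selection** (`pipeline`): a candidate pool of the consensus top 30
   plus the top 2 of each top-15 cluster; models with more than 25
   clashes excluded; if Maxscore ≥ 0.1 all 10 submissions come from the
   consensus ranking, otherwise 1 consensus pick plus 9 picks spread over
   distinct clusters; final order by interface extent (contacts, then
   buried area, then score).

Two support modules make the pipeline testable end to end without any
external data: `synth` generates labeled decoy ensembles (near-native
jitters, random touching poses, optional alternative-monomer and
clash-injected decoys around an idealized helical-hairpin homodimer),
and `assess` classifies models against a reference with the standard
CAPRI measures (f(nat), ligand RMSD, interface RMSD → high / medium /
acceptable / incorrect).

## Worked example

```bash
# make a synthetic scoring set: 100 decoys, 30% near-native
consrank synth --n-models 100 --planted-fraction 0.3 --seed 1 --out decoys/

# score it
consrank score decoys/ --target decoys/target.fasta --out scored/
```

The score command logs the filtering and consensus summary and prints
the final selection:

```
INFO scoring 100 models against 2 target chains
INFO kept 100/100 models; Maxscore 0.319 (strong-consensus)
position  model_id    n_contacts  interface_area  n_clashes  S_norm    sources
1         decoy_0036  37          483.8           18         0.218378  consrank:30
2         decoy_0054  32          470.9           9          0.246250  consrank:29
3         decoy_0033  32          452.9           10         0.247500  consrank:27
4         decoy_0068  32          448.1           8          0.247500  consrank:28
5         decoy_0000  28          432.5           5          0.265714  consrank:25
...
```

Maxscore 0.319 means the contacts of the top-ranked model are conserved
in ≈32% of the ensemble — a sharp consensus, so the whole submission is
drawn from the consensus ranking (`strong-consensus`), then re-ordered
by interface extent: position 1 is the pooled model with the most
contacts and the largest buried area, not necessarily consensus rank 1.
`scored/` contains every intermediate table (filter report, ranking,
consensus matrix, cluster assignments, interface table, selection) plus
a JSON run manifest. With ground truth available the selection can be
checked:

```bash
consrank assess decoys/ --native reference.pdb     # fnat, L-rms, I-rms, class
```

## Library use

```python
import consrank as cr

spec = cr.SyntheticSpec(n_models=100, planted_fraction=0.3, seed=1)
models, truth = cr.generate_ensemble(spec)
result = cr.run_pipeline(models, cr.target_spec(spec))
print(result.ranking.maxscore, result.selection.regime)
for cand in result.selection.selected:
    print(cand.model_id, cand.report.n_contacts, cand.report.interface_area)
```

See `docs/methods.md` for the model, parameter and design details.
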