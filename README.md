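# substispace

Tools for navigating the bioisosteric space of organic substituents.

Medicinal chemists optimising a lead compound routinely swap one substituent
for another that is similar in size and physicochemical profile
(*bioisosteric replacement*), or deliberately pick substituents with very
different properties to span a design space.  The classic instrument for
both tasks is the **Craig plot**: a scatter of substituents with the
Hansch–Fujita hydrophobicity parameter **π** on one axis and the Hammett
electronic constant **σ** on the other.  Nearby points are bioisosteric
candidates; different quadrants give diversity.

`substispace` builds everything needed for that workflow from a plain
molecule table:

1. **Extraction** — every chemically activated single bond of each molecule
   is cut (ring–nonring bonds, carbon–heteroatom bonds, bonds adjacent to
   multiple bonds); fragments with up to 12 heavy atoms become
   attachment-marked substituents (`[*]` marks the cut), aggregated with two
   frequencies: distinct-molecule frequency and raw occurrence count.
2. **Classification** — substituents are clustered by their root atom
   (`R–C`, `R–c`, `R–N`, …, lowercase = aromatic, `R–X` = halogens) and by
   the second shell (`R–C(=O)–N`, `R–c(:n):c`, …), and each carries an
   attachment profile: how often it hangs off an aliphatic carbon, aromatic
   carbon, nitrogen, carbonyl carbon, etc.
3. **Properties** — π is computed as logP(mono-substituted benzene) −
   logP(benzene) with Wildman–Crippen atom contributions, so π(H) ≡ 0.
   The electronic parameter is a σ-para-compatible value: partial charges
   (PEOE σ charges plus self-consistent ω-Hückel π charges) of the
   substituted-benzene probe are read at the ring position para to the
   substituent, and an ordinary least-squares line calibrates this charge
   descriptor onto the experimental σ-para scale.
4. **Navigation** — filtering by root class, attachment point, size,
   frequency and (π, σ) windows; k-nearest-neighbour bioisostere search;
   max-min diverse selection; Craig-plot rendering with a machine-readable
   sidecar table.

A seeded synthetic-corpus generator (`substispace.fixtures`) emulates the
long-tail substituent frequency structure of real bioactivity databases so
the entire pipeline is testable offline.

## Worked example

```python
import substispace as ss

model = ss.default_calibration()          # packaged textbook sigma-para table
print(f"calibration: slope={model.slope:.2f} intercept={model.intercept:.3f} "
      f"r^2={model.r_squared:.2f} (n={model.n_train})")
for name, smi in [("CF3", "[*]C(F)(F)F"), ("OMe", "[*]OC"), ("NMe2", "[*]N(C)C")]:
    pi, sigma = ss.compute_pi(smi), ss.compute_sigma(smi, model)
    q = ss.quadrant_of(ss.PropertyVector(pi, sigma))
    print(f"{name:5s} pi={pi:+.2f}  sigma={sigma:+.2f}  quadrant={q}")

corpus = ss.generate_corpus(ss.CorpusConfig(seed=7, n_molecules=500))
catalog = ss.fragment_corpus(corpus.records, min_molecule_freq=5)
print(f"{catalog.corpus_size} molecules -> {len(catalog)} unique substituents, "
      f"{len(catalog.common())} common (>=5 molecules)")
ss.annotate_catalog(catalog, model)
target = catalog.get(ss.fragment_from_smiles("[*]Cl").canonical_form)
for e, d in ss.nearest_bioisosteres(catalog, target, k=3):
    print(f"  neighbour of Cl: {e.smiles:12s} d={d:.3f} "
          f"(pi={e.properties.pi:+.2f}, sigma={e.properties.sigma:+.2f})")
```

prints

```
calibration: slope=27.37 intercept=0.090 r^2=0.78 (n=26)
CF3   pi=+1.02  sigma=+0.22  quadrant=π+σ+
OMe   pi=+0.01  sigma=-0.29  quadrant=π+σ−
NMe2  pi=+0.07  sigma=-0.61  quadrant=π+σ−
500 molecules -> 591 unique substituents, 54 common (>=5 molecules)
  neighbour of Cl: *c1cncc(O)c1    d=0.116 (pi=+0.77, sigma=+0.15)
  neighbour of Cl: *c1ncc(OC)c(C)n1 d=0.131 (pi=+0.77, sigma=+0.16)
  neighbour of Cl: *c1c(F)ncnc1NC  d=0.135 (pi=+0.64, sigma=+0.12)
```

The trifluoromethyl group lands in the hydrophobic/electron-withdrawing
quadrant, methoxy and dimethylamino among the donors, and the nearest
neighbours of chloro on this synthetic catalog are small electron-poor
aromatics with similar hydrophobicity — exactly the reading a chemist makes
on a Craig plot.  Distances are Euclidean in per-axis standardized (π, σ).

The same pipeline is available from the shell:

```bash
substispace fixtures --seed 7 --n 500 --out fixture.smi --manifest manifest.tsv
substispace extract  --in fixture.smi --max-atoms 12 --min-freq 5 --out catalog.tsv
substispace annotate --catalog catalog.tsv --out annotated.tsv
substispace classify --catalog annotated.tsv --out table.tsv
substispace stats    --catalog annotated.tsv --corpus-size 500
substispace query    --catalog annotated.tsv --root R–O --max-atoms 8 --out hits.tsv
substispace plot     --catalog annotated.tsv --out craig.svg
```

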