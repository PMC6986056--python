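# Methods

This note documents the models behind `substispace`, the parameters that
matter, the numerical choices, and what the synthetic test corpora do and
do not show about real data.

## Substituent extraction

A substituent is a fragment connected to the rest of a molecule through one
single bond.  The extractor visits every bond of a sanitized molecule and
cuts it when it is *chemically activated*:

* acyclic single bond, both endpoints heavy atoms, and
* (a) one endpoint in a ring and the other not, or
* (b) one endpoint carbon and the other a heteroatom, or
* (c) either endpoint carries a double or triple bond to a third atom
  (carbonyl, nitrile, vinyl, azo neighbourhoods).

Ring bonds and multiple bonds are never cut.  Aromatic bonds do not count
as "multiple" for rule (c); aromatic attachment enters through rule (a).
Cuts are made one at a time; both fragments of a cut are candidate
substituents, and each side is kept when its heavy-atom count is within the
cap (default **12**, the conventional upper bound for a "substituent" as
opposed to a scaffold).  Each kept occurrence records the atom on the other
side of the cut — element, aromaticity, and whether it is a carbonyl carbon
— as its attachment context.

Two historically ambiguous bond families sit behind `BondRules` switches,
both off by default: bonds whose endpoints are both heteroatoms (e.g. N–N),
and acyclic ring–ring linkages (biaryls).  With the defaults, a phenyl
planted directly on an aromatic scaffold is *not* recovered — the biaryl
bond matches none of the three rules.  This is the one systematic loss the
recovery statistics show.

Frequencies are counted two ways, because they answer different questions:
`molecule_frequency` counts distinct molecules (the "present in ≥ N
molecules" threshold for a *common* substituent uses this; default
N = 50), while `occurrence_count` counts every cut and is the weighting
used for corpus-level classification tables.

Canonical identity of a fragment is its RDKit canonical SMILES with a
single dummy atom (`[*]`) at the attachment point; the RDKit default
aromaticity model is fixed for the whole pipeline.  Stereo markers are
preserved but not normalized, so stereoisomeric fragments stay distinct.
Salts are reduced to the largest covalent component at parse time; charged
substituents are kept as-is by default (a `neutralize` option exists for
simple protonation states).

## Classification grammar

Level 1 is the root atom: `R–C`, `R–c`, `R–N`, `R–n`, `R–O`, `R–S`, with
halogens pooled as `R–X` and lowercase meaning aromatic.  Level 2 appends
the root's heavy neighbours: double-bonded oxygens inline first
(`R–C(=O)–N`), remaining neighbours ordered by the fixed precedence
C < c < N < n < O < S < X, all but the last parenthesized with their bond
annotation (`–` single, `:` aromatic, `=` double, `#` triple).  One
rendering override reproduces the printed convention of classification
tables for the mixed aromatic ortho pair, which is written `(:n):c` rather
than `(:c):n`.  A depth-3 renderer extends unambiguous linear chains
(`R–C–C–O`); depth 2 is the class key everywhere else.

Attachment categories pool aromatic and aliphatic nitrogen (`N,n`) and all
halogens (`X`), and give the carbonyl carbon (`C(=O)*`) precedence over the
plain carbon categories, mirroring the way attachment tables are printed.
Aromatic oxygen is merged into `O` (no separate `o` category).

## The π model

π is the Hansch–Fujita substituent hydrophobicity: the difference between
the octanol–water logP of the substituted parent and the parent itself.
The parent scaffold is benzene for every substituent — the same probe used
for the electronic parameter and the aromatic context of the classic π
scale.  logP is the Wildman–Crippen atom-contribution sum (RDKit
implementation), so π is deterministic, exactly additive, and π(H) = 0 by
construction (the probe *is* benzene).  On the packaged table of 26
experimental π values the computed values correlate with r² ≈ 0.90
(recomputed, not asserted, by `scripts/acceptance.py`).

## The electronic (σ-compatible) parameter

Experimental Hammett constants exist for only a minority of substituents,
so the pipeline computes a surrogate from partial atomic charges of the
substituted-benzene probe.  The total charge of an atom is a sum of two
parts:

* **σ charges** from partial equalization of orbital electronegativity
  (PEOE / Gasteiger–Marsili, 50 damped iterations, RDKit implementation),
  with each heavy atom's value taken together with its attached hydrogens;
* **π charges** from a Hückel treatment of the conjugated system.  π
  centres are aromatic atoms, atoms in double/triple bonds, lone-pair
  donors single-bonded to such atoms (N, O, S, halogens), and plain alkyl
  carbons bonded to a π-system carbon, treated as 2-electron
  pseudo-heteroatoms (the standard hyperconjugation model).  Coulomb
  integrals α + hβ and resonance integrals kβ use conventional heteroatom
  parameters (e.g. pyridine N h = 0.5; amine N h = 1.5, k = 0.8; ether O
  h = 2.0, k = 0.8; carbonyl O h = 1.0, k = 1.0; halogens h = 3.0…1.3
  with weak k = 0.6…0.15; alkyl pseudo-atom h = 2.0, k = 0.45; formal
  charge shifts h by ±1).  The halogen and alkyl resonance factors were
  fixed, within the ranges quoted in the Hückel literature, so that the
  model reproduces the textbook donor/acceptor ordering
  NO₂ > CN > Cl > H > CH₃ > OCH₃ > NMe₂ — a deliberate calibration of the
  default parameter set against qualitative chemistry, not against any
  held-out data.
* the **ω-technique** couples the two: every π centre's Coulomb integral is
  shifted by ω·q (ω = 1.4) with q its current total (σ+π) charge, and the
  π charges are iterated to self-consistency (mixing 0.5, tolerance 1e-6
  on max |Δq|, cap 200 iterations; non-convergence raises with
  diagnostics).  This coupling is what transmits inductive polarization
  into the ring — a σ-only charge model places the resonance donors
  OCH₃/NMe₂ on the wrong side of hydrogen, because their inductive effect
  at the para position is withdrawing.

The raw descriptor is the total charge on the **para** ring carbon plus its
hydrogen, minus the same sum in benzene.  Electron-withdrawing substituents
leave the para position electron-poor, so the descriptor is positive for
acceptors and exactly zero for hydrogen.  The para position (not meta) is
used because the para scale has the larger span and separates substituents
better.

The descriptor lives on an arbitrary charge scale, so an ordinary
least-squares line maps it onto experimental σ-para values.  The package
ships a 26-entry table of textbook constants for the classic benzene
substituents; users can supply their own larger compilations.  The fit
reports slope, intercept, r² and standard errors; on the packaged table
r² ≈ 0.78, with perfluorinated groups (OCF₃, CF₃) and thiomethyl the worst
outliers — their field/inductive effects are under-represented by a
para-charge descriptor.  This surrogate is the package's own construction;
it is *compatible with* the σ-para scale by calibration, and the package
makes no claim that it reproduces any particular published charge scheme.

## Navigator semantics

Nearest-neighbour and diversity searches need a metric, which a visual
plot does not: distances are Euclidean in per-axis standardized (π, σ)
(each axis divided by the catalog standard deviation), making the wide π
axis (span ≈ 6 log units) commensurate with σ (span ≈ 2).  `scaling="raw"`
disables this.  Ties break by descending molecule frequency (favouring
common, synthetically accessible groups) then canonical form.

`diverse_selection` maximizes the minimum pairwise distance, always
anchored at the most frequent substituent.  Instances small enough to
enumerate (≤ 5000 candidate selections) are solved exactly; larger ones use
the classic greedy farthest-point heuristic.  Quadrants are assigned by
sign, with exact zeros reported as `boundary` rather than silently binned.

The Craig plot is rendered with π horizontal, σ vertical, origin
cross-hairs, point area monotone (log-scaled) in molecule frequency, and
axis limits covering the data with a 5% margin.  Every rendered figure is
accompanied by a sidecar TSV of the plotted points — the machine-readable
contract for any downstream interactive UI.

## Synthetic corpora

`fixtures.generate_corpus` emulates the statistical shape of substituent
collections extracted from bioactivity databases: a pool of substituents
(36 classic medicinal-chemistry groups, combinatorially extended with
seeded chain fragments when a larger pool is requested) is sampled with
Zipf weights ∝ rank^(−s) (default s = 2, a long-tail exponent typical of
such frequency distributions) and planted at random open positions of
aromatic scaffolds (benzene, pyridine, pyrimidine, naphthalene, thiophene;
1–3 decorations per molecule).  A manifest records every planting, and a
pseudo-activity column makes ~80% of molecules "bioactive" (flag only; no
dose–response structure).  Default problem sizes — 120–500 molecules in the
test suite, 2000 in the acceptance script — were chosen as the smallest
corpora on which the long-tail statistics stabilize.

What the fixtures do **not** emulate: realistic scaffold diversity,
aliphatic attachment points (all plantings are on aromatic carbons),
correlations between substituents and activity, stereochemistry, and
counter-ions.  Passing tests therefore demonstrate the correctness of the
extraction/counting/property machinery, not that any particular published
corpus-level percentage will be reproduced — those depend on the underlying
database release.  Extraction recovery against the manifest is ≈ 99.9%;
the shortfall is exactly the biaryl case described above.

## Known limitations

* Biaryl and heteroatom–heteroatom bonds are not cut by default (switches
  exist); consequently aryl-on-aryl substituents are invisible to the
  default rules.
* The charge descriptor reads a single ring position; purely field-effect
  acceptors (CF₃, SO₂R at distance) are systematically underestimated.
* Crippen logP inherits the known biases of atom-contribution schemes for
  strongly hydrogen-bonding groups.
* Probes assume the substituent can bond to an aromatic carbon; fragments
  whose attachment valence cannot (rare) are left unannotated and are
  skipped by property-space queries.
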