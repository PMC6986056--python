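"""Seeded synthetic molecule corpora with a long-tail substituent structure.

Real substituent collections come from fragmenting large bioactivity
databases; their frequency distribution is a power law — a handful of very
common groups and an enormous tail of rare ones.  This module emulates that
situation without any download: a weighted pool of substituents with Zipf
(rank^-s) sampling weights decorates aromatic scaffolds at random open
positions, and a manifest records exactly which substituent was planted on
which molecule, so extraction can be validated against ground truth.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import AttachmentMarkedFragment, MoleculeRecord, fragment_from_smiles

#: Classic medicinal-chemistry substituents, ordered roughly by how common
#: such groups are in bioactive molecules (halogens/small alkyls/ethers
#: first).  Identities are general-chemistry staples, including the classic
#: Craig-plot groups (halogens, alkyls, OMe, NO2, CN, CF3, NMe2, acyl,
#: phenyl).
VOCABULARY = (
    "[*]C",
    "[*]F",
    "[*]OC",
    "[*]Cl",
    "[*]O",
    "[*]N",
    "[*]CC",
    "[*]C(C)=O",
    "[*]C(F)(F)F",
    "[*]Br",
    "[*]C#N",
    "[*][N+](=O)[O-]",
    "[*]N(C)C",
    "[*]C(C)C",
    "[*]OCC",
    "[*]NC",
    "[*]C(=O)OC",
    "[*]C(N)=O",
    "[*]SC",
    "[*]CCC",
    "[*]C(C)(C)C",
    "[*]C=C",
    "[*]I",
    "[*]c1ccccc1",
    "[*]Cc1ccccc1",
    "[*]OC(F)(F)F",
    "[*]S(C)(=O)=O",
    "[*]N1CCOCC1",
    "[*]N1CCNCC1",
    "[*]C1CC1",
    "[*]C(=O)N(C)C",
    "[*]NC(C)=O",
    "[*]OCC(F)(F)F",
    "[*]CCO",
    "[*]CN",
    "[*]C(O)=O",
)

DEFAULT_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1cncnc1",
    "c1ccc2ccccc2c1",
    "c1ccsc1",
)


@dataclass(frozen=True)
class CorpusConfig:
    """Deterministic description of one synthetic corpus."""

    seed: int
    n_molecules: int
    scaffold_set: Sequence[str] = DEFAULT_SCAFFOLDS
    pool_size: int = 60
    zipf_exponent: float = 2.0
    max_decorations: int = 3
    bioactive_rate: float = 0.8


@dataclass
class SubstituentPool:
    """Attachment-marked fragments with Zipf sampling weights."""

    fragments: list[AttachmentMarkedFragment]
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class CorpusResult:
    records: list[MoleculeRecord]
    manifest: pd.DataFrame  # columns: mol_id, substituent, scaffold

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------


_CHAIN_ATOMS = ("C", "C", "C", "O", "N")
_TERMINALS = ("", "F", "Cl", "O", "N", "C#N", "C(F)(F)F", "OC")


def _combinatorial_fragments(rng: np.random.Generator, needed: int, known: set[str]):
    """Extend the vocabulary with deterministic random chain fragments."""
    out = []
    attempts = 0
    while len(out) < needed and attempts < 50 * needed + 1000:
        attempts += 1
        length = int(rng.integers(1, 8))
        body = "".join(rng.choice(_CHAIN_ATOMS) for _ in range(length))
        term = str(rng.choice(_TERMINALS))
        smiles = "[*]" + body + term
        try:
            frag = fragment_from_smiles(smiles)
        except ValueError:
            continue
        if frag.heavy_atom_count == 0 or frag.heavy_atom_count > 12:
            continue
        if frag.canonical_form in known:
            continue
        known.add(frag.canonical_form)
        out.append(frag)
    return out


def zipf_pool(seed: int, pool_size: int, exponent: float = 2.0) -> SubstituentPool:
    """A pool of ``pool_size`` substituents with rank^(-exponent) weights.

    The built-in vocabulary supplies the head of the distribution; extra
    fragments are generated combinatorially (seeded) when the pool is larger
    than the vocabulary.  Weights are normalized to sum to one.
    """
    if exponent <= 1:
        raise ValueError("zipf exponent must exceed 1")
    if pool_size < 10:
        raise ValueError("pool_size must be at least 10")
    rng = np.random.default_rng(seed)
    fragments = []
    known: set[str] = set()
    for smi in VOCABULARY[:pool_size]:
        frag = fragment_from_smiles(smi)
        if frag.canonical_form not in known:
            known.add(frag.canonical_form)
            fragments.append(frag)
    if len(fragments) < pool_size:
        fragments.extend(
            _combinatorial_fragments(rng, pool_size - len(fragments), known)
        )
    fragments = fragments[:pool_size]
    ranks = np.arange(1, len(fragments) + 1, dtype=float)
    weights = ranks ** (-exponent)
    weights /= weights.sum()
    return SubstituentPool(fragments=fragments, weights=weights)


def _open_positions(scaffold: Chem.Mol) -> list[int]:
    """Aromatic carbons with at least one hydrogen (decoration sites)."""
    return [
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]


def _decorate(scaffold: Chem.Mol, positions: Sequence[int], fragments) -> Chem.Mol:
    """Attach each fragment to its scaffold position; returns the molecule."""
    mol = Chem.RWMol(scaffold)
    for pos, frag in zip(positions, fragments):
        fmol = frag.mol()
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol.GetMol(), fmol))
        star = next(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetIdx() >= offset
        )
        anchor = mol.GetAtomWithIdx(star).GetNeighbors()[0].GetIdx()
        mol.AddBond(pos, anchor, Chem.BondType.SINGLE)
        mol.RemoveAtom(star)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def generate_corpus(config: CorpusConfig, pool: Optional[SubstituentPool] = None) -> CorpusResult:
    """Decorated-scaffold corpus plus the ground-truth planting manifest.

    Each molecule is one scaffold with 1..max_decorations substituents drawn
    from the Zipf pool at distinct open ring positions.  The manifest has
    one row per planted substituent (mol_id, substituent, scaffold) and is
    the oracle for extraction-recovery checks.  The same config yields a
    byte-identical corpus.
    """
    rng = np.random.default_rng(config.seed)
    if pool is None:
        pool = zipf_pool(config.seed, config.pool_size, config.zipf_exponent)
    scaffolds = []
    for smi in config.scaffold_set:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable scaffold {smi!r}")
        positions = _open_positions(mol)
        if not positions:
            import warnings

            warnings.warn(f"scaffold {smi!r} has no open position; skipped")
            continue
        scaffolds.append((smi, mol, positions))
    if not scaffolds:
        raise ValueError("no usable scaffold")

    records: list[MoleculeRecord] = []
    manifest_rows = []
    for i in range(config.n_molecules):
        smi, scaffold, positions = scaffolds[int(rng.integers(len(scaffolds)))]
        n_dec = int(rng.integers(1, config.max_decorations + 1))
        n_dec = min(n_dec, len(positions))
        chosen = rng.choice(len(positions), size=n_dec, replace=False)
        frag_idx = rng.choice(len(pool.fragments), size=n_dec, p=pool.weights)
        frags = [pool.fragments[int(j)] for j in frag_idx]
        mol = _decorate(scaffold, [positions[int(c)] for c in chosen], frags)
        mol_id = f"mol{i:05d}"
        records.append(
            MoleculeRecord(
                id=mol_id,
                structure=Chem.MolToSmiles(mol),
                bioactive=bool(rng.random() < config.bioactive_rate),
            )
        )
        for frag in frags:
            manifest_rows.append(
                {"mol_id": mol_id, "substituent": frag.canonical_form, "scaffold": smi}
            )
    manifest = pd.DataFrame(manifest_rows, columns=["mol_id", "substituent", "scaffold"])
    return CorpusResult(records=records, manifest=manifest)


def write_corpus(result: CorpusResult, path: str, manifest_path: Optional[str] = None) -> None:
    """Write a corpus as a .smi table (SMILES, id, pseudo-activity column)."""
    with open(path, "w") as fh:
        for rec in result.records:
            activity = 1.0 if rec.bioactive else 100.0
            fh.write(f"{rec.structure}\t{rec.id}\t{activity}\n")
    if manifest_path:
        result.manifest.to_csv(manifest_path, sep="\t", index=False)
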