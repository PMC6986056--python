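"""Breakable-bond rules and substituent extraction.

A substituent is obtained by cutting one *chemically activated* single bond
and keeping the side that is small enough (the default cap is 12 heavy
atoms).  A single acyclic single bond is activated when any of these holds:

* it joins a ring atom to a non-ring atom (substituent on a ring),
* it joins a carbon to a heteroatom,
* either endpoint carries a double or triple bond to a third atom
  (carbonyl, nitrile, vinyl, azo neighbourhoods).

Ring bonds and multiple bonds are never cut, and aromatic bonds do not count
as "multiple" for the adjacency rule.  Both fragments of a cut are candidate
substituents; each occurrence records the atom on the *other* side as its
attachment context.  Hydrogens are never extracted (only heavy–heavy bonds
are cut).

Two historically ambiguous cases sit behind explicit switches, both off by
default: cutting bonds whose endpoints are both heteroatoms, and cutting
acyclic ring–ring (biaryl-type) linkages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from rdkit import Chem

from .catalog import (
    AttachmentProfile,
    Substituent,
    SubstituentCatalog,
    category_of,
    level2_class,
    root_class,
)
from .chem_io import AttachmentMarkedFragment, MoleculeRecord


@dataclass(frozen=True)
class BondRules:
    """Switches for the two rule variants the default leaves off."""

    cut_hetero_hetero: bool = False
    cut_ring_ring: bool = False


DEFAULT_RULES = BondRules()


@dataclass(frozen=True)
class AttachmentContext:
    """The skeleton atom a substituent occurrence was attached to."""

    element: str
    aromatic: bool
    carbonyl: bool

    def __post_init__(self):
        if self.carbonyl and self.element != "C":
            raise ValueError("carbonyl attachment implies a carbon atom")

    @property
    def category(self) -> str:
        return category_of(self.element, self.aromatic, self.carbonyl)


@dataclass(frozen=True)
class SubstituentOccurrence:
    """One (substituent, source molecule, attachment context) event."""

    fragment: AttachmentMarkedFragment
    source_id: str
    attachment: AttachmentContext


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 6:
        return False
    for bond in atom.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.DOUBLE
            and bond.GetOtherAtom(atom).GetAtomicNum() == 8
        ):
            return True
    return False


def _has_multiple_bond(atom: Chem.Atom, exclude_bond_idx: int) -> bool:
    for bond in atom.GetBonds():
        if bond.GetIdx() == exclude_bond_idx:
            continue
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            return True
    return False


def is_breakable(bond: Chem.Bond, rules: BondRules = DEFAULT_RULES) -> bool:
    """Decide whether one bond is chemically activated for cutting.

    Total function: any bond of a sanitized molecule gets an answer.  Only
    acyclic single (non-aromatic) bonds between two heavy atoms qualify at
    all; see the module docstring for the activation rules.
    """
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
        return False
    if bond.IsInRing():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
        return False
    if a.IsInRing() != b.IsInRing():
        return True
    carbons = (a.GetAtomicNum() == 6) + (b.GetAtomicNum() == 6)
    if carbons == 1:
        return True
    if carbons == 0 and rules.cut_hetero_hetero:
        return True
    if a.IsInRing() and b.IsInRing() and rules.cut_ring_ring:
        return True
    if _has_multiple_bond(a, bond.GetIdx()) or _has_multiple_bond(b, bond.GetIdx()):
        return True
    return False


def _coerce_mol(molecule) -> tuple[Chem.Mol, str]:
    if isinstance(molecule, MoleculeRecord):
        return molecule.mol(), molecule.id
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES {molecule!r}")
        return mol, molecule
    return molecule, ""


def extract_substituents(
    molecule,
    max_heavy: int = 12,
    rules: BondRules = DEFAULT_RULES,
    source_id: Optional[str] = None,
) -> list[SubstituentOccurrence]:
    """Cut every breakable bond of one molecule, one bond at a time.

    Each cut yields up to two occurrences: each side whose heavy-atom count
    is within ``max_heavy`` becomes a substituent, annotated with the
    element/aromaticity/carbonyl context of the atom it was attached to.
    The result is sorted by canonical form for determinism.
    """
    mol, default_id = _coerce_mol(molecule)
    sid = source_id if source_id is not None else default_id

    cut_ids = [b.GetIdx() for b in mol.GetBonds() if is_breakable(b, rules)]
    occurrences: list[SubstituentOccurrence] = []
    for bond_idx in cut_ids:
        bond = mol.GetBondWithIdx(bond_idx)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        pieces = Chem.FragmentOnBonds(
            mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)]
        )
        try:
            frag_mols = Chem.GetMolFrags(
                pieces, asMols=True, sanitizeFrags=True, frags=None
            )
            frag_maps = Chem.GetMolFrags(pieces)
        except Chem.AtomValenceException:  # pragma: no cover - defensive
            warnings.warn(f"skipping uncuttable bond {bond_idx} in {sid!r}")
            continue
        for frag, amap in zip(frag_mols, frag_maps):
            heavy = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)
            if heavy > max_heavy or heavy == 0:
                continue
            # the attachment atom sits on the other side of the cut
            other_idx = j if i in amap else i
            other = mol.GetAtomWithIdx(other_idx)
            for atom in frag.GetAtoms():
                atom.SetAtomMapNum(0)
                atom.SetIsotope(0)
            canonical = Chem.MolToSmiles(frag)
            occurrences.append(
                SubstituentOccurrence(
                    fragment=AttachmentMarkedFragment(
                        canonical_form=canonical, heavy_atom_count=heavy
                    ),
                    source_id=sid,
                    attachment=AttachmentContext(
                        element=other.GetSymbol(),
                        aromatic=other.GetIsAromatic(),
                        carbonyl=_is_carbonyl_carbon(other),
                    ),
                )
            )
    occurrences.sort(key=lambda o: (o.fragment.canonical_form, o.source_id))
    return occurrences


def fragment_corpus(
    molecules: Iterable[Union[MoleculeRecord, str]],
    max_heavy: int = 12,
    min_molecule_freq: int = 50,
    rules: BondRules = DEFAULT_RULES,
    bioactive_only: bool = False,
) -> SubstituentCatalog:
    """Aggregate substituent occurrences over a corpus into a catalog.

    ``molecule_frequency`` counts distinct molecules (a molecule containing
    the same substituent twice contributes one); ``occurrence_count`` counts
    every cut.  Entries below ``min_molecule_freq`` stay in the catalog's
    raw statistics; the ``common()`` view applies the threshold.
    """
    acc: dict[str, dict] = {}
    corpus_size = 0
    for k, molecule in enumerate(molecules):
        if isinstance(molecule, MoleculeRecord):
            if bioactive_only and not molecule.bioactive:
                continue
            sid = molecule.id
        else:
            sid = f"mol{k}"
        corpus_size += 1
        for occ in extract_substituents(
            molecule, max_heavy=max_heavy, rules=rules, source_id=sid
        ):
            slot = acc.setdefault(
                occ.fragment.canonical_form,
                {
                    "fragment": occ.fragment,
                    "molecules": set(),
                    "occurrences": 0,
                    "profile": AttachmentProfile(),
                },
            )
            slot["molecules"].add(occ.source_id)
            slot["occurrences"] += 1
            slot["profile"].add(occ.attachment.category)

    entries = []
    for smiles in sorted(acc):
        slot = acc[smiles]
        frag = slot["fragment"]
        entries.append(
            Substituent(
                fragment=frag,
                molecule_frequency=len(slot["molecules"]),
                occurrence_count=slot["occurrences"],
                attachment_profile=slot["profile"],
                root_class=root_class(frag),
                level2_class=level2_class(frag),
            )
        )
    return SubstituentCatalog(
        entries, corpus_size=corpus_size, min_molecule_freq=min_molecule_freq
    )
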