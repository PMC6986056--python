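"""Reading and writing molecule and substituent tables.

Molecules enter the pipeline as SMILES line notation (``SMILES<ws>id
[<ws>activity]``).  Substituents are represented throughout as
*attachment-marked fragments*: a canonical SMILES string containing exactly
one dummy atom (``*``) that marks the point where the fragment was attached
to the parent skeleton.  All canonicalization is delegated to RDKit, so two
fragments are "the same substituent" exactly when their canonical marked
SMILES agree.

Aromaticity dialect: the RDKit default aromaticity model is used for the
whole pipeline; lowercase atoms in canonical forms therefore follow RDKit's
perception.  This matters for the aliphatic/aromatic split in the
classification tables, so it is fixed here once and never overridden
downstream.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd
from rdkit import Chem, RDLogger

# RDKit is chatty about unparseable SMILES and dummy-atom hydrogens; the
# parser reports skips itself.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Columns every written substituent table carries, in this order.
DEFAULT_COLUMNS = (
    "smiles",
    "molecule_frequency",
    "occurrence_count",
    "pi",
    "sigma",
    "root_class",
    "level2_class",
)

#: Extra columns that allow a written catalog to be reconstructed losslessly.
PROFILE_COLUMNS = (
    "att_C",
    "att_c",
    "att_Nn",
    "att_O",
    "att_S",
    "att_X",
    "att_CO",
    "att_other",
)

ATTACHMENT_CATEGORIES = ("C", "c", "N,n", "O", "S", "X", "C(=O)*", "other")

#: category -> column name used in flat tables (TSV-safe identifiers).
CATEGORY_TO_COLUMN = dict(zip(ATTACHMENT_CATEGORIES, PROFILE_COLUMNS))
COLUMN_TO_CATEGORY = {v: k for k, v in CATEGORY_TO_COLUMN.items()}

HALOGENS = frozenset(("F", "Cl", "Br", "I"))


class ParseError(ValueError):
    """Raised for structurally malformed input tables."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One input structure: identifier, structure and optional bioactivity flag.

    ``structure`` is the canonical SMILES of the largest covalent component
    of the input line (salts/solvates are dropped during parsing).
    """

    id: str
    structure: str
    bioactive: Optional[bool] = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:  # pragma: no cover - structure is canonical by construction
            raise ValueError(f"record {self.id!r}: structure no longer parses")
        return m


@dataclass(frozen=True)
class AttachmentMarkedFragment:
    """A substituent: canonical SMILES with exactly one attachment marker.

    ``heavy_atom_count`` excludes both hydrogens and the marker itself.  The
    hydrogen substituent ``[*][H]`` is the one legal fragment with a heavy
    atom count of zero.
    """

    canonical_form: str
    heavy_atom_count: int

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.canonical_form)
        if m is None:  # pragma: no cover
            raise ValueError(f"fragment {self.canonical_form!r} no longer parses")
        return m


@dataclass
class ParseResult:
    """Outcome of parsing a molecule table: records plus skip accounting."""

    records: list[MoleculeRecord]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def largest_component(mol: Chem.Mol) -> Chem.Mol:
    """Return the covalent component with the most heavy atoms.

    Ties are broken by canonical SMILES so the choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def _coerce_stream(stream: Union[str, TextIO]) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_molecule_table(
    stream: Union[str, TextIO],
    *,
    delimiter: Optional[str] = None,
    activity_threshold: float = 10.0,
    header: bool = False,
    neutralize: bool = False,
) -> ParseResult:
    """Parse a SMILES line-notation table into molecule records.

    Each non-empty line is ``SMILES<delim>id[<delim>activity]``; ``delimiter``
    ``None`` means any whitespace.  When an activity column is present the
    record's ``bioactive`` flag is ``activity < activity_threshold`` (the
    threshold is interpreted in the column's own unit; the conventional cut
    is 10 µM).  Unparseable lines are skipped and counted, never fatal.

    With ``header=True`` the first line must name a ``smiles`` column;
    anything else raises :class:`ParseError` identifying the line.
    """
    fh = _coerce_stream(stream)
    records: list[MoleculeRecord] = []
    skipped: list[tuple[int, str]] = []
    seen_any = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split(delimiter)
        if lineno == 1:
            if header:
                if tokens[0].strip().lower() != "smiles":
                    raise ParseError(
                        f"line 1: malformed header {line!r}: first column must be 'smiles'"
                    )
                seen_any = True
                continue
            if tokens[0].strip().lower() == "smiles":
                raise ParseError(
                    "line 1: looks like a header row; pass header=True to skip it"
                )
        seen_any = True
        smiles = tokens[0]
        mol_id = tokens[1] if len(tokens) > 1 else f"line{lineno}"
        bioactive: Optional[bool] = None
        if len(tokens) > 2:
            try:
                bioactive = float(tokens[2]) < activity_threshold
            except ValueError:
                skipped.append((lineno, line))
                continue
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            skipped.append((lineno, line))
            continue
        mol = largest_component(mol)
        if neutralize:
            mol = _neutralize(mol)
        records.append(
            MoleculeRecord(id=mol_id, structure=Chem.MolToSmiles(mol), bioactive=bioactive)
        )
    if not seen_any and not records:
        warnings.warn("empty molecule table", stacklevel=2)
    return ParseResult(records=records, skipped=skipped)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize simple protonation-state charges (optional preprocessing)."""
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        n_h = atom.GetTotalNumHs()
        # only plain acid/base charges: skip charge-separated groups (e.g. nitro)
        if any(nb.GetFormalCharge() != 0 for nb in atom.GetNeighbors()):
            continue
        if q > 0 and n_h >= q:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - q))
        elif q < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(n_h - q)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def _count_heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_from_smiles(smiles: str) -> AttachmentMarkedFragment:
    """Canonicalize an attachment-marked SMILES into a fragment object.

    The input must contain exactly one dummy atom carrying exactly one single
    bond.  ``[*][H]`` (the hydrogen substituent) is accepted with a heavy
    atom count of zero.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable fragment SMILES: {smiles!r}")
    return canonical_substituent(mol)


def canonical_substituent(
    fragment: Union[Chem.Mol, str],
    attachment_atom: Optional[int] = None,
) -> AttachmentMarkedFragment:
    """Produce the canonical attachment-marked form of a fragment.

    Two call styles:

    * ``canonical_substituent(mol_with_one_dummy)`` — the fragment already
      carries its attachment marker;
    * ``canonical_substituent(plain_mol, attachment_atom=i)`` — atom ``i``
      lost a neighbour when the bond was cut; a marker is attached to it.

    The result is canonical: any atom-order permutation of the same fragment
    maps to the identical string (RDKit canonical SMILES).
    """
    if isinstance(fragment, str):
        mol = Chem.MolFromSmiles(fragment)
        if mol is None:
            raise ValueError(f"unparseable fragment SMILES: {fragment!r}")
    else:
        mol = Chem.Mol(fragment)

    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if attachment_atom is not None:
        if dummies:
            raise ValueError(
                "fragment already carries an attachment marker; "
                "attachment_atom must not be given as well"
            )
        rw = Chem.RWMol(mol)
        star = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(attachment_atom, star, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        dummies = [star]
    if len(dummies) != 1:
        raise ValueError(
            f"fragment must have exactly one attachment point, found {len(dummies)}"
        )
    dummy = mol.GetAtomWithIdx(dummies[0])
    if dummy.GetDegree() != 1:
        raise ValueError("attachment marker must carry exactly one bond")
    bond = dummy.GetBonds()[0]
    if bond.GetBondType() != Chem.BondType.SINGLE:
        raise ValueError("attachment marker bond must be single")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    canonical = Chem.MolToSmiles(mol)
    return AttachmentMarkedFragment(
        canonical_form=canonical, heavy_atom_count=_count_heavy(mol)
    )


# ---------------------------------------------------------------------------
# substituent tables


def _entry_rows(catalog, columns: Sequence[str]) -> Iterable[dict]:
    if hasattr(catalog, "to_rows"):
        rows = catalog.to_rows()
    else:
        rows = catalog
    for row in rows:
        if not isinstance(row, dict):
            row = dict(row)
        missing = [c for c in columns if c not in row]
        if missing:
            raise KeyError(
                f"catalog entry lacks requested column(s): {', '.join(missing)}"
            )
        yield {c: row[c] for c in columns}


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def write_substituent_table(
    catalog,
    stream: Union[str, TextIO],
    columns: Optional[Sequence[str]] = None,
    *,
    delimiter: str = "\t",
) -> int:
    """Write a catalog as delimited text; returns the number of data rows.

    ``catalog`` is either an object with ``to_rows()`` or an iterable of
    mappings.  Missing numeric values are written as empty cells (missing is
    not zero).  A requested column absent from the entries raises
    ``KeyError`` naming the column.  Floats are written with full ``repr``
    precision so a matching reader round-trips them bit-exactly.
    """
    columns = tuple(columns) if columns is not None else DEFAULT_COLUMNS
    own = isinstance(stream, str)
    fh = open(stream, "w") if own else stream
    try:
        fh.write(delimiter.join(columns) + "\n")
        count = 0
        for row in _entry_rows(catalog, columns):
            fh.write(delimiter.join(_format_cell(row[c]) for c in columns) + "\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count


def read_substituent_table(
    stream: Union[str, TextIO], *, delimiter: str = "\t"
) -> pd.DataFrame:
    """Read a substituent table written by :func:`write_substituent_table`."""
    fh = stream if not isinstance(stream, str) else stream
    df = pd.read_csv(fh, sep=delimiter, dtype={"smiles": str})
    return df
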