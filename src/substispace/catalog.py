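"""Substituent catalogs: classification, attachment profiles, frequency stats.

A catalog aggregates attachment-marked fragments over a corpus.  Each unique
substituent carries two frequencies: ``molecule_frequency`` (number of
distinct molecules containing it — the quantity the "common substituent"
threshold applies to) and ``occurrence_count`` (every cut counted, the
weighting used for attachment-profile tables).

Classification follows the root-atom convention of medicinal-chemistry
substituent tables: level 1 is the root atom (the substituent atom bonded to
the skeleton), written ``R–C`` / ``R–c`` / ``R–N`` … with lowercase for
aromatic atoms and ``R–X`` pooling the halogens; level 2 appends the root's
heavy-atom neighbours with their bond annotation, e.g. ``R–C(=O)–N`` for
amides or ``R–c(:c):c`` for attached aromatic rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem

from .chem_io import (
    ATTACHMENT_CATEGORIES,
    CATEGORY_TO_COLUMN,
    DEFAULT_COLUMNS,
    HALOGENS,
    PROFILE_COLUMNS,
    AttachmentMarkedFragment,
    fragment_from_smiles,
)

DASH = "–"  # en-dash, as printed in substituent classification tables


def attachment_category(context) -> str:
    """Classify the skeleton atom a substituent is bonded to.

    ``context`` needs ``element``, ``aromatic`` and ``carbonyl`` attributes
    (see :class:`substispace.fragmenter.AttachmentContext`).  Carbonyl carbon
    takes precedence over the plain carbon categories; aromatic and
    aliphatic nitrogen are pooled ("N,n"); halogens are pooled ("X").
    """
    return category_of(context.element, context.aromatic, context.carbonyl)


def category_of(element: str, aromatic: bool, carbonyl: bool) -> str:
    if carbonyl:
        return "C(=O)*"
    if element == "C":
        return "c" if aromatic else "C"
    if element == "N":
        return "N,n"
    if element == "O":
        return "O"
    if element == "S":
        return "S"
    if element in HALOGENS:
        return "X"
    return "other"


@dataclass
class AttachmentProfile:
    """Occurrence counts per attachment category for one substituent."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, category: str, n: int = 1) -> None:
        self.counts[category] = self.counts.get(category, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def share(self, category: str) -> float:
        total = self.total
        return self.counts.get(category, 0) / total if total else 0.0

    def modal_category(self) -> Optional[str]:
        if not self.counts:
            return None
        # deterministic tie-break: category order of the fixed vocabulary
        order = {c: i for i, c in enumerate(ATTACHMENT_CATEGORIES)}
        return max(self.counts, key=lambda c: (self.counts[c], -order.get(c, 99)))


@dataclass
class Substituent:
    """A unique substituent aggregated over a corpus."""

    fragment: AttachmentMarkedFragment
    molecule_frequency: int
    occurrence_count: int
    attachment_profile: AttachmentProfile
    root_class: str
    level2_class: str
    properties: Optional["PropertyVector"] = None  # noqa: F821 (set by annotate)

    @property
    def smiles(self) -> str:
        return self.fragment.canonical_form

    @property
    def heavy_atom_count(self) -> int:
        return self.fragment.heavy_atom_count


# ---------------------------------------------------------------------------
# pattern grammar


_PRECEDENCE = {s: i for i, s in enumerate(("C", "c", "N", "n", "O", "S", "X"))}


def _root_atom(mol: Chem.Mol) -> Chem.Atom:
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError("fragment must carry exactly one attachment marker")
    return dummies[0].GetNeighbors()[0]


def _as_mol(substituent) -> Chem.Mol:
    if isinstance(substituent, Substituent):
        return substituent.fragment.mol()
    if isinstance(substituent, AttachmentMarkedFragment):
        return substituent.mol()
    if isinstance(substituent, str):
        return fragment_from_smiles(substituent).mol()
    return substituent  # assume Mol


def _symbol(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if sym in HALOGENS:
        return "X"
    return sym.lower() if atom.GetIsAromatic() else sym


def root_class(substituent) -> str:
    """Level-1 class: ``R–`` plus the root atom symbol (halogens pooled as X)."""
    mol = _as_mol(substituent)
    return f"R{DASH}{_symbol(_root_atom(mol))}"


def _bond_char(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return ":"
    if bond.GetBondType() == Chem.BondType.DOUBLE:
        return "="
    if bond.GetBondType() == Chem.BondType.TRIPLE:
        return "#"
    return DASH


def _neighbour_patterns(mol: Chem.Mol, atom: Chem.Atom, exclude: set[int]):
    """Split an atom's heavy neighbours into inline ``=O`` and ordered rest."""
    carbonyl_os: list[str] = []
    rest: list[tuple[int, str, str, int]] = []
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetIdx() in exclude or other.GetAtomicNum() <= 1:
            continue
        if other.GetAtomicNum() == 0:
            continue
        bc = _bond_char(bond)
        sym = _symbol(other)
        if sym == "O" and bc == "=":
            carbonyl_os.append("(=O)")
            continue
        rank = _PRECEDENCE.get(sym, 50 + ord(sym[0].lower()))
        rest.append((rank, bc, sym, other.GetIdx()))
    rest.sort(key=lambda t: (t[0], t[1]))
    return carbonyl_os, rest


# The canonical neighbour order is the fixed precedence above; the printed
# convention of classification tables parenthesizes the ring heteroatom for
# mixed aromatic ortho pairs (…(:n):c), so that multiset is re-rendered.
_PRINT_OVERRIDES = {
    ((":", "c"), (":", "n")): [(":", "n"), (":", "c")],
}


def level2_class(substituent, depth: int = 2) -> str:
    """Root atom plus its heavy neighbours, in the printed table grammar.

    Double-bonded oxygens are rendered inline first (``R–C(=O)–N``); the
    remaining neighbours are ordered by a fixed precedence (C < c < N < n <
    O < S < X), all but the last wrapped in parentheses with their bond
    annotation (``–`` single, ``:`` aromatic, ``=`` double, ``#`` triple).
    ``depth=3`` extends a linear chain one shell further (``R–C–C–O``) when
    the continuation is unambiguous, otherwise falls back to depth 2.
    """
    mol = _as_mol(substituent)
    root = _root_atom(mol)
    base = f"R{DASH}{_symbol(root)}"
    carbonyl_os, rest = _neighbour_patterns(mol, root, exclude=set())
    if not carbonyl_os and not rest:
        return base
    out = base + "".join(carbonyl_os)
    if rest:
        parts = [(bc, sym) for _rank, bc, sym, _idx in rest]
        parts = _PRINT_OVERRIDES.get(tuple(parts), parts)
        for bc, sym in parts[:-1]:
            out += f"({bc}{sym})"
        bc, sym = parts[-1]
        out += f"{bc}{sym}"
        last_idx = rest[-1][3]
        if depth >= 3 and len(rest) == 1 and not carbonyl_os:
            nxt = mol.GetAtomWithIdx(last_idx)
            cos, onward = _neighbour_patterns(mol, nxt, exclude={root.GetIdx()})
            if not cos and len(onward) == 1:
                _r, bc2, sym2, _i = onward[0]
                out += f"{bc2}{sym2}"
    return out


# ---------------------------------------------------------------------------
# the catalog container


class SubstituentCatalog:
    """Unique substituents of a corpus, keyed by canonical marked SMILES."""

    def __init__(
        self,
        entries: Union[Mapping[str, Substituent], Iterable[Substituent]],
        corpus_size: int,
        min_molecule_freq: int = 50,
    ):
        if isinstance(entries, Mapping):
            self.entries = dict(entries)
        else:
            self.entries = {e.smiles: e for e in entries}
        self.corpus_size = corpus_size
        self.min_molecule_freq = min_molecule_freq

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Substituent]:
        return iter(sorted(self.entries.values(), key=lambda e: e.smiles))

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.entries

    def get(self, smiles: str) -> Optional[Substituent]:
        return self.entries.get(smiles)

    def common(self) -> list[Substituent]:
        """Entries at or above the molecule-frequency threshold."""
        return [
            e
            for e in self
            if e.molecule_frequency >= self.min_molecule_freq
        ]

    def common_catalog(self) -> "SubstituentCatalog":
        return SubstituentCatalog(
            self.common(), self.corpus_size, self.min_molecule_freq
        )

    def subset(self, entries: Iterable[Substituent]) -> "SubstituentCatalog":
        return SubstituentCatalog(
            list(entries), self.corpus_size, self.min_molecule_freq
        )

    def annotated(self) -> list[Substituent]:
        return [e for e in self if e.properties is not None]

    def to_rows(self) -> list[dict]:
        rows = []
        for e in self:
            row = {
                "smiles": e.smiles,
                "heavy_atom_count": e.heavy_atom_count,
                "molecule_frequency": e.molecule_frequency,
                "occurrence_count": e.occurrence_count,
                "pi": e.properties.pi if e.properties else None,
                "sigma": e.properties.sigma if e.properties else None,
                "root_class": e.root_class,
                "level2_class": e.level2_class,
            }
            for cat, col in CATEGORY_TO_COLUMN.items():
                row[col] = e.attachment_profile.counts.get(cat, 0)
            rows.append(row)
        return rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_rows(),
            columns=list(DEFAULT_COLUMNS[:3])
            + ["heavy_atom_count"]
            + list(DEFAULT_COLUMNS[3:])
            + list(PROFILE_COLUMNS),
        )


def catalog_from_frame(
    df: pd.DataFrame, corpus_size: int, min_molecule_freq: int = 50
) -> SubstituentCatalog:
    """Rebuild a catalog from a table written by the pipeline.

    Property columns (``pi``/``sigma``) and attachment-profile columns are
    restored when present.
    """
    from .properties import PropertyVector  # local import, no cycle at module load

    entries = []
    for _, row in df.iterrows():
        frag = fragment_from_smiles(row["smiles"])
        profile = AttachmentProfile()
        for cat, col in CATEGORY_TO_COLUMN.items():
            if col in df.columns and pd.notna(row[col]) and int(row[col]):
                profile.add(cat, int(row[col]))
        props = None
        if (
            "pi" in df.columns
            and "sigma" in df.columns
            and pd.notna(row["pi"])
            and pd.notna(row["sigma"])
        ):
            props = PropertyVector(pi=float(row["pi"]), sigma=float(row["sigma"]))
        entries.append(
            Substituent(
                fragment=frag,
                molecule_frequency=int(row["molecule_frequency"]),
                occurrence_count=int(row["occurrence_count"]),
                attachment_profile=profile,
                root_class=row.get("root_class") or root_class(frag),
                level2_class=row.get("level2_class") or level2_class(frag),
                properties=props,
            )
        )
    return SubstituentCatalog(entries, corpus_size, min_molecule_freq)


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class ClassificationTable:
    """Root-level and level-2 percentage tables (the classification analogue)."""

    by_root: pd.DataFrame
    by_level2: pd.DataFrame
    weighting: str


def aggregate_profiles(
    catalog: SubstituentCatalog, weighting: str = "occurrence"
) -> ClassificationTable:
    """Percentage of substituents per root/level-2 class plus attachment mix.

    ``weighting='occurrence'`` counts every cut (each substituent weighted by
    its occurrence count, the convention of corpus-wide classification
    tables); ``'unique'`` counts each unique substituent once, with its
    attachment profile normalized to a single vote.
    """
    if weighting not in ("occurrence", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    entries = list(catalog)
    if not entries:
        empty = pd.DataFrame()
        return ClassificationTable(empty, empty, weighting)

    rows = []
    for e in entries:
        weight = e.occurrence_count if weighting == "occurrence" else 1.0
        att = {cat: 0.0 for cat in ATTACHMENT_CATEGORIES}
        total = e.attachment_profile.total
        for cat, n in e.attachment_profile.counts.items():
            if weighting == "occurrence":
                att[cat] += n
            elif total:
                att[cat] += n / total
        rows.append((e.root_class, e.level2_class, weight, att))

    grand_total = sum(w for _, _, w, _ in rows)

    def _table(keyfunc):
        agg: dict = {}
        for root, lvl2, w, att in rows:
            key = keyfunc(root, lvl2)
            slot = agg.setdefault(
                key, {"weight": 0.0, "att": {c: 0.0 for c in ATTACHMENT_CATEGORIES}}
            )
            slot["weight"] += w
            for c, v in att.items():
                slot["att"][c] += v
        out = []
        for key, slot in agg.items():
            rec = {
                "root_class": key[0],
                "percent": 100.0 * slot["weight"] / grand_total,
            }
            if len(key) > 1:
                rec["level2_class"] = key[1]
            att_total = sum(slot["att"].values())
            for c in ATTACHMENT_CATEGORIES:
                rec[f"attached_{CATEGORY_TO_COLUMN[c][4:]}"] = (
                    100.0 * slot["att"][c] / att_total if att_total else 0.0
                )
            out.append(rec)
        df = pd.DataFrame(out).sort_values(
            "percent", ascending=False, kind="mergesort"
        )
        return df.reset_index(drop=True)

    by_root = _table(lambda r, l: (r,))
    by_level2 = _table(lambda r, l: (r, l))
    cols = ["root_class", "level2_class", "percent"] + [
        c for c in by_level2.columns if c.startswith("attached_")
    ]
    by_level2 = by_level2[cols]
    return ClassificationTable(by_root=by_root, by_level2=by_level2, weighting=weighting)


# ---------------------------------------------------------------------------
# frequency statistics


@dataclass
class DistributionSummary:
    """Long-tail statistics of a substituent frequency distribution."""

    unique_count: int
    total_occurrences: int
    singleton_count: int
    singleton_fraction: float
    n_above_fraction: dict[float, int]


def frequency_summary(
    catalog: SubstituentCatalog,
    corpus_size: Optional[int] = None,
    thresholds: Sequence[float] = (0.01, 0.001),
) -> DistributionSummary:
    """Singleton statistics and counts above corpus-fraction thresholds.

    A *singleton* is a substituent present in exactly one molecule.
    ``n_above_fraction[t]`` counts substituents present in **more than**
    ``t * corpus_size`` molecules; it is non-increasing in ``t``.
    """
    if corpus_size is None:
        corpus_size = catalog.corpus_size
    if not corpus_size:
        raise ValueError("corpus_size must be positive")
    entries = list(catalog.entries.values())
    unique = len(entries)
    singles = sum(1 for e in entries if e.molecule_frequency == 1)
    return DistributionSummary(
        unique_count=unique,
        total_occurrences=sum(e.occurrence_count for e in entries),
        singleton_count=singles,
        singleton_fraction=singles / unique if unique else 0.0,
        n_above_fraction={
            t: sum(1 for e in entries if e.molecule_frequency > t * corpus_size)
            for t in thresholds
        },
    )
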