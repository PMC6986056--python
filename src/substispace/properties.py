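"""Hansch–Fujita π and Hammett-σ-compatible electronic parameters.

π is the classic substituent hydrophobicity: the octanol/water logP of the
mono-substituted benzene probe minus the logP of benzene itself, with logP
computed by the Wildman–Crippen atom-contribution scheme.  π(H) is exactly
zero by construction.

The electronic parameter is a calibrated surrogate for the Hammett σ-para
constant.  A substituted-benzene probe is built for the substituent and
partial atomic charges are computed with a two-part model:

* σ-framework charges from iterative partial equalization of orbital
  electronegativity (PEOE, Gasteiger–Marsili), and
* π charges from a Hückel treatment of the conjugated system, with the
  standard heteroatom (h, k) parameters and the ω-technique: the Coulomb
  integral of every π centre is shifted by ω times its current total
  charge, and the π charges are iterated to self-consistency.  This is what
  lets the model express both resonance donation/withdrawal and the
  inductive polarization of the ring.

The raw descriptor is the total charge (σ + π) on the ring carbon *para* to
the substituent plus its hydrogen, minus the same quantity in benzene;
electron-withdrawing substituents give a positive descriptor.  An ordinary
least-squares line maps the descriptor onto the experimental σ-para scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges
from scipy import stats

from .chem_io import AttachmentMarkedFragment, fragment_from_smiles

__all__ = [
    "PropertyVector",
    "CalibrationModel",
    "BenzeneProbe",
    "ChargeConvergenceError",
    "logp_atom_contrib",
    "build_probe",
    "compute_pi",
    "charge_descriptor",
    "fit_sigma_calibration",
    "compute_sigma",
    "evaluate_calibration",
    "annotate_catalog",
    "load_reference_table",
    "default_calibration",
]


@dataclass(frozen=True)
class PropertyVector:
    """The (π, σ) pair that positions a substituent on a Craig plot."""

    pi: float
    sigma: float


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from the charge descriptor onto the σ-para scale."""

    slope: float
    intercept: float
    r_squared: float
    n_train: int
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")


@dataclass(frozen=True)
class CalibrationDiagnostics:
    r_squared: float
    mae: float
    n: int


class ChargeConvergenceError(RuntimeError):
    """π-charge self-consistency loop failed to converge."""


# ---------------------------------------------------------------------------
# logP and π


def _as_mol(molecule: Union[Chem.Mol, str]) -> Chem.Mol:
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES {molecule!r}")
        return mol
    return molecule


def logp_atom_contrib(molecule: Union[Chem.Mol, str]) -> float:
    """Octanol–water logP by Wildman–Crippen atom contributions.

    Deterministic sum of published per-atom-type contributions; atoms that
    match no specific type fall to the published wildcard contribution.
    """
    return Crippen.MolLogP(_as_mol(molecule))


@dataclass(frozen=True)
class BenzeneProbe:
    """A mono-substituted benzene with its ipso/para ring positions marked."""

    mol: Chem.Mol
    ipso: int
    para: int


_BENZENE = Chem.MolFromSmiles("c1ccccc1")
HYDROGEN_SUBSTITUENT = "[*][H]"


def _coerce_fragment(substituent) -> AttachmentMarkedFragment:
    if isinstance(substituent, AttachmentMarkedFragment):
        return substituent
    if isinstance(substituent, str):
        return fragment_from_smiles(substituent)
    if hasattr(substituent, "fragment"):  # Substituent
        return substituent.fragment
    raise TypeError(f"cannot interpret {substituent!r} as a substituent")


def build_probe(substituent) -> BenzeneProbe:
    """Replace the attachment marker by a bond to a benzene ring carbon.

    The hydrogen substituent maps to benzene itself.  The benzene carbons
    occupy atom indices 0–5 of the probe with ipso at 0 and para at 3.
    """
    frag = _coerce_fragment(substituent)
    if frag.heavy_atom_count == 0:
        return BenzeneProbe(mol=Chem.Mol(_BENZENE), ipso=0, para=3)
    fmol = frag.mol()
    combo = Chem.RWMol(Chem.CombineMols(_BENZENE, fmol))
    star = next(a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0)
    anchor = combo.GetAtomWithIdx(star).GetNeighbors()[0].GetIdx()
    combo.AddBond(0, anchor, Chem.BondType.SINGLE)
    combo.RemoveAtom(star)
    probe = combo.GetMol()
    try:
        Chem.SanitizeMol(probe)
    except Exception as exc:
        raise ValueError(
            f"substituent {frag.canonical_form!r} cannot bond to an aromatic carbon: {exc}"
        ) from exc
    return BenzeneProbe(mol=probe, ipso=0, para=3)


def compute_pi(substituent) -> float:
    """π = logP(substituted benzene) − logP(benzene)."""
    probe = build_probe(substituent)
    return logp_atom_contrib(probe.mol) - logp_atom_contrib(_BENZENE)


# ---------------------------------------------------------------------------
# the σ + π charge model

# Hückel Coulomb-integral increments h (α_X = α + h·β) and the number of π
# electrons contributed, per role.  Values follow the standard heteroatom
# parameter tables; positive formal charge adds 1.0 to h, negative subtracts.
_H_PARAMS = {
    ("C", "core"): (0.0, 1),
    ("N", "core_pyridine"): (0.5, 1),
    ("N", "core_pyrrole"): (1.5, 2),
    ("N", "donor"): (1.5, 2),
    ("O", "core"): (1.0, 1),  # carbonyl-type =O
    ("O", "aromatic"): (2.0, 2),
    ("O", "donor"): (2.0, 2),
    ("S", "core"): (0.8, 1),
    ("S", "aromatic"): (1.3, 2),
    ("S", "donor"): (1.3, 2),
    ("F", "donor"): (3.0, 2),
    ("Cl", "donor"): (2.0, 2),
    ("Br", "donor"): (1.5, 2),
    ("I", "donor"): (1.3, 2),
    ("CH3", "hyper"): (2.0, 2),  # alkyl pseudo-heteroatom (hyperconjugation)
}

# Resonance-integral factors k (β_XY = k·β) for bonds inside the π system.
_K_SINGLE = {
    frozenset(("C", "C")): 0.9,
    frozenset(("C", "N")): 0.8,
    frozenset(("C", "O")): 0.8,
    frozenset(("C", "S")): 0.45,
    frozenset(("C", "F")): 0.6,
    frozenset(("C", "Cl")): 0.25,
    frozenset(("C", "Br")): 0.2,
    frozenset(("C", "I")): 0.15,
    frozenset(("N", "O")): 0.8,
    frozenset(("N", "N")): 0.8,
    frozenset(("C", "CH3")): 0.45,
}

_OMEGA = 1.4  # ω-technique coupling of charge into the Coulomb integral
_MIX = 0.5  # damping factor of the self-consistency iteration

_DONOR_ELEMENTS = {"N", "O", "S", "F", "Cl", "Br", "I"}


def _sigma_charges(mol: Chem.Mol) -> np.ndarray:
    """PEOE charge of each heavy atom plus its attached hydrogens."""
    m = Chem.Mol(mol)
    ComputeGasteigerCharges(m, nIter=50)
    q = np.zeros(m.GetNumAtoms())
    for atom in m.GetAtoms():
        q[atom.GetIdx()] = float(atom.GetDoubleProp("_GasteigerCharge")) + float(
            atom.GetDoubleProp("_GasteigerHCharge")
        )
    return q


def _pi_system(mol: Chem.Mol):
    """Identify π centres, their (h, electrons) parameters and bond k factors.

    Core centres are aromatic atoms and atoms in non-aromatic double/triple
    bonds; peripheral centres are lone-pair donors single-bonded to a core
    atom, and plain alkyl carbons single-bonded to a core *carbon* (treated
    as 2-electron pseudo-heteroatoms, the hyperconjugation model).
    """
    core: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            core.add(atom.GetIdx())
    for bond in mol.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            core.add(bond.GetBeginAtomIdx())
            core.add(bond.GetEndAtomIdx())

    label: dict[int, str] = {}  # atom idx -> element key used in parameter tables
    h0: dict[int, float] = {}
    electrons: dict[int, int] = {}

    def _assign(idx: int, key: tuple[str, str], charge: int):
        h, ne = _H_PARAMS[key]
        label[idx] = key[0]
        h0[idx] = h + 1.0 * charge
        # a positive centre that nominally donates 2 e keeps only 1 (e.g. =N+<)
        electrons[idx] = ne

    for idx in core:
        atom = mol.GetAtomWithIdx(idx)
        sym = atom.GetSymbol()
        q = atom.GetFormalCharge()
        if sym == "C":
            _assign(idx, ("C", "core"), q)
        elif sym == "N":
            if atom.GetIsAromatic():
                # pyrrole-type N (three σ bonds / bears H) donates its lone pair
                if atom.GetTotalNumHs() + atom.GetDegree() >= 3 and q == 0:
                    _assign(idx, ("N", "core_pyrrole"), q)
                else:
                    _assign(idx, ("N", "core_pyridine"), q)
            else:
                _assign(idx, ("N", "core_pyridine"), q)
        elif sym == "O":
            if atom.GetIsAromatic():
                _assign(idx, ("O", "aromatic"), q)
            else:
                _assign(idx, ("O", "core"), q)
        elif sym == "S":
            if atom.GetIsAromatic():
                _assign(idx, ("S", "aromatic"), q)
            else:
                _assign(idx, ("S", "core"), q)
        else:
            # unparameterized π centre: treat as carbon-like
            _assign(idx, ("C", "core"), q)
            label[idx] = "C"

    # peripheral donors and hyperconjugating alkyl carbons
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in core or atom.GetAtomicNum() <= 1:
            continue
        sym = atom.GetSymbol()
        core_neighbours = [nb for nb in atom.GetNeighbors() if nb.GetIdx() in core]
        if not core_neighbours:
            continue
        if sym in _DONOR_ELEMENTS:
            _assign(idx, (sym, "donor"), atom.GetFormalCharge())
        elif sym == "C":
            plain_alkyl = all(
                nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors()
            ) and atom.GetFormalCharge() == 0
            attached_to_core_carbon = any(
                nb.GetSymbol() == "C" for nb in core_neighbours
            )
            if plain_alkyl and attached_to_core_carbon:
                label[idx] = "CH3"
                h0[idx] = _H_PARAMS[("CH3", "hyper")][0]
                electrons[idx] = _H_PARAMS[("CH3", "hyper")][1]

    atoms = sorted(label)
    pos = {a: i for i, a in enumerate(atoms)}
    k_entries = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i not in label or j not in label:
            continue
        bt = bond.GetBondType()
        if bond.GetIsAromatic() or bt == Chem.BondType.AROMATIC:
            k = 1.0
        elif bt in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            k = 1.0
        elif bt == Chem.BondType.SINGLE:
            # a single bond conjugates only if it links two π centres
            k = _K_SINGLE.get(frozenset((label[i], label[j])), 0.6)
        else:  # pragma: no cover
            continue
        k_entries.append((pos[i], pos[j], k))
    return atoms, [h0[a] for a in atoms], [electrons[a] for a in atoms], k_entries


def _pi_charges(
    mol: Chem.Mol,
    sigma_q: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """Self-consistent ω-Hückel π charges, one value per atom of ``mol``."""
    atoms, h0, electrons, k_entries = _pi_system(mol)
    out = np.zeros(mol.GetNumAtoms())
    if not atoms:
        return out
    n = len(atoms)
    n_el = int(sum(electrons))
    h0 = np.asarray(h0, dtype=float)
    contrib = np.asarray(electrons, dtype=float)
    sigma_local = np.asarray([sigma_q[a] for a in atoms])

    base = np.zeros((n, n))
    for i, j, k in k_entries:
        base[i, j] = base[j, i] = k

    q_pi = np.zeros(n)
    for _it in range(max_iter):
        H = base.copy()
        np.fill_diagonal(H, h0 + _OMEGA * (sigma_local + q_pi))
        vals, vecs = np.linalg.eigh(H)
        # β < 0: larger eigenvalue of the (h, k) matrix means lower energy
        order = np.argsort(vals)[::-1]
        occ = np.zeros(n)
        remaining = n_el
        for o in order:
            if remaining <= 0:
                break
            fill = min(2, remaining)
            occ[o] = fill
            remaining -= fill
        density = (vecs**2 * occ[np.newaxis, :]).sum(axis=1)
        q_new = contrib - density
        delta = float(np.max(np.abs(q_new - q_pi)))
        q_pi = _MIX * q_pi + (1.0 - _MIX) * q_new
        if delta < tol:
            for a, q in zip(atoms, q_pi):
                out[a] = q
            return out
    raise ChargeConvergenceError(
        f"π-charge iteration did not converge within {max_iter} steps "
        f"(last max |Δq| = {delta:.3e}, {n} π centres, {n_el} electrons)"
    )


def _para_charge_sum(probe: BenzeneProbe) -> float:
    sigma_q = _sigma_charges(probe.mol)
    pi_q = _pi_charges(probe.mol, sigma_q)
    return float(sigma_q[probe.para] + pi_q[probe.para])


_BENZENE_REF: Optional[float] = None


def charge_descriptor(probe: BenzeneProbe) -> float:
    """Charge-based electronic descriptor of a substituted-benzene probe.

    Total (σ+π) charge on the para ring carbon and its hydrogen, minus the
    same sum in benzene.  Positive values mean electron withdrawal.  Exact
    zero for benzene itself.
    """
    global _BENZENE_REF
    if _BENZENE_REF is None:
        _BENZENE_REF = _para_charge_sum(BenzeneProbe(Chem.Mol(_BENZENE), 0, 3))
    return _para_charge_sum(probe) - _BENZENE_REF


# ---------------------------------------------------------------------------
# calibration onto the σ-para scale


def _pair_descriptor(x) -> float:
    if isinstance(x, (int, float, np.floating)):
        return float(x)
    return charge_descriptor(build_probe(x))


def fit_sigma_calibration(
    training_pairs: Iterable[tuple],
) -> CalibrationModel:
    """Ordinary least squares of experimental σ-para on the charge descriptor.

    Pairs are ``(descriptor, σ_exp)``; the first element may also be a
    substituent (marked SMILES or fragment), in which case the descriptor is
    computed on the fly.
    """
    pairs = [( _pair_descriptor(x), float(y)) for x, y in training_pairs]
    if len(pairs) < 2:
        raise ValueError("calibration needs at least 2 training pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration: all descriptors identical")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_train=len(pairs),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def compute_sigma(substituent, model: CalibrationModel) -> float:
    """σ-para-compatible value: affine map of the charge descriptor."""
    return model.slope * charge_descriptor(build_probe(substituent)) + model.intercept


def evaluate_calibration(
    model: CalibrationModel, reference_pairs: Iterable[tuple]
) -> CalibrationDiagnostics:
    """r² and mean absolute error of the calibrated predictions.

    ``reference_pairs`` are ``(descriptor-or-substituent, σ_exp)`` held-out
    pairs; r² is 1 − SS_res/SS_tot against the reference values.
    """
    pairs = [(_pair_descriptor(x), float(y)) for x, y in reference_pairs]
    if len(pairs) < 2:
        raise ValueError("evaluation needs at least 2 reference pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    pred = model.slope * x + model.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationDiagnostics(
        r_squared=r2, mae=float(np.mean(np.abs(y - pred))), n=len(pairs)
    )


# ---------------------------------------------------------------------------
# packaged reference constants and catalog annotation


def load_reference_table(path: Optional[str] = None) -> pd.DataFrame:
    """Load a calibration table (columns smiles, sigma_para_exp, pi_exp).

    Without a path, the packaged table of textbook σ-para and π constants
    for classic benzene substituents is used.
    """
    # note: '#' appears inside SMILES (triple bonds), so only lines *starting*
    # with '#' are comments; pandas' comment= kwarg would truncate nitriles.
    if path is None:
        ref = resources.files("substispace.data").joinpath("sigma_para_reference.tsv")
        with resources.as_file(ref) as p:
            text = p.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")


def default_calibration(path: Optional[str] = None) -> CalibrationModel:
    """Fit the σ calibration on a reference table (packaged one by default)."""
    table = load_reference_table(path)
    return fit_sigma_calibration(
        (row["smiles"], row["sigma_para_exp"]) for _, row in table.iterrows()
    )


def annotate_catalog(catalog, model: CalibrationModel):
    """Attach a :class:`PropertyVector` to every entry of a catalog.

    Entries whose probe cannot be built (unbondable attachment valence) are
    left unannotated.  Returns the catalog for chaining.
    """
    for entry in catalog:
        try:
            probe = build_probe(entry.fragment)
        except ValueError:
            continue
        pi = logp_atom_contrib(probe.mol) - logp_atom_contrib(_BENZENE)
        sigma = model.slope * charge_descriptor(probe) + model.intercept
        entry.properties = PropertyVector(pi=pi, sigma=sigma)
    return catalog
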