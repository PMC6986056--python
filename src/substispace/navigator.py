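"""Query, rank and select substituents in (π, σ) space; Craig-plot export.

The navigator answers the working questions of bioisosteric design: filter a
catalog by root atom, connection point, size, frequency or property windows;
find the k nearest neighbours of a target substituent; pick property-diverse
subsets; and write the classic Craig plot (π horizontal, σ vertical, origin
cross-hairs) with a machine-readable sidecar table.

Distances are Euclidean in per-axis standardized (π, σ) by default, so the
wide π scale (span ≈ 6 log units) and the narrower σ scale (span ≈ 2) are
commensurate; ``scaling="raw"`` uses the plain units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .catalog import Substituent, SubstituentCatalog
from .properties import CalibrationModel, PropertyVector, build_probe, charge_descriptor, compute_pi

QUADRANT_PP = "π+σ+"
QUADRANT_PM = "π+σ−"
QUADRANT_MP = "π−σ+"
QUADRANT_MM = "π−σ−"
BOUNDARY = "boundary"


@dataclass
class QuerySpec:
    """Conjunctive filter over an annotated catalog.

    Every present field must be satisfied.  ``attachment_filter`` names
    attachment categories; an entry passes when one of the named categories
    reaches ``attachment_min_share`` of its attachment profile, or — when no
    share is given — when its modal attachment category is among the named
    ones.
    """

    root_filter: Optional[set[str]] = None
    attachment_filter: Optional[set[str]] = None
    attachment_min_share: Optional[float] = None
    max_heavy: Optional[int] = None
    min_molecule_freq: Optional[int] = None
    pi_range: Optional[tuple[float, float]] = None
    sigma_range: Optional[tuple[float, float]] = None
    k: Optional[int] = None

    def __post_init__(self):
        for rng in (self.pi_range, self.sigma_range):
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"interval {rng} is not well ordered")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


def _passes(entry: Substituent, query: QuerySpec) -> bool:
    if query.root_filter is not None and entry.root_class not in query.root_filter:
        return False
    if query.max_heavy is not None and entry.heavy_atom_count > query.max_heavy:
        return False
    if (
        query.min_molecule_freq is not None
        and entry.molecule_frequency < query.min_molecule_freq
    ):
        return False
    if query.attachment_filter is not None:
        if query.attachment_min_share is None:
            if entry.attachment_profile.modal_category() not in query.attachment_filter:
                return False
        elif not any(
            entry.attachment_profile.share(cat) >= query.attachment_min_share
            for cat in query.attachment_filter
        ):
            return False
    if query.pi_range is not None or query.sigma_range is not None:
        if entry.properties is None:
            return False
        if query.pi_range is not None and not (
            query.pi_range[0] <= entry.properties.pi <= query.pi_range[1]
        ):
            return False
        if query.sigma_range is not None and not (
            query.sigma_range[0] <= entry.properties.sigma <= query.sigma_range[1]
        ):
            return False
    return True


def filter_catalog(catalog: SubstituentCatalog, query: QuerySpec) -> SubstituentCatalog:
    """Entries satisfying every present filter (idempotent, subset of input)."""
    return catalog.subset(e for e in catalog if _passes(e, query))


# ---------------------------------------------------------------------------
# nearest neighbours


def _axis_scales(entries: Sequence[Substituent]) -> tuple[float, float]:
    pis = np.array([e.properties.pi for e in entries])
    sigmas = np.array([e.properties.sigma for e in entries])
    s_pi = float(pis.std()) or 1.0
    s_sigma = float(sigmas.std()) or 1.0
    return s_pi, s_sigma


def _target_vector(target, model: Optional[CalibrationModel]) -> PropertyVector:
    if isinstance(target, PropertyVector):
        return target
    if isinstance(target, Substituent):
        if target.properties is not None:
            return target.properties
        target = target.fragment
    if model is None:
        raise ValueError(
            "target has no precomputed properties; pass a CalibrationModel "
            "so π and σ can be computed on the fly"
        )
    probe = build_probe(target)
    return PropertyVector(
        pi=compute_pi(target),
        sigma=model.slope * charge_descriptor(probe) + model.intercept,
    )


def _target_smiles(target) -> Optional[str]:
    if isinstance(target, Substituent):
        return target.smiles
    if isinstance(target, str):
        from .chem_io import fragment_from_smiles

        return fragment_from_smiles(target).canonical_form
    if hasattr(target, "canonical_form"):
        return target.canonical_form
    return None


def nearest_bioisosteres(
    catalog: SubstituentCatalog,
    target,
    k: int = 5,
    scaling: str = "standardize",
    include_self: bool = False,
    model: Optional[CalibrationModel] = None,
) -> list[tuple[Substituent, float]]:
    """k catalog entries closest to the target in (π, σ).

    Distances are Euclidean, per-axis standardized by the catalog's standard
    deviations unless ``scaling="raw"``.  Ties break by descending molecule
    frequency, then lexicographic canonical form.  The target itself (same
    canonical form) is excluded unless ``include_self``.
    """
    if scaling not in ("standardize", "raw"):
        raise ValueError(f"unknown scaling {scaling!r}")
    entries = catalog.annotated()
    tvec = _target_vector(target, model)
    tsmiles = _target_smiles(target)
    if not include_self and tsmiles is not None:
        entries = [e for e in entries if e.smiles != tsmiles]
    if not entries:
        return []
    if k > len(entries):
        warnings.warn(
            f"k={k} exceeds catalog size {len(entries)}; returning all entries"
        )
        k = len(entries)
    if scaling == "standardize":
        s_pi, s_sigma = _axis_scales(entries)
    else:
        s_pi = s_sigma = 1.0
    scored = []
    for e in entries:
        d = math.hypot(
            (e.properties.pi - tvec.pi) / s_pi,
            (e.properties.sigma - tvec.sigma) / s_sigma,
        )
        scored.append((d, -e.molecule_frequency, e.smiles, e))
    scored.sort(key=lambda t: t[:3])
    return [(e, d) for d, _nf, _s, e in scored[:k]]


def quadrant_of(vector: PropertyVector) -> str:
    """Craig-plot quadrant by sign of (π, σ); exact zeros are 'boundary'."""
    if not (math.isfinite(vector.pi) and math.isfinite(vector.sigma)):
        raise ValueError("property vector must be finite")
    if vector.pi == 0.0 or vector.sigma == 0.0:
        return BOUNDARY
    if vector.pi > 0:
        return QUADRANT_PP if vector.sigma > 0 else QUADRANT_PM
    return QUADRANT_MP if vector.sigma > 0 else QUADRANT_MM


def diverse_selection(catalog: SubstituentCatalog, n: int) -> list[Substituent]:
    """Max-min selection of n property-diverse substituents.

    Works in standardized (π, σ) and always includes the most frequent
    substituent as the anchor.  Small instances are solved exactly
    (exhaustive max-min over all selections containing the anchor); larger
    ones use the classic greedy farthest-point heuristic, repeatedly adding
    the entry farthest from the current selection.  Ties break by descending
    frequency, then canonical form.
    """
    import itertools

    entries = catalog.annotated()
    if not entries:
        return []
    if n >= len(entries):
        return list(entries)
    s_pi, s_sigma = _axis_scales(entries)
    coords = {
        e.smiles: (e.properties.pi / s_pi, e.properties.sigma / s_sigma)
        for e in entries
    }

    def dist(a: Substituent, b: Substituent) -> float:
        xa, ya = coords[a.smiles]
        xb, yb = coords[b.smiles]
        return math.hypot(xa - xb, ya - yb)

    start = min(entries, key=lambda e: (-e.molecule_frequency, e.smiles))
    rest = sorted(
        (e for e in entries if e.smiles != start.smiles),
        key=lambda e: (-e.molecule_frequency, e.smiles),
    )

    if math.comb(len(rest), n - 1) <= 5000:
        best_combo, best_obj = None, -math.inf
        for combo in itertools.combinations(rest, n - 1):
            sel = (start, *combo)
            obj = min(dist(a, b) for a, b in itertools.combinations(sel, 2))
            if obj > best_obj:
                best_obj, best_combo = obj, sel
        return list(best_combo)

    selected = [start]
    while len(selected) < n and rest:
        best = min(
            rest,
            key=lambda e: (
                -min(dist(e, s) for s in selected),
                -e.molecule_frequency,
                e.smiles,
            ),
        )
        selected.append(best)
        rest.remove(best)
    return selected


def maxmin_objective(
    entries: Sequence[Substituent], s_pi: float = 1.0, s_sigma: float = 1.0
) -> float:
    """Smallest pairwise distance of a selection (the max-min objective)."""
    best = math.inf
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            d = math.hypot(
                (a.properties.pi - b.properties.pi) / s_pi,
                (a.properties.sigma - b.properties.sigma) / s_sigma,
            )
            best = min(best, d)
    return best


# ---------------------------------------------------------------------------
# Craig plot


@dataclass
class CraigPlotData:
    """Points of a Craig plot: label, π (x), σ (y), size encoding, frequency."""

    points: list[tuple[str, float, float, float]] = field(default_factory=list)
    frequencies: list[int] = field(default_factory=list)


def build_craig_plot_data(catalog: SubstituentCatalog) -> CraigPlotData:
    """Plot data for every annotated entry; point size monotone in frequency."""
    entries = catalog.annotated()
    data = CraigPlotData()
    if not entries:
        return data
    freqs = np.array([e.molecule_frequency for e in entries], dtype=float)
    # log-scaled area encoding: strictly monotone in molecule frequency
    sizes = 20.0 + 60.0 * np.log1p(freqs) / max(float(np.log1p(freqs).max()), 1e-12)
    for e, s in zip(entries, sizes):
        if not (math.isfinite(e.properties.pi) and math.isfinite(e.properties.sigma)):
            continue
        data.points.append((e.smiles, e.properties.pi, e.properties.sigma, float(s)))
        data.frequencies.append(e.molecule_frequency)
    return data


def axis_limits(values: Sequence[float]) -> tuple[float, float]:
    """Axis range covering the data with a 5% margin on each side."""
    lo, hi = min(values), max(values)
    span = hi - lo
    pad = 0.05 * span if span > 0 else 0.5
    return lo - pad, hi + pad


def render_craig_plot(
    plot_data: CraigPlotData,
    output_path: Union[str, Path],
    labels: bool = False,
    title: Optional[str] = None,
) -> Path:
    """Write the Craig plot figure plus a sidecar TSV of the plotted points.

    π is on the horizontal axis, σ on the vertical one, with origin
    cross-hairs; axis limits cover the data with at least a 5% margin.  The
    sidecar table (same path, ``.tsv`` suffix) is the machine-readable
    contract: columns label, pi, sigma, size.
    """
    if not plot_data.points:
        raise ValueError("cannot render an empty Craig plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    output_path = Path(output_path)
    labels_, pis, sigmas, sizes = zip(*plot_data.points)
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(pis, sigmas, s=sizes, alpha=0.7, edgecolors="k", linewidths=0.4)
    if labels:
        for lab, x, y, _s in plot_data.points:
            ax.annotate(lab, (x, y), fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlim(*axis_limits(pis))
    ax.set_ylim(*axis_limits(sigmas))
    ax.set_xlabel("π (Hansch–Fujita hydrophobicity)")
    ax.set_ylabel("σ (Hammett-compatible, para)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)

    sidecar = output_path.with_suffix(".tsv")
    with open(sidecar, "w") as fh:
        fh.write("label\tpi\tsigma\tsize\n")
        for lab, x, y, s in plot_data.points:
            fh.write(f"{lab}\t{x!r}\t{y!r}\t{s!r}\n")
    return output_path
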