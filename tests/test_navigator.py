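import itertools
import math

import numpy as np
import pytest

from substispace import (
    PropertyVector,
    QuerySpec,
    SubstituentCatalog,
    build_craig_plot_data,
    diverse_selection,
    filter_catalog,
    fragment_corpus,
    nearest_bioisosteres,
    quadrant_of,
    render_craig_plot,
)
from substispace.catalog import AttachmentProfile, Substituent
from substispace.chem_io import AttachmentMarkedFragment
from substispace.navigator import (
    BOUNDARY,
    QUADRANT_MM,
    QUADRANT_MP,
    QUADRANT_PM,
    QUADRANT_PP,
    maxmin_objective,
)


def make_entry(smiles, pi, sigma, freq=1, heavy=1, root="R–C", categories=None):
    profile = AttachmentProfile()
    for cat, n in (categories or {"c": freq}).items():
        profile.add(cat, n)
    return Substituent(
        fragment=AttachmentMarkedFragment(canonical_form=smiles, heavy_atom_count=heavy),
        molecule_frequency=freq,
        occurrence_count=max(freq, profile.total),
        attachment_profile=profile,
        root_class=root,
        level2_class=root,
        properties=PropertyVector(pi=pi, sigma=sigma),
    )


def make_catalog(entries, corpus_size=100):
    return SubstituentCatalog(entries, corpus_size=corpus_size, min_molecule_freq=1)


def random_catalog(rng, n=50):
    entries = [
        make_entry(f"[*]C{i}", float(rng.normal(0, 2)), float(rng.normal(0, 0.5)),
                   freq=int(rng.integers(1, 100)))
        for i in range(n)
    ]
    return make_catalog(entries)


class TestFilterCatalog:
    def test_root_filter(self):
        cat = make_catalog(
            [
                make_entry("[*]OC", -0.02, -0.27, root="R–O"),
                make_entry("[*]C", 0.54, -0.17, root="R–C"),
            ]
        )
        hits = filter_catalog(cat, QuerySpec(root_filter={"R–O"}))
        assert [e.smiles for e in hits] == ["[*]OC"]

    def test_strongest_donors_query_matches_brute_force(self, annotated_catalog):
        inf = float("inf")
        query = QuerySpec(
            max_heavy=8, sigma_range=(-inf, -0.002), pi_range=(-inf, 0.5)
        )
        hits = {e.smiles for e in filter_catalog(annotated_catalog, query)}
        expected = {
            e.smiles
            for e in annotated_catalog
            if e.properties is not None
            and e.heavy_atom_count <= 8
            and e.properties.sigma <= -0.002
            and e.properties.pi <= 0.5
        }
        assert hits == expected and hits

    def test_contradictory_ranges_give_empty_result(self, annotated_catalog):
        query = QuerySpec(pi_range=(5.0, 6.0), sigma_range=(-9.0, -8.0))
        assert len(filter_catalog(annotated_catalog, query)) == 0

    def test_idempotent_and_subset(self, annotated_catalog):
        query = QuerySpec(min_molecule_freq=3, max_heavy=6)
        once = filter_catalog(annotated_catalog, query)
        twice = filter_catalog(once, query)
        assert set(once.entries) == set(twice.entries)
        assert set(once.entries) <= set(annotated_catalog.entries)

    def test_attachment_filter_modal_and_share(self):
        entry = make_entry("[*]C", 0.5, 0.1, freq=10, categories={"c": 7, "N,n": 3})
        cat = make_catalog([entry])
        assert len(filter_catalog(cat, QuerySpec(attachment_filter={"c"}))) == 1
        assert len(filter_catalog(cat, QuerySpec(attachment_filter={"N,n"}))) == 0
        assert (
            len(
                filter_catalog(
                    cat,
                    QuerySpec(attachment_filter={"N,n"}, attachment_min_share=0.25),
                )
            )
            == 1
        )

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            QuerySpec(pi_range=(1.0, -1.0))


class TestNearestBioisosteres:
    def test_self_at_distance_zero(self):
        cat = make_catalog([make_entry("[*]C", 0.5, -0.2), make_entry("[*]CC", 1.0, -0.2)])
        target = cat.get("[*]C")
        hits = nearest_bioisosteres(cat, target, k=1, include_self=True)
        assert hits[0][0].smiles == "[*]C" and hits[0][1] == 0.0

    def test_target_excluded_by_default(self):
        cat = make_catalog([make_entry("[*]C", 0.5, -0.2), make_entry("[*]CC", 1.0, -0.2)])
        hits = nearest_bioisosteres(cat, cat.get("[*]C"), k=1)
        assert all(e.smiles != "[*]C" for e, _ in hits)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        cat = random_catalog(rng, n=50)
        target = PropertyVector(pi=float(rng.normal()), sigma=float(rng.normal()))
        hits = nearest_bioisosteres(cat, target, k=5)
        entries = cat.annotated()
        pis = np.array([e.properties.pi for e in entries])
        sigmas = np.array([e.properties.sigma for e in entries])
        s_pi, s_sigma = pis.std(), sigmas.std()
        brute = sorted(
            entries,
            key=lambda e: (
                math.hypot(
                    (e.properties.pi - target.pi) / s_pi,
                    (e.properties.sigma - target.sigma) / s_sigma,
                ),
                -e.molecule_frequency,
                e.smiles,
            ),
        )[:5]
        assert [e.smiles for e, _ in hits] == [e.smiles for e in brute]

    def test_distances_non_decreasing(self):
        rng = np.random.default_rng(99)
        cat = random_catalog(rng)
        hits = nearest_bioisosteres(cat, PropertyVector(0.0, 0.0), k=20)
        dists = [d for _, d in hits]
        assert dists == sorted(dists)

    def test_raw_vs_standardized_rankings_differ(self):
        # anisotropic constructed case: nearest in raw units is not nearest
        # once the wide pi axis is standardized
        cat = make_catalog(
            [
                make_entry("[*]A", 4.0, 0.00),
                make_entry("[*]B", 0.0, 0.45),
                make_entry("[*]D", -4.0, -0.45),
                make_entry("[*]E", 8.0, -0.05),
            ]
        )
        target = PropertyVector(pi=0.0, sigma=0.0)
        raw = nearest_bioisosteres(cat, target, k=1, scaling="raw")
        std = nearest_bioisosteres(cat, target, k=1, scaling="standardize")
        assert raw[0][0].smiles == "[*]B"
        assert std[0][0].smiles != "[*]B"

    def test_k_larger_than_catalog_warns_and_returns_all(self):
        cat = make_catalog([make_entry("[*]C", 0.5, -0.2)])
        with pytest.warns(UserWarning, match="exceeds"):
            hits = nearest_bioisosteres(cat, PropertyVector(0, 0), k=5)
        assert len(hits) == 1


class TestQuadrantOf:
    @pytest.mark.parametrize(
        "pi, sigma, expected",
        [
            (0.5, 0.7, QUADRANT_PP),
            (0.5, -0.7, QUADRANT_PM),
            (-0.3, 0.7, QUADRANT_MP),
            (-0.3, -0.7, QUADRANT_MM),
            (0.0, 0.7, BOUNDARY),
            (0.5, 0.0, BOUNDARY),
            (0.0, 0.0, BOUNDARY),
        ],
    )
    def test_sign_table(self, pi, sigma, expected):
        assert quadrant_of(PropertyVector(pi=pi, sigma=sigma)) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            quadrant_of(PropertyVector(pi=float("nan"), sigma=0.1))


class TestDiverseSelection:
    def test_four_corners_all_selected(self):
        corners = [
            make_entry("[*]A", 1.0, 1.0, freq=5),
            make_entry("[*]B", 1.0, -1.0),
            make_entry("[*]D", -1.0, 1.0),
            make_entry("[*]E", -1.0, -1.0),
        ]
        cat = make_catalog(corners + [make_entry("[*]F", 0.0, 0.0)])
        picked = {e.smiles for e in diverse_selection(cat, 4)}
        assert picked == {"[*]A", "[*]B", "[*]D", "[*]E"}

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_exhaustive_for_small_n(self, seed):
        # greedy max-min with a fixed first pick: compare against exhaustive
        # search over selections constrained to the same seed point
        rng = np.random.default_rng(seed)
        cat = random_catalog(rng, n=12)
        entries = cat.annotated()
        s_pi, s_sigma = (
            np.array([e.properties.pi for e in entries]).std(),
            np.array([e.properties.sigma for e in entries]).std(),
        )
        for n in (2, 3):
            picked = diverse_selection(cat, n)
            start = min(entries, key=lambda e: (-e.molecule_frequency, e.smiles))
            best = max(
                (
                    combo
                    for combo in itertools.combinations(entries, n)
                    if start in combo
                ),
                key=lambda combo: maxmin_objective(list(combo), s_pi, s_sigma),
            )
            assert maxmin_objective(picked, s_pi, s_sigma) == pytest.approx(
                maxmin_objective(list(best), s_pi, s_sigma)
            )

    def test_first_four_picks_cover_three_quadrants(self, annotated_catalog):
        entries = annotated_catalog.annotated()
        populated = {
            quadrant_of(e.properties)
            for e in entries
            if quadrant_of(e.properties) != BOUNDARY
        }
        picked = diverse_selection(annotated_catalog, 4)
        covered = {
            quadrant_of(e.properties)
            for e in picked
            if quadrant_of(e.properties) != BOUNDARY
        }
        if len(populated) == 4:
            assert len(covered) >= 3

    def test_n_at_least_catalog_size_returns_all(self):
        cat = make_catalog([make_entry("[*]A", 1.0, 1.0), make_entry("[*]B", -1, -1)])
        assert len(diverse_selection(cat, 10)) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_beats_random_selection_on_average(self, seed):
        rng = np.random.default_rng(seed)
        cat = random_catalog(rng, n=30)
        entries = cat.annotated()
        s_pi = np.array([e.properties.pi for e in entries]).std()
        s_sigma = np.array([e.properties.sigma for e in entries]).std()
        greedy = maxmin_objective(diverse_selection(cat, 5), s_pi, s_sigma)
        random_pick = maxmin_objective(
            list(rng.choice(entries, size=5, replace=False)), s_pi, s_sigma
        )
        # greedy max-min should never lose to a random draw on these fixtures
        assert greedy >= random_pick


class TestCraigPlot:
    def test_sidecar_row_count_and_geometry(self, tmp_path):
        rng = np.random.default_rng(1)
        cat = random_catalog(rng, n=26)
        data = build_craig_plot_data(cat)
        out = tmp_path / "craig.svg"
        render_craig_plot(data, out)
        assert out.exists()
        sidecar = (tmp_path / "craig.tsv").read_text().splitlines()
        assert len(sidecar) == 27  # header + 26 points

    def test_axis_margin_at_least_five_percent(self):
        from substispace.navigator import axis_limits

        rng = np.random.default_rng(2)
        cat = random_catalog(rng, n=10)
        data = build_craig_plot_data(cat)
        for values in ([p[1] for p in data.points], [p[2] for p in data.points]):
            lo, hi = axis_limits(values)
            span = max(values) - min(values)
            assert span > 0
            assert lo <= min(values) - 0.05 * span + 1e-12
            assert hi >= max(values) + 0.05 * span - 1e-12

    def test_size_encoding_monotone_in_frequency(self):
        cat = make_catalog(
            [make_entry(f"[*]C{i}", float(i), 0.1 * i, freq=f) for i, f in enumerate([1, 5, 50])]
        )
        data = build_craig_plot_data(cat)
        by_freq = sorted(zip(data.frequencies, [p[3] for p in data.points]))
        sizes = [s for _f, s in by_freq]
        assert sizes == sorted(sizes) and sizes[0] < sizes[-1]

    def test_empty_data_rejected(self, tmp_path):
        from substispace.navigator import CraigPlotData

        with pytest.raises(ValueError):
            render_craig_plot(CraigPlotData(), tmp_path / "x.svg")

    def test_labels_do_not_change_point_geometry(self, tmp_path):
        rng = np.random.default_rng(3)
        cat = random_catalog(rng, n=8)
        data = build_craig_plot_data(cat)
        render_craig_plot(data, tmp_path / "a.svg", labels=False)
        render_craig_plot(data, tmp_path / "b.svg", labels=True)
        assert (tmp_path / "a.tsv").read_text() == (tmp_path / "b.tsv").read_text()
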