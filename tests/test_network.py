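"""Modified cosine and molecular-network construction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from saponet.network import (
    build_network,
    export_graphml,
    modified_cosine,
    read_graphml,
)
from saponet.simulate import SimConfig, simulate_cohort
from saponet.spectra import CLASS_LABELS, Peak, Spectrum


def _flat(sid, precursor, mzs):
    return Spectrum(id=sid, precursor_mz=precursor, rt=None,
                    peaks=[Peak(mz) for mz in mzs])


class TestModifiedCosine:
    def test_self_similarity_is_exactly_one(self):
        s = _flat("a", 945.55, [459.38, 621.44, 783.49, 945.55])
        score, n = modified_cosine(s, s)
        assert score == 1.0
        assert n == len(s)

    def test_disjoint_spectra_score_zero_without_shift(self):
        a = _flat("a", 900.0, [200.0, 300.0, 400.0])
        b = _flat("b", 901.0, [250.0, 350.0, 450.0])
        assert modified_cosine(a, b, precursor_shift=False) == (0.0, 0)

    def test_flat_intensity_closed_form(self):
        # 3 shared ions out of 4 unit-intensity peaks each: 3/sqrt(16)
        a = _flat("a", 945.54, [459.3838, 621.4366, 783.4894, 945.5423])
        b = _flat("b", 1107.60, [459.3838, 621.4366, 783.4894, 1107.5951])
        score, n = modified_cosine(a, b, precursor_shift=False)
        assert n == 3
        assert score == pytest.approx(0.75, abs=1e-12)

    def test_empty_spectrum_scores_zero(self):
        a = _flat("a", 900.0, [200.0])
        b = Spectrum(id="b", precursor_mz=500.0, peaks=[])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_precursor_shift_links_precursor_offset_analogs(self):
        # every peak of b sits exactly one precursor difference above a's:
        # nothing matches directly, everything matches under the shift
        a = _flat("a", 700.0, [300.0, 450.0, 600.0])
        b = _flat("b", 800.0, [400.0, 550.0, 700.0])
        score_direct, n_direct = modified_cosine(a, b, precursor_shift=False)
        score_shift, n_shift = modified_cosine(a, b, precursor_shift=True)
        assert (score_direct, n_direct) == (0.0, 0)
        assert n_shift == 3
        assert score_shift == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=100, max_value=1900), min_size=1, max_size=6),
        st.lists(st.floats(min_value=100, max_value=1900), min_size=1, max_size=6),
        st.booleans(),
    )
    def test_symmetry_and_bounds(self, mzs_a, mzs_b, shift):
        a = _flat("a", 1950.0, mzs_a)
        b = _flat("b", 1960.0, mzs_b)
        s_ab, n_ab = modified_cosine(a, b, precursor_shift=shift)
        s_ba, n_ba = modified_cosine(b, a, precursor_shift=shift)
        assert abs(s_ab - s_ba) <= 1e-12
        assert n_ab == n_ba
        assert 0.0 <= s_ab <= 1.0 + 1e-12

    def test_greedy_never_exceeds_optimal_assignment(self):
        # exhaustive oracle: maximum-weight one-to-one matching over the
        # admissible peak pairs via linear_sum_assignment
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(17)
        tol = 0.02
        for _ in range(50):
            na, nb = rng.integers(1, 6), rng.integers(1, 6)
            mzs_a = np.sort(rng.uniform(100, 1000, na))
            mzs_b = np.sort(rng.uniform(100, 1000, nb))
            ia = rng.uniform(0.2, 1.0, na)
            ib = rng.uniform(0.2, 1.0, nb)
            # force some admissible pairs
            if rng.random() < 0.8:
                mzs_b[0] = mzs_a[0] + rng.normal(0, 0.01)
                mzs_b = np.sort(mzs_b)
            a = Spectrum(id="a", precursor_mz=1100.0,
                         peaks=[Peak(m, i) for m, i in zip(mzs_a, ia)])
            b = Spectrum(id="b", precursor_mz=1100.0,
                         peaks=[Peak(m, i) for m, i in zip(mzs_b, ib)])
            weights = np.zeros((len(a), len(b)))
            for i, pa in enumerate(a.peaks):
                for j, pb in enumerate(b.peaks):
                    if abs(pa.mz - pb.mz) <= tol:
                        weights[i, j] = pa.intensity * pb.intensity
            rows, cols = linear_sum_assignment(-weights)
            norm = math.sqrt(
                sum(p.intensity**2 for p in a.peaks)
                * sum(p.intensity**2 for p in b.peaks)
            )
            optimal = weights[rows, cols].sum() / norm
            greedy, _ = modified_cosine(a, b, frag_tol=tol, precursor_shift=False)
            assert greedy <= optimal + 1e-9

    def test_cross_check_against_matchms(self):
        import matchms
        from matchms.similarity import ModifiedCosine

        cohort = simulate_cohort(["PPD"], 4, SimConfig(seed=2))

        def to_matchms(s):
            return matchms.Spectrum(
                mz=np.array(s.mzs),
                intensities=np.array(s.intensities),
                metadata={"precursor_mz": s.precursor_mz},
                metadata_harmonization=False,
            )

        scorer = ModifiedCosine(tolerance=0.02)
        for i in range(len(cohort)):
            for j in range(i + 1, len(cohort)):
                ours, n_ours = modified_cosine(
                    cohort[i], cohort[j], frag_tol=0.02, precursor_shift=True
                )
                theirs = scorer.pair(to_matchms(cohort[i]), to_matchms(cohort[j]))
                assert ours == pytest.approx(float(theirs["score"]), abs=1e-6)
                assert n_ours == int(theirs["matches"])


class TestBuildNetwork:
    def test_single_spectrum(self):
        s = _flat("only", 900.0, [400.0, 500.0])
        net = build_network([s])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.clusters == [["only"]]

    def test_threshold_above_one_gives_singletons(self):
        cohort = simulate_cohort(["PPD", "PPT"], 3, SimConfig(seed=4))
        net = build_network(cohort, score_threshold=1.01)
        assert net.graph.number_of_edges() == 0
        assert len(net.clusters) == len(cohort)

    def test_six_class_cohort_separates_into_pure_regions(self):
        cohort = simulate_cohort(list(CLASS_LABELS), 3, SimConfig(seed=6))
        net = build_network(cohort)
        assert len(net.clusters) == 6
        label = {s.id: s.metadata["class"] for s in cohort}
        for cluster in net.clusters:
            assert len({label[n] for n in cluster}) == 1

    def test_duplicate_ids_rejected(self):
        s = _flat("x", 900.0, [400.0])
        with pytest.raises(ValueError, match="unique"):
            build_network([s, s])

    def test_edge_attributes_respect_thresholds(self):
        cohort = simulate_cohort(["PPD"], 5, SimConfig(seed=8))
        net = build_network(cohort, score_threshold=0.7, min_matched=3)
        assert net.graph.number_of_edges() > 0
        for _, _, data in net.graph.edges(data=True):
            assert data["score"] >= 0.7
            assert data["n_matched"] >= 3


class TestGraphML:
    def test_round_trip_preserves_counts(self, tmp_path):
        cohort = simulate_cohort(list(CLASS_LABELS), 3, SimConfig(seed=6))
        net = build_network(cohort)
        path = export_graphml(net, tmp_path / "net.graphml")
        back = read_graphml(path)
        assert back.graph.number_of_nodes() == net.graph.number_of_nodes()
        assert back.graph.number_of_edges() == net.graph.number_of_edges()
        assert len(back.clusters) == len(net.clusters)

    def test_empty_edge_network_exports_nodes_only(self, tmp_path):
        s = _flat("solo", 900.0, [400.0, 410.0])
        net = build_network([s])
        path = export_graphml(net, tmp_path / "solo.graphml")
        back = read_graphml(path)
        assert back.graph.number_of_nodes() == 1
        assert back.graph.number_of_edges() == 0
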