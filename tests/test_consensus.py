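"""Strong-edge extraction and consensus logic on the published edge lists."""

import pytest
from hypothesis import given, settings, strategies as st

from trpnet import published as pub
from trpnet.bn import StrengthTable
from trpnet.consensus import (
    cross_method_consensus,
    percent,
    possible_pairs,
    reproducible_edges,
    sign_flips,
    strong_edges_bn,
    strong_edges_ggm,
    summarize,
)
from trpnet.edges import EdgeSet, Provenance, canonical


class TestStrongEdgesGGM:
    def test_published_male_baseline_all_retained(self):
        """All six reported strong edges survive the 0.3 cutoff, including
        the negative picolinic--anthranilic edge (cutoff is on |pcor|)."""
        weights = pub.GGM_ADJUSTED_STRONG[("male", "baseline")]
        es = strong_edges_ggm(weights, threshold=0.3)
        assert len(es) == 6
        assert (pub.PIC, pub.ANT) in es
        assert es.weight((pub.PIC, pub.ANT)) == -0.31

    def test_threshold_is_inclusive_at_point_three(self):
        weights = pub.GGM_ADJUSTED_STRONG[("female", "followup")]
        es = strong_edges_ggm(weights, threshold=0.3)
        assert (pub.XA, pub.HIAA) in es  # reported at exactly r = .3

    def test_all_zero_network_empty(self):
        assert len(strong_edges_ggm({}, threshold=0.3)) == 0

    def test_covariate_pairs_filtered(self):
        weights = {("birth-weight", "birth-length"): 0.9, ("a", "b"): 0.5}
        es = strong_edges_ggm(weights, 0.3, metabolite_names=["a", "b"])
        assert len(es) == 1 and ("a", "b") in es


class TestStrongEdgesBN:
    def test_inclusive_at_085(self):
        strengths = {("A", "B"): 1.0, ("C", "D"): 0.85, ("E", "F"): 0.84}
        es = strong_edges_bn(strengths, threshold=0.85)
        assert es.edges == {("A", "B"), ("C", "D")}

    def test_zero_strengths_empty(self):
        assert len(strong_edges_bn({("A", "B"): 0.0}, 0.85)) == 0

    def test_unanimous_only_at_one(self):
        strengths = {("A", "B"): 1.0, ("C", "D"): 0.999}
        assert strong_edges_bn(strengths, threshold=1.0).edges == {("A", "B")}

    def test_accepts_strength_table(self):
        table = StrengthTable(
            names=("A", "B", "C"),
            strength={("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.85},
            direction={("A", "B"): 1.0, ("A", "C"): 0.0, ("B", "C"): 0.5},
            B=100,
        )
        assert strong_edges_bn(table).edges == {("A", "B"), ("B", "C")}


class TestTemporalReproducibility:
    def test_published_male_ggm_three_edges(self):
        rep = reproducible_edges(
            pub.ggm_strong_edges("male", "baseline"),
            pub.ggm_strong_edges("male", "followup"),
        )
        assert rep.edges == {
            canonical(pub.IAM, pub.IAA),
            canonical(pub.TRP, pub.KYN),
            canonical(pub.KYNA, pub.XA),
        }
        # weights become (baseline, followup) pairs
        assert rep.weight((pub.TRP, pub.KYN)) == (0.42, 0.31)

    def test_published_female_ggm_three_edges(self):
        rep = reproducible_edges(
            pub.ggm_strong_edges("female", "baseline"),
            pub.ggm_strong_edges("female", "followup"),
        )
        assert rep.edges == {
            canonical(pub.KYNA, pub.IAA),
            canonical(pub.KYN, pub.HK),
            canonical(pub.HK, pub.HAA),
        }

    def test_published_male_bn_two_edges(self):
        rep = reproducible_edges(
            pub.bn_strong_edges("male", "baseline"),
            pub.bn_strong_edges("male", "followup"),
        )
        assert rep.edges == {
            canonical(pub.TRP, pub.KYN),
            canonical(pub.KYNA, pub.XA),
        }

    def test_published_female_bn_seven_edges(self):
        rep = reproducible_edges(
            pub.bn_strong_edges("female", "baseline"),
            pub.bn_strong_edges("female", "followup"),
        )
        assert len(rep) == 7
        assert canonical(pub.TRP, pub.KYN) in rep

    def test_disjoint_sets_empty(self):
        a = EdgeSet.from_pairs([("A", "B")])
        b = EdgeSet.from_pairs([("C", "D")])
        assert len(reproducible_edges(a, b)) == 0

    def test_provenance_mismatch_rejected(self):
        a = EdgeSet.from_pairs([("A", "B")], Provenance(method="ggm", sex="male"))
        b = EdgeSet.from_pairs([("A", "B")], Provenance(method="bn", sex="male"))
        with pytest.raises(ValueError, match="provenance"):
            reproducible_edges(a, b)

    def test_sign_flip_flagged_not_dropped(self):
        base = EdgeSet.from_pairs({("A", "B"): 0.4})
        follow = EdgeSet.from_pairs({("A", "B"): -0.31})
        rep = reproducible_edges(base, follow)
        assert ("A", "B") in rep
        assert sign_flips(rep) == [("A", "B")]


class TestCrossMethodConsensus:
    def test_published_male_two(self):
        ggm_rep = reproducible_edges(
            pub.ggm_strong_edges("male", "baseline"),
            pub.ggm_strong_edges("male", "followup"),
        )
        bn_rep = reproducible_edges(
            pub.bn_strong_edges("male", "baseline"),
            pub.bn_strong_edges("male", "followup"),
        )
        consensus = cross_method_consensus(ggm_rep, bn_rep)
        assert consensus.edges == {
            canonical(pub.TRP, pub.KYN),
            canonical(pub.KYNA, pub.XA),
        }

    def test_published_female_three(self):
        ggm_rep = reproducible_edges(
            pub.ggm_strong_edges("female", "baseline"),
            pub.ggm_strong_edges("female", "followup"),
        )
        bn_rep = reproducible_edges(
            pub.bn_strong_edges("female", "baseline"),
            pub.bn_strong_edges("female", "followup"),
        )
        consensus = cross_method_consensus(ggm_rep, bn_rep)
        assert consensus.edges == {
            canonical(pub.KYNA, pub.IAA),
            canonical(pub.KYN, pub.HK),
            canonical(pub.HK, pub.HAA),
        }

    def test_empty_input_empty_output(self):
        a = EdgeSet.from_pairs([])
        b = EdgeSet.from_pairs([("A", "B")])
        assert len(cross_method_consensus(a, b)) == 0

    def test_sex_mismatch_rejected(self):
        a = EdgeSet.from_pairs([("A", "B")], Provenance(sex="male"))
        b = EdgeSet.from_pairs([("A", "B")], Provenance(sex="female"))
        with pytest.raises(ValueError, match="sex"):
            cross_method_consensus(a, b)

    @given(
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=15),
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=15),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_intersections_are_subsets(self, pa, pb):
        def mk(pairs):
            return EdgeSet.from_pairs(
                [(f"v{i}", f"v{j}") for i, j in pairs if i != j]
            )

        a, b = mk(pa), mk(pb)
        rep = reproducible_edges(a, b)
        assert rep.edges <= a.edges and rep.edges <= b.edges
        cons = cross_method_consensus(rep, b)
        assert cons.edges <= rep.edges


class TestSummarize:
    def test_pair_arithmetic(self):
        assert possible_pairs(19) == 171

    @pytest.mark.parametrize(
        "count,total,expected",
        [(7, 171, 4.1), (4, 171, 2.3), (7, 82, 8.5), (0, 171, 0.0)],
    )
    def test_percent_round_half_up(self, count, total, expected):
        assert percent(count, total) == expected

    def _published_report(self):
        ggm_rep, bn_rep = {}, {}
        for sex in ("male", "female"):
            ggm_rep[sex] = reproducible_edges(
                pub.ggm_strong_edges(sex, "baseline"),
                pub.ggm_strong_edges(sex, "followup"),
            )
            bn_rep[sex] = reproducible_edges(
                pub.bn_strong_edges(sex, "baseline"),
                pub.bn_strong_edges(sex, "followup"),
            )
        return summarize(
            ggm_rep,
            bn_rep,
            n_metabolites=19,
            strong_counts={
                sex: {"ggm_baseline": pub.BASELINE_STRONG_EDGES[sex]}
                for sex in ("male", "female")
            },
            nonzero_counts=pub.BASELINE_NONZERO_EDGES,
        )

    def test_published_consensus_report(self):
        report = self._published_report()
        assert report.total_possible_pairs == 171
        assert report.consensus_counts == {"male": 2, "female": 3}
        assert report.overall_consensus_count == 5
        assert len(report.metabolite_panel) == 7
        assert set(report.metabolite_panel) == {
            pub.TRP, pub.KYN, pub.KYNA, pub.XA, pub.HK, pub.HAA, pub.IAA,
        }
        assert report.strong_percent_of_possible("male") == 4.1
        assert report.strong_percent_of_possible("female") == 2.3
        assert report.strong_percent_of_nonzero("male") == 8.5

    def test_report_serialization(self, tmp_path):
        report = self._published_report()
        payload = report.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").exists()
        assert '"overall_consensus_count": 5' in payload
        df = report.consensus_frame()
        assert len(df) == 5 and set(df.sex) == {"male", "female"}
        assert "consensus" in report.summary()
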