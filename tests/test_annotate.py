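"""Site localization, consensus voting, rank tests, annotation output."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, rankdata

from archaeoprom.annclf import TrainConfig, featurize_set, train_rprop
from archaeoprom.annotate import (
    AnnotationCall,
    consensus_call,
    kruskal_wallis,
    locate_site,
    profile_compare,
    write_annotation,
)
from archaeoprom.corpus import PromoterRecord, control_shuffle
from archaeoprom.statclf import SliceSpec, fit_interval
from archaeoprom.synthfix import SynthSpec, generate_promoters


def upstream_with_tata(pos_coord=-40, length=400):
    """GC background with one embedded TTATAAAA at a known coordinate."""
    seq = "GC" * (length // 2)
    idx = (length - 1) + pos_coord  # coord_rank(p<0) = p; 3' end is +1
    return seq[:idx] + "TTATAAAA" + seq[idx + 8:]


@pytest.fixture(scope="module")
def trained_models(table):
    pos = generate_promoters(SynthSpec(n=150, rng_seed=71))
    neg = [control_shuffle(r, 7100 + i) for i, r in enumerate(pos)]
    spec = SliceSpec()
    stat = fit_interval(pos, spec, table, organism_tag="synthA")
    X = featurize_set(pos + neg, spec, table)
    y = np.array([1] * 150 + [0] * 150)
    ann = train_rprop(X, y, TrainConfig(rng_seed=72, max_steps=20000),
                      slice_spec=spec, tag="synthA")
    return stat, ann


class TestLocateSite:
    def test_unique_embedded_maximum(self, table):
        assert locate_site(upstream_with_tata(-40), table) == -40

    def test_homopolymer_tie_breaks_tss_proximal(self, table):
        # all windows equal; the most TSS-proximal start wins (-22 keeps
        # the 8-nt slice inside the default -50..-15 region)
        assert locate_site("A" * 400, table) == -22

    def test_region_of_exactly_slice_width(self, table):
        assert locate_site("A" * 400, table,
                           search_region=(-40, -33)) == -40

    def test_invariant_to_content_outside_region(self, table):
        a = upstream_with_tata(-40)
        # default search region -50..-15 touches 0-based indices 349..384
        b = "T" * 349 + a[349:385] + "T" * 15
        assert locate_site(a, table) == locate_site(b, table) == -40

    def test_region_shorter_than_slice_rejected(self, table):
        with pytest.raises(ValueError, match="shorter"):
            locate_site("A" * 400, table, search_region=(-20, -15))


class TestConsensus:
    def test_all_votes_promoter_accepts(self, table, trained_models):
        stat, ann = trained_models
        ups = generate_promoters(
            SynthSpec(n=30, length_nt=400, anchor=-399, rng_seed=80))
        calls = [consensus_call(r, [stat, ann], table) for r in ups]
        for c in calls:
            votes = set(c.per_model_votes.values())
            if votes == {"promoter"}:
                assert c.final == "promoter"
            else:
                assert c.final == "non_promoter"

    def test_single_model_reduces_to_classifier(self, table, trained_models):
        stat, _ = trained_models
        ups = generate_promoters(
            SynthSpec(n=20, length_nt=400, anchor=-399, rng_seed=81))
        for r in ups:
            c = consensus_call(r, [stat], table)
            assert c.final == list(c.per_model_votes.values())[0]

    def test_adding_model_only_shrinks_accepted_set(self, table, trained_models):
        stat, ann = trained_models
        ups = generate_promoters(
            SynthSpec(n=40, length_nt=400, anchor=-399, rng_seed=82))
        small = {r.id for r in ups
                 if consensus_call(r, [ann], table).final == "promoter"}
        large = {r.id for r in ups
                 if consensus_call(r, [ann, stat], table).final == "promoter"}
        assert large <= small

    def test_empty_model_list_rejected(self, table):
        with pytest.raises(ValueError, match="at least one"):
            consensus_call("A" * 400, [], table)

    def test_scan_mode_evaluates_located_site(self, table, trained_models):
        stat, _ = trained_models
        c = consensus_call(upstream_with_tata(-40), [stat], table, mode="scan")
        assert c.candidate_site == -40


def kw_bruteforce(groups):
    """Independent midrank Kruskal-Wallis with tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = rankdata(pooled)
    start, rsums = 0, []
    for g in groups:
        rsums.append(ranks[start:start + len(g)].sum())
        start += len(g)
    H = 12.0 / (N * (N + 1)) * sum(
        r * r / len(g) for r, g in zip(rsums, groups)) - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    C = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if C == 0:
        return 0.0, 1.0
    H /= C
    return H, chi2.sf(H, len(groups) - 1)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            H, p = kruskal_wallis([[1, 1], [1, 1]])
        assert (H, p) == (0.0, 1.0)

    def test_two_separated_groups(self):
        H, p = kruskal_wallis([[1, 2, 3], [101, 102, 103]])
        assert H == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            kruskal_wallis([[1, 2], []])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([[1, 2, 3]])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(0, 3), min_size=1, max_size=4),
        min_size=2, max_size=3,
    ).filter(lambda gs: sum(len(g) for g in gs) <= 8))
    def test_matches_bruteforce_rank_oracle(self, groups):
        expect_H, expect_p = kw_bruteforce([np.array(g, float) for g in groups])
        pooled = [v for g in groups for v in g]
        if len(set(pooled)) == 1:
            with pytest.warns(UserWarning):
                H, p = kruskal_wallis(groups)
        else:
            H, p = kruskal_wallis(groups)
        assert H == pytest.approx(expect_H, abs=1e-10)
        assert p == pytest.approx(expect_p, abs=1e-10)


class TestProfileCompare:
    def test_set_against_itself_degenerate(self, table):
        # identical groups tie rank-for-rank, so H collapses to 0 exactly
        pos = generate_promoters(SynthSpec(n=20, rng_seed=90))
        out = profile_compare({"a": pos}, {"b": pos}, table, (-40, -1))
        assert out["H"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_same_generator_family_null(self, table):
        a = generate_promoters(SynthSpec(n=200, rng_seed=91))
        b = generate_promoters(SynthSpec(n=200, rng_seed=92))
        out = profile_compare({"a": a}, {"b": b}, table, (-40, -1))
        assert out["p"] > 0.01

    def test_region_outside_profile_rejected(self, table):
        pos = generate_promoters(SynthSpec(n=5, rng_seed=93))
        with pytest.raises(ValueError, match="outside"):
            profile_compare({"a": pos}, {}, table, (-120, -90))


class TestWriteAnnotation:
    def make_calls(self):
        return [
            AnnotationCall("g1", -32, {"stat:A": "promoter"}, "promoter",
                           -6.0, {}, seq_len=400, slice_width=8),
            AnnotationCall("g2", -32, {"stat:A": "non_promoter"},
                           "non_promoter", -11.0, {}, seq_len=400,
                           slice_width=8),
        ]

    def test_tsv_row_count(self, tmp_path):
        p = tmp_path / "calls.tsv"
        write_annotation(self.make_calls(), p, "tsv")
        lines = p.read_text().splitlines()
        assert len(lines) == 3  # header + 2 calls
        assert lines[0].startswith("id\tfinal\tsite\tstatistic")

    def test_gff3_structure(self, tmp_path):
        p = tmp_path / "calls.gff3"
        write_annotation(self.make_calls(), p, "gff3")
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        rows = lines[1:]
        assert len(rows) == 1  # only the accepted promoter
        cols = rows[0].split("\t")
        assert len(cols) == 9
        assert cols[2] == "promoter"
        # slice -32..-25 on a 400-nt region, 3' end = +1
        assert (cols[3], cols[4]) == ("368", "375")

    def test_zero_accepted_calls_header_only(self, tmp_path):
        p = tmp_path / "none.gff3"
        write_annotation([self.make_calls()[1]], p, "gff3")
        assert p.read_text() == "##gff-version 3\n"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_annotation([], tmp_path / "x", "bed")
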