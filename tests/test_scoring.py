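"""Per-allele fractions, genotype scores, totals, and the severity classifier."""

import pytest
from hypothesis import given, settings, strategies as st

from crb1kit import (
    DomainError,
    Phenotype,
    ScoringConfig,
    ScoringError,
    allele_pathogenic_fraction,
    classify_phenotype,
    expression_retained_fraction,
    genotype_isoform_scores,
    missense_damaging_fraction,
    splice_impact_fraction,
    total_pathogenicity,
)
from crb1kit.model import SpliceToken
from crb1kit.scoring import ISOFORMS, IsoformScoreSet

from conftest import make_variant


class TestFractions:
    @pytest.mark.parametrize(
        "consequence, expected",
        [("truncating", 0.0), ("splice_site", 0.05), ("missense", 1.0), ("in_frame", 1.0)],
    )
    def test_expression_retention(self, default_cfg, consequence, expected):
        assert expression_retained_fraction(consequence, default_cfg) == expected

    @pytest.mark.parametrize(
        "d, expected",
        [(6, 0.5), (10, 0.5), (11, 0.7), (12, 0.7), (13, 0.8), (14, 0.8),
         (3, 0.0), (0, 0.0), (15, 0.8)],
    )
    def test_damaging_bins(self, default_cfg, d, expected):
        assert missense_damaging_fraction(d, default_cfg) == expected

    def test_negative_damaging_count(self, default_cfg):
        with pytest.raises(DomainError):
            missense_damaging_fraction(-1, default_cfg)

    @pytest.mark.parametrize(
        "tokens, expected",
        [
            ((SpliceToken(2, "gain"),), 0.4),
            ((SpliceToken(4, "loss"),), 0.8),
            ((SpliceToken(1, "gain"),), 0.2),
            ((), 0.0),
        ],
    )
    def test_splice_impact(self, default_cfg, tokens, expected):
        assert splice_impact_fraction(tokens, default_cfg) == pytest.approx(expected)

    def test_splice_impact_tool_count_capped(self, default_cfg):
        with pytest.raises(DomainError):
            splice_impact_fraction(
                (SpliceToken(3, "gain"), SpliceToken(3, "loss")), default_cfg
            )


class TestAlleleFraction:
    def test_wild_type_allele(self, default_cfg):
        impact = allele_pathogenic_fraction([], default_cfg)
        assert impact.pathogenic_fraction == 0.0
        assert impact.retained_expression_fraction == 1.0

    def test_truncating_is_total_loss(self, default_cfg):
        impact = allele_pathogenic_fraction(
            [make_variant(2, "truncating")], default_cfg
        )
        assert impact.pathogenic_fraction == 1.0
        assert impact.retained_expression_fraction == 0.0

    def test_in_frame_deletion(self, default_cfg):
        impact = allele_pathogenic_fraction([make_variant(2, "in_frame")], default_cfg)
        assert impact.pathogenic_fraction == pytest.approx(0.2)
        assert impact.retained_expression_fraction == 1.0

    def test_splice_site_residual(self, default_cfg):
        impact = allele_pathogenic_fraction(
            [make_variant(9, "splice_site")], default_cfg
        )
        assert impact.pathogenic_fraction == pytest.approx(0.95)
        assert impact.retained_expression_fraction == pytest.approx(0.05)

    def test_missense_additive_clamped(self, default_cfg):
        # 6 damaging predictors + 2 splice tools, like p.Arg764Cys
        v = make_variant(7, "missense", damaging_count=6,
                         splice_tokens=(SpliceToken(2, "gain"),))
        assert allele_pathogenic_fraction([v], default_cfg).pathogenic_fraction == (
            pytest.approx(0.9)
        )
        # 14 damaging + 4 splice tools, like p.Cys948Tyr: clamps at 1
        v = make_variant(9, "missense", damaging_count=14,
                         splice_tokens=(SpliceToken(4, "loss"),))
        assert allele_pathogenic_fraction([v], default_cfg).pathogenic_fraction == 1.0

    def test_missense_multiplicative_option(self, default_cfg):
        cfg = default_cfg.with_options(combine_rule="multiplicative")
        v = make_variant(7, "missense", damaging_count=6,
                         splice_tokens=(SpliceToken(2, "gain"),))
        # 1 - (1-0.5)(1-0.4)
        assert allele_pathogenic_fraction([v], cfg).pathogenic_fraction == (
            pytest.approx(0.7)
        )

    def test_cis_variants_combine(self, default_cfg):
        variants = [make_variant(2, "in_frame"),
                    make_variant(6, "missense", damaging_count=14,
                                 splice_tokens=(SpliceToken(2, "gain"),))]
        impact = allele_pathogenic_fraction(variants, default_cfg)
        assert impact.pathogenic_fraction == 1.0  # min(1, 0.2 + 1.0)

    def test_missense_without_predictor_count(self, default_cfg):
        with pytest.raises(ScoringError, match="c.1000G>A"):
            allele_pathogenic_fraction([make_variant(5, "missense")], default_cfg)


class TestGenotypeScores:
    def test_homozygous_truncating_exon2(self, default_cfg):
        v = make_variant(2, "truncating")
        scores = genotype_isoform_scores(([v], [v]), default_cfg)
        assert scores.expression_pct == {"A": 0.0, "B": 100.0, "C": 0.0}
        assert scores.pathogenicity_pct == {"A": 100.0, "B": 0.0, "C": 100.0}

    def test_wild_type_genotype(self, default_cfg):
        scores = genotype_isoform_scores(([], []), default_cfg)
        assert all(scores.expression_pct[i] == 100.0 for i in ISOFORMS)
        assert all(scores.pathogenicity_pct[i] == 0.0 for i in ISOFORMS)

    def test_homozygous_in_frame_exon2(self, default_cfg):
        v = make_variant(2, "in_frame")
        scores = genotype_isoform_scores(([v], [v]), default_cfg)
        assert scores.expression_pct == {"A": 100.0, "B": 100.0, "C": 100.0}
        assert scores.pathogenicity_pct["A"] == pytest.approx(20.0)
        assert scores.pathogenicity_pct["B"] == 0.0
        assert scores.pathogenicity_pct["C"] == pytest.approx(20.0)

    def test_genotype_needs_two_alleles(self, default_cfg):
        with pytest.raises(DomainError):
            genotype_isoform_scores(([],), default_cfg)

    def test_total_mean_over_three(self, default_cfg):
        scores = IsoformScoreSet(
            {"A": 100, "B": 100, "C": 100},
            {"A": 20.0, "B": 0.0, "C": 20.0},
        )
        assert total_pathogenicity(scores, default_cfg) == pytest.approx(13.3333, abs=1e-3)
        zero = IsoformScoreSet({i: 100 for i in ISOFORMS}, {i: 0.0 for i in ISOFORMS})
        assert total_pathogenicity(zero, default_cfg) == 0.0

    def test_total_sum_over_affected_option(self, default_cfg):
        cfg = default_cfg.with_options(total_rule="sum_over_affected")
        scores = IsoformScoreSet(
            {"A": 100, "B": 100, "C": 100},
            {"A": 20.0, "B": 0.0, "C": 20.0},
        )
        assert total_pathogenicity(scores, cfg) == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "paths, expected",
        [
            ({"A": 100.0, "B": 100.0, "C": 0.0}, Phenotype.LCA),
            ({"A": 90.0, "B": 90.0, "C": 40.0}, Phenotype.LCA),
            ({"A": 60.0, "B": 50.0, "C": 70.0}, Phenotype.CRD),
            ({"A": 20.0, "B": 0.0, "C": 20.0}, Phenotype.CD),
            ({"A": 0.0, "B": 0.0, "C": 0.0}, Phenotype.NONE),
        ],
    )
    def test_classifier_thresholds(self, default_cfg, paths, expected):
        scores = IsoformScoreSet({i: 100.0 for i in ISOFORMS}, paths)
        assert classify_phenotype(scores, default_cfg) is expected


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

_CFG = ScoringConfig.default()


@st.composite
def variant_strategy(draw):
    consequence = draw(
        st.sampled_from(["truncating", "missense", "in_frame", "splice_site"])
    )
    exon = draw(st.integers(min_value=1, max_value=12))
    damaging = None
    tokens = ()
    if consequence == "missense":
        damaging = draw(st.integers(min_value=0, max_value=15))
        n_tools = draw(st.integers(min_value=0, max_value=4))
        if n_tools:
            tokens = (SpliceToken(n_tools, draw(st.sampled_from(["gain", "loss"]))),)
    position = draw(st.integers(min_value=1, max_value=4000))
    return make_variant(exon, consequence, damaging, tokens, position=position)


def genotype_strategy():
    allele = st.lists(variant_strategy(), min_size=0, max_size=2)
    return st.tuples(allele, allele)


def _oracle_variant_fraction(v):
    """Independent re-derivation of a variant's pathogenic fraction."""
    cls = v.consequence_class.value
    if cls == "truncating":
        return 1.0
    if cls == "splice_site":
        return 0.95
    if cls == "in_frame":
        return 0.2
    d = v.damaging_count
    if d >= 13:
        m = 0.8
    elif d >= 11:
        m = 0.7
    elif d >= 6:
        m = 0.5
    else:
        m = 0.0
    if d == 15:
        m = 0.8
    s = 0.2 * sum(t.count for t in v.splice_tokens)
    return min(1.0, m + s)


def _oracle_scores(genotype):
    """Brute-force per-isoform score: enumerate allele x isoform contributions."""
    membership = {
        "A": set(range(1, 13)),
        "B": set(range(6, 13)),
        "C": set(range(1, 7)),
    }
    retention = {"truncating": 0.0, "splice_site": 0.05, "missense": 1.0, "in_frame": 1.0}
    expression, pathogenicity = {}, {}
    for iso, exons in membership.items():
        e_pts, p_pts = 0.0, 0.0
        for allele in genotype:
            hits = [v for v in allele if v.exon in exons]
            p = min(1.0, sum(_oracle_variant_fraction(v) for v in hits))
            loss = min(1.0, sum(1.0 - retention[v.consequence_class.value] for v in hits))
            e_pts += 50.0 * (1.0 - loss)
            p_pts += 50.0 * p
        expression[iso], pathogenicity[iso] = e_pts, p_pts
    return expression, pathogenicity


@settings(max_examples=200, deadline=None, derandomize=True)
@given(genotype_strategy())
def test_scores_bounded(genotype):
    scores = genotype_isoform_scores(genotype, _CFG)
    for iso in ISOFORMS:
        assert 0.0 <= scores.expression_pct[iso] <= 100.0
        assert 0.0 <= scores.pathogenicity_pct[iso] <= 100.0
    assert 0.0 <= total_pathogenicity(scores, _CFG) <= 100.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(genotype_strategy(), variant_strategy(), st.integers(min_value=0, max_value=1))
def test_adding_a_variant_is_monotone(genotype, extra, which):
    """More variants never raise expression and never lower pathogenicity."""
    before = genotype_isoform_scores(genotype, _CFG)
    grown = list(map(list, genotype))
    grown[which] = grown[which] + [extra]
    after = genotype_isoform_scores(tuple(grown), _CFG)
    for iso in ISOFORMS:
        assert after.expression_pct[iso] <= before.expression_pct[iso] + 1e-9
        assert after.pathogenicity_pct[iso] >= before.pathogenicity_pct[iso] - 1e-9


@settings(max_examples=200, deadline=None, derandomize=True)
@given(genotype_strategy())
def test_matches_brute_force_oracle(genotype):
    scores = genotype_isoform_scores(genotype, _CFG)
    expr, path = _oracle_scores(genotype)
    for iso in ISOFORMS:
        assert scores.expression_pct[iso] == pytest.approx(expr[iso])
        assert scores.pathogenicity_pct[iso] == pytest.approx(path[iso])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(genotype_strategy())
def test_loss_classes_tie_pathogenicity_to_expression_loss(genotype):
    """For pure truncating/splice alleles, pathogenic load equals expression loss."""
    loss_only = tuple(
        [v for v in allele if v.consequence_class.value in ("truncating", "splice_site")]
        for allele in genotype
    )
    scores = genotype_isoform_scores(loss_only, _CFG)
    for iso in ISOFORMS:
        assert scores.pathogenicity_pct[iso] == pytest.approx(
            100.0 - scores.expression_pct[iso]
        )
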