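"""Isoform-aware impact scoring for biallelic CRB1 genotypes.

The model works on a 0–100 expression scale per isoform, each of the two
alleles contributing up to 50 points.  Consequence classes set how much of
an allele's output survives (truncating 0%, canonical splice-site 5%,
missense and in-frame 100%) and, separately, how pathogenic the surviving
product is: in-frame indels are assigned a fixed fraction, missense
variants a fraction binned by the number of damaging in-silico predictors
(of 15) plus 0.2 per splice-prediction tool (of 4) flagging the site.  A
variant only touches the isoforms whose transcript contains its exon, so a
single genotype produces different scores for CRB1-A, -B and -C.

Severity classification follows the two observed cohort thresholds: near
complete CRB1-A pathogenicity (>= 85%) marks Leber congenital amaurosis;
below that, total pathogenicity across the three isoforms separates
cone-rod dystrophy (>= 50%) from cone dystrophy (> 0%).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .model import (
    ConsequenceClass,
    DomainError,
    IsoformModel,
    SpliceToken,
    VariantRecord,
    build_isoform_models,
    DEFAULT_ISOFORM_EXONS,
    N_SPLICE_TOOLS,
)

logger = logging.getLogger(__name__)

ISOFORMS = ("A", "B", "C")


class ScoringError(ValueError):
    """Raised when a variant cannot be scored (e.g. missense without predictor count)."""


class Phenotype(str, enum.Enum):
    LCA = "LCA"
    CRD = "CRD"
    CD = "CD"
    NONE = "none"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringConfig:
    """Every constant of the scoring rules; loadable from YAML.

    ``damaging_bins`` is an ordered tuple of ``(lo, hi, fraction)`` over the
    predictor-count range; counts below the lowest bin score 0 and counts
    above the highest clamp to the top fraction (both log a warning).
    """

    allele_share: float = 50.0
    expression_retention: Mapping[str, float] = field(
        default_factory=lambda: {
            "truncating": 0.0,
            "splice_site": 0.05,
            "missense": 1.0,
            "in_frame": 1.0,
        }
    )
    in_frame_fraction: float = 0.2
    damaging_bins: tuple[tuple[int, int, float], ...] = (
        (6, 10, 0.5),
        (11, 12, 0.7),
        (13, 14, 0.8),
    )
    splice_tool_unit: float = 0.2
    combine_rule: str = "additive_clamped"
    total_rule: str = "mean_over_three_isoforms"
    splice_residual_mode: str = "allele_fraction"
    lca_a_loss_threshold: float = 85.0
    cd_total_threshold: float = 50.0
    isoform_exons: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {k: sorted(v) for k, v in DEFAULT_ISOFORM_EXONS.items()}
    )

    def __post_init__(self) -> None:
        if self.combine_rule not in {"additive_clamped", "multiplicative"}:
            raise DomainError(f"unknown combine_rule {self.combine_rule!r}")
        if self.total_rule not in {"mean_over_three_isoforms", "sum_over_affected"}:
            raise DomainError(f"unknown total_rule {self.total_rule!r}")
        if self.splice_residual_mode not in {"allele_fraction", "absolute_points"}:
            raise DomainError(f"unknown splice_residual_mode {self.splice_residual_mode!r}")
        for cls, frac in self.expression_retention.items():
            if not (0.0 <= frac <= 1.0):
                raise DomainError(f"retention fraction for {cls} outside [0,1]: {frac}")
        for name, frac in [
            ("in_frame_fraction", self.in_frame_fraction),
            ("splice_tool_unit", self.splice_tool_unit),
        ]:
            if not (0.0 <= frac <= 1.0):
                raise DomainError(f"{name} outside [0,1]: {frac}")
        for thr in (self.lca_a_loss_threshold, self.cd_total_threshold):
            if not (0.0 <= thr <= 100.0):
                raise DomainError(f"threshold outside [0,100]: {thr}")
        prev_hi = None
        for lo, hi, frac in self.damaging_bins:
            if lo > hi or not (0.0 <= frac <= 1.0):
                raise DomainError(f"malformed damaging bin ({lo},{hi},{frac})")
            if prev_hi is not None and lo != prev_hi + 1:
                raise DomainError("damaging bins must be contiguous and non-overlapping")
            prev_hi = hi
        build_isoform_models(self.isoform_exons)  # validates the model

    # -- construction -------------------------------------------------------

    @classmethod
    def default(cls) -> "ScoringConfig":
        """The bundled default rules (shipped as package data)."""
        text = resources.files("crb1kit.data").joinpath("default_config.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise DomainError(f"config file {path} does not hold a mapping")
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ScoringConfig":
        kwargs = dict(data)
        if "damaging_bins" in kwargs:
            kwargs["damaging_bins"] = tuple(
                (int(lo), int(hi), float(frac)) for lo, hi, frac in kwargs["damaging_bins"]
            )
        if "isoform_model" in kwargs:
            kwargs["isoform_exons"] = kwargs.pop("isoform_model")
        known = set(cls.__dataclass_fields__)
        unknown = set(kwargs) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def with_options(self, **kwargs) -> "ScoringConfig":
        return replace(self, **kwargs)

    def isoform_models(self) -> dict[str, IsoformModel]:
        return build_isoform_models(self.isoform_exons)

    def to_dict(self) -> dict:
        """Plain-dict form of the effective config, echoed into reports."""
        return {
            "allele_share": self.allele_share,
            "expression_retention": dict(self.expression_retention),
            "in_frame_fraction": self.in_frame_fraction,
            "damaging_bins": [list(b) for b in self.damaging_bins],
            "splice_tool_unit": self.splice_tool_unit,
            "combine_rule": self.combine_rule,
            "total_rule": self.total_rule,
            "splice_residual_mode": self.splice_residual_mode,
            "lca_a_loss_threshold": self.lca_a_loss_threshold,
            "cd_total_threshold": self.cd_total_threshold,
            "isoform_model": {k: sorted(v) for k, v in self.isoform_exons.items()},
        }


# ---------------------------------------------------------------------------
# per-variant and per-allele fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleImpact:
    """Fractions describing one allele: expression retained and pathogenic load."""

    retained_expression_fraction: float = 1.0
    missense_fraction: float = 0.0
    splice_fraction: float = 0.0
    pathogenic_fraction: float = 0.0


def expression_retained_fraction(
    consequence: ConsequenceClass, cfg: ScoringConfig
) -> float:
    """Fraction of the allele's output retained for a consequence class."""
    key = ConsequenceClass(consequence).value
    if key not in cfg.expression_retention:
        raise DomainError(f"no expression retention configured for class {key!r}")
    frac = cfg.expression_retention[key]
    if key == "splice_site" and cfg.splice_residual_mode == "absolute_points":
        # residual read as absolute points of the 100-point total rather than
        # a fraction of the 50-point allele share
        frac = min(1.0, frac * 100.0 / cfg.allele_share)
    return frac


def missense_damaging_fraction(d: int, cfg: ScoringConfig) -> float:
    """Pathogenic fraction from the number of damaging predictor calls."""
    if d < 0:
        raise DomainError(f"negative damaging count {d}")
    lowest = cfg.damaging_bins[0][0]
    top_hi, top_frac = cfg.damaging_bins[-1][1], cfg.damaging_bins[-1][2]
    if d < lowest:
        logger.warning(
            "damaging count %d below the lowest bin (%d); scoring 0 impact", d, lowest
        )
        return 0.0
    if d > top_hi:
        logger.warning(
            "damaging count %d above the top bin (%d); clamping to %.2f", d, top_hi, top_frac
        )
        return top_frac
    for lo, hi, frac in cfg.damaging_bins:
        if lo <= d <= hi:
            return frac
    raise DomainError(f"damaging count {d} not covered by the configured bins")


def splice_impact_fraction(
    tokens: Sequence[SpliceToken], cfg: ScoringConfig
) -> float:
    """Pathogenic fraction from splice-tool predictions (gain and loss weighted alike)."""
    total = sum(t.count for t in tokens)
    if total > N_SPLICE_TOOLS:
        raise DomainError(
            f"{total} splice-tool calls exceed the {N_SPLICE_TOOLS} tools consulted"
        )
    return min(1.0, cfg.splice_tool_unit * total)


def _combine(fractions: Sequence[float], cfg: ScoringConfig) -> float:
    if not fractions:
        return 0.0
    if cfg.combine_rule == "multiplicative":
        surviving = 1.0
        for f in fractions:
            surviving *= 1.0 - f
        return 1.0 - surviving
    return min(1.0, sum(fractions))


def variant_impact(variant: VariantRecord, cfg: ScoringConfig) -> AlleleImpact:
    """Impact fractions of a single variant."""
    cls = variant.consequence_class
    f_e = expression_retained_fraction(cls, cfg)
    if cls is ConsequenceClass.TRUNCATING:
        return AlleleImpact(f_e, 0.0, 0.0, 1.0)
    if cls is ConsequenceClass.SPLICE_SITE:
        return AlleleImpact(f_e, 0.0, 0.0, 1.0 - f_e)
    if cls is ConsequenceClass.IN_FRAME:
        return AlleleImpact(f_e, 0.0, 0.0, cfg.in_frame_fraction)
    # missense
    if variant.damaging_count is None:
        raise ScoringError(
            f"missense variant {variant.cdna} has no damaging-predictor count"
        )
    m = missense_damaging_fraction(variant.damaging_count, cfg)
    s = splice_impact_fraction(variant.splice_tokens, cfg)
    return AlleleImpact(f_e, m, s, _combine([m, s], cfg))


def allele_pathogenic_fraction(
    variants_on_allele: Sequence[VariantRecord], cfg: ScoringConfig
) -> AlleleImpact:
    """Combined impact of all variants in cis on one allele.

    An empty list is a wild-type allele (no pathogenic load, full
    expression).  Multiple cis variants combine by the configured rule on
    both the pathogenic fraction and the expression-loss fraction.
    """
    if not variants_on_allele:
        return AlleleImpact()
    impacts = [variant_impact(v, cfg) for v in variants_on_allele]
    p = _combine([i.pathogenic_fraction for i in impacts], cfg)
    loss = _combine([1.0 - i.retained_expression_fraction for i in impacts], cfg)
    return AlleleImpact(
        retained_expression_fraction=1.0 - loss,
        missense_fraction=_combine([i.missense_fraction for i in impacts], cfg),
        splice_fraction=_combine([i.splice_fraction for i in impacts], cfg),
        pathogenic_fraction=p,
    )


# ---------------------------------------------------------------------------
# genotype-level scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformScoreSet:
    """Per-isoform expression and pathogenicity (percent) for one genotype."""

    expression_pct: Mapping[str, float]
    pathogenicity_pct: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso in ISOFORMS:
            for mapping, name in (
                (self.expression_pct, "expression"),
                (self.pathogenicity_pct, "pathogenicity"),
            ):
                v = mapping[iso]
                if not (-1e-9 <= v <= 100.0 + 1e-9):
                    raise DomainError(f"{name} for {iso} outside [0,100]: {v}")


def genotype_isoform_scores(
    genotype,
    cfg: ScoringConfig,
    models: Optional[Mapping[str, IsoformModel]] = None,
) -> IsoformScoreSet:
    """Score a biallelic genotype against the three isoforms.

    ``genotype`` is a pair of allele variant lists (or any object with an
    ``alleles`` attribute holding one).  Per isoform, each allele starts at
    ``allele_share`` points of expression; variants whose exon belongs to
    the isoform's transcript scale those points by the retained fraction
    and convert ``p x share`` points to pathogenic load.  Variants outside
    the transcript leave that isoform untouched.
    """
    alleles = getattr(genotype, "alleles", genotype)
    alleles = list(alleles)
    if len(alleles) != 2:
        raise DomainError(f"a genotype has exactly two alleles, got {len(alleles)}")
    if models is None:
        models = cfg.isoform_models()

    expression = {}
    pathogenicity = {}
    for iso in ISOFORMS:
        exons = models[iso].exons
        expr = 0.0
        path = 0.0
        for allele in alleles:
            hitting = [v for v in allele if v.exon in exons]
            impact = allele_pathogenic_fraction(hitting, cfg)
            expr += cfg.allele_share * impact.retained_expression_fraction
            path += cfg.allele_share * impact.pathogenic_fraction
        expression[iso] = min(100.0, expr)
        pathogenicity[iso] = min(100.0, path)
    return IsoformScoreSet(expression, pathogenicity)


def total_pathogenicity(scores: IsoformScoreSet, cfg: ScoringConfig) -> float:
    """Aggregate the three per-isoform pathogenicity values to one percentage.

    Default: mean over A, B, C (i.e. the sum expressed as a percentage of
    the 300-point maximum).  ``sum_over_affected`` averages only over the
    isoforms with a nonzero pathogenic load.
    """
    values = [scores.pathogenicity_pct[iso] for iso in ISOFORMS]
    if cfg.total_rule == "sum_over_affected":
        affected = [v for v in values if v > 0]
        return sum(affected) / len(affected) if affected else 0.0
    return sum(values) / len(ISOFORMS)


def classify_phenotype(scores: IsoformScoreSet, cfg: ScoringConfig) -> Phenotype:
    """Severity class from the score profile.

    Near-complete CRB1-A pathogenic load (>= ``lca_a_loss_threshold``)
    marks LCA regardless of the other isoforms; otherwise the total over
    the three isoforms separates CRD (>= ``cd_total_threshold``) from CD
    (> 0).  A silent genotype returns ``none``.
    """
    if scores.pathogenicity_pct["A"] >= cfg.lca_a_loss_threshold:
        return Phenotype.LCA
    total = total_pathogenicity(scores, cfg)
    if total >= cfg.cd_total_threshold:
        return Phenotype.CRD
    if total > 0:
        return Phenotype.CD
    return Phenotype.NONE
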