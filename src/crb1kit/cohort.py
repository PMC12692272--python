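"""Cohort loading, scoring, and cohort-level statistics.

Takes a clinical table (one row per proband x variant, mirroring the usual
clinical-report layout: proband id, diagnosis, cDNA and protein change,
zygosity, exon, ages, visual acuity) plus a variant-annotation table
(damaging-predictor counts, splice-prediction tokens, novelty, MAF),
assembles typed biallelic genotypes, scores every proband against the
three CRB1 isoforms, and computes the cohort statistics: per-variant
carrier prevalence, zygosity-weighted exon distribution, per-isoform
zygosity / expression / pathogenicity matrices ordered by clinical
severity, and the clinical-vs-predicted classification table.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    ClassificationError,
    ConsequenceClass,
    VariantParseError,
    VariantRecord,
    classify_consequence,
    normalize_protein_change,
    parse_cdna_variant,
    parse_damaging_count,
    parse_splice_tokens,
)
from .scoring import (
    ISOFORMS,
    IsoformScoreSet,
    Phenotype,
    ScoringConfig,
    classify_phenotype,
    genotype_isoform_scores,
    total_pathogenicity,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["proband_id", "diagnosis", "cdna", "zygosity", "exon"]
ANNOTATION_COLUMNS = ["cdna", "protein", "exon", "damaging_count", "splice_tokens", "novel"]

#: visual-acuity tokens kept as ordinal categories below any decimal acuity
BCVA_TOKENS = ("LP", "NLP", "HM")


class CohortLoadError(ValueError):
    """Raised when a cohort or annotation table cannot be assembled."""


@dataclass(frozen=True)
class ProbandRecord:
    """One patient: identity, clinical labels, and a phased biallelic genotype."""

    proband_id: str
    alias: str
    clinical_diagnosis: str
    alleles: tuple[tuple[VariantRecord, ...], tuple[VariantRecord, ...]]
    subtype: str = ""
    age_of_onset: str = ""
    onset_category: str = ""
    age: Optional[float] = None
    bcva_od: str = ""
    bcva_os: str = ""
    severity_rank: int = 0

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise CohortLoadError(f"{self.proband_id}: a genotype has exactly two alleles")
        if not self.clinical_diagnosis:
            raise CohortLoadError(f"{self.proband_id}: empty clinical diagnosis")

    @property
    def variants(self) -> tuple[VariantRecord, ...]:
        """Distinct variants carried (cis duplicates collapsed)."""
        seen: dict[str, VariantRecord] = {}
        for allele in self.alleles:
            for v in allele:
                seen.setdefault(v.cdna, v)
        return tuple(seen.values())

    def carries(self, cdna: str) -> bool:
        return any(v.cdna == cdna for allele in self.alleles for v in allele)

    def allele_count(self, cdna: str) -> int:
        return sum(1 for allele in self.alleles for v in allele if v.cdna == cdna)


@dataclass
class CohortSummary:
    """Cohort-level matrices and statistics, rows ordered by clinical severity."""

    n_probands: int
    isoform_scores: pd.DataFrame
    proband_summary: pd.DataFrame
    zygosity_matrix: pd.DataFrame
    expression_matrix: pd.DataFrame
    pathogenicity_matrix: pd.DataFrame
    prevalence: pd.Series
    exon_distribution: pd.DataFrame
    concordance: pd.DataFrame
    novel_count: int
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_tsv(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    raise CohortLoadError(f"unsupported table source {type(source)!r}")


def _missing(value: str) -> bool:
    return str(value).strip() in {"", "-", "--", ".", "nan"}


def load_annotations(source) -> dict[str, dict]:
    """Index a variant-annotation table by cDNA string."""
    df = _read_tsv(source)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortLoadError(f"annotation table lacks columns {missing_cols}")
    table: dict[str, dict] = {}
    for _, row in df.iterrows():
        cdna = row["cdna"].strip()
        if not cdna:
            continue
        if cdna in table:
            raise CohortLoadError(f"duplicate annotation row for {cdna}")
        table[cdna] = {
            "protein": None if _missing(row["protein"]) else row["protein"].strip(),
            "exon": int(row["exon"]),
            "damaging_count": parse_damaging_count(row["damaging_count"]),
            "splice_tokens": parse_splice_tokens(row["splice_tokens"]),
            "novel": str(row["novel"]).strip().lower() in {"yes", "true", "1"},
            "maf": None if _missing(row.get("maf", "")) else float(row["maf"]),
        }
    return table


def _build_variant(
    cdna: str, protein_raw: str, exon_raw: str, annotations: dict[str, dict]
) -> VariantRecord:
    descriptor = parse_cdna_variant(cdna)
    protein, _ = normalize_protein_change(protein_raw)
    ann = annotations.get(cdna)
    if ann is not None:
        protein = protein or ann["protein"]
        exon = int(exon_raw) if not _missing(exon_raw) else ann["exon"]
        damaging, tokens = ann["damaging_count"], ann["splice_tokens"]
        novel, maf = ann["novel"], ann["maf"]
    else:
        if _missing(exon_raw):
            raise CohortLoadError(f"variant {cdna} has no exon and no annotation row")
        exon = int(exon_raw)
        damaging, tokens, novel, maf = None, (), False, None
    try:
        consequence = classify_consequence(descriptor, protein)
    except (ClassificationError, VariantParseError) as exc:
        raise CohortLoadError(f"cannot classify variant {cdna}: {exc}") from exc
    if consequence is ConsequenceClass.MISSENSE and damaging is None:
        raise CohortLoadError(
            f"missense variant {cdna} lacks an annotation row with a damaging count"
        )
    return VariantRecord(
        descriptor=descriptor,
        exon=exon,
        consequence_class=consequence,
        protein_change=protein,
        damaging_count=damaging,
        splice_tokens=tokens,
        novel=novel,
        maf=maf,
    )


def _phase_alleles(
    variants: Sequence[tuple[VariantRecord, str]], proband_id: str
) -> tuple[tuple[VariantRecord, ...], tuple[VariantRecord, ...]]:
    """Place variants on two alleles.

    Homozygous variants sit on both alleles (two homozygous variants in one
    proband are therefore in cis on each allele); heterozygous variants are
    placed in trans, one per allele, in table order.
    """
    allele_a: list[VariantRecord] = []
    allele_b: list[VariantRecord] = []
    het_slot = 0
    for variant, zygosity in variants:
        z = zygosity.strip().lower()
        if z in {"homo", "hom", "homozygous"}:
            allele_a.append(variant)
            allele_b.append(variant)
        elif z in {"het", "heterozygous"}:
            if het_slot == 0:
                allele_a.append(variant)
            elif het_slot == 1:
                allele_b.append(variant)
            else:
                raise CohortLoadError(
                    f"{proband_id}: more than two heterozygous variants cannot be "
                    f"phased onto two alleles"
                )
            het_slot += 1
        else:
            raise CohortLoadError(f"{proband_id}: unknown zygosity {zygosity!r}")
    return tuple(allele_a), tuple(allele_b)


def load_cohort(cohort_source, annotation_source) -> list[ProbandRecord]:
    """Load and phase a cohort table against its variant annotations."""
    df = _read_tsv(cohort_source)
    if df.empty:
        raise CohortLoadError("empty cohort table")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortLoadError(f"cohort table lacks columns {missing_cols}")
    annotations = load_annotations(annotation_source)

    probands: list[ProbandRecord] = []
    seen_ids: set[str] = set()
    rank = 0
    for pid, group in df.groupby("proband_id", sort=False):
        if pid in seen_ids:
            raise CohortLoadError(f"duplicate proband id {pid}")
        seen_ids.add(pid)
        rank += 1
        head = group.iloc[0]
        for col in ("alias", "diagnosis"):
            if col in group.columns and group[col].nunique() > 1:
                raise CohortLoadError(
                    f"duplicate proband id {pid} with conflicting {col} values"
                )
        variants = [
            (_build_variant(r["cdna"], r.get("protein", ""), r["exon"], annotations),
             r["zygosity"])
            for _, r in group.iterrows()
        ]
        alleles = _phase_alleles(variants, pid)
        age_raw = head.get("age", "")
        probands.append(
            ProbandRecord(
                proband_id=pid,
                alias=head.get("alias", pid) or pid,
                clinical_diagnosis=head["diagnosis"].strip(),
                subtype=head.get("subtype", ""),
                alleles=alleles,
                age_of_onset=head.get("age_of_onset", ""),
                onset_category=head.get("onset_category", ""),
                age=None if _missing(age_raw) else float(age_raw),
                bcva_od=head.get("bcva_od", ""),
                bcva_os=head.get("bcva_os", ""),
                severity_rank=rank,
            )
        )
    return probands


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def carrier_prevalence(cohort: Sequence[ProbandRecord], cdna: str) -> float:
    """Percentage of probands carrying at least one allele of ``cdna``."""
    if not cohort:
        raise CohortLoadError("empty cohort")
    carriers = sum(1 for p in cohort if p.carries(cdna))
    if carriers == 0:
        logger.warning("variant %s not carried by any proband", cdna)
    return 100.0 * carriers / len(cohort)


def exon_allele_distribution(cohort: Sequence[ProbandRecord]) -> pd.DataFrame:
    """Zygosity-weighted variant-allele counts per exon.

    A heterozygous occurrence counts one allele, a homozygous occurrence
    two, so the percentages describe the pool of mutant alleles rather
    than of distinct variants.
    """
    counts: dict[int, int] = {}
    for p in cohort:
        for allele in p.alleles:
            for v in allele:
                counts[v.exon] = counts.get(v.exon, 0) + 1
    total = sum(counts.values())
    rows = [
        {"exon": exon, "allele_count": n, "percentage": 100.0 * n / total}
        for exon, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["exon", "allele_count", "percentage"])


def count_novel_variants(cohort: Sequence[ProbandRecord]) -> int:
    """Number of distinct variants flagged as novel (first reported here)."""
    return len({v.cdna for p in cohort for v in p.variants if v.novel})


def _zygosity_for_isoform(proband: ProbandRecord, exons: frozenset[int]) -> str:
    hit = [any(v.exon in exons for v in allele) for allele in proband.alleles]
    n = sum(hit)
    return {0: "unaffected", 1: "monoallelic", 2: "biallelic"}[n]


def score_cohort(
    cohort: Sequence[ProbandRecord], cfg: Optional[ScoringConfig] = None
) -> CohortSummary:
    """Score every proband and assemble the cohort-level summary."""
    if not cohort:
        raise CohortLoadError("empty cohort")
    if cfg is None:
        cfg = ScoringConfig.default()
    models = cfg.isoform_models()
    ordered = sorted(cohort, key=lambda p: p.severity_rank)

    iso_rows = []
    summary_rows = []
    zyg_rows = {}
    expr_rows = {}
    path_rows = {}
    for p in ordered:
        try:
            scores = genotype_isoform_scores(p.alleles, cfg, models)
        except ValueError as exc:
            raise CohortLoadError(f"scoring failed for proband {p.alias}: {exc}") from exc
        total = total_pathogenicity(scores, cfg)
        predicted = classify_phenotype(scores, cfg)
        for iso in ISOFORMS:
            iso_rows.append(
                {
                    "proband_id": p.proband_id,
                    "alias": p.alias,
                    "clinical_diagnosis": p.clinical_diagnosis,
                    "isoform": iso,
                    "expression_pct": scores.expression_pct[iso],
                    "pathogenicity_pct": scores.pathogenicity_pct[iso],
                }
            )
        summary_rows.append(
            {
                "proband_id": p.proband_id,
                "alias": p.alias,
                "clinical_diagnosis": p.clinical_diagnosis,
                "subtype": p.subtype,
                "total_pathogenicity_pct": total,
                "predicted_class": predicted.value,
                "severity_rank": p.severity_rank,
            }
        )
        zyg_rows[p.alias] = {
            iso: _zygosity_for_isoform(p, models[iso].exons) for iso in ISOFORMS
        }
        expr_rows[p.alias] = dict(scores.expression_pct)
        path_rows[p.alias] = dict(scores.pathogenicity_pct)

    aliases = [p.alias for p in ordered]
    summary = pd.DataFrame(summary_rows)
    all_variants = {v.cdna for p in cohort for v in p.variants}
    prevalence = pd.Series(
        {cdna: carrier_prevalence(cohort, cdna) for cdna in sorted(all_variants)},
        name="carrier_prevalence_pct",
    )
    concordance = pd.crosstab(
        summary["clinical_diagnosis"], summary["predicted_class"]
    )
    return CohortSummary(
        n_probands=len(cohort),
        isoform_scores=pd.DataFrame(iso_rows),
        proband_summary=summary,
        zygosity_matrix=pd.DataFrame.from_dict(zyg_rows, orient="index").loc[
            aliases, list(ISOFORMS)
        ],
        expression_matrix=pd.DataFrame.from_dict(expr_rows, orient="index").loc[
            aliases, list(ISOFORMS)
        ],
        pathogenicity_matrix=pd.DataFrame.from_dict(path_rows, orient="index").loc[
            aliases, list(ISOFORMS)
        ],
        prevalence=prevalence,
        exon_distribution=exon_allele_distribution(cohort),
        concordance=concordance,
        novel_count=count_novel_variants(cohort),
        config=cfg.to_dict(),
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_report(summary: CohortSummary, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write TSV/JSON reports and figures; deterministic for fixed input.

    Produces ``isoform_scores.tsv`` (one row per proband x isoform),
    ``proband_summary.tsv`` (one row per proband), ``report.json`` (the
    full summary including the effective config), and three figures
    (expression heatmap, pathogenicity heatmap, exon bar chart).
    """
    if summary.n_probands == 0:
        raise CohortLoadError("refusing to render a report for an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _round(df: pd.DataFrame) -> pd.DataFrame:
        return df.round(1)

    paths["isoform_scores"] = outdir / "isoform_scores.tsv"
    _round(summary.isoform_scores).to_csv(paths["isoform_scores"], sep="\t", index=False)
    paths["proband_summary"] = outdir / "proband_summary.tsv"
    _round(summary.proband_summary).to_csv(paths["proband_summary"], sep="\t", index=False)

    payload = {
        "n_probands": summary.n_probands,
        "novel_variants": summary.novel_count,
        "carrier_prevalence_pct": summary.prevalence.round(1).to_dict(),
        "exon_allele_distribution": _round(summary.exon_distribution).to_dict("records"),
        "zygosity_matrix": summary.zygosity_matrix.to_dict("index"),
        "expression_matrix": _round(summary.expression_matrix).to_dict("index"),
        "pathogenicity_matrix": _round(summary.pathogenicity_matrix).to_dict("index"),
        "proband_summary": _round(summary.proband_summary).to_dict("records"),
        "concordance": summary.concordance.to_dict("index"),
        "config": summary.config,
    }
    paths["report_json"] = outdir / "report.json"
    paths["report_json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    paths.update(_render_figures(summary, outdir))
    return paths


def _render_figures(summary: CohortSummary, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    paths = {}
    for name, matrix, cmap in (
        ("expression_heatmap", summary.expression_matrix, "viridis"),
        ("pathogenicity_heatmap", summary.pathogenicity_matrix, "rocket_r"),
    ):
        fig, ax = plt.subplots(figsize=(4, 0.32 * len(matrix) + 1.5))
        sns.heatmap(matrix, vmin=0, vmax=100, cmap=cmap, ax=ax,
                    cbar_kws={"label": "%"})
        ax.set_xlabel("CRB1 isoform")
        ax.set_ylabel("proband (by clinical severity)")
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths[name] = path

    dist = summary.exon_distribution
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(dist["exon"].astype(str), dist["percentage"], color="#4C72B0")
    ax.set_xlabel("exon")
    ax.set_ylabel("% of variant alleles")
    fig.tight_layout()
    path = outdir / "exon_distribution.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths["exon_distribution"] = path
    return paths
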