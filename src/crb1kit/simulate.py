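"""Seeded synthetic cohorts with the statistical structure of a CRB1 clinic.

The generator emits cohort + annotation tables in the same schema as the
bundled 25-proband fixture: biallelic genotypes drawn from a consequence
class mixture, exon placement concentrated on exons 2 and 9, predictor
counts and splice tokens matching the empirical distributions of the
clinical tables.  Truth labels are defined by the scoring rules themselves
(before optional label noise), which makes the generator a closed-loop
test harness for the pipeline rather than an independent disease model.

Also provides small helpers to synthesize qPCR standard curves and
measurement tables for the quantification module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConsequenceClass,
    DomainError,
    VariantRecord,
    classify_consequence,
    parse_cdna_variant,
    parse_splice_tokens,
)
from .qpcr import DilutionSeries
from .scoring import ScoringConfig, classify_phenotype, genotype_isoform_scores

#: synthetic coding map: each exon owns an equal slice of a 4320-nt CDS
_EXON_SPAN = 360

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
_BASES = "ACGT"

COHORT_HEADER = [
    "proband_id", "alias", "diagnosis", "subtype", "cdna", "protein", "zygosity",
    "exon", "age_of_onset", "onset_category", "age", "bcva_od", "bcva_os", "reference",
]
ANNOTATION_HEADER = [
    "cdna", "protein", "exon", "damaging_count", "splice_tokens", "novel", "maf",
    "reference",
]
TRUTH_HEADER = ["proband_id", "alias", "truth_class", "label_flipped"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the empirical structure of the bundled clinical
    fixture: the class mixture and exon weights follow its allele pool,
    damaging counts and splice tokens follow the annotation table, and the
    homozygosity probability matches its 7/25 homozygous genotypes.
    """

    n_probands: int = 25
    seed: int = 0
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.45,
            "in_frame": 0.25,
            "truncating": 0.20,
            "splice_site": 0.10,
        }
    )
    homozygosity_prob: float = 0.3
    exon_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.38, 3: 0.02, 5: 0.02, 6: 0.08, 7: 0.11, 9: 0.35, 11: 0.04}
    )
    damaging_count_weights: Mapping[int, float] = field(
        default_factory=lambda: {6: 1.0, 11: 1.0, 12: 1.0, 13: 1.0, 14: 5.0}
    )
    splice_token_weights: Mapping[int, float] = field(
        default_factory=lambda: {0: 4.0, 1: 1.0, 2: 3.0, 4: 1.0}
    )
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_probands < 0:
            raise DomainError(f"n_probands must be >= 0, got {self.n_probands}")
        if not (0.0 <= self.label_noise <= 1.0):
            raise DomainError(f"label_noise outside [0,1]: {self.label_noise}")
        for name, weights in (
            ("class_mixture", self.class_mixture),
            ("exon_weights", self.exon_weights),
            ("damaging_count_weights", self.damaging_count_weights),
            ("splice_token_weights", self.splice_token_weights),
        ):
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise DomainError(f"{name} must hold non-negative weights summing > 0")
        unknown = set(self.class_mixture) - {c.value for c in ConsequenceClass}
        if unknown:
            raise DomainError(f"unknown consequence classes in mixture: {sorted(unknown)}")


@dataclass
class SimulatedCohort:
    """Generated tables plus the pre-noise truth labels."""

    cohort: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort": outdir / "cohort.tsv",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.cohort.to_csv(paths["cohort"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _weighted_choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights.keys())
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _residue(position: int) -> int:
    return (position - 1) // 3 + 1


class _VariantFactory:
    """Synthesizes annotated variants; recurrent draws reuse the same allele."""

    def __init__(self, rng: np.random.Generator, cfg: SimulationConfig) -> None:
        self.rng = rng
        self.cfg = cfg
        self.registry: dict[str, dict] = {}

    def draw(self) -> dict:
        rng = self.rng
        cls = ConsequenceClass(_weighted_choice(rng, self.cfg.class_mixture))
        exon = int(_weighted_choice(rng, self.cfg.exon_weights))
        lo, hi = (exon - 1) * _EXON_SPAN + 1, exon * _EXON_SPAN

        if cls is ConsequenceClass.SPLICE_SITE:
            offset = int(rng.integers(1, 4))
            cdna = f"c.{hi}+{offset}G>A"
            protein, damaging, tokens = None, None, ""
        elif cls is ConsequenceClass.MISSENSE:
            pos = int(rng.integers(lo, hi + 1))
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            cdna = f"c.{pos}{ref}>{alt}"
            aa_from, aa_to = rng.choice(_AA3, size=2, replace=False)
            protein = f"p.{aa_from}{_residue(pos)}{aa_to}"
            damaging = int(_weighted_choice(rng, self.cfg.damaging_count_weights))
            n_tools = int(_weighted_choice(rng, self.cfg.splice_token_weights))
            direction = rng.choice(["G", "L"])
            tokens = f"{n_tools}{direction}" if n_tools else ""
        elif cls is ConsequenceClass.IN_FRAME:
            length = int(rng.choice([3, 6, 9]))
            pos = int(rng.integers(lo, hi - length + 1))
            end = pos + length - 1
            aa1, aa2 = rng.choice(_AA3, size=2, replace=True)
            r1, r2 = _residue(pos), _residue(pos) + length // 3 - 1
            protein = (
                f"p.{aa1}{r1}del" if r1 == r2 else f"p.{aa1}{r1}_{aa2}{r2}del"
            )
            cdna = f"c.{pos}_{end}del"
            damaging, tokens = None, ""
        else:  # truncating
            pos = int(rng.integers(lo, hi))
            aa = rng.choice(_AA3)
            if rng.random() < 0.5:  # nonsense substitution
                ref, alt = rng.choice(list(_BASES), size=2, replace=False)
                cdna = f"c.{pos}{ref}>{alt}"
                protein = f"p.{aa}{_residue(pos)}Ter"
            else:  # 1- or 2-nt frameshift deletion
                if rng.random() < 0.5:
                    base = rng.choice(list(_BASES))
                    cdna = f"c.{pos}del{base}"
                else:
                    b1, b2 = rng.choice(list(_BASES), size=2)
                    cdna = f"c.{pos}_{pos + 1}del{b1}{b2}"
                aa2 = rng.choice(_AA3)
                protein = f"p.{aa}{_residue(pos)}{aa2}fsTer{int(rng.integers(2, 30))}"
            damaging, tokens = None, ""

        if cdna in self.registry:  # recurrent allele: reuse its annotation
            return self.registry[cdna]
        entry = {
            "cdna": cdna,
            "protein": protein,
            "exon": exon,
            "damaging_count": f"{damaging}D" if damaging is not None else "--",
            "splice_tokens": tokens or "--",
        }
        # the synthesized string must survive the parser round-trip
        descriptor = parse_cdna_variant(cdna)
        assert descriptor.format() == cdna, cdna
        entry["record"] = VariantRecord(
            descriptor=descriptor,
            exon=exon,
            consequence_class=classify_consequence(descriptor, protein),
            protein_change=protein,
            damaging_count=damaging,
            splice_tokens=parse_splice_tokens(tokens or None),
        )
        self.registry[cdna] = entry
        return entry


def generate_cohort(
    cfg: SimulationConfig, scoring: Optional[ScoringConfig] = None
) -> SimulatedCohort:
    """Generate a synthetic cohort, annotation table, and truth labels.

    Deterministic for a given config (the seed lives in the config).  The
    truth label of each proband is the phenotype the scoring rules assign
    to its genotype; with ``label_noise > 0`` the clinical diagnosis column
    is flipped to a different class with that probability while the truth
    table keeps the pre-noise label.
    """
    rng = np.random.default_rng(cfg.seed)
    if scoring is None:
        scoring = ScoringConfig.default()
    factory = _VariantFactory(rng, cfg)

    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []
    classes = ["CD", "CRD", "LCA"]
    for i in range(cfg.n_probands):
        pid = f"SIM{cfg.seed}/{i + 1:04d}"
        alias = f"SIM_{i + 1}"
        if rng.random() < cfg.homozygosity_prob:
            entries = [(factory.draw(), "homo")]
            alleles = ([entries[0][0]["record"]], [entries[0][0]["record"]])
        else:
            first = factory.draw()
            second = factory.draw()
            while second["cdna"] == first["cdna"]:  # compound het needs two alleles
                second = factory.draw()
            entries = [(first, "het"), (second, "het")]
            alleles = ([first["record"]], [second["record"]])

        scores = genotype_isoform_scores(alleles, scoring)
        truth = classify_phenotype(scores, scoring).value
        label = truth
        flipped = False
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            others = [c for c in classes if c != truth] or classes
            label = others[int(rng.integers(len(others)))]
            flipped = True
        truth_rows.append(
            {"proband_id": pid, "alias": alias, "truth_class": truth,
             "label_flipped": flipped}
        )
        for entry, zygosity in entries:
            cohort_rows.append(
                {
                    "proband_id": pid,
                    "alias": alias,
                    "diagnosis": label,
                    "subtype": label,
                    "cdna": entry["cdna"],
                    "protein": entry["protein"] or "-",
                    "zygosity": zygosity,
                    "exon": entry["exon"],
                    "age_of_onset": "",
                    "onset_category": "",
                    "age": "",
                    "bcva_od": "-",
                    "bcva_os": "-",
                    "reference": "synthetic",
                }
            )

    annotation_rows = [
        {
            "cdna": e["cdna"],
            "protein": e["protein"] or "-",
            "exon": e["exon"],
            "damaging_count": e["damaging_count"],
            "splice_tokens": e["splice_tokens"],
            "novel": "no",
            "maf": "--",
            "reference": "synthetic",
        }
        for e in factory.registry.values()
    ]
    cohort = pd.DataFrame(cohort_rows, columns=COHORT_HEADER).astype(str)
    annotations = pd.DataFrame(annotation_rows, columns=ANNOTATION_HEADER).astype(str)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_HEADER)
    return SimulatedCohort(cohort, annotations, truth, cfg)


# ---------------------------------------------------------------------------
# bundled clinical fixture
# ---------------------------------------------------------------------------

def fixture_paths() -> dict[str, Path]:
    """Paths of the bundled 25-proband cohort and its annotation table."""
    data = resources.files("crb1kit.data")
    return {
        "cohort": Path(str(data.joinpath("cohort_fixture.tsv"))),
        "annotations": Path(str(data.joinpath("variant_annotations.tsv"))),
    }


def emit_fixture(outdir) -> dict[str, Path]:
    """Write the bundled clinical fixture tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, src in fixture_paths().items():
        dst = outdir / src.name
        dst.write_text(src.read_text())
        out[name] = dst
    return out


# ---------------------------------------------------------------------------
# synthetic qPCR data
# ---------------------------------------------------------------------------

def simulate_dilution_series(
    efficiency: float,
    n_points: int = 5,
    intercept: float = 30.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> DilutionSeries:
    """Standard curve of a primer pair with known efficiency (10-fold steps)."""
    if rng is None:
        rng = np.random.default_rng(0)
    slope = -1.0 / np.log10(efficiency)
    points = []
    for k in range(n_points):
        log_amount = -float(k)
        cq = intercept + slope * log_amount
        if noise_sd > 0:
            cq += rng.normal(0.0, noise_sd)
        points.append((log_amount, cq))
    return DilutionSeries(tuple(points))


def simulate_qpcr_table(
    shares_by_sample: Mapping[str, Sequence[float]],
    efficiency: float = 2.0,
    anchor_cq: float = 22.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long-format measurement table realizing given isoform shares.

    Per sample, isoform quantities proportional to the requested A/B/C
    shares are converted to Cq around a total-CRB1 anchor; optional
    Gaussian Cq jitter and technical replicates emulate bench noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for sample_id, shares in shares_by_sample.items():
        shares = np.asarray(shares, dtype=float)
        if shares.shape != (3,) or shares.min() <= 0:
            raise DomainError("each sample needs three positive isoform shares")
        shares = shares / shares.sum()
        for _ in range(replicates):
            rows.append(
                {"sample_id": sample_id, "target_id": "CRB1_total",
                 "Cq": anchor_cq + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                 "efficiency": efficiency}
            )
        for iso, share in zip("ABC", shares):
            cq = anchor_cq - np.log(share) / np.log(efficiency)
            for _ in range(replicates):
                rows.append(
                    {"sample_id": sample_id, "target_id": f"CRB1_{iso}",
                     "Cq": cq + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                     "efficiency": efficiency}
                )
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "Cq", "efficiency"])
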