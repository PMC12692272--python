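import pytest

from crb1kit import (
    ConsequenceClass,
    ScoringConfig,
    VariantDescriptor,
    VariantRecord,
    fixture_paths,
    load_cohort,
)
from crb1kit.model import CodingCoord, EditKind


@pytest.fixture(scope="session")
def default_cfg():
    return ScoringConfig.default()


@pytest.fixture(scope="session")
def fixture_cohort():
    paths = fixture_paths()
    return load_cohort(paths["cohort"], paths["annotations"])


def make_variant(
    exon,
    consequence,
    damaging_count=None,
    splice_tokens=(),
    position=1000,
    protein=None,
):
    """Minimal annotated variant for scoring tests (descriptor is a stand-in)."""
    descriptor = VariantDescriptor(
        raw_cdna=f"c.{position}G>A",
        start=CodingCoord(position),
        end=None,
        edit_kind=EditKind.SUBSTITUTION,
    )
    return VariantRecord(
        descriptor=descriptor,
        exon=exon,
        consequence_class=ConsequenceClass(consequence),
        protein_change=protein,
        damaging_count=damaging_count,
        splice_tokens=tuple(splice_tokens),
    )
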