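import pytest

from immunome.ingest import ingest_directory
from immunome.novelty import KnownArchitectureCatalog
from immunome.pipeline import classify_catalog
from immunome.records import (
    DomainHit,
    HomologyHit,
    OrfRecord,
    TmdSegment,
    TranscriptAnnotation,
)
from immunome.rules import load_rules
from immunome.simulate import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def known_catalog():
    return KnownArchitectureCatalog.from_tsv()


def make_annotation(
    tx="tx1",
    domains=(),
    tmds=(),
    homology=(),
    peptide_length=1000,
    has_start=True,
    has_stop=True,
    species="test_sp",
):
    """Build a TranscriptAnnotation from shorthand domain specs.

    ``domains`` entries: (name, family, clan, start, end) or
    (name, family, clan) with auto-layout; ``tmds``: (start, end) pairs;
    ``homology``: (subject_id, species) pairs (peptide-level swissprot hits).
    """
    hits = []
    pos = 10
    for spec in domains:
        if len(spec) == 5:
            name, fam, clan, start, end = spec
        else:
            name, fam, clan = spec
            start, end = pos, pos + 79
            pos = end + 20
        hits.append(DomainHit(tx, name, fam, clan, start, end, 1e-20))
    peptide = "M" + "A" * (peptide_length - 1)
    return TranscriptAnnotation(
        transcript_id=tx,
        gene_group_id=tx,
        species_label=species,
        orf=OrfRecord(tx, tx + ".p1", peptide, has_start, has_stop),
        domains=hits,
        tmds=[TmdSegment(tx, s, e) for s, e in tmds],
        homology=[
            HomologyHit(tx, "swissprot", subj, sp, 1e-20, "peptide")
            for subj, sp in homology
        ],
    )


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The standard planted fixture: 9 families x 3 genes, 30% partials,
    10 decoys; seed 42."""
    outdir = tmp_path_factory.mktemp("fixture42")
    cfg = FixtureConfig()
    path, truth = generate_fixture(cfg, 42, outdir)
    return path, truth, cfg


@pytest.fixture(scope="session")
def classified_fixture(default_fixture, known_catalog):
    path, truth, cfg = default_fixture
    catalog, warns = ingest_directory(path, cfg.species_label)
    result = classify_catalog(
        catalog,
        known=known_catalog,
        masp_reference_ids=set(truth.masp_reference_ids),
    )
    return catalog, truth, result
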