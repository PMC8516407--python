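import pytest

from becath import ElectronEquivalentCatalog, ReactorConfig
from becath import datasets


@pytest.fixture(scope="session")
def config() -> ReactorConfig:
    """Published reactor geometry: Q = 0.58 L/d, Vc = 0.821 L."""
    return ReactorConfig()


@pytest.fixture(scope="session")
def catalog() -> ElectronEquivalentCatalog:
    return ElectronEquivalentCatalog()


@pytest.fixture(scope="session")
def dehalogenase_records():
    return datasets.dmccartyi_dehalogenase_records()


@pytest.fixture(scope="session")
def crispr_records():
    return datasets.dmccartyi_crispr_records()


@pytest.fixture(scope="session")
def cobalamin_records():
    return datasets.dmccartyi_cobalamin_records()


@pytest.fixture(scope="session")
def hydrogenase_records():
    return datasets.dmccartyi_hydrogenase_records()


@pytest.fixture(scope="session")
def dmccartyi_genome():
    return datasets.dmccartyi_records()


@pytest.fixture(scope="session")
def methanogen_records():
    return datasets.methanogen_m00567_records()


@pytest.fixture(scope="session")
def marker_catalogs():
    from becath import load_catalogs

    return load_catalogs()


@pytest.fixture(scope="session")
def marker_pool(marker_catalogs):
    """Pool of (symbol, product) pairs — markers, near-misses and decoys —
    for randomized profiler/oracle comparisons."""
    pool = [
        ("rdha", "reductive dehalogenase"),
        ("", "reductive dehalogenase"),
        ("rdhb", "reductive dehalogenase membrane-anchoring subunit RdhB"),
        ("", "dehalogenase hypothetical protein"),
        ("", "haloacid dehalogenase"),
        ("tcea", "TceA reductive dehalogenase catalytic subunit"),
        ("cas3", "CRISPR-associated helicase Cas3"),
        ("", "type I-E CRISPR-associated protein Cse1/CasA"),
        ("", "LexA family transcriptional regulator"),
        ("cobc", "alpha-ribazole phosphatase"),
        ("cobn", "cobaltochelatase subunit CobN"),
        ("cbid", "cobalt-precorrin-5B (C(1))-methyltransferase"),
        ("cysg", "siroheme synthase"),
        ("btuf", "vitamin B12 ABC transporter B12-binding component BtuF"),
        ("fwda", "formylmethanofuran dehydrogenase subunit A"),
        ("mcra", "coenzyme-B sulfoethylthiotransferase subunit alpha"),
        ("mtrh", "tetrahydromethanopterin S-methyltransferase subunit H"),
        ("frhb", "coenzyme F420 hydrogenase subunit beta"),
        ("hdrc", "CoB-CoM heterodisulfide reductase subunit C"),
        ("hypa", "hydrogenase maturation nickel metallochaperone HypA"),
        ("hycc", "hydrogenase membrane subunit"),
        ("hymd", "[Fe] hydrogenase, HymD subunit"),
        ("vhua", "Ni/Fe hydrogenase subunit alpha"),
        ("eche", "Ni-dependent hydrogenase large subunit"),
        ("hupl", "uptake hydrogenase large subunit"),
        ("hypc/hybg/hupf", "HypC/HybG/HupF family hydrogenase formation chaperone"),
        ("mtra", "extracellular electron conduit MtrA"),
        ("mtrb", "extracellular electron conduit MtrB"),
        ("mtrc", "extracellular electron conduit MtrC"),
        ("", "cytochrome c"),
        ("", "putative b-type cytochrome subunit"),
        ("", "ABC transporter ATP-binding protein"),
        ("", "ABC transporter permease"),
        ("npdg", "NADPH-dependent F420 reductase"),
        ("", "NADPH-dependent FMN reductase"),
        ("", "hypothetical protein"),
        ("rpob", "DNA-directed RNA polymerase subunit beta"),
        ("gyra", "DNA gyrase subunit A"),
        ("tuf", "elongation factor Tu"),
        ("", "formate dehydrogenase H"),
        ("sdha", "succinate dehydrogenase flavoprotein subunit"),
    ]
    return pool
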