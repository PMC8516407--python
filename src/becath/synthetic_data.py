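"""Synthetic test-data generators with known ground truth.

Three generators, all deterministic under a seed:

* :func:`generate_series` — steady-state reactor monitoring series:
  i.i.d. Gaussian noise around stated analyte means (truncated at zero)
  plus a noisy current trace, with the noiseless efficiency report
  attached as ground truth.
* :func:`generate_genome` — mock annotation tables that plant exactly the
  marker genes needed for a requested capability profile, padded with
  neutral decoy genes that are guaranteed (checked at generation time)
  not to collide with any catalog rule.
* :func:`generate_asv_table` — Dirichlet-distributed relative-abundance
  tables over a bundled lineage list.

The generators are statistical stand-ins for the study system (a
dechlorinating / Cr(VI)-reducing / methanogenic biocathode at steady
state); they model no reactor dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .capability_profiler import (
    GeneRecord,
    MarkerCatalog,
    load_catalogs,
    profile_genome,
)
from .community_summary import AbundanceTable
from .datasets import tce_cr_run_conditions
from .electron_balance import (
    ANALYTES,
    EfficiencyReport,
    MonitoringSeries,
    ReactorConfig,
    summarize_run,
)

__all__ = [
    "SyntheticSpec",
    "GenomeProfile",
    "ContradictionError",
    "DMCCARTYI_LIKE",
    "M_FORMICICUM_LIKE",
    "M_ARBORIPHILUS_LIKE",
    "ALL_FALSE",
    "PROFILES",
    "generate_series",
    "generate_genome",
    "generate_asv_table",
]


class ContradictionError(ValueError):
    """A requested capability profile cannot be planted as constrained."""


class SyntheticSpec(BaseModel):
    """Generative parameters for a synthetic monitoring series.

    Defaults emulate the TCE/Cr(VI) steady-state run: concentration means
    back-solved from the published rates and Coulombic efficiencies,
    5 % coefficient of variation measurement noise, 50 samples.
    """

    seed: int = 0
    n_samples: int = Field(ge=1, default=50)
    analyte_means: dict[str, float] | None = None
    noise_cv: float = Field(ge=0, default=0.05)
    current_mean_uA: float | None = None
    current_cv: float = Field(ge=0, default=0.05)
    reactor: ReactorConfig = Field(default_factory=ReactorConfig)
    influent: dict[str, float] | None = None

    def resolved(self) -> "SyntheticSpec":
        """Fill unset means/current/influent from the TCE/Cr(VI) run."""
        if self.analyte_means is not None and self.current_mean_uA is not None:
            return self
        run = tce_cr_run_conditions(self.reactor)
        return self.model_copy(update={
            "analyte_means": self.analyte_means or run["concentrations"],
            "current_mean_uA": self.current_mean_uA or run["current_uA"],
            "influent": self.influent or run["influent"],
        })

    def true_report(self, ce_decimals: int = 2) -> EfficiencyReport:
        """Efficiency report of the noiseless (mean) conditions."""
        spec = self.resolved()
        series = MonitoringSeries.from_samples(
            [0.0], spec.analyte_means, spec.current_mean_uA
        )
        return summarize_run(series, spec.reactor, influent=spec.influent,
                             ce_decimals=ce_decimals)


def generate_series(spec: SyntheticSpec) -> tuple[MonitoringSeries, EfficiencyReport]:
    """Draw a noisy monitoring series; returns (series, ground truth).

    Each analyte is sampled i.i.d. Normal(mean, cv*mean), truncated at 0
    (a mild upward bias at large cv); the current likewise.  Identical
    seeds give identical series.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    times = np.arange(n, dtype=float)
    conc: dict[str, np.ndarray] = {}
    for analyte in ANALYTES:
        mean = spec.analyte_means.get(analyte)
        if mean is None:
            continue
        draws = rng.normal(mean, spec.noise_cv * mean, size=n)
        conc[analyte] = np.clip(draws, 0.0, None)
    current = np.clip(
        rng.normal(spec.current_mean_uA, spec.current_cv * spec.current_mean_uA, size=n),
        0.0, None,
    )
    series = MonitoringSeries.from_samples(times, conc, current)
    return series, spec.true_report()


# ---------------------------------------------------------------------------
# Genome generation


@dataclass(frozen=True)
class GenomeProfile:
    """Target capability verdicts for a mock genome.

    Each knob maps to a planted marker set; the profiler run on the
    generated records reproduces the implied verdicts by construction.
    ``forbidden_symbol_prefixes`` forbids planting any gene whose symbol
    starts with one of the prefixes — a request that requires such a gene
    raises :class:`ContradictionError`.
    """

    name: str
    rdase_counts: Mapping[str, int] = field(default_factory=dict)
    crispr: bool = False
    crispr_auxiliary_only: bool = False
    cobalamin_upstream: bool = False
    cobalamin_downstream: bool = False
    btuf: bool = False
    methanogenesis: bool = False
    hydrogenase_complexes: tuple[str, ...] = ()
    mtrcab: bool = False
    cytochrome_c: bool = False
    n_abc_atp: int = 0
    n_abc_permease: int = 0
    npdg: bool = False
    forbidden_symbol_prefixes: tuple[str, ...] = ()

    @property
    def cr_extracellular(self) -> bool:
        return self.mtrcab and self.cytochrome_c

    @property
    def cr_intracellular(self) -> bool:
        return self.n_abc_atp > 0 and self.n_abc_permease > 0 and self.npdg


DMCCARTYI_LIKE = GenomeProfile(
    name="dmccartyi_like",
    rdase_counts={"catalytic_rdhA": 13, "anchor_rdhB": 1,
                  "hypothetical_dehalogenase": 14, "haloacid_dehalogenase": 1},
    crispr=True,
    cobalamin_upstream=False,
    cobalamin_downstream=True,
    btuf=True,
    hydrogenase_complexes=("Hyp", "Hyc", "Hym", "Vhu", "Ech"),
)

M_FORMICICUM_LIKE = GenomeProfile(
    name="m_formicicum_like",
    methanogenesis=True,
    cobalamin_upstream=True,
    mtrcab=True,
    cytochrome_c=True,
    n_abc_atp=16,
    n_abc_permease=17,
    npdg=True,
)

M_ARBORIPHILUS_LIKE = GenomeProfile(
    name="m_arboriphilus_like",
    methanogenesis=True,
    cobalamin_upstream=True,
    mtrcab=True,
    cytochrome_c=False,
    n_abc_atp=11,
    n_abc_permease=10,
    npdg=False,
)

ALL_FALSE = GenomeProfile(name="all_false")

PROFILES: dict[str, GenomeProfile] = {
    p.name: p for p in (DMCCARTYI_LIKE, M_FORMICICUM_LIKE, M_ARBORIPHILUS_LIKE, ALL_FALSE)
}

#: Neutral decoy vocabulary: (symbol, product). None of these may match
#: any catalog rule; this is asserted against the loaded catalogs at
#: generation time.
_DECOYS: tuple[tuple[str, str], ...] = (
    ("", "hypothetical protein"),
    ("rpsl", "30S ribosomal protein S12"),
    ("rplb", "50S ribosomal protein L2"),
    ("gyra", "DNA gyrase subunit A"),
    ("tuf", "elongation factor Tu"),
    ("dnak", "molecular chaperone DnaK"),
    ("ftsz", "cell division protein FtsZ"),
    ("secy", "preprotein translocase subunit SecY"),
    ("rpob", "DNA-directed RNA polymerase subunit beta"),
    ("infb", "translation initiation factor IF-2"),
)

_RDASE_TEMPLATES = {
    "catalytic_rdhA": ("rdha", "reductive dehalogenase"),
    "anchor_rdhB": ("rdhb", "reductive dehalogenase membrane-anchoring subunit RdhB"),
    "hypothetical_dehalogenase": ("", "dehalogenase hypothetical protein"),
    "haloacid_dehalogenase": ("", "haloacid dehalogenase"),
}

_HYDROGENASE_REPRESENTATIVES = {
    "Hyp": ("hypd", "hydrogenase formation protein HypD"),
    "Hyc": ("hycc", "hydrogenase membrane subunit HycC"),
    "Hym": ("hymd", "[Fe] hydrogenase, HymD subunit"),
    "Vhu": ("vhua", "Ni/Fe hydrogenase subunit alpha"),
    "Ech": ("eche", "Ni-dependent hydrogenase large subunit"),
    "Hup": ("hupl", "uptake hydrogenase large subunit"),
}


def _assert_decoys_neutral(catalogs: Mapping[str, MarkerCatalog]) -> None:
    records = [GeneRecord(f"DECOY{i:04d}", sym, prod)
               for i, (sym, prod) in enumerate(_DECOYS)]
    report = profile_genome(records, catalogs, genome_id="decoy_check")
    ok = (
        report.dehalogenase_inventory["total"] == 0
        and not report.crispr["present"]
        and not report.crispr["auxiliary_hits"]
        and report.cobalamin["upstream_M00924_completeness"] == 0
        and report.cobalamin["downstream_M00122_completeness"] == 0
        and not report.cobalamin["btuF_transport"]
        and report.methanogenesis_M00567_completeness == 0
        and not report.hydrogenase_complexes
        and not report.cr_reduction["extracellular"]
        and not report.cr_reduction["intracellular"]
        and not any(report.cr_reduction["evidence"][k]
                    for k in ("c_type_cytochromes", "abc_atp_dependent",
                              "abc_permeases", "nadph_reductases"))
    )
    if not ok:
        raise AssertionError("decoy vocabulary collides with a marker catalog rule")


def generate_genome(
    profile: GenomeProfile | str,
    n_decoys: int = 20,
    seed: int = 0,
    catalogs: Mapping[str, MarkerCatalog] | None = None,
) -> list[GeneRecord]:
    """Emit annotation records realizing exactly the requested profile.

    One alternative gene is planted per required pathway block, marker
    records per boolean knob, plus ``n_decoys`` neutral genes.  Record
    order is shuffled under ``seed`` (verdicts are order-independent).
    """
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise KeyError(
                f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
            ) from None
    catalogs = catalogs or load_catalogs()
    _assert_decoys_neutral(catalogs)
    forbidden = tuple(p.lower() for p in profile.forbidden_symbol_prefixes)

    planted: list[tuple[str, str]] = []

    def plant(symbol: str, product: str) -> None:
        if any(symbol.startswith(p) for p in forbidden if p):
            raise ContradictionError(
                f"profile {profile.name!r} requires gene {symbol!r} but symbols "
                f"with prefixes {forbidden} are forbidden"
            )
        planted.append((symbol, product))

    for cls, count in profile.rdase_counts.items():
        symbol, product = _RDASE_TEMPLATES[cls]
        for _ in range(count):
            plant(symbol, product)
    if profile.crispr:
        plant("cas3", "CRISPR-associated helicase Cas3")
    if profile.crispr or profile.crispr_auxiliary_only:
        plant("", "LexA family transcriptional regulator")
    if profile.cobalamin_upstream:
        for block in catalogs["m00924"].blocks:
            plant(block.alternatives[0], f"corrin ring biosynthesis protein {block.name}")
    if profile.cobalamin_downstream:
        for block in catalogs["m00122"].blocks:
            plant(block.alternatives[0], f"cobalamin biosynthesis protein {block.name}")
    if profile.btuf:
        plant("btuf", "vitamin B12 ABC transporter B12-binding component BtuF")
    if profile.methanogenesis:
        for block in catalogs["m00567"].blocks:
            plant(block.alternatives[0], f"methanogenesis enzyme ({block.name})")
    for complex_name in profile.hydrogenase_complexes:
        symbol, product = _HYDROGENASE_REPRESENTATIVES[complex_name]
        plant(symbol, product)
    if profile.mtrcab:
        plant("mtra", "extracellular electron conduit periplasmic component MtrA")
        plant("mtrb", "extracellular electron conduit outer membrane component MtrB")
        plant("mtrc", "extracellular electron conduit decaheme component MtrC")
    if profile.cytochrome_c:
        plant("", "cytochrome c")
    for _ in range(profile.n_abc_atp):
        plant("", "ABC transporter ATP-binding protein")
    for _ in range(profile.n_abc_permease):
        plant("", "ABC transporter permease")
    if profile.npdg:
        plant("npdg", "NADPH-dependent F420 reductase")

    rng = np.random.default_rng(seed)
    for _ in range(n_decoys):
        symbol, product = _DECOYS[rng.integers(len(_DECOYS))]
        planted.append((symbol, product))

    order = rng.permutation(len(planted))
    return [
        GeneRecord(f"SYN{profile.name.upper()}_{i:05d}", planted[j][0], planted[j][1])
        for i, j in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# ASV tables

#: Bundled lineage pool: key taxa of dechlorinating biocathode biofilms.
LINEAGES: tuple[str, ...] = (
    "Bacteria;Chloroflexi;Dehalococcoidia;Dehalococcoidales;Dehalococcoidaceae;Dehalococcoides;Dehalococcoides mccartyi",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfovibrionales;Desulfovibrionaceae;Desulfovibrio;Desulfovibrio sulfodismutans",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Lentimicrobiaceae;Lentimicrobium",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Betaproteobacteriales;Rhodocyclaceae",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Betaproteobacteriales;Hydrogenophilaceae;Thiobacillus",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Caulobacterales;Caulobacteraceae;Brevundimonas;Brevundimonas diminuta",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Brucellaceae;Ochrobactrum;Ochrobactrum anthropi",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Betaproteobacteriales;Rhodocyclaceae;Dechloromonas",
    "Bacteria;Synergistetes;Synergistia;Synergistales;Synergistaceae;Thermovirga",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Soehngenia",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Acidaminobacter",
    "Bacteria;Actinobacteria;Coriobacteriia;OPB41",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium;Methanobacterium formicicum",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobrevibacter;Methanobrevibacter arboriphilus",
)


def generate_asv_table(
    seed: int, n_asvs: int, n_samples: int, concentration: float = 0.8
) -> AbundanceTable:
    """Dirichlet-distributed ASV relative abundances summing to 100 %.

    Taxonomy strings cycle through the bundled lineage pool; ASV ids are
    ASV1..ASVn.  ``concentration`` is the symmetric Dirichlet parameter
    (smaller -> more uneven communities, as in real biofilms).
    """
    if n_asvs < 1 or n_samples < 1:
        raise ValueError("n_asvs and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    columns = rng.dirichlet([concentration] * n_asvs, size=n_samples).T * 100.0
    ids = [f"ASV{i + 1}" for i in range(n_asvs)]
    taxonomy = [LINEAGES[i % len(LINEAGES)] for i in range(n_asvs)]
    frame = pd.DataFrame(
        columns, index=ids, columns=[f"S{j + 1}" for j in range(n_samples)]
    )
    frame.insert(0, AbundanceTable.TAXONOMY_COL, taxonomy)
    frame.index.name = "asv_id"
    return AbundanceTable(frame)
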