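"""Relative-abundance table plumbing and qPCR normalization.

Handles the tabular side of 16S community profiling: ASV relative
abundance tables with Silva-style taxonomy lineages (aggregation to a
taxonomic rank, top-N reduction for heatmaps) and conversion of qPCR
copies-per-reaction into copies per gram of carrier material (graphite
granules).  No sequence processing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AbundanceTable",
    "QpcrMeasurement",
    "QpcrResult",
    "aggregate",
    "top_asvs",
    "copies_per_gram",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Silva/QIIME-style rank prefixes stripped from lineage fields.
_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")

UNCLASSIFIED = "unclassified"


def _clean_rank(token: str) -> str:
    token = token.strip()
    for prefix in _PREFIXES:
        if token.startswith(prefix):
            token = token[len(prefix):]
            break
    return token.strip() or UNCLASSIFIED


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ';'-separated lineage into rank->name; short lineages are
    padded with 'unclassified'."""
    tokens = [_clean_rank(t) for t in lineage.split(";")] if lineage else []
    return {
        rank: tokens[i] if i < len(tokens) else UNCLASSIFIED
        for i, rank in enumerate(RANKS)
    }


class AbundanceTable:
    """ASV x sample relative abundances (%) with a taxonomy column.

    Wraps a DataFrame indexed by feature id with a ``taxonomy`` column
    followed by one column per sample.  Values are percentages; each
    sample column must sum to <= 100 (+0.5 tolerance).
    """

    TAXONOMY_COL = "taxonomy"

    def __init__(self, frame: pd.DataFrame):
        if self.TAXONOMY_COL not in frame.columns:
            raise ValueError("abundance table needs a 'taxonomy' column")
        samples = [c for c in frame.columns if c != self.TAXONOMY_COL]
        if not samples:
            raise ValueError("abundance table needs >=1 sample column")
        values = frame[samples].apply(pd.to_numeric)
        if (values < 0).any().any():
            raise ValueError("abundances must be >= 0")
        sums = values.sum(axis=0)
        if (sums > 100.5).any():
            bad = sums[sums > 100.5].index.tolist()
            raise ValueError(f"sample columns exceed 100%: {bad}")
        self.frame = pd.concat([frame[[self.TAXONOMY_COL]], values], axis=1)

    @property
    def samples(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.TAXONOMY_COL]

    @property
    def values(self) -> pd.DataFrame:
        return self.frame[self.samples]

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")


def aggregate(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum abundances within each taxon at ``rank``.

    Lineages too short for the rank are bucketed under 'unclassified';
    per-sample column totals are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    names = table.frame[AbundanceTable.TAXONOMY_COL].map(
        lambda lin: parse_lineage(str(lin))[rank]
    )
    grouped = table.values.groupby(names, sort=True).sum()
    grouped.insert(0, AbundanceTable.TAXONOMY_COL, grouped.index)
    grouped.index.name = rank
    return AbundanceTable(grouped)


def top_asvs(table: AbundanceTable, n: int) -> AbundanceTable:
    """Keep the n features with the highest max-across-samples abundance;
    collapse the remainder into an 'other' row (column sums preserved).
    Ties are broken by feature id, lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranking = pd.DataFrame({
        "peak": table.values.max(axis=1),
        "id": table.frame.index.astype(str),
    }).sort_values(["peak", "id"], ascending=[False, True])
    keep = ranking.index[:n]
    kept = table.frame.loc[keep]
    rest = table.values.drop(index=keep)
    other = rest.sum(axis=0)
    other_row = pd.DataFrame(
        {AbundanceTable.TAXONOMY_COL: ["other"], **{s: [other[s]] for s in table.samples}},
        index=["other"],
    )
    return AbundanceTable(pd.concat([kept, other_row]))


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR quantification of a target gene.

    ``copies_per_reaction`` holds the replicate measurements (a scalar is
    treated as a single replicate); volumes in uL, sample mass in grams.
    """

    target: str
    copies_per_reaction: tuple[float, ...]
    template_volume_uL: float
    eluate_volume_uL: float
    sample_mass_g: float

    def __post_init__(self) -> None:
        if self.template_volume_uL <= 0 or self.eluate_volume_uL <= 0:
            raise ValueError("template and eluate volumes must be > 0")
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be > 0")
        if not self.copies_per_reaction:
            raise ValueError("at least one replicate required")
        if any(c < 0 for c in self.copies_per_reaction):
            raise ValueError("copies must be >= 0")

    @classmethod
    def single(cls, target: str, copies: float, template_volume_uL: float,
               eluate_volume_uL: float, sample_mass_g: float) -> "QpcrMeasurement":
        return cls(target, (copies,), template_volume_uL, eluate_volume_uL, sample_mass_g)


@dataclass(frozen=True)
class QpcrResult:
    target: str
    mean_copies_per_g: float
    sd_copies_per_g: float
    n_replicates: int


def copies_per_gram(m: QpcrMeasurement) -> QpcrResult:
    """Normalize reaction copies to gene copies per gram of sample.

    copies/g = copies/reaction * (eluate volume / template volume) / mass.
    Replicates are converted individually; mean and sd (ddof=1, 0 for a
    single replicate) are reported.
    """
    factor = (m.eluate_volume_uL / m.template_volume_uL) / m.sample_mass_g
    per_g = np.asarray(m.copies_per_reaction, dtype=float) * factor
    sd = float(per_g.std(ddof=1)) if per_g.size > 1 else 0.0
    return QpcrResult(m.target, float(per_g.mean()), sd, per_g.size)
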