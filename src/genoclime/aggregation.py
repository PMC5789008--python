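"""Aggregate sample-level allele frequencies to population-level frequencies.

Published frequencies for the same polymorphism come from many independent
samples of very different sizes.  Following standard meta-analytic practice,
the per-population frequency is the sample-size-weighted mean of all samples
from that population, after every record has been oriented to the
polymorphism's canonical allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polymorphisms import CANONICAL_IDS, get, resolve_id

#: required columns of a sample-level frequency table
SAMPLE_COLUMNS = (
    "sample_id",
    "population_id",
    "continent",
    "polymorphism_id",
    "allele",
    "freq",
    "n",
)


def orient_allele(raw_freq: float, polymorphism_id: str, reported_allele: str) -> float:
    """Express ``raw_freq`` on the polymorphism's canonical allele.

    If the record reports the canonical allele the frequency passes through;
    if it reports the complementary allele the complement ``1 - raw_freq`` is
    returned.

    Raises
    ------
    ValueError
        If the frequency is outside [0, 1] or the allele label is not one of
        the polymorphism's two coded alleles.
    """
    if not 0.0 <= raw_freq <= 1.0:
        raise ValueError(f"frequency {raw_freq} outside [0, 1]")
    poly = get(polymorphism_id)
    allele = reported_allele.strip()
    if allele.lower() == poly.canonical_allele.lower():
        return float(raw_freq)
    if allele.lower() == poly.other_allele.lower():
        return float(1.0 - raw_freq)
    raise ValueError(
        f"unknown allele {reported_allele!r} for {poly.gene} {poly.rsid} "
        f"({poly.label}); expected {poly.canonical_allele!r} or {poly.other_allele!r}"
    )


@dataclass
class PopulationFrequencyMatrix:
    """Populations × polymorphisms matrix of weighted canonical-allele frequencies.

    ``frequencies`` holds the weighted mean frequency (NaN where no sample
    exists); ``support`` the total number of participants behind each cell.
    """

    frequencies: pd.DataFrame
    support: pd.DataFrame
    continents: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.frequencies.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if present.any() and ((vals[present] < 0) | (vals[present] > 1)).any():
            raise ValueError("frequencies outside [0, 1]")
        supp = self.support.to_numpy(dtype=float)
        if (present & ~(supp > 0)).any():
            raise ValueError("present cells must have positive support")

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.index)

    def to_csv(self, path) -> None:
        self.frequencies.to_csv(path, index_label="population_id")

    @classmethod
    def from_csv(cls, path) -> "PopulationFrequencyMatrix":
        freq = pd.read_csv(path, index_col="population_id", comment="#")
        support = pd.DataFrame(
            np.where(freq.notna(), 1.0, np.nan), index=freq.index, columns=freq.columns
        )
        return cls(frequencies=freq, support=support)


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample-level CSV (columns ``SAMPLE_COLUMNS``)."""
    df = pd.read_csv(path, comment="#")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    return df


def aggregate_samples(records: pd.DataFrame) -> PopulationFrequencyMatrix:
    """Weighted-average sample records into one frequency per population per locus.

    Each cell is ``sum(n_i * f_i) / sum(n_i)`` over the population's samples
    for that polymorphism; cells with no sample are missing.  Frequencies are
    oriented to the canonical allele before averaging.

    Raises
    ------
    ValueError
        On invalid frequencies or sample sizes, unknown polymorphism or
        allele labels, or when the same ``sample_id`` appears twice for one
        (population, polymorphism) pair — each study population may enter the
        average only once.
    """
    df = records.copy()
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")

    df["polymorphism_id"] = df["polymorphism_id"].map(resolve_id)
    if not (df["n"] >= 1).all():
        raise ValueError("sample sizes must be >= 1")
    dup = df.duplicated(subset=["population_id", "polymorphism_id", "sample_id"])
    if dup.any():
        rows = df.loc[dup, ["population_id", "polymorphism_id", "sample_id"]]
        raise ValueError(
            "duplicate sample_id for the same population and polymorphism "
            f"(each study population enters once): {rows.to_dict('records')}"
        )

    df["freq_canonical"] = [
        orient_allele(f, pid, allele)
        for f, pid, allele in zip(df["freq"], df["polymorphism_id"], df["allele"])
    ]
    df["_wf"] = df["freq_canonical"] * df["n"]

    grouped = df.groupby(["population_id", "polymorphism_id"])
    wsum = grouped["_wf"].sum().unstack("polymorphism_id")
    nsum = grouped["n"].sum().unstack("polymorphism_id")
    freq = wsum / nsum

    # fixed canonical column order; loci never observed stay all-missing
    freq = freq.reindex(columns=list(CANONICAL_IDS))
    nsum = nsum.reindex(columns=list(CANONICAL_IDS))

    continents = (
        df.drop_duplicates("population_id")
        .set_index("population_id")["continent"]
        .reindex(freq.index)
    )
    return PopulationFrequencyMatrix(frequencies=freq, support=nsum, continents=continents)


def sample_level_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot sample records to a samples × polymorphisms frequency matrix.

    Used for the sample-level principal-component analysis that is compared
    with the population-level solution.  Frequencies are oriented to the
    canonical allele; samples reporting only a subset of loci yield missing
    cells.
    """
    df = records.copy()
    df["polymorphism_id"] = df["polymorphism_id"].map(resolve_id)
    df["freq_canonical"] = [
        orient_allele(f, pid, allele)
        for f, pid, allele in zip(df["freq"], df["polymorphism_id"], df["allele"])
    ]
    wide = df.pivot_table(
        index="sample_id", columns="polymorphism_id", values="freq_canonical"
    )
    return wide.reindex(columns=list(CANONICAL_IDS))
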