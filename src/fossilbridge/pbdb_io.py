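"""Reading, cleaning, dating and binning of fossil occurrence tables.

The input format is the Paleobiology Database (PBDB) occurrence CSV export:
one row per occurrence with a taxon name, a family assignment, a collection
identifier and an age range (``max_ma`` older bound, ``min_ma`` younger
bound, both in Ma). The pipeline is

``read_occurrences -> clean_occurrences -> draw_collection_ages -> bin_family``

and turns the raw table into a per-family vector of sampled species richness
in fixed-width time bins (default 1 Myr), the quantity the Brownian-bridge
model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "BinnedCounts",
    "CleaningReport",
    "DEFAULT_DIALECT",
    "read_occurrences",
    "clean_occurrences",
    "draw_collection_ages",
    "bin_family",
    "read_modern_diversity",
]

#: Default mapping from logical field names to PBDB export column names.
#: ``trace_values``: values of the trace column that flag a trace fossil
#: (ichnofossils; footprints, burrows etc. rather than body fossils).
DEFAULT_DIALECT: Mapping[str, object] = {
    "species": "accepted_name",
    "family": "family",
    "collection": "collection_no",
    "max_ma": "max_ma",
    "min_ma": "min_ma",
    "trace": "pres_mode",
    "trace_values": ("trace",),
}


@dataclass
class OccurrenceRecord:
    """A single fossil occurrence (one taxon in one collection)."""

    species_name: str | None
    family: str | None
    collection_id: object
    max_ma: float
    min_ma: float
    is_trace: bool = False
    age: float | None = None  # assigned by draw_collection_ages

    def age_range(self) -> float:
        return self.max_ma - self.min_ma


@dataclass
class BinnedCounts:
    """Sampled species richness of one family in fixed-width time bins.

    ``counts[i]`` is the number of distinct species with an assigned age in
    bin ``i``, where bin ``i`` covers ``[i*w, (i+1)*w)`` Ma before present
    (half-open; bin 0 is the most recent). ``n_extant`` is present-day
    species richness; 0 marks an extinct family.
    """

    family: str
    counts: np.ndarray
    n_extant: int
    bin_width: float = 1.0
    oldest_fossil: float = field(default=np.nan)
    youngest_fossil: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.any():
            raise ValueError(f"family {self.family!r}: all bins empty")
        if self.n_extant < 0:
            raise ValueError("n_extant must be non-negative")
        nz = np.flatnonzero(self.counts)
        w = self.bin_width
        if np.isnan(self.oldest_fossil):
            self.oldest_fossil = (nz[-1] + 1) * w  # older edge of oldest bin
        if np.isnan(self.youngest_fossil):
            self.youngest_fossil = nz[0] * w  # younger edge of youngest bin
        if self.oldest_fossil < self.youngest_fossil:
            raise ValueError("oldest_fossil must be >= youngest_fossil")

    @property
    def is_extant(self) -> bool:
        return self.n_extant > 0

    @property
    def n_fossils(self) -> int:
        """Total binned diversity (distinct species-in-bin entries)."""
        return int(self.counts.sum())


@dataclass
class CleaningReport:
    """Tally of removals applied by :func:`clean_occurrences`."""

    n_input: int = 0
    n_removed_no_family: int = 0
    n_removed_no_species: int = 0
    n_removed_age_range: int = 0
    n_removed_trace: int = 0
    n_removed_duplicates: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_occurrences(
    path,
    dialect: Mapping[str, object] | None = None,
) -> list[OccurrenceRecord]:
    """Read a PBDB-style occurrence CSV into records.

    No cleaning happens here: missing species/family fields are preserved as
    ``None`` and filtered later by :func:`clean_occurrences`. A row whose age
    bounds are inverted (``max_ma < min_ma``) is a hard error because no
    downstream step can interpret it.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path)
    required = ["species", "family", "collection", "max_ma", "min_ma"]
    for key in required:
        col = d[key]
        if col not in df.columns:
            raise ValueError(f"required column {col!r} (field {key!r}) not found in {path}")
    trace_col = d.get("trace")
    trace_values = {str(v).lower() for v in d.get("trace_values", ())}
    records: list[OccurrenceRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        max_ma = float(rowd[d["max_ma"]])
        min_ma = float(rowd[d["min_ma"]])
        if max_ma < min_ma:
            raise ValueError(f"row {idx}: max_ma ({max_ma}) < min_ma ({min_ma})")
        if min_ma < 0:
            raise ValueError(f"row {idx}: negative age")
        species = rowd[d["species"]]
        family = rowd[d["family"]]
        is_trace = False
        if trace_col is not None and trace_col in df.columns:
            is_trace = str(rowd[trace_col]).lower() in trace_values
        records.append(
            OccurrenceRecord(
                species_name=None if _is_missing(species) else str(species),
                family=None if _is_missing(family) else str(family),
                collection_id=rowd[d["collection"]],
                max_ma=max_ma,
                min_ma=min_ma,
                is_trace=is_trace,
            )
        )
    return records


def clean_occurrences(
    records: Sequence[OccurrenceRecord],
    max_age_range: float = 20.0,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Apply the occurrence-quality filters.

    Removes records lacking a family or species assignment, records whose
    stratigraphic age range exceeds ``max_age_range`` Myr (strictly greater;
    a 20-Myr range is retained under the default), and trace fossils. A
    record failing several filters is tallied once, under the first failing
    rule in the order: no-family, no-species, age-range, trace.
    """
    report = CleaningReport(n_input=len(records))
    kept: list[OccurrenceRecord] = []
    for rec in records:
        if rec.family is None:
            report.n_removed_no_family += 1
        elif rec.species_name is None:
            report.n_removed_no_species += 1
        elif rec.age_range() > max_age_range:
            report.n_removed_age_range += 1
        elif rec.is_trace:
            report.n_removed_trace += 1
        else:
            kept.append(rec)
    report.n_output = len(kept)
    return kept, report


def draw_collection_ages(
    records: Sequence[OccurrenceRecord],
    seed: int,
) -> list[OccurrenceRecord]:
    """Assign each record an age drawn uniformly from its collection's range.

    One age is drawn per collection (in order of first appearance) and shared
    by every occurrence from that collection, mirroring the fact that a
    collection is a single fossil assemblage with one true age. Reproducible
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ages: dict[object, float] = {}
    out: list[OccurrenceRecord] = []
    for rec in records:
        if rec.collection_id not in ages:
            ages[rec.collection_id] = float(rng.uniform(rec.min_ma, rec.max_ma))
        out.append(
            OccurrenceRecord(
                species_name=rec.species_name,
                family=rec.family,
                collection_id=rec.collection_id,
                max_ma=rec.max_ma,
                min_ma=rec.min_ma,
                is_trace=rec.is_trace,
                age=ages[rec.collection_id],
            )
        )
    return out


def bin_family(
    records: Sequence[OccurrenceRecord],
    family: str,
    n_extant: int,
    bin_width: float = 1.0,
) -> BinnedCounts:
    """Bin one family's dated occurrences into distinct-species counts.

    Bin ``i`` covers ``[i*w, (i+1)*w)`` Ma (half-open, bin 0 most recent);
    a species occurring several times within one bin counts once. Duplicate
    removal also counts across collections within the bin: the vector is
    diversity through time, not abundance.
    """
    recs = [r for r in records if r.family == family]
    if not recs:
        raise ValueError(f"no data for family {family!r}")
    for r in recs:
        if r.age is None:
            raise ValueError("records must carry drawn ages; run draw_collection_ages first")
    pairs = {(r.species_name, int(r.age // bin_width)) for r in recs}
    n_bins = max(b for _, b in pairs) + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, b in pairs:
        counts[b] += 1
    ages = [r.age for r in recs]
    return BinnedCounts(
        family=family,
        counts=counts,
        n_extant=n_extant,
        bin_width=bin_width,
        oldest_fossil=max(ages),
        youngest_fossil=min(ages),
    )


def read_modern_diversity(path) -> dict[str, int]:
    """Read a (family, n_extant) CSV into a mapping; absent families are extinct."""
    df = pd.read_csv(path)
    if not {"family", "n_extant"}.issubset(df.columns):
        raise ValueError(f"modern-diversity file {path} needs columns 'family' and 'n_extant'")
    return {str(f): int(n) for f, n in zip(df["family"], df["n_extant"])}
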