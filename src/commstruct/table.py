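"""Taxon-by-count community tables: I/O, aggregation, exclusion, ranking.

The central data structures are :class:`CommunityTable` — one record per
lowest-level taxon (species or morphospecies) with family/order rank labels,
an optional trophic-guild label and an integer individual count — and
:class:`AbundanceVector`, the ranked positive counts at one taxonomic level,
which is what the abundance-distribution models and diversity indices
consume.

The on-disk format is a plain UTF-8 CSV with the mandatory header
``taxon_id,species,family,order,guild,count``.  Lines starting with ``#``
before the header carry provenance metadata (e.g. ``# filters: ...`` on a
filtered table) and are round-tripped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "GUILDS",
    "TaxonRecord",
    "CommunityTable",
    "AbundanceVector",
    "read_table",
    "write_table",
    "aggregate",
    "exclude_taxa",
    "relative_abundance",
]

#: Taxonomic levels at which the community can be analysed.
RANKS = ("species", "family", "order")

#: Recognised trophic-guild labels. "unknown" is legal in a table but is
#: excluded (and counted) by the guild analysis.
GUILDS = ("herbivore", "predator", "scavenger", "unknown")

REQUIRED_COLUMNS = ("taxon_id", "species", "family", "order", "guild", "count")


class TableFormatError(ValueError):
    """The file does not conform to the CSV dialect (missing columns...)."""


class TableValidationError(ValueError):
    """The file parses but violates a table invariant (bad count, dup id...)."""


@dataclass(frozen=True)
class TaxonRecord:
    """One lowest-level taxon and its pooled individual count."""

    taxon_id: str
    species: str
    family: str
    order: str
    guild: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise TableValidationError(
                f"taxon {self.taxon_id!r}: count must be >= 0, got {self.count}"
            )
        for rank in ("species", "family", "order"):
            if not getattr(self, rank):
                raise TableValidationError(
                    f"taxon {self.taxon_id!r}: empty {rank} label"
                )
        if self.guild not in GUILDS:
            raise TableValidationError(
                f"taxon {self.taxon_id!r}: guild must be one of {GUILDS}, "
                f"got {self.guild!r}"
            )


@dataclass(frozen=True)
class CommunityTable:
    """Ordered collection of taxon records plus free-text provenance."""

    records: tuple[TaxonRecord, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = [r.taxon_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            raise TableValidationError(f"duplicate taxon_id(s): {sorted(set(dups))}")

    @property
    def total(self) -> int:
        """Total number of individuals N."""
        return int(sum(r.count for r in self.records))

    @property
    def n_zero_count(self) -> int:
        """Number of retained zero-count records (flagged, not analysed)."""
        return sum(1 for r in self.records if r.count == 0)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a pandas DataFrame (one row per record)."""
        return pd.DataFrame([vars(r) for r in self.records], columns=REQUIRED_COLUMNS)


@dataclass(frozen=True)
class AbundanceVector:
    """Ranked (descending) positive counts at one taxonomic level.

    ``counts[i]`` is the abundance of the group ``labels[i]``; length is the
    richness S at that level.  Ties in the descending sort are broken by
    first appearance in the source table, so rank profiles are deterministic.
    """

    level: str
    counts: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.level not in RANKS:
            raise ValueError(f"level must be one of {RANKS}, got {self.level!r}")
        if len(self.counts) != len(self.labels):
            raise ValueError("counts and labels must be parallel")
        if len(self.counts) == 0:
            raise ValueError("abundance vector must not be empty")
        arr = np.asarray(self.counts)
        if np.any(arr <= 0):
            raise ValueError("all counts must be strictly positive")
        if np.any(np.diff(arr) > 0):
            raise ValueError("counts must be non-increasing")

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _parse_metadata(lines: list[str]) -> dict:
    meta: dict = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if body.startswith("filters:"):
            meta.setdefault("filters", []).extend(
                f.strip() for f in body[len("filters:"):].split(";") if f.strip()
            )
        elif body:
            meta.setdefault("comments", []).append(body)
    return meta


def read_table(path) -> CommunityTable:
    """Read a community table from a CSV file.

    Raises :class:`TableFormatError` if a required column is missing and
    :class:`TableValidationError` (with the offending row) for negative or
    non-integer counts and duplicate taxon ids.  Zero-count rows are kept
    (they are dropped later by :func:`aggregate`).
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header_meta = []
    body_start = 0
    for ln in text.splitlines(keepends=True):
        if ln.startswith("#"):
            header_meta.append(ln)
            body_start += len(ln)
        else:
            break
    df = pd.read_csv(
        io.StringIO(text[body_start:]), dtype=str, keep_default_na=False
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = getattr(row, "count")
        try:
            cnt = int(raw)
        except (TypeError, ValueError):
            raise TableValidationError(
                f"{path}, row {i}: count {raw!r} is not an integer"
            ) from None
        if str(raw).strip() != str(cnt):
            raise TableValidationError(
                f"{path}, row {i}: count {raw!r} is not an integer"
            )
        if cnt < 0:
            raise TableValidationError(f"{path}, row {i}: negative count {cnt}")
        guild = row.guild.strip() or "unknown"
        records.append(
            TaxonRecord(
                taxon_id=row.taxon_id,
                species=row.species,
                family=row.family,
                order=row.order,
                guild=guild,
                count=cnt,
            )
        )
    meta = _parse_metadata([m.rstrip("\n") for m in header_meta])
    meta["source"] = str(path)
    return CommunityTable(records=tuple(records), metadata=meta)


def write_table(table: CommunityTable, path) -> None:
    """Write a community table in the same CSV dialect read_table accepts.

    Applied filters recorded in ``table.metadata["filters"]`` are emitted as
    a single ``# filters:`` comment line before the header.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        filters = table.metadata.get("filters")
        if filters:
            fh.write("# filters: " + "; ".join(filters) + "\n")
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                f"{r.taxon_id},{r.species},{r.family},{r.order},{r.guild},{r.count}\n"
            )


def aggregate(table: CommunityTable, level: str) -> AbundanceVector:
    """Sum counts within each distinct label at ``level`` and rank them.

    Groups whose summed count is zero are dropped (abundance-model
    likelihoods are defined on observed groups only).  The descending sort
    is stable: tied groups keep their order of first appearance.
    """
    if level not in RANKS:
        raise ValueError(f"unknown level {level!r}; expected one of {RANKS}")
    totals: dict[str, int] = {}
    for r in table.records:
        label = getattr(r, level)
        totals[label] = totals.get(label, 0) + r.count
    items = [(lab, n) for lab, n in totals.items() if n > 0]
    if not items:
        raise TableValidationError("no positive counts to aggregate")
    items.sort(key=lambda kv: -kv[1])  # stable: ties keep insertion order
    labels, counts = zip(*items)
    return AbundanceVector(level=level, counts=tuple(counts), labels=tuple(labels))


def exclude_taxa(table: CommunityTable, level: str, label: str) -> CommunityTable:
    """Return a new table without records matching ``label`` at ``level``.

    The filter is recorded in the metadata of the returned table; the input
    table is unchanged.  If nothing matches, a warning is issued and the
    table is returned as-is.
    """
    if level not in RANKS:
        raise ValueError(f"unknown level {level!r}; expected one of {RANKS}")
    kept = tuple(r for r in table.records if getattr(r, level) != label)
    if len(kept) == len(table.records):
        warnings.warn(
            f"exclude_taxa: no record matches {level}={label!r}; table unchanged",
            stacklevel=2,
        )
        return table
    meta = dict(table.metadata)
    meta["filters"] = list(meta.get("filters", [])) + [f"exclude {level}={label}"]
    return CommunityTable(records=kept, metadata=meta)


def relative_abundance(vector: AbundanceVector) -> np.ndarray:
    """Proportions p_i = n_i / N for a ranked abundance vector."""
    counts = vector.as_array()
    return counts / counts.sum()
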