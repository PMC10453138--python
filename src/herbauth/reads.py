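"""Metabarcoding read-table post-processing and classification.

The input is the per-sample output of a read-attribution pipeline: one
row per taxon with a kingdom annotation and a read count.  Processing
follows the decision rules of the authentication workflow:

1. restrict to the kingdom of interest (Plantae — fungal, bacterial and
   animal reads are irrelevant to botanical purity);
2. convert counts to read percentages;
3. attach a class to every taxon — *ingredient* (the declared species),
   *adulterant* (bulking species reported in the fraud literature),
   *contaminant* (field weeds and co-processed foodstuffs) or *noise*
   (attributions that are rare or geographically implausible);
4. decide follow-up: any adulterant with at least one read is confirmed
   by a species-specific ddPCR assay; a contaminant is confirmed only
   when its read share is elevated (strictly above 5% by default).

Read percentages are a presence signal, not a quantity: the class/action
logic treats them only as a triage threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .accounting import CLASS_LABELS

__all__ = [
    "ReadTable",
    "ClassifiedReads",
    "ClassMap",
    "filter_kingdom",
    "read_percentages",
    "classify",
    "load_class_map",
    "default_class_map",
    "esa_read_table",
    "read_table_tsv",
    "write_read_tables_tsv",
]

logger = logging.getLogger(__name__)

READ_COLUMNS = ["taxon", "kingdom", "reads"]


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass
class ReadTable:
    """Taxon read counts for one sample (columns: taxon, kingdom, reads)."""

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(READ_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"read table missing columns: {sorted(missing)}")
        self.data = self.data.loc[:, READ_COLUMNS].reset_index(drop=True)
        if self.data["taxon"].duplicated().any():
            dupes = self.data.loc[self.data["taxon"].duplicated(), "taxon"].tolist()
            raise ValueError(f"duplicate taxa in sample {self.sample_id}: {dupes}")
        reads = self.data["reads"]
        if (reads < 0).any() or not (reads == reads.astype(int)).all():
            raise ValueError("read counts must be non-negative integers")
        self.data["reads"] = reads.astype(int)

    @property
    def total_reads(self) -> int:
        return int(self.data["reads"].sum())


@dataclass
class ClassifiedReads:
    """Read percentages (and, after :func:`classify`, classes and actions)."""

    sample_id: str
    data: pd.DataFrame  # taxon, kingdom, reads, read_pct [, class_label, action]
    denominator: str = "retained"
    denominator_total: int = 0
    flags: frozenset[str] = field(default_factory=frozenset)


def filter_kingdom(table: ReadTable, kingdom: str = "Plantae") -> ReadTable:
    """Keep only rows of the requested kingdom; counts unchanged; idempotent."""
    mask = table.data["kingdom"].map(_normalize) == _normalize(kingdom)
    out = ReadTable(sample_id=table.sample_id,
                    data=table.data.loc[mask].reset_index(drop=True))
    if out.data.empty:
        logger.warning("sample %s: no %s rows after kingdom filter",
                       table.sample_id, kingdom)
    return out


def read_percentages(
    table: ReadTable,
    denominator: str = "retained",
    all_total: int | None = None,
) -> ClassifiedReads:
    """Convert counts to read percentages.

    ``denominator='retained'`` divides by the sum of the rows present
    (the default: post-filter percentages that sum to 100).  With
    ``denominator='all'`` the caller supplies the pre-filter total
    (``all_total``), e.g. when percentages against the full sequencing
    output are wanted.
    """
    if denominator not in {"retained", "all"}:
        raise ValueError("denominator must be 'retained' or 'all'")
    total = table.total_reads if denominator == "retained" else all_total
    if denominator == "all" and total is None:
        raise ValueError("denominator='all' requires all_total")
    if not total or total <= 0:
        raise ValueError(f"sample {table.sample_id}: zero-read denominator")
    df = table.data.copy()
    df["read_pct"] = 100.0 * df["reads"] / total
    return ClassifiedReads(sample_id=table.sample_id, data=df,
                           denominator=denominator, denominator_total=int(total))


@dataclass(frozen=True)
class ClassMap:
    """Case-normalised taxon → class lookup with genus-level fallback.

    Entries ending in "spp." act as genus wildcards: a species absent
    from the map inherits its genus entry when one exists.  Taxa with no
    entry at all default to noise (their attribution is unvetted).
    """

    entries: dict[str, str]

    def lookup(self, taxon: str) -> str | None:
        key = _normalize(taxon)
        if key in self.entries:
            return self.entries[key]
        parts = key.split()
        if len(parts) >= 2:
            genus_key = f"{parts[0]} spp."
            if genus_key in self.entries:
                return self.entries[genus_key]
        return None

    def __contains__(self, taxon: str) -> bool:
        return self.lookup(taxon) is not None


def load_class_map(source) -> ClassMap:
    """Load a (taxon, class) TSV into a :class:`ClassMap`.

    Classes must be one of ingredient / adulterant / contaminant / noise.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    if not {"taxon", "class_label"} <= set(df.columns):
        raise ValueError("class map needs columns: taxon, class_label")
    entries: dict[str, str] = {}
    for row in df.itertuples(index=False):
        label = str(row.class_label).strip().lower()
        if label not in CLASS_LABELS:
            raise ValueError(f"malformed class label {row.class_label!r} "
                             f"for taxon {row.taxon!r}")
        entries[_normalize(str(row.taxon))] = label
    return ClassMap(entries=entries)


def default_class_map() -> ClassMap:
    """The packaged oregano class map (published classification scheme)."""
    with resources.files("herbauth.data").joinpath("class_map.tsv").open() as fh:
        return load_class_map(fh)


def esa_read_table() -> ReadTable:
    """Packaged read-count fixture for the ESA oregano quality-control material.

    A gravimetric multi-species reference blend; notable features are the
    heavy over-reporting of bindweed reads relative to its 1% mass and
    the complete dropout of sumac (zero reads despite 10% declared mass).
    """
    with resources.files("herbauth.data").joinpath("esa_reads.tsv").open() as fh:
        tables = read_table_tsv(fh)
    return tables[0]


def classify(
    reads: ClassifiedReads,
    class_map: ClassMap,
    threshold_pct: float = 5.0,
) -> ClassifiedReads:
    """Attach class labels and ddPCR-confirmation actions.

    Adulterants with >= 1 read are always confirmed by ddPCR; a
    contaminant is confirmed only when its read share is strictly above
    ``threshold_pct``; ingredients and noise require no follow-up.
    """
    df = reads.data.copy()
    flags = set(reads.flags)
    labels = []
    for taxon in df["taxon"]:
        label = class_map.lookup(taxon)
        if label is None:
            logger.info("sample %s: taxon %r not in class map; defaulting to noise",
                        reads.sample_id, taxon)
            flags.add("unmapped_taxa")
            label = "noise"
        labels.append(label)
    df["class_label"] = labels

    def _action(row) -> str:
        if row.class_label == "adulterant" and row.reads >= 1:
            return "confirm_ddPCR"
        if row.class_label == "contaminant" and row.read_pct > threshold_pct:
            return "confirm_ddPCR"
        return "none"

    df["action"] = [_action(r) for r in df.itertuples(index=False)]
    return ClassifiedReads(
        sample_id=reads.sample_id,
        data=df,
        denominator=reads.denominator,
        denominator_total=reads.denominator_total,
        flags=frozenset(flags),
    )


def read_table_tsv(source) -> list[ReadTable]:
    """Read one or more samples from a TSV (sample, taxon, kingdom, reads)."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"sample", "taxon", "kingdom", "reads"}
    if not required <= set(df.columns):
        raise ValueError(f"read table TSV needs columns {sorted(required)}")
    return [
        ReadTable(sample_id=str(sample), data=group[READ_COLUMNS].copy())
        for sample, group in df.groupby("sample", sort=False)
    ]


def write_read_tables_tsv(tables, path) -> None:
    frames = []
    for t in tables:
        df = t.data.copy()
        df.insert(0, "sample", t.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
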