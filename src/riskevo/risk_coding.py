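"""Ingest a species/IUCN table and code Red List categories to integer states.

Categories are coded EN=1, VU=2, NT=3, LC=4 — an ordered severity scale used
as distances by the disparity analysis and as plain labels by the symmetric
Markov model.  DD (data deficient) and NE (no Red List record) species are
excluded with a logged reason rather than coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CATEGORY_CODES = {"EN": 1, "VU": 2, "NT": 3, "LC": 4}
EXCLUDED_CATEGORIES = {"DD": "DD", "NE": "no-record"}
VALID_CATEGORIES = set(CATEGORY_CODES) | set(EXCLUDED_CATEGORIES)

COLUMN_ALIASES = {
    "order": "order",
    "family": "family",
    "species": "species",
    "binomial": "species",
    "common_name": "common_name",
    "common name": "common_name",
    "iucn": "category",
    "category": "category",
    "status": "category",
}


class RiskTableError(ValueError):
    """Raised for malformed risk-table input."""


@dataclass(frozen=True)
class SpeciesRecord:
    order: str
    family: str
    species: str
    common_name: str
    category: str


@dataclass
class CodedStates:
    """Species -> integer state map plus an exclusion log.

    ``states`` maps species binomials to states in {1, 2, 3, 4};
    ``exclusions`` records (species, reason) pairs with reason one of
    "DD", "no-record", "not-in-tree".
    """

    states: dict[str, int] = field(default_factory=dict)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        bad = {s for s, v in self.states.items() if v not in {1, 2, 3, 4}}
        if bad:
            raise RiskTableError(f"states outside 1..4 for: {sorted(bad)}")
        overlap = set(self.states) & {s for s, _ in self.exclusions}
        if overlap:
            raise RiskTableError(f"species both coded and excluded: {sorted(overlap)}")

    @property
    def species(self) -> list[str]:
        return sorted(self.states)

    def state_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for v in self.states.values():
            counts[v] = counts.get(v, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "state": [self.states[s] for s in self.species]}
        )

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["species", "reason"])


def bundled_risk_table_path() -> Path:
    """Path to the packaged endemic-bird IUCN table (48 species)."""
    return Path(resources.files("riskevo.data") / "chinese_endemic_birds_iucn.csv")


def read_risk_table(path) -> list[SpeciesRecord]:
    """Read a CSV/TSV species table into :class:`SpeciesRecord` rows.

    The header must contain recognizable column names (order, family,
    species, common name, IUCN category); categories are upper-cased.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise RiskTableError(f"risk table {path} contains no data rows")
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = {"species", "category"} - set(df.columns)
    if missing:
        raise RiskTableError(f"risk table missing required columns: {sorted(missing)}")

    records = []
    seen = set()
    for i, row in df.iterrows():
        species = str(row["species"]).strip()
        if not species or species.lower() == "nan":
            raise RiskTableError(f"row {i + 2}: empty species name")
        if species in seen:
            raise RiskTableError(f"row {i + 2}: duplicate species {species!r}")
        seen.add(species)
        cat = str(row["category"]).strip().upper()
        if cat in {"", "NAN", "NO RECORD", "NONE"}:
            cat = "NE"
        if cat not in VALID_CATEGORIES:
            raise RiskTableError(f"row {i + 2}: unknown IUCN category {cat!r} for {species}")
        records.append(
            SpeciesRecord(
                order=str(row.get("order", "")).strip(),
                family=str(row.get("family", "")).strip(),
                species=species,
                common_name=str(row.get("common_name", "")).strip(),
                category=cat,
            )
        )
    return records


def code_categories(records: list[SpeciesRecord]) -> CodedStates:
    """Map categories to integer states; exclude DD and no-record species."""
    states: dict[str, int] = {}
    exclusions: list[tuple[str, str]] = []
    for rec in sorted(records, key=lambda r: r.species):
        if rec.category in CATEGORY_CODES:
            states[rec.species] = CATEGORY_CODES[rec.category]
        else:
            exclusions.append((rec.species, EXCLUDED_CATEGORIES[rec.category]))
    return CodedStates(states=states, exclusions=exclusions)


def _canon(name: str) -> str:
    return name.strip().replace("_", " ").casefold()


def match_to_tree(states: CodedStates, tree) -> CodedStates:
    """Restrict coded states to the tree's tip set.

    Name matching normalizes underscores/spaces and case but is otherwise
    exact: a species absent from the tree is logged "not-in-tree", never
    fuzzily matched.  Fewer than 3 matches is an error (no comparative
    analysis is possible).
    """
    tip_by_canon = {_canon(lab): lab for lab in tree.tip_labels}
    matched: dict[str, int] = {}
    exclusions = list(states.exclusions)
    for sp, st in states.states.items():
        tip = tip_by_canon.get(_canon(sp))
        if tip is None:
            exclusions.append((sp, "not-in-tree"))
        else:
            matched[tip] = st
    if len(matched) < 3:
        raise RiskTableError(
            f"only {len(matched)} species matched tree tips; need at least 3"
        )
    return CodedStates(states=matched, exclusions=exclusions)
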