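"""Domain types and file I/O for habitat species-pool trait analyses.

The unit of analysis is the regional species pool of a habitat, not the
vegetation plot: a species table (taxonomy, growth form, invasion status,
three functional traits), a long-format habitat membership table, and a
rooted phylogeny whose tips are species ids.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

TRAITS = ("sla", "height_max", "seed_weight")
#: Column order used throughout the multivariate analyses: SLA, height, seed weight.

MISSING_SENTINELS = {"", "na", "nan", "null", "none"}


class GrowthForm(str, Enum):
    tree = "tree"
    non_tree = "non_tree"


class Status(str, Enum):
    native = "native"
    casual = "casual"
    naturalized = "naturalized"
    invasive = "invasive"


#: The two alien-vs-native contrasts run in every analysis.
COMPARISONS = (
    ("naturalized_vs_native", Status.naturalized),
    ("invasive_vs_native", Status.invasive),
)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: taxonomy, growth form, invasion status and trait values.

    Trait values are on the natural measurement scale (SLA in mm2/mg, maximum
    height in m, seed weight in mg); a missing trait is ``None``, never 0.
    """

    species_id: str
    genus: str
    family: str
    growth_form: GrowthForm
    status: Status
    sla: float | None = None
    height_max: float | None = None
    seed_weight: float | None = None

    def __post_init__(self) -> None:
        for trait in TRAITS:
            value = getattr(self, trait)
            if value is not None and not (value > 0 and math.isfinite(value)):
                raise ValueError(
                    f"species {self.species_id!r}: trait {trait} must be a "
                    f"positive finite number, got {value!r}"
                )

    def trait(self, name: str) -> float | None:
        if name not in TRAITS:
            raise KeyError(f"unknown trait {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class HabitatPool:
    """Species pool of one habitat; pools may overlap across habitats."""

    habitat_id: str
    habitat_name: str
    member_ids: frozenset[str]
    open_habitat: bool

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Phylogeny:
    """Rooted tree with species ids as tip labels.

    Branch lengths are optional: the Abouheif proximity used downstream is
    topology-only. Polytomies are preserved (supertrees contain them).
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValueError(f"duplicate tip label {dup!r}")


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Species records as a DataFrame indexed by species_id (NaN = missing)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "genus": r.genus,
                "family": r.family,
                "growth_form": r.growth_form.value,
                "status": r.status.value,
                "sla": math.nan if r.sla is None else r.sla,
                "height_max": math.nan if r.height_max is None else r.height_max,
                "seed_weight": math.nan if r.seed_weight is None else r.seed_weight,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "species_id", "genus", "family", "growth_form", "status", *TRAITS,
        ],
    )
    return frame.set_index("species_id")


def read_trait_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the species trait CSV.

    Columns: species_id, genus, family, growth_form, status, sla, height_max,
    seed_weight. Empty cells or the literal "NA" denote a missing trait.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["species_id", "genus", "family", "growth_form", "status", *TRAITS]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"trait table {path}: missing columns {missing_cols}")

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        sid = row["species_id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate species_id {sid!r}")
        seen.add(sid)
        traits: dict[str, float | None] = {}
        for trait in TRAITS:
            raw = row[trait].strip()
            if raw.lower() in MISSING_SENTINELS:
                traits[trait] = None
                continue
            value = float(raw)
            if not value > 0:
                raise ValueError(
                    f"row {pos}: non-positive value {value} for trait {trait}"
                )
            traits[trait] = value
        records.append(
            SpeciesRecord(
                species_id=sid,
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                growth_form=GrowthForm(row["growth_form"].strip()),
                status=Status(row["status"].strip()),
                **traits,
            )
        )
    return records


def write_trait_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    """Inverse of :func:`read_trait_table`; missing traits become empty cells."""
    frame = records_to_frame(records).reset_index()
    frame.to_csv(path, index=False, float_format="%.17g")


def read_habitat_table(path: str | Path) -> list[HabitatPool]:
    """Read the long-format habitat membership CSV.

    Columns: habitat_id, habitat_name, open_habitat, species_id — one row per
    (habitat, species) membership.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["habitat_id", "habitat_name", "open_habitat", "species_id"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"habitat table {path}: missing columns {missing_cols}")
    pools: list[HabitatPool] = []
    for hid, group in frame.groupby("habitat_id", sort=False):
        names = group["habitat_name"].unique()
        opens = group["open_habitat"].str.strip().str.lower().unique()
        if len(names) > 1 or len(opens) > 1:
            raise ValueError(f"habitat {hid!r}: inconsistent name/open_habitat")
        pools.append(
            HabitatPool(
                habitat_id=str(hid),
                habitat_name=str(names[0]),
                member_ids=frozenset(group["species_id"].str.strip()),
                open_habitat=opens[0] in {"true", "1", "yes"},
            )
        )
    return pools


def write_habitat_table(pools: Sequence[HabitatPool], path: str | Path) -> None:
    rows = [
        {
            "habitat_id": p.habitat_id,
            "habitat_name": p.habitat_name,
            "open_habitat": str(p.open_habitat).lower(),
            "species_id": sid,
        }
        for p in pools
        for sid in sorted(p.member_ids)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single rooted tree in Newick format, preserving polytomies."""
    text = Path(path).read_text()
    return phylogeny_from_newick(text)


def phylogeny_from_newick(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(
        phylogeny.tree.as_string(schema="newick", unquoted_underscores=True)
    )


def filter_pool(
    pool: HabitatPool, records: Sequence[SpeciesRecord]
) -> HabitatPool:
    """Apply the pool-composition rules; the input pool is left unchanged.

    Casual aliens are removed from every pool (they do not form
    self-sustaining populations and were excluded from all analyses), and
    tree species are removed from open habitats, where they occur only as
    juveniles whose measured traits refer to adults.
    """
    by_id = {r.species_id: r for r in records}
    unknown = sorted(pool.member_ids - by_id.keys())
    if unknown:
        raise KeyError(
            f"habitat {pool.habitat_id!r}: unknown species ids {unknown[:5]}"
        )
    kept = set()
    for sid in pool.member_ids:
        rec = by_id[sid]
        if rec.status is Status.casual:
            continue
        if pool.open_habitat and rec.growth_form is GrowthForm.tree:
            continue
        kept.add(sid)
    return dataclasses.replace(pool, member_ids=frozenset(kept))


# ---------------------------------------------------------------------------
# Tidy result tables

RESULT_COLUMNS = [
    "habitat_id",
    "comparison",
    "trait",
    "statistic",
    "value",
    "p",
    "p_adj",
    "n_perm",
    "seed",
    "dataset",
]


def result_table(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Assemble tidy result rows; validates the p / p_adj invariants."""
    frame = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    for col in ("p", "p_adj"):
        vals = frame[col].dropna()
        if len(vals) and not ((vals >= 0) & (vals <= 1)).all():
            raise ValueError(f"{col} outside [0, 1]")
    return frame


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write one CSV per analysis family plus a JSON run summary.

    Values are written at full double precision so a round-trip read
    reproduces them exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        written[name] = path
    if summary is not None:
        path = out / "run_summary.json"
        path.write_text(json.dumps(dict(summary), indent=2, default=str) + "\n")
        written["run_summary"] = path
    return written
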