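"""Dataset assembly, filtering, splitting, and persistence.

Complexes arrive either from PDBBind-style index files (one line per
complex: code, resolution, year, -log(affinity), and an affinity field
like ``Kd=1uM`` or ``Ki>10mM``) or from flat CSV/TSV tables carrying
SMILES, pocket sequence, descriptor columns, and labels.  Affinity
cases mirror the usual benchmark constructions: Kd-only, Ki-only, or
the combined Kd+Ki set; censored measurements (relational qualifiers)
are excluded from point-label training sets by default.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .featurize import AffinityLabel, to_pk

logger = logging.getLogger(__name__)

_AFFINITY_RE = re.compile(
    r"^(Kd|Ki|IC50)(<=|>=|=|<|>|~)([0-9.eE+\-]+)(fM|pM|nM|uM|µM|mM|M)$"
)

_QUALIFIER = {
    "=": "exact",
    ">": "lower_bound",
    ">=": "lower_bound",
    "<": "upper_bound",
    "<=": "upper_bound",
    "~": "approximate",
}


@dataclass
class ComplexRecord:
    """One protein-ligand complex with its affinity label."""

    id: str
    smiles: str = ""
    pocket_seq: str = ""
    descriptors: np.ndarray | None = None
    label: AffinityLabel | None = None
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if self.descriptors is not None:
            self.descriptors = np.asarray(self.descriptors, dtype=np.float64)


@dataclass
class DatasetSplit:
    train: list[ComplexRecord]
    test: list[ComplexRecord]
    seed: int | None = None
    manifest: dict = field(default_factory=dict)

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=1))


def parse_index_file(index_text: str, pk_tolerance: float = 0.05) -> list[ComplexRecord]:
    """Parse a PDBBind-style index into partial records (id + label).

    Lines starting with ``#`` are comments.  Data lines are
    whitespace-separated: complex code, resolution, year, -log value,
    affinity field (e.g. ``Kd=25nM``); anything after the affinity
    field is ignored.  Malformed data lines are skipped with a logged
    warning; recomputed pK values disagreeing with the file's -log
    column by more than ``pk_tolerance`` are logged but kept.
    """
    records: list[ComplexRecord] = []
    skipped = 0
    for lineno, line in enumerate(index_text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            logger.warning("index line %d: too few fields, skipped", lineno)
            skipped += 1
            continue
        code, _resolution, _year, neglog, affinity = fields[:5]
        m = _AFFINITY_RE.match(affinity)
        if m is None:
            logger.warning(
                "index line %d (%s): unparseable affinity field %r, skipped",
                lineno, code, affinity,
            )
            skipped += 1
            continue
        kind, rel, value, unit = m.groups()
        try:
            label = AffinityLabel.from_measurement(
                kind, float(value), unit, qualifier=_QUALIFIER[rel]
            )
        except ValueError as exc:
            logger.warning("index line %d (%s): %s, skipped", lineno, code, exc)
            skipped += 1
            continue
        try:
            stated = float(neglog)
        except ValueError:
            stated = None
        if stated is not None and abs(stated - label.pk) > pk_tolerance:
            logger.warning(
                "index line %d (%s): -log column %.3f disagrees with "
                "recomputed pK %.3f", lineno, code, stated, label.pk,
            )
        records.append(ComplexRecord(id=code, label=label))
    if not records:
        raise ValueError(f"no parseable index lines ({skipped} skipped)")
    if skipped:
        logger.info("index parse: %d records, %d lines skipped", len(records), skipped)
    return records


CASES = ("kd_only", "ki_only", "kd_and_ki")


def assemble_case(
    records: Iterable[ComplexRecord],
    case: str,
    include_censored: bool = False,
    include_ic50: bool = False,
) -> list[ComplexRecord]:
    """Filter records to one affinity case (Kd-only / Ki-only / both).

    IC50 measurements and censored qualifiers (<, >, ~) are excluded by
    default: a censored value is not a point label.
    """
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    kinds = {"kd_only": {"Kd"}, "ki_only": {"Ki"}, "kd_and_ki": {"Kd", "Ki"}}[case]
    if include_ic50:
        kinds = kinds | {"IC50"}
    out = [
        r for r in records
        if r.label is not None
        and r.label.kind in kinds
        and (include_censored or r.label.qualifier == "exact")
    ]
    if not out:
        raise ValueError(f"case filter {case!r} produced an empty dataset")
    return out


def merge_sources(refined: Iterable[ComplexRecord],
                  general: Iterable[ComplexRecord]) -> list[ComplexRecord]:
    """Union of refined and general sets; refined wins on duplicate ids."""
    out: dict[str, ComplexRecord] = {}
    for rec in general:
        out[rec.id] = replace(rec, source="general")
    for rec in refined:
        out[rec.id] = replace(rec, source="refined")
    return list(out.values())


def split_dataset(
    records: Sequence[ComplexRecord],
    test_fraction: float | None = None,
    test_count: int | None = None,
    seed: int | None = None,
    test_ids: Iterable[str] | None = None,
) -> DatasetSplit:
    """Partition records into train/test, deterministically given seed.

    Either give ``test_fraction`` / ``test_count`` for a seeded random
    split, or ``test_ids`` to reproduce a published test-set listing
    verbatim.
    """
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids; cannot split")
    if test_ids is not None:
        wanted = set(test_ids)
        missing = wanted - set(ids)
        if missing:
            raise ValueError(f"test ids not in dataset: {sorted(missing)}")
        test = [r for r in records if r.id in wanted]
        train = [r for r in records if r.id not in wanted]
    else:
        if test_count is None:
            if test_fraction is None:
                raise ValueError("give test_fraction, test_count, or test_ids")
            test_count = int(round(test_fraction * len(records)))
        if not (0 < test_count < len(records)):
            raise ValueError(
                f"test size {test_count} must be in (0, {len(records)})"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        test_idx = set(order[:test_count].tolist())
        train = [records[i] for i in range(len(records)) if i not in test_idx]
        test = [records[i] for i in sorted(test_idx)]
    manifest = {
        "train": [r.id for r in train],
        "test": [r.id for r in test],
        "seed": seed,
    }
    return DatasetSplit(train=train, test=test, seed=seed, manifest=manifest)


_MANDATORY = ("id", "smiles", "pocket_seq")


def read_dataset_table(path: str | Path) -> list[ComplexRecord]:
    """Read a CSV/TSV dataset table into complex records.

    Mandatory columns: ``id``, ``smiles``, ``pocket_seq``, and either
    ``pk`` (with optional ``kind``/``qualifier``) or the trio
    ``value``/``unit``/``kind``.  Descriptor columns are ``d1..dD``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str}, keep_default_na=False)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"dataset table {path} is missing column {col!r}")
    if "pk" not in df.columns and not {"value", "unit", "kind"} <= set(df.columns):
        raise ValueError(
            f"dataset table {path} needs a 'pk' column or value/unit/kind columns"
        )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in {path}: {dups}")
    dcols = sorted(
        (c for c in df.columns if re.fullmatch(r"d\d+", c)),
        key=lambda c: int(c[1:]),
    )
    records = []
    for _, row in df.iterrows():
        kind = str(row.get("kind", "Kd")) or "Kd"
        qualifier = str(row.get("qualifier", "exact")) or "exact"
        if "pk" in df.columns and row["pk"] != "":
            label = AffinityLabel.from_pk(kind, float(row["pk"]), qualifier)
        else:
            label = AffinityLabel.from_measurement(
                kind, float(row["value"]), str(row["unit"]), qualifier
            )
        desc = (
            np.array([float(row[c]) for c in dcols], dtype=np.float64)
            if dcols else None
        )
        records.append(
            ComplexRecord(
                id=str(row["id"]),
                smiles=str(row["smiles"]),
                pocket_seq=str(row["pocket_seq"]),
                descriptors=desc,
                label=label,
                source=str(row.get("source", "user")) or "user",
            )
        )
    return records


def write_dataset_table(records: Sequence[ComplexRecord], path: str | Path) -> None:
    """Write records to CSV/TSV; round-trips through read_dataset_table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    widths = {len(r.descriptors) for r in records if r.descriptors is not None}
    if len(widths) > 1:
        raise ValueError(f"inconsistent descriptor widths: {sorted(widths)}")
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label")
        row = {
            "id": r.id,
            "smiles": r.smiles,
            "pocket_seq": r.pocket_seq,
            "kind": r.label.kind,
            "qualifier": r.label.qualifier,
            "pk": repr(float(r.label.pk)),
            "source": r.source,
        }
        if r.descriptors is not None:
            row.update({f"d{j+1}": repr(float(v))
                        for j, v in enumerate(r.descriptors)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
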