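"""Data model and file formats shared by every analysis stage.

Three artifact types move through the pipeline:

* :class:`ResponseMatrix` — persons x items polytomous responses (integer
  category codes, explicit missingness) with optional respondent group
  metadata, read from / written to plain CSV;
* :class:`ItemBank` — per-item partial-credit threshold parameters (deltas on
  the theta metric) plus the raw-to-scored category map, stored as JSON with a
  CSV export mirroring the published item table layout;
* :class:`PurificationLedger` — the ordered audit trail of item actions
  (flag / rescore / remove / keep), stored as JSON lines.

Missingness is always an explicit mask (NaN in the response array), never a
sentinel category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MISSING_CODES",
    "ResponseMatrix",
    "Item",
    "ItemBank",
    "ThetaEstimate",
    "LedgerEntry",
    "PurificationLedger",
    "read_response_matrix",
    "write_response_matrix",
    "read_item_bank",
    "write_item_bank",
    "item_bank_to_csv",
    "read_ledger",
    "write_ledger",
]

#: Tokens treated as missing on ingest (configurable per call).
DEFAULT_MISSING_CODES = frozenset({"", "NA", "NaN", "nan", "na", "N/A"})

_RESERVED_COLUMNS = ("person_id", "group")


class DataValidationError(ValueError):
    """A response matrix or item bank violates its invariants."""


@dataclass
class ResponseMatrix:
    """Persons x items polytomous responses with an explicit missingness mask.

    Parameters
    ----------
    responses:
        Float array of shape ``(n_persons, n_items)``; integer category codes
        ``0..max_cat[j]`` with ``NaN`` marking missing cells.
    person_ids, item_ids:
        Unique opaque identifiers.
    max_cat:
        Highest admissible category code per item (length ``n_items``).
    group:
        Optional per-person labels (e.g. ``service_user`` / ``carer`` /
        ``both`` / ``unreported``).
    """

    responses: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    max_cat: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        self.max_cat = np.asarray(self.max_cat, dtype=int)
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if len(self.group) != len(self.person_ids):
                raise DataValidationError("group labels must match person count")
        if self.responses.ndim != 2:
            raise DataValidationError("responses must be 2-D")
        n, k = self.responses.shape
        if n != len(self.person_ids) or k != len(self.item_ids):
            raise DataValidationError("id lists inconsistent with response shape")
        if len(set(self.person_ids)) != n:
            raise DataValidationError("duplicate person ids")
        if len(set(self.item_ids)) != k:
            raise DataValidationError("duplicate item ids")
        if self.max_cat.shape != (k,) or (self.max_cat < 1).any():
            raise DataValidationError("max_cat must be >= 1 per item")
        obs = ~np.isnan(self.responses)
        vals = self.responses[obs]
        if vals.size and not np.array_equal(vals, np.round(vals)):
            raise DataValidationError("non-integer response codes present")
        bad = obs & ((self.responses < 0) | (self.responses > self.max_cat))
        if bad.any():
            p, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"response {self.responses[p, j]:g} out of range 0..{self.max_cat[j]}"
                f" for person {self.person_ids[p]!r}, item {self.item_ids[j]!r}"
            )

    # -- basic geometry -----------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a response was observed."""
        return ~np.isnan(self.responses)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.responses).mean())

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(str(item_id))
        except ValueError:
            raise KeyError(f"item {item_id!r} not in matrix") from None

    def column(self, item_id: str) -> np.ndarray:
        return self.responses[:, self.item_index(item_id)]

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_index(i) for i in item_ids]
        return ResponseMatrix(
            self.responses[:, idx].copy(),
            list(self.person_ids),
            [self.item_ids[j] for j in idx],
            self.max_cat[idx].copy(),
            None if self.group is None else self.group.copy(),
        )

    def copy(self) -> "ResponseMatrix":
        return self.subset_items(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        if self.group is not None:
            df.insert(1, "group", self.group)
        return df


@dataclass(frozen=True)
class Item:
    """One calibrated item: thresholds on the theta metric plus scoring map."""

    item_id: str
    label: str
    deltas: tuple[float, ...]
    scoring_map: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", tuple(float(d) for d in self.deltas))
        object.__setattr__(self, "scoring_map", tuple(int(s) for s in self.scoring_map))
        sm = self.scoring_map
        if not sm or sm[0] != 0:
            raise DataValidationError(f"item {self.item_id}: scoring_map must start at 0")
        if any(b < a for a, b in zip(sm, sm[1:])):
            raise DataValidationError(f"item {self.item_id}: scoring_map must be non-decreasing")
        if any(b - a > 1 for a, b in zip(sm, sm[1:])):
            raise DataValidationError(f"item {self.item_id}: scoring_map must be surjective")
        if len(self.deltas) != max(sm):
            raise DataValidationError(
                f"item {self.item_id}: {len(self.deltas)} deltas inconsistent with "
                f"{max(sm) + 1} scored categories"
            )

    @property
    def n_scored_categories(self) -> int:
        return len(self.deltas) + 1

    @property
    def max_raw_category(self) -> int:
        return len(self.scoring_map) - 1


@dataclass
class ItemBank:
    """Ordered collection of calibrated items."""

    items: list[Item]

    def __post_init__(self) -> None:
        if not self.items:
            raise DataValidationError("empty bank")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate item ids in bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def get(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == str(item_id):
                return it
        raise KeyError(f"item {item_id!r} not in bank")

    def deltas(self) -> list[np.ndarray]:
        return [np.asarray(it.deltas) for it in self.items]

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        wanted = [str(i) for i in item_ids]
        return ItemBank([self.get(i) for i in wanted])


@dataclass(frozen=True)
class ThetaEstimate:
    """Latent-trait point estimate with its posterior standard deviation."""

    person_id: str
    theta: float
    se: float
    n_items_used: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise DataValidationError("posterior SE must be positive")


@dataclass
class LedgerEntry:
    stage: str
    item_ids: tuple[str, ...]
    action: str  # flag | rescore | remove | keep
    statistic: dict = field(default_factory=dict)
    rationale: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.item_ids, str):
            self.item_ids = (self.item_ids,)
        self.item_ids = tuple(str(i) for i in self.item_ids)


@dataclass
class PurificationLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def add(self, stage: str, item_ids, action: str, statistic=None, rationale: str = "") -> None:
        removed = self.removed_items()
        entry = LedgerEntry(stage, item_ids, action, dict(statistic or {}), rationale)
        if action == "remove":
            dup = set(entry.item_ids) & removed
            if dup:
                raise DataValidationError(f"items {sorted(dup)} already removed")
        self.entries.append(entry)

    def removed_items(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            if e.action == "remove":
                out.update(e.item_ids)
        return out

    def stages(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if not seen or seen[-1] != e.stage:
                seen.append(e.stage)
        return seen


# ---------------------------------------------------------------------------
# Response matrix I/O
# ---------------------------------------------------------------------------

def read_response_matrix(
    path,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    max_cat: int | Sequence[int] | None = None,
) -> ResponseMatrix:
    """Read a persons-as-rows CSV into a :class:`ResponseMatrix`.

    The header row carries item identifiers; optional ``person_id`` and
    ``group`` columns carry metadata.  Any cell whose (stripped) text is in
    ``missing_codes`` becomes an explicit missing entry; any other
    non-integer token raises a parse error naming the offending cell.
    ``max_cat`` defaults to the highest observed code per item.
    """
    missing = {str(c).strip() for c in missing_codes}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "person_id" in df.columns:
        person_ids = [s.strip() for s in df["person_id"]]
    else:
        person_ids = [str(i) for i in range(len(df))]
    if len(set(person_ids)) != len(person_ids):
        dup = pd.Series(person_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise DataValidationError(f"duplicate person id {dup!r}")
    group = None
    if "group" in df.columns:
        group = np.array(
            [g.strip() if g.strip() not in missing else "unreported" for g in df["group"]],
            dtype=object,
        )
    item_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if not item_cols:
        raise DataValidationError("no item columns found")
    resp = np.full((len(df), len(item_cols)), np.nan)
    for j, col in enumerate(item_cols):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok in missing:
                continue
            try:
                resp[i, j] = int(tok)
            except ValueError:
                raise DataValidationError(
                    f"cannot parse response {tok!r} at row {i + 1}, column {col!r}"
                ) from None
    if max_cat is None:
        with np.errstate(all="ignore"):
            mc = np.nanmax(np.where(np.isnan(resp), 0, resp), axis=0)
        mc = np.maximum(mc, 1).astype(int)
    elif np.isscalar(max_cat):
        mc = np.full(len(item_cols), int(max_cat))
    else:
        mc = np.asarray(max_cat, dtype=int)
    return ResponseMatrix(resp, person_ids, item_cols, mc, group)


def write_response_matrix(matrix: ResponseMatrix, path) -> None:
    df = matrix.to_frame()
    for c in matrix.item_ids:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Item bank I/O
# ---------------------------------------------------------------------------

def read_item_bank(path) -> ItemBank:
    """Read a JSON item bank (``{"items": [{item_id, label, deltas, scoring_map}]}``)."""
    with open(path) as fh:
        payload = json.load(fh)
    raw_items = payload.get("items", payload if isinstance(payload, list) else None)
    if raw_items is None:
        raise DataValidationError("bank file must contain an 'items' list")
    if not raw_items:
        raise DataValidationError("empty bank")
    items = []
    for rec in raw_items:
        try:
            items.append(
                Item(
                    item_id=str(rec["item_id"]),
                    label=rec.get("label", ""),
                    deltas=tuple(rec["deltas"]),
                    scoring_map=tuple(rec.get("scoring_map", range(len(rec["deltas"]) + 1))),
                )
            )
        except KeyError as exc:
            raise DataValidationError(f"bank record missing field {exc}") from None
    return ItemBank(items)


def write_item_bank(bank: ItemBank, path, **metadata) -> None:
    payload = {
        **metadata,
        "items": [
            {
                "item_id": it.item_id,
                "label": it.label,
                "deltas": list(it.deltas),
                "scoring_map": list(it.scoring_map),
            }
            for it in bank
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def item_bank_to_csv(bank: ItemBank, path) -> None:
    """Delimited export mirroring the published item-table columns."""
    rows = []
    for k, it in enumerate(bank, start=1):
        row = {"item_number": k, "item_id": it.item_id, "wording": it.label}
        for h, d in enumerate(it.deltas, start=1):
            row[f"delta_{h}"] = d
        row["scoring"] = "-".join(str(s) for s in it.scoring_map)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ledger I/O (JSON lines, one entry per action)
# ---------------------------------------------------------------------------

def write_ledger(ledger: PurificationLedger, path) -> None:
    with open(path, "w") as fh:
        for e in ledger.entries:
            fh.write(json.dumps(asdict(e), sort_keys=True) + "\n")


def read_ledger(path) -> PurificationLedger:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            entries.append(
                LedgerEntry(
                    rec["stage"],
                    tuple(rec["item_ids"]),
                    rec["action"],
                    rec.get("statistic", {}),
                    rec.get("rationale", ""),
                )
            )
    return PurificationLedger(entries)
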