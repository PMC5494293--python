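"""Reading and writing of Cq matrices, sample sheets and miRNA lists.

A quantitation-cycle (Cq) matrix has miRNA rows and sample columns.
Amplifications that do not reach threshold by the censoring cycle
(default 40) carry no usable Cq value: such cells are *undetected* and
are represented as missing, never as an imputed Cq.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CENSOR_AT",
    "DEFAULT_SENTINELS",
    "GROUPS",
    "CqTable",
    "SampleSheet",
    "MirnaList",
    "FilterResult",
    "canonical_mirna",
    "read_cq_table",
    "write_cq_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_mirna_list",
    "write_mirna_list",
    "summarize_cohort",
    "filter_detected",
    "file_sha256",
]

#: Cq values at or above this cycle count are treated as undetected.
DEFAULT_CENSOR_AT = 40.0

#: Cell contents that mark an undetected amplification in delimited input.
DEFAULT_SENTINELS = ("", "NA", "N/A", "NaN", "nan", "Undetermined", "undetected")

#: Recognised two-group phenotype labels (canonical, lower case).
GROUPS = ("healthy", "periodontitis")

_GENDER_MAP = {"m": "M", "male": "M", "f": "F", "female": "F"}


def canonical_mirna(name: str) -> str:
    """Return the canonical form of a mature miRNA name.

    Canonicalization trims whitespace, lower-cases, and enforces the
    ``hsa-`` species prefix.  Star names (``miR-205*``) are kept verbatim
    apart from these transformations; no database-version remapping is
    attempted.

    >>> canonical_mirna("  hsa-miR-223-3p ")
    'hsa-mir-223-3p'
    >>> canonical_mirna("miR-21-5p")
    'hsa-mir-21-5p'
    """
    out = str(name).strip().lower()
    if not out:
        raise ValueError("empty miRNA name")
    if not out.startswith("hsa-"):
        out = "hsa-" + out
    return out


def _canonicalize_unique(names: Iterable[str], what: str) -> list[str]:
    canon = [canonical_mirna(n) for n in names]
    seen: dict[str, str] = {}
    for raw, c in zip(names, canon):
        if c in seen:
            raise ValueError(
                f"duplicate {what} after canonicalization: {raw!r} and "
                f"{seen[c]!r} both map to {c!r}"
            )
        seen[c] = str(raw)
    return canon


@dataclass(frozen=True)
class MirnaList:
    """A named, ordered set of canonical miRNA names.

    Members are canonicalized on construction and deduplicated while
    preserving first-occurrence order.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        canon: list[str] = []
        seen: set[str] = set()
        for m in self.members:
            c = canonical_mirna(m)
            if c not in seen:
                seen.add(c)
                canon.append(c)
        object.__setattr__(self, "members", tuple(canon))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, item: str) -> bool:
        return canonical_mirna(item) in set(self.members)


@dataclass
class CqTable:
    """Raw quantitation-cycle matrix with an implicit detection mask.

    Parameters
    ----------
    cq
        Float matrix (miRNA rows x sample columns).  ``NaN`` marks an
        undetected amplification; every finite value is a usable Cq.
    panel_id
        Free-text identifier of the assay panel.
    censor_at
        The detection cutoff the table was produced with.  Detected Cq
        must satisfy ``0 < Cq < censor_at``.
    """

    cq: pd.DataFrame
    panel_id: str = "custom"
    censor_at: float = DEFAULT_CENSOR_AT

    def __post_init__(self) -> None:
        df = self.cq.copy()
        df.index = pd.Index(
            _canonicalize_unique(list(df.index), "miRNA label"), name="mirna_id"
        )
        cols = [str(c).strip() for c in df.columns]
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate sample labels: {dupes}")
        df.columns = pd.Index(cols, name="sample_id")
        df = df.astype(float)
        vals = df.to_numpy()
        bad = (vals <= 0) | (vals >= self.censor_at)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"Cq value {vals[i, j]} for {df.index[i]!r} / {df.columns[j]!r} "
                f"outside the detected range (0, {self.censor_at})"
            )
        self.cq = df

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask, same shape as ``cq``; True where a Cq is usable."""
        return self.cq.notna()

    @property
    def n_mirna(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    def subset(self, mirnas: Iterable[str]) -> "CqTable":
        """Restrict to the given miRNAs (canonical match, given order)."""
        want = [canonical_mirna(m) for m in mirnas]
        missing = [m for m in want if m not in self.cq.index]
        if missing:
            raise KeyError(f"miRNAs absent from table: {missing}")
        return CqTable(self.cq.loc[want], panel_id=self.panel_id, censor_at=self.censor_at)


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cq_table(
    path: str | Path,
    *,
    sep: str | None = None,
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
    censor_at: float = DEFAULT_CENSOR_AT,
    transpose: bool = False,
    panel_id: str | None = None,
) -> CqTable:
    """Read a delimited Cq matrix and apply the detection rule.

    The first column holds miRNA labels and the header row holds sample
    labels (set ``transpose=True`` if the file is the other way around —
    no orientation auto-detection is attempted).  Blank cells, sentinel
    strings, and numeric Cq at or above ``censor_at`` are marked
    undetected; every other cell must parse as a positive number.

    Raises
    ------
    ValueError
        On duplicate miRNA/sample labels, or a non-numeric non-sentinel
        cell (the offending row and column are named).
    """
    path = Path(path)
    if sep is None:
        sep = _infer_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample labels in header: {dupes}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        raw = raw.T
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty Cq matrix")

    stripped = raw.map(lambda v: v.strip())
    sentinel_set = {s.lower() for s in sentinels} | {""}
    is_sentinel = stripped.map(lambda v: v.lower() in sentinel_set)
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    invalid = numeric.isna() & ~is_sentinel
    if invalid.to_numpy().any():
        i, j = np.argwhere(invalid.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {stripped.iat[i, j]!r} at "
            f"row {raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    values = numeric.where(~is_sentinel)
    values = values.where(values < censor_at)  # >= censor_at -> undetected

    neg = values.to_numpy() <= 0
    if (neg & ~np.isnan(values.to_numpy())).any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: non-positive Cq at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    return CqTable(
        values.astype(float),
        panel_id=panel_id if panel_id is not None else path.stem,
        censor_at=censor_at,
    )


def write_cq_table(table: CqTable, path: str | Path, *, sep: str | None = None) -> None:
    """Write a Cq matrix; undetected cells are emitted as blanks."""
    path = Path(path)
    if sep is None:
        sep = _infer_sep(path)
    table.cq.to_csv(path, sep=sep, na_rep="")


@dataclass
class SampleSheet:
    """Per-sample metadata: group, sample-set membership and clinical fields.

    Backed by a DataFrame indexed by ``sample_id`` with at least the
    canonical columns ``group`` and ``set_id``; any additional columns
    are preserved untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValueError("sample sheet requires a sample_id column")
            df["sample_id"] = df["sample_id"].astype(str).str.strip()
            df = df.set_index("sample_id")
        if df.shape[0] == 0:
            raise ValueError("no samples in sample sheet")
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate sample_id values: {dupes}")
        for col in ("group", "set_id"):
            if col not in df.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
            if df[col].isna().any() or (df[col].astype(str).str.strip() == "").any():
                raise ValueError(f"missing values in required column {col!r}")
        group = df["group"].astype(str).str.strip().str.lower()
        unknown = sorted(set(group) - set(GROUPS))
        if unknown:
            raise ValueError(f"unknown group labels {unknown}; expected one of {GROUPS}")
        df["group"] = group
        df["set_id"] = (
            df["set_id"].astype(str).str.strip().str.lower().str.replace(r"[\s#]+", "", regex=True)
        )
        if "age" in df.columns:
            df["age"] = pd.to_numeric(df["age"], errors="raise")
        if "gender" in df.columns:
            g = df["gender"].astype(str).str.strip().str.lower()
            bad = sorted(set(g[~g.isin(_GENDER_MAP)].dropna()) - {"", "nan"})
            if bad:
                raise ValueError(f"unknown gender labels {bad}; expected M/F")
            df["gender"] = g.map(_GENDER_MAP)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def set_ids(self) -> list[str]:
        return sorted(self.data["set_id"].unique())

    def samples_in_group(self, group: str, set_id: str | None = None) -> list[str]:
        mask = self.data["group"] == group.lower()
        if set_id is not None:
            mask &= self.data["set_id"] == set_id
        return list(self.data.index[mask])

    def restrict(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = [s for s in sample_ids]
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from sheet: {missing}")
        return SampleSheet(self.data.loc[ids])


def read_sample_sheet(path: str | Path, *, sep: str | None = None) -> SampleSheet:
    """Read a delimited sample sheet (requires sample_id, group, set_id)."""
    path = Path(path)
    if sep is None:
        sep = _infer_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path)


def read_mirna_list(path: str | Path, name: str | None = None) -> MirnaList:
    """Read a one-name-per-line miRNA list; ``#`` starts a comment."""
    path = Path(path)
    members = []
    for line in path.read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            members.append(entry)
    return MirnaList(name if name is not None else path.stem, tuple(members))


def write_mirna_list(mlist: MirnaList, path: str | Path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in mlist.members))


def summarize_cohort(sheet: SampleSheet) -> pd.DataFrame:
    """Per (set_id, group) summary: n, mean age (1 decimal), gender counts.

    Mean age is the arithmetic mean over listed ages, rounded to one
    decimal for display.
    """
    rows = []
    for (set_id, group), sub in sheet.data.groupby(["set_id", "group"], sort=True):
        ages = pd.to_numeric(sub["age"], errors="coerce") if "age" in sub else pd.Series(dtype=float)
        genders = sub["gender"] if "gender" in sub else pd.Series(dtype=str)
        rows.append(
            {
                "set_id": set_id,
                "group": group,
                "n": len(sub),
                "mean_age": round(float(ages.mean()), 1) if ages.notna().any() else np.nan,
                "n_male": int((genders == "M").sum()),
                "n_female": int((genders == "F").sum()),
            }
        )
    return pd.DataFrame(rows).set_index(["set_id", "group"])


@dataclass
class FilterResult:
    """Outcome of the detection filter."""

    table: CqTable
    retained: tuple[str, ...]
    dropped: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def filter_detected(
    table: CqTable, sheet: SampleSheet, *, min_per_group: int = 1
) -> FilterResult:
    """Keep miRNAs detected in at least ``min_per_group`` samples of each group.

    Only the table's samples are considered; both groups must be
    represented among them.
    """
    sub = sheet.restrict(table.sample_ids)
    det = table.detected
    counts = {}
    for group in GROUPS:
        ids = sub.samples_in_group(group)
        if not ids:
            raise ValueError(f"no {group!r} samples among the table's columns")
        counts[group] = det[ids].sum(axis=1)
    keep = np.ones(table.n_mirna, dtype=bool)
    for group in GROUPS:
        keep &= (counts[group] >= min_per_group).to_numpy()
    retained = tuple(np.asarray(table.mirna_ids)[keep])
    dropped = tuple(np.asarray(table.mirna_ids)[~keep])
    out = CqTable(
        table.cq.loc[list(retained)], panel_id=table.panel_id, censor_at=table.censor_at
    )
    return FilterResult(out, retained, dropped)


def file_sha256(path: str | Path) -> str:
    """Hex SHA-256 of a file, for provenance records."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
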