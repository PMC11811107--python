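"""Reading and writing TPS landmark files and assembling labelled datasets.

The TPS dialect understood here is the one produced by tpsDig/tpsUtil:
records start with ``LM=<k>`` followed by ``k`` lines of two decimal
numbers, optionally followed by ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.
Unknown keys are tolerated with a logged warning, since files in the wild
carry extras.

Specimen metadata (species, genus, sex, source) travels in a separate CSV
table and is joined onto the landmark configurations by specimen id
(case-insensitively — ids typically originate from image filenames).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used for a missing classifier value (e.g. an unsexable specimen).
UNKNOWN = "unknown"

#: Metadata columns expected in a specimen table.
META_COLUMNS = ("specimen_id", "species", "genus", "sex", "source")


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


class DatasetError(ValueError):
    """Raised when landmark configurations and metadata cannot be combined."""


class SmallSampleWarning(UserWarning):
    """A group violates the 2x-landmarks minimum-sample rule of thumb."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark configuration.

    Landmark order is semantic: index ``i`` is the same vein intersection in
    every specimen of a dataset.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    landmarks : (k, 2) ndarray
        Landmark coordinates, in pixels or dimensionless units.
    scale : float, optional
        Pixels-per-unit factor, if the source file carried one.
    labels : dict
        Classifier name -> value (species, genus, sex, ...). Missing values
        are the explicit :data:`UNKNOWN` sentinel, never the empty string.
    """

    specimen_id: str
    landmarks: np.ndarray
    scale: float | None = None
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError(
                f"landmarks must be a (k, 2) array, got {self.landmarks.shape}"
            )
        if self.landmarks.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        centered = self.landmarks - self.landmarks.mean(axis=0)
        if not np.any(centered):
            raise ValueError(
                f"degenerate configuration (all landmarks coincident) "
                f"in specimen {self.specimen_id!r}"
            )

    @property
    def k(self) -> int:
        """Number of landmarks."""
        return self.landmarks.shape[0]


@dataclass
class SpecimenTable:
    """Specimen metadata: one row per specimen id.

    Wraps a :class:`pandas.DataFrame` with columns
    ``specimen_id, species, genus, sex, source``. Missing values are stored
    as the :data:`UNKNOWN` sentinel.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"specimen table lacks columns: {missing}")
        for col in META_COLUMNS:
            df[col] = df[col].astype("string")
        df = df.fillna(UNKNOWN)
        df.loc[:, df.columns != "specimen_id"] = df.loc[
            :, df.columns != "specimen_id"
        ].replace("", UNKNOWN)
        dup = df["specimen_id"].str.lower().duplicated()
        if dup.any():
            raise DatasetError(
                f"duplicate specimen ids: {sorted(df.loc[dup, 'specimen_id'])}"
            )
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpecimenTable":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def lookup(self, specimen_id: str) -> pd.Series:
        key = specimen_id.lower()
        hit = self.frame[self.frame["specimen_id"].str.lower() == key]
        if hit.empty:
            raise DatasetError(f"specimen id {specimen_id!r} not in table")
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LabeledDataset:
    """Analysis-ready landmark dataset: coordinates plus group labels.

    Attributes
    ----------
    coords : (n, k, 2) ndarray
        Raw (pre-superimposition) landmark coordinates.
    specimen_ids : list of str
    labels : DataFrame
        Metadata rows aligned with ``coords``.
    classifier : str
        The grouping column used to build the dataset (species/genus/sex).
    """

    coords: np.ndarray
    specimen_ids: list[str]
    labels: pd.DataFrame
    classifier: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        if len(self.specimen_ids) != self.coords.shape[0]:
            raise ValueError("specimen_ids length does not match coords")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def groups(self) -> np.ndarray:
        """Group label per specimen under the dataset's classifier."""
        return self.labels[self.classifier].to_numpy(dtype=object)

    def group_labels(self) -> list[str]:
        return sorted(set(self.groups))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "wingmorph-dataset",
            "version": 1,
            "classifier": self.classifier,
            "coords": self.coords.tolist(),
            "specimen_ids": self.specimen_ids,
            "labels": self.labels.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "LabeledDataset":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "wingmorph-dataset":
            raise DatasetError(f"{path} is not a wingmorph dataset file")
        return cls(
            coords=np.array(doc["coords"]),
            specimen_ids=list(doc["specimen_ids"]),
            labels=pd.DataFrame(doc["labels"]),
            classifier=doc["classifier"],
        )

    def configurations(self) -> list[LandmarkConfiguration]:
        out = []
        for i, sid in enumerate(self.specimen_ids):
            out.append(
                LandmarkConfiguration(
                    specimen_id=sid,
                    landmarks=self.coords[i],
                    labels={
                        c: self.labels.at[i, c]
                        for c in self.labels.columns
                        if c != "specimen_id"
                    },
                )
            )
        return out


# ---------------------------------------------------------------------------
# TPS I/O


def _finish_record(
    records: list[LandmarkConfiguration],
    k: int | None,
    coords: list[list[float]],
    meta: dict[str, str],
    record_index: int,
    flip_y: bool,
) -> None:
    if k is None:
        return
    if len(coords) != k:
        raise TPSParseError(
            f"record {record_index}: LM={k} declared but "
            f"{len(coords)} coordinate lines found"
        )
    arr = np.array(coords, dtype=float)
    scale = None
    if "SCALE" in meta:
        try:
            scale = float(meta["SCALE"])
        except ValueError as exc:
            raise TPSParseError(
                f"record {record_index}: non-numeric SCALE={meta['SCALE']!r}"
            ) from exc
        arr = arr * scale
    if flip_y:
        arr[:, 1] = arr[:, 1].max() - arr[:, 1]
    specimen_id = meta.get("ID") or meta.get("IMAGE") or f"specimen_{record_index}"
    records.append(
        LandmarkConfiguration(specimen_id=specimen_id, landmarks=arr, scale=scale)
    )


def read_tps(path: str | Path, flip_y: bool = False) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Parameters
    ----------
    path : path
        TPS text file. Each record: ``LM=<k>``, then ``k`` lines of two
        decimal numbers, then optional ``IMAGE=``, ``ID=``, ``SCALE=`` lines.
    flip_y : bool
        If set, replace y with ``max_y - y`` within each record. Image
        coordinates put the origin at the top-left; plotting conventions put
        it at the bottom-left. Off by default: coordinates are stored as read.

    Returns
    -------
    list of LandmarkConfiguration
        One per record, in file order. ``SCALE=`` is applied multiplicatively.

    Raises
    ------
    TPSParseError
        On malformed records, with the record index or line number.
    """
    path = Path(path)
    records: list[LandmarkConfiguration] = []
    k: int | None = None
    coords: list[list[float]] = []
    meta: dict[str, str] = {}
    record_index = 0

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if "=" in line and not _looks_like_coords(line):
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "LM":
                    _finish_record(records, k, coords, meta, record_index, flip_y)
                    record_index += 1
                    try:
                        k = int(value)
                    except ValueError as exc:
                        raise TPSParseError(
                            f"line {lineno}: bad LM= value {value!r}"
                        ) from exc
                    coords, meta = [], {}
                elif key in ("IMAGE", "ID", "SCALE"):
                    meta[key] = value
                else:
                    logger.warning("ignoring unknown TPS key %r at line %d", key, lineno)
            else:
                if k is None:
                    raise TPSParseError(f"line {lineno}: coordinates before any LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise TPSParseError(
                        f"line {lineno}: expected two numbers, got {line!r}"
                    )
                try:
                    coords.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise TPSParseError(
                        f"line {lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
    _finish_record(records, k, coords, meta, record_index, flip_y)

    if not records:
        raise TPSParseError(f"no records found in {path}")
    ks = {r.k for r in records}
    if len(ks) > 1:
        raise TPSParseError(
            f"inconsistent landmark counts across records: {sorted(ks)}"
        )
    return records


def _looks_like_coords(line: str) -> bool:
    # "1.0 2.0" has no '='; guard against ids containing '=' being misread.
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(
    configs: Sequence[LandmarkConfiguration], path: str | Path
) -> None:
    """Write configurations as a TPS file readable by :func:`read_tps`.

    Coordinates are written with full ``repr`` precision so that a
    write/read round trip reproduces them bit-identically. ``ID=`` is
    written from ``specimen_id``; no ``SCALE=`` is emitted (coordinates are
    stored already scaled).
    """
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty list of configurations")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
    path = Path(path)
    with path.open("w") as fh:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.landmarks:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# Dataset assembly


def assemble_dataset(
    configs: Sequence[LandmarkConfiguration],
    table: SpecimenTable,
    classifier: str,
) -> LabeledDataset:
    """Join configurations with metadata and restrict to a usable subset.

    Specimens whose value for ``classifier`` is missing (the ``unknown``
    sentinel) are dropped — e.g. unsexable specimens are excluded from a
    sexual-dimorphism dataset. Coordinates are never modified, only
    membership and labels.

    A :class:`SmallSampleWarning` is emitted for any group whose sample size
    falls below twice the number of landmarks (Bookstein's rule of thumb for
    landmark-based analyses; 14 specimens for the 7-landmark wing scheme).

    Raises
    ------
    DatasetError
        If a configuration's id is absent from the table, or the classifier
        column does not exist.
    """
    configs = list(configs)
    if not configs:
        raise DatasetError("no configurations supplied")
    if classifier not in table.frame.columns or classifier == "specimen_id":
        raise DatasetError(
            f"classifier {classifier!r} is not a column of the specimen table"
        )
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetError(f"inconsistent landmark counts: {sorted(ks)}")

    by_id = {
        sid.lower(): row
        for sid, row in zip(
            table.frame["specimen_id"], table.frame.to_dict("records")
        )
    }
    unmatched = [c.specimen_id for c in configs if c.specimen_id.lower() not in by_id]
    if unmatched:
        raise DatasetError(f"specimen ids missing from metadata table: {unmatched}")

    kept_coords, kept_ids, kept_rows = [], [], []
    for c in configs:
        row = by_id[c.specimen_id.lower()]
        if row[classifier] == UNKNOWN:
            continue
        kept_coords.append(c.landmarks)
        kept_ids.append(c.specimen_id)
        kept_rows.append(row)
    if not kept_coords:
        raise DatasetError(
            f"no specimen has a known value for classifier {classifier!r}"
        )

    labels = pd.DataFrame(kept_rows)
    ds = LabeledDataset(
        coords=np.stack(kept_coords),
        specimen_ids=kept_ids,
        labels=labels,
        classifier=classifier,
    )
    k = ds.k
    counts = labels[classifier].value_counts()
    for group, n_g in counts.items():
        if n_g < 2 * k:
            warnings.warn(
                f"group {group!r} has n={n_g} < {2 * k} (twice the landmark "
                f"count); results for this group are unreliable",
                SmallSampleWarning,
                stacklevel=2,
            )
    return ds
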