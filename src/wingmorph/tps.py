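"""Reading and writing landmark data in the TPS dialect of tpsDig2/tpsUtil.

A TPS record is a plain-text block starting with ``LM=<k>``, followed by k
lines of ``x y`` coordinates and optional ``IMAGE=``, ``ID=`` and ``SCALE=``
keyword lines.  This module establishes the package's conventions:

* coordinates are stored exactly as read (tpsDig2's bottom-left origin is
  not flipped; all specimens are assumed digitized on the same wing side);
* landmarks are indexed 0-based internally, 1-based in user-facing reports;
* ``SCALE=`` factors are applied by default so centroid sizes are
  comparable across images.

Specimen metadata (apiary, colony, altitude in m a.s.l., reference-group
label) lives in a sidecar CSV joined on ``specimen_id``.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DatasetError, TPSParseError

logger = logging.getLogger(__name__)

#: Altitudinal floors (label, low, high), closed bands on integer-rounded
#: altitude in metres above sea level.
ALTITUDE_FLOORS: tuple[tuple[str, int, int], ...] = (
    ("2600-2800", 2600, 2800),
    ("2801-3000", 2801, 3000),
    ("3001-3274", 3001, 3274),
)

_KNOWN_KEYWORDS = {"LM", "IMAGE", "ID", "SCALE"}

METADATA_COLUMNS = ("apiary", "colony", "altitude_masl", "group_label")


def altitude_floor(altitude_masl: float) -> Optional[str]:
    """Map an altitude to its altitudinal floor label, or None if outside
    all bands.  Altitude is rounded to the nearest integer first so the
    closed bands [2600, 2800], [2801, 3000], [3001, 3274] tile the whole
    range without gaps."""
    a = int(round(float(altitude_masl)))
    for label, lo, hi in ALTITUDE_FLOORS:
        if lo <= a <= hi:
            return label
    return None


@dataclass
class LandmarkConfiguration:
    """One specimen's raw landmark coordinates plus identifiers/metadata.

    coords is a (k, 2) float array in image units.  All configurations in a
    dataset must share k and landmark ordering.
    """

    specimen_id: str
    coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise DatasetError(f"specimen {self.specimen_id!r}: no landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise DatasetError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        alt = self.metadata.get("altitude_masl")
        if alt is not None and not (pd.isna(alt) or alt > 0):
            raise DatasetError(
                f"specimen {self.specimen_id!r}: altitude_masl must be > 0"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def floor(self) -> Optional[str]:
        alt = self.metadata.get("altitude_masl")
        if alt is None or pd.isna(alt):
            return None
        return altitude_floor(alt)


class Dataset:
    """An ordered collection of landmark configurations sharing one k.

    Supports deriving named group partitions (reference subspecies labels,
    apiary, altitudinal floor) used by the downstream statistics.
    """

    def __init__(self, configurations: Iterable[LandmarkConfiguration]):
        self.configurations: list[LandmarkConfiguration] = list(configurations)
        if self.configurations:
            ks = {c.k for c in self.configurations}
            if len(ks) > 1:
                raise DatasetError(
                    f"inconsistent landmark counts across records: {sorted(ks)}"
                )
            ids = [c.specimen_id for c in self.configurations]
            seen: set[str] = set()
            for sid in ids:
                if sid in seen:
                    raise DatasetError(f"duplicate specimen_id {sid!r}")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def k(self) -> int:
        if not self.configurations:
            raise DatasetError("empty dataset has no landmark count")
        return self.configurations[0].k

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.configurations:
            row = {"specimen_id": c.specimen_id}
            for col in METADATA_COLUMNS:
                row[col] = c.metadata.get(col)
            row["floor"] = c.floor
            rows.append(row)
        return pd.DataFrame(rows).set_index("specimen_id")

    def group_labels(self, by: str) -> pd.Series:
        """Per-specimen group labels for a partition.

        by: 'group_label' (reference subspecies / placebo), 'apiary',
        'colony', or 'floor' (derived altitudinal band).  Specimens with no
        value for the chosen field get NaN and are excluded by the group
        statistics.
        """
        meta = self.metadata_frame()
        if by not in meta.columns:
            raise ConfigError(f"unknown grouping variable {by!r}")
        return meta[by]

    def subset(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        return Dataset(
            [c for c, m in zip(self.configurations, mask) if m]
        )


def read_tps(path: str | os.PathLike, scale_policy: str = "apply") -> Dataset:
    """Read a TPS file into a Dataset.

    scale_policy 'apply' multiplies coordinates by the record's SCALE=
    factor when present; 'ignore' leaves coordinates in pixel units.
    Records are preserved in file order; ID= (or the IMAGE= basename as a
    fallback) becomes the specimen_id.
    """
    if scale_policy not in ("apply", "ignore"):
        raise ConfigError(f"scale_policy must be 'apply' or 'ignore', got {scale_policy!r}")
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    record_index = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(
                f"{path}:{i + 1}: expected 'LM=' header, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise TPSParseError(f"{path}:{i + 1}: malformed LM= header {line!r}") from None
        if k < 1:
            raise TPSParseError(f"{path}:{i + 1}: LM= count must be >= 1")
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n_lines:
                raise TPSParseError(
                    f"{path}: record starting near line {i - j}: "
                    f"expected {k} coordinate lines, file ended after {j}"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}:{i + 1}: expected 'x y' coordinate pair, got {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError:
                raise TPSParseError(
                    f"{path}:{i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from None
            i += 1
        specimen_id: Optional[str] = None
        image: Optional[str] = None
        scale: Optional[float] = None
        # keyword lines up to the next LM= block
        while i < n_lines:
            kwline = lines[i].strip()
            if not kwline:
                i += 1
                continue
            if kwline.upper().startswith("LM="):
                break
            if "=" not in kwline:
                raise TPSParseError(
                    f"{path}:{i + 1}: unexpected line {kwline!r} (not a keyword)"
                )
            key, _, value = kwline.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError:
                    raise TPSParseError(
                        f"{path}:{i + 1}: malformed SCALE= value {value!r}"
                    ) from None
            elif key in _KNOWN_KEYWORDS:
                pass
            else:
                warnings.warn(
                    f"{path}:{i + 1}: ignoring unknown TPS keyword {key!r}",
                    stacklevel=2,
                )
            i += 1
        if specimen_id is None:
            if image is not None:
                specimen_id = os.path.splitext(os.path.basename(image))[0]
            else:
                specimen_id = str(record_index)
        if scale is not None and scale_policy == "apply":
            coords = coords * scale
        configs.append(LandmarkConfiguration(specimen_id, coords))
        record_index += 1
    return Dataset(configs)


def write_tps(dataset: Dataset, path: str | os.PathLike) -> None:
    """Write a Dataset as a TPS file (LM=, 'x y' lines at 6 significant
    digits, ID= per record); the output round-trips through read_tps."""
    if len(dataset) == 0:
        raise DatasetError("cannot write an empty dataset")
    path = os.fspath(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for config in dataset:
                fh.write(f"LM={config.k}\n")
                for x, y in config.coords:
                    fh.write(f"{x:.6g} {y:.6g}\n")
                fh.write(f"ID={config.specimen_id}\n")
    except OSError as exc:
        raise TPSParseError(f"failed to write TPS file {path!r}: {exc}") from exc


def attach_metadata(dataset: Dataset, table: "str | os.PathLike | pd.DataFrame") -> Dataset:
    """Join a metadata table (CSV path or DataFrame) onto a dataset by
    specimen_id.  Specimens missing from the table keep empty metadata and
    trigger a logged warning.  Returns a new Dataset."""
    if isinstance(table, pd.DataFrame):
        meta = table.copy()
    else:
        meta = pd.read_csv(os.fspath(table), dtype={"specimen_id": str})
    if "specimen_id" not in meta.columns:
        raise ConfigError("metadata table must have a 'specimen_id' column")
    if meta["specimen_id"].duplicated().any():
        dups = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ConfigError(f"metadata table has duplicate specimen_id values: {dups[:5]}")
    meta = meta.set_index("specimen_id")
    if "altitude_masl" in meta.columns:
        meta["altitude_masl"] = pd.to_numeric(meta["altitude_masl"], errors="coerce")

    out: list[LandmarkConfiguration] = []
    missing: list[str] = []
    for config in dataset:
        if config.specimen_id in meta.index:
            row = meta.loc[config.specimen_id]
            md = {
                col: (None if pd.isna(row[col]) else row[col])
                for col in meta.columns
                if col in METADATA_COLUMNS or col in ("population",)
            }
        else:
            md = {}
            missing.append(config.specimen_id)
        out.append(LandmarkConfiguration(config.specimen_id, config.coords.copy(), md))
    if missing:
        logger.warning(
            "%d specimens missing from metadata table (e.g. %s)",
            len(missing), missing[:3],
        )
    return Dataset(out)
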