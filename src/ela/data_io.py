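"""Reading abundance matrices and factor metadata; writing result tables.

The expected input layout mirrors the classic factor-by-timepoint matrix used
in marine time-series studies: one row per factor (an OTU or an environmental
measurement), one column per sampling time, tab-delimited, with a header row
of timepoint labels and the factor identifier in the first column.  Missing
observations are marked with a token (``na`` by default) or left empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTU = "OTU"
ENVIRONMENT = "environment"
FACTOR_CLASSES = (OTU, ENVIRONMENT)

PAIR_COLUMNS = ["X", "Y", "LS", "sign", "interval_start", "interval_end", "delay", "P", "Q"]
TRIPLET_COLUMNS = ["X", "Y", "Z", "LA", "P", "Q", "type"]


@dataclass
class AbundanceTable:
    """A factor-by-timepoint numeric matrix with an explicit missing mask.

    ``values`` is a float DataFrame (factors as rows, timepoints as columns)
    where missing observations are NaN.  ``factor_class`` maps every factor id
    to either ``"OTU"`` or ``"environment"``.
    """

    values: pd.DataFrame
    factor_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1:
            raise ValueError("abundance table needs at least one factor row")
        if self.values.shape[1] < 2:
            raise ValueError("abundance table needs at least two timepoints")
        ids = list(self.values.index)
        dupes = [x for x in ids if ids.count(x) > 1]
        if dupes:
            raise ValueError(f"duplicate factor id {dupes[0]!r}")
        for fid in ids:
            self.factor_class.setdefault(fid, OTU)
            if self.factor_class[fid] not in FACTOR_CLASSES:
                raise ValueError(
                    f"factor {fid!r} has unknown class {self.factor_class[fid]!r}"
                )

    @property
    def factor_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoint_labels(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_factors(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the observation is missing."""
        return self.values.isna()


@dataclass
class FactorClassTable:
    """Rows of (factor_id, class); class is ``OTU`` or ``environment``."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        for fid, cls in self.classes.items():
            if cls not in FACTOR_CLASSES:
                raise ValueError(f"factor {fid!r} has unknown class {cls!r}")

    def get(self, factor_id: str) -> str:
        return self.classes.get(factor_id, OTU)


def read_abundance_table(path, na_token: str = "na",
                         classes: FactorClassTable | None = None) -> AbundanceTable:
    """Read a tab-delimited factor-by-timepoint matrix.

    The first row is a header of timepoint labels, the first column holds
    factor ids.  Cells equal to ``na_token`` (case-insensitive) or empty are
    treated as missing.  Duplicate factor ids, ragged rows and non-numeric
    cells raise ValueError with the offending location.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one factor row")
    header = lines[0].split("\t")
    timepoints = header[1:]
    n = len(timepoints)
    if n < 2:
        raise ValueError(f"{path}: need at least two timepoint columns")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    token = na_token.lower()
    for row_no, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        fid = cells[0]
        if fid in ids:
            raise ValueError(f"{path}: duplicate factor id {fid!r} (row {row_no})")
        if len(cells) - 1 != n:
            raise ValueError(
                f"{path}: row {row_no} ({fid!r}) has {len(cells) - 1} values, expected {n}"
            )
        vals = np.empty(n)
        for j, cell in enumerate(cells[1:]):
            c = cell.strip()
            if c == "" or c.lower() == token:
                vals[j] = np.nan
            else:
                try:
                    vals[j] = float(c)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at row {row_no}, "
                        f"column {header[1 + j]!r}"
                    ) from None
        ids.append(fid)
        rows.append(vals)

    values = pd.DataFrame(np.vstack(rows), index=ids, columns=timepoints)
    class_map: dict[str, str] = {}
    if classes is not None:
        for fid in ids:
            if fid not in classes.classes:
                logger.warning("factor %r missing from class table; defaulting to OTU", fid)
            class_map[fid] = classes.get(fid)
    return AbundanceTable(values=values, factor_class=class_map)


def read_factor_classes(path) -> FactorClassTable:
    """Read a two-column tab-delimited (factor_id, class) file."""
    classes: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row_no, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n").rstrip("\r")
            if ln == "" or (row_no == 1 and ln.lower().startswith("factor")):
                continue
            cells = ln.split("\t")
            if len(cells) != 2:
                raise ValueError(f"{path}: row {row_no} does not have two columns")
            fid, cls = cells[0], cells[1].strip()
            if cls not in FACTOR_CLASSES:
                raise ValueError(
                    f"{path}: row {row_no}: unknown class {cls!r} "
                    f"(expected one of {FACTOR_CLASSES})"
                )
            classes[fid] = cls
    return FactorClassTable(classes=classes)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_table(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_pair_table(pairs, path) -> None:
    """Write screened pairs as TSV, sorted by (P, -|LS|, X, Y)."""
    rows = sorted(
        pairs, key=lambda a: (a.p, -abs(a.ls), a.x_id, a.y_id)
    )
    df = pd.DataFrame(
        [
            {
                "X": a.x_id, "Y": a.y_id, "LS": float(a.ls), "sign": a.sign,
                "interval_start": a.interval_start, "interval_end": a.interval_end,
                "delay": a.delay, "P": float(a.p), "Q": float(a.q),
            }
            for a in rows
        ],
        columns=PAIR_COLUMNS,
    )
    _write_table(df, path)


def write_triplet_table(triplets, path) -> None:
    """Write mediated triplets as TSV, sorted by (P, -|LA|, X, Y, Z)."""
    rows = sorted(
        triplets, key=lambda t: (t.p, -abs(t.la), t.x_id, t.y_id, t.z_id)
    )
    df = pd.DataFrame(
        [
            {
                "X": t.x_id, "Y": t.y_id, "Z": t.z_id, "LA": float(t.la),
                "P": float(t.p), "Q": float(t.q), "type": t.la_type,
            }
            for t in rows
        ],
        columns=TRIPLET_COLUMNS,
    )
    _write_table(df, path)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_triplet_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
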