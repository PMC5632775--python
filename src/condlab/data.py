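"""Tabular data model and file IO.

A :class:`ConditioningTable` holds one row per participant with the mean
conditioned response (CR) to each of two stimuli (CS1, CS2) and an optional
two-level group label.  Readers accept comma-separated (.csv) and
whitespace-delimited (.txt) files with a header row; SPSS .sav files are
supported when ``pyreadstat`` is installed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("condlab")

__all__ = [
    "ConditioningTable",
    "ResultsBundle",
    "read_table",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class ConditioningTable:
    """Per-participant CS1/CS2 response magnitudes with optional grouping.

    Parameters
    ----------
    cs1, cs2
        Response magnitudes (arbitrary CR units, e.g. mean startle EMG) for
        the reinforced and unreinforced stimulus.  Equal length ``n >= 2``,
        all values finite.
    subject_id
        Opaque per-row labels; defaults to ``s1 ... sn``.
    group
        Optional categorical labels with exactly two distinct levels, each
        holding at least two rows.  Level order is first appearance, which
        fixes the sign convention of the between-group comparison.
    """

    cs1: np.ndarray
    cs2: np.ndarray
    subject_id: np.ndarray = None  # type: ignore[assignment]
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        cs1 = np.asarray(self.cs1, dtype=float)
        cs2 = np.asarray(self.cs2, dtype=float)
        object.__setattr__(self, "cs1", cs1)
        object.__setattr__(self, "cs2", cs2)
        if cs1.ndim != 1 or cs2.ndim != 1 or len(cs1) != len(cs2):
            raise ValueError("cs1 and cs2 must be 1-D arrays of equal length")
        if len(cs1) < 2:
            raise ValueError(f"need at least 2 complete rows, got {len(cs1)}")
        if not (np.isfinite(cs1).all() and np.isfinite(cs2).all()):
            raise ValueError("cs1/cs2 contain non-finite values")
        if self.subject_id is None:
            object.__setattr__(
                self, "subject_id", np.array([f"s{i + 1}" for i in range(len(cs1))])
            )
        else:
            sid = np.asarray(self.subject_id)
            if len(sid) != len(cs1):
                raise ValueError("subject_id length mismatch")
            object.__setattr__(self, "subject_id", sid)
        if self.group is not None:
            grp = np.asarray(self.group)
            if len(grp) != len(cs1):
                raise ValueError("group length mismatch")
            levels = list(pd.unique(grp))
            if len(levels) != 2:
                raise ValueError(
                    f"group column must have exactly 2 levels, found {len(levels)}: {levels}"
                )
            for lev in levels:
                if int(np.sum(grp == lev)) < 2:
                    raise ValueError(f"group level {lev!r} has fewer than 2 rows")
            object.__setattr__(self, "group", grp)

    @property
    def n(self) -> int:
        return len(self.cs1)

    @property
    def group_levels(self) -> Optional[list]:
        """Group levels in first-appearance order, or None if ungrouped."""
        if self.group is None:
            return None
        return list(pd.unique(self.group))

    def diffs(self) -> np.ndarray:
        """Within-subject difference scores CS1 - CS2."""
        return self.cs1 - self.cs2

    def diffs_by_group(self) -> tuple[np.ndarray, np.ndarray]:
        """Difference scores split by group (first-appearance order)."""
        if self.group is None:
            raise ValueError("table has no group column")
        d = self.diffs()
        lev1, lev2 = self.group_levels  # type: ignore[misc]
        return d[self.group == lev1], d[self.group == lev2]

    def to_frame(self) -> pd.DataFrame:
        cols = {"subject_id": self.subject_id, "cs1": self.cs1, "cs2": self.cs2}
        if self.group is not None:
            cols["group"] = self.group
        return pd.DataFrame(cols)


@dataclass
class ResultsBundle:
    """Container tying together all results computed from one table."""

    descriptives: pd.DataFrame
    freq: "FreqResult"  # noqa: F821 - forward ref to frequentist module
    bayes: "BayesResult"  # noqa: F821
    sensitivity: Optional["SensitivityCurve"] = None  # noqa: F821
    alpha: float = 0.05


def read_table(
    path: str | os.PathLike,
    cs1_col: str,
    cs2_col: str,
    group_col: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> ConditioningTable:
    """Read a delimited data file into a validated :class:`ConditioningTable`.

    Rows with a missing value in any selected column are dropped listwise;
    the number of dropped rows is reported through the ``condlab`` logger.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If a named column is absent from the file.
    ValueError
        If fewer than 2 complete rows remain, the CS columns are not
        numeric, or the group column does not have exactly 2 levels.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".sav":
        try:
            import pyreadstat  # soft dependency
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "reading .sav files requires the optional 'pyreadstat' package"
            ) from exc
        df, _ = pyreadstat.read_sav(path)  # pragma: no cover
    elif delimiter is not None:
        df = pd.read_csv(path, sep=delimiter)
    elif ext == ".csv":
        df = pd.read_csv(path)
    else:
        # .txt and anything else: any-whitespace delimited with a header row
        df = pd.read_csv(path, sep=r"\s+")

    wanted = [cs1_col, cs2_col] + ([group_col] if group_col else [])
    for col in wanted:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found; file has {list(df.columns)}")

    sub = df[wanted].copy()
    for col in (cs1_col, cs2_col):
        sub[col] = pd.to_numeric(sub[col], errors="coerce")
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.warning(
            "read_table: dropped %d of %d rows with missing values (listwise)",
            n_dropped,
            n_before,
        )
    if len(sub) < 2:
        raise ValueError(
            f"fewer than 2 complete rows after missing-data handling ({len(sub)})"
        )
    subject_id = (
        df.loc[sub.index, "subject_id"].to_numpy()
        if "subject_id" in df.columns
        else np.array([f"s{i + 1}" for i in sub.index])
    )
    return ConditioningTable(
        cs1=sub[cs1_col].to_numpy(dtype=float),
        cs2=sub[cs2_col].to_numpy(dtype=float),
        subject_id=subject_id,
        group=sub[group_col].to_numpy() if group_col else None,
    )


# ---------------------------------------------------------------------------
# Results serialization


def _bundle_to_dict(bundle: ResultsBundle) -> dict:
    out: dict = {
        "descriptives": bundle.descriptives.to_dict(orient="records"),
        "frequentist": dataclasses.asdict(bundle.freq),
        "bayesian": dataclasses.asdict(bundle.bayes),
        "alpha": bundle.alpha,
    }
    if bundle.sensitivity is not None:
        out["sensitivity"] = {
            "r": list(bundle.sensitivity.r),
            "bf10": list(bundle.sensitivity.bf10),
            "bf01": list(bundle.sensitivity.bf01),
            "direction_stable": bool(bundle.sensitivity.direction_stable),
        }
    return out


def write_results(bundle: ResultsBundle, path: str | os.PathLike, format: str = "json") -> None:
    """Serialize a :class:`ResultsBundle` at full numeric precision.

    ``format='json'`` writes a nested round-trippable document;
    ``format='csv'`` writes one tidy ``(section, quantity, value)`` row per
    numeric field.  Display rounding is the report module's job.
    """
    d = _bundle_to_dict(bundle)
    path = os.fspath(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
    elif format == "csv":
        rows = []

        def flatten(section: str, obj, prefix: str = "") -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    flatten(section, v, f"{prefix}{k}." if prefix else f"{k}.")
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    flatten(section, v, f"{prefix}{i}.")
            else:
                rows.append({"section": section, "quantity": prefix.rstrip("."), "value": obj})

        for section in ("descriptives", "frequentist", "bayesian", "sensitivity"):
            if section in d:
                flatten(section, d[section])
        rows.append({"section": "meta", "quantity": "alpha", "value": bundle.alpha})
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


def read_results(path: str | os.PathLike) -> dict:
    """Re-read a JSON results file written by :func:`write_results`."""
    with open(os.fspath(path)) as fh:
        return json.load(fh)
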