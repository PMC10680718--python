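"""Replicate-level QC for multiplex bead-immunoassay (Luminex) plate data.

A raw plate arrives as a long-format table with one row per technical
replicate of one analyte in one sample: the interpolated concentration
(pg/mL) and the number of beads the reading was derived from.  The cleaning
pipeline applies, in order:

1. detection-limit censoring (below-limit readings are set to 0 pg/mL),
2. a minimum-bead filter (readings from fewer than ``min_beads`` beads are
   dropped),
3. a triplicate-discordance rule (a replicate whose distance to each of the
   other two exceeds twice their mutual distance is dropped),
4. averaging of the retained replicates per sample x analyte cell,
5. removal of analytes that are mostly zero without partitioning between
   experimental groups.

The output is a wide samples x analytes concentration matrix plus a report
tallying every removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DETECTION_LIMIT",
    "DEFAULT_MIN_BEADS",
    "REQUIRED_COLUMNS",
    "PlateTable",
    "CleanTable",
    "CleaningReport",
    "CleaningError",
    "read_plate_table",
    "censor_below_detection",
    "filter_low_bead",
    "drop_discordant_replicate",
    "collapse_replicates",
    "drop_sparse_analytes",
    "run_cleaning",
]

DEFAULT_DETECTION_LIMIT = 3.2  # pg/mL
DEFAULT_MIN_BEADS = 35

REQUIRED_COLUMNS = (
    "sample_id",
    "group",
    "analyte",
    "replicate",
    "concentration",
    "bead_count",
)


class CleaningError(ValueError):
    """Raised on invalid plate data or cleaning configuration."""


@dataclass(frozen=True)
class PlateTable:
    """Long-format raw plate readings plus the QC constants to apply.

    ``readings`` must carry the columns in :data:`REQUIRED_COLUMNS`.  The
    ``concentration`` column may contain NaN for readings the instrument
    flagged as out-of-range-low; censoring maps those to 0 pg/mL.
    """

    readings: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    min_beads: int = DEFAULT_MIN_BEADS

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.readings.columns]
        if missing:
            raise CleaningError(f"plate table missing required columns: {missing}")
        if not self.detection_limit > 0:
            raise CleaningError("detection_limit must be > 0")
        if self.min_beads < 0:
            raise CleaningError("min_beads must be >= 0")
        df = self.readings
        if (df["bead_count"] < 0).any():
            raise CleaningError("bead_count must be >= 0")
        sizes = df.groupby(["sample_id", "analyte"], sort=False).size()
        if (sizes > 3).any():
            bad = sizes[sizes > 3].index[0]
            raise CleaningError(f"more than 3 replicates for {bad}")
        dup = df.groupby(["sample_id", "analyte"], sort=False)["replicate"].nunique()
        if (dup != sizes).any():
            raise CleaningError("replicate indices not unique within sample x analyte")
        ngroups = df.groupby("sample_id", sort=False)["group"].nunique()
        if (ngroups > 1).any():
            raise CleaningError("group label must be constant within a sample")


@dataclass(frozen=True)
class CleanTable:
    """Samples x analytes matrix of mean concentrations after QC.

    ``matrix`` is indexed by sample_id with one column per retained analyte;
    missing cells (all replicates removed) are NaN, never imputed as 0.
    ``provenance`` has the same shape and holds the number of replicates
    averaged into each cell.
    """

    matrix: pd.DataFrame
    sample_groups: pd.Series
    provenance: pd.DataFrame


@dataclass
class CleaningReport:
    """Tally of everything the pipeline removed and why."""

    n_low_bead_removed: int = 0
    n_discordant_removed: int = 0
    analytes_dropped: list[tuple[str, str]] = field(default_factory=list)
    samples_dropped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_low_bead_removed": self.n_low_bead_removed,
            "n_discordant_removed": self.n_discordant_removed,
            "analytes_dropped": [
                {"analyte": a, "reason": r} for a, r in self.analytes_dropped
            ],
            "samples_dropped": list(self.samples_dropped),
        }


def read_plate_table(
    path,
    *,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    min_beads: int = DEFAULT_MIN_BEADS,
    sep: str | None = None,
) -> PlateTable:
    """Read a long-format plate CSV/TSV into a :class:`PlateTable`.

    Non-numeric concentration entries (e.g. ``OOR <``) are treated as
    below-detection flags and become NaN, which censoring maps to 0.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CleaningError(f"plate file missing required columns: {missing}")
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    df["bead_count"] = pd.to_numeric(df["bead_count"]).astype(int)
    return PlateTable(df, detection_limit=detection_limit, min_beads=min_beads)


def censor_below_detection(concentration, limit: float = DEFAULT_DETECTION_LIMIT):
    """Set concentrations below the detection limit to 0 pg/mL.

    Accepts a scalar or array.  NaN inputs are below-detection flags and
    become 0.  The limit itself is retained (only strictly-below values are
    censored).  Negative concentrations are invalid.
    """
    if not limit > 0:
        raise CleaningError("detection limit must be > 0")
    arr = np.asarray(concentration, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise CleaningError("negative concentration is invalid")
    out = np.where(np.isnan(arr) | (arr < limit), 0.0, arr)
    if np.isscalar(concentration) or arr.ndim == 0:
        return float(out)
    return out


def filter_low_bead(readings: pd.DataFrame, min_beads: int = DEFAULT_MIN_BEADS) -> pd.DataFrame:
    """Keep only readings derived from at least ``min_beads`` beads.

    Readings with ``bead_count < min_beads`` are removed; row order is
    preserved.  ``min_beads = 0`` is a vacuous filter.
    """
    if min_beads < 0:
        raise CleaningError("min_beads must be >= 0")
    return readings[readings["bead_count"] >= min_beads]


def drop_discordant_replicate(values: Sequence[float]) -> tuple[list[float], int | None]:
    """Apply the triplicate-discordance rule to exactly three concentrations.

    Replicate *i* is removed iff its distance to each of the other two
    replicates exceeds twice their mutual distance:
    ``min(|vi - vj|, |vi - vk|) > 2 * |vj - vk|``.  At most one replicate can
    satisfy this (two candidates would force their mutual distance below
    itself), and the decision is invariant to input ordering.  With two equal
    replicates (mutual distance 0), any strictly deviating third replicate is
    removed; all-equal triplets are retained in full.

    Returns ``(retained_values, removed_index)`` with a 0-based index, or
    ``None`` when nothing is removed.
    """
    v = [float(x) for x in values]
    if len(v) != 3:
        raise CleaningError("discordance rule is defined for exactly 3 replicates")
    candidates = []
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        if min(abs(v[i] - v[j]), abs(v[i] - v[k])) > 2.0 * abs(v[j] - v[k]):
            candidates.append(i)
    assert len(candidates) <= 1, "discordance rule selected more than one replicate"
    if not candidates:
        return v, None
    i = candidates[0]
    return [v[m] for m in range(3) if m != i], i


def collapse_replicates(values: Sequence[float]) -> tuple[float, int]:
    """Average the retained replicates of one sample x analyte cell.

    Returns ``(mean, n_averaged)``; an empty input yields ``(nan, 0)`` — a
    missing cell, never 0.
    """
    v = [float(x) for x in values]
    if not v:
        return math.nan, 0
    return float(np.mean(v)), len(v)


def _zero_fractions(col: pd.Series, groups: pd.Series):
    """Overall and per-group fractions of zero readings among non-missing cells."""
    obs = col.dropna()
    if obs.empty:
        return 1.0, {}
    overall = float((obs == 0).mean())
    per_group = {
        str(g): float((obs[groups.loc[obs.index] == g] == 0).mean())
        for g in groups.loc[obs.index].unique()
    }
    return overall, per_group


def drop_sparse_analytes(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    rule: str = "per_group",
    delta: float = 0.25,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Remove analytes that are mostly zero without partitioning between groups.

    An analyte is dropped when over half of its (non-missing) readings are
    0 pg/mL and the zeros do not separate the experimental groups.  Two
    operationalizations of "did not partition" are available:

    - ``rule="per_group"`` (default): the zero fraction exceeds 0.5 within
      *every* group level, so zeros carry no group signal.
    - ``rule="max_diff"``: the largest between-group difference in zero
      fraction is below ``delta``.

    Requires at least two group levels.  Returns the reduced matrix and the
    list of ``(analyte, reason)`` pairs removed.
    """
    groups = groups.loc[matrix.index]
    levels = groups.unique()
    if len(levels) < 2:
        raise CleaningError("sparse-analyte rule requires >= 2 group levels")
    if rule not in ("per_group", "max_diff"):
        raise CleaningError(f"unknown sparse-analyte rule: {rule!r}")
    dropped: list[tuple[str, str]] = []
    keep = []
    for analyte in matrix.columns:
        overall, per_group = _zero_fractions(matrix[analyte], groups)
        if overall > 0.5:
            fracs = [per_group.get(str(g), 0.0) for g in levels]
            if rule == "per_group":
                nonpartitioning = all(f > 0.5 for f in fracs)
            else:
                nonpartitioning = (max(fracs) - min(fracs)) < delta
            if nonpartitioning:
                dropped.append(
                    (str(analyte), f"sparse:zero_fraction={overall:.2f},nonpartitioning")
                )
                continue
        keep.append(analyte)
    return matrix[keep], dropped


def run_cleaning(
    plate: PlateTable,
    *,
    sparse_rule: str = "per_group",
    sparse_delta: float = 0.25,
    apply_sparse_rule: bool = True,
) -> tuple[CleanTable, CleaningReport]:
    """Run the full QC pipeline on a raw plate.

    Stages, in order: detection-limit censoring, bead filter, discordance
    rule (applied only to cells where all three replicates survive the bead
    filter; pairs and singletons bypass it), replicate averaging, and the
    sparse-analyte drop.  Samples whose every cell went missing are dropped
    and reported; analyte columns that end up all-missing are dropped too.
    """
    report = CleaningReport()
    df = plate.readings.copy()
    df["concentration"] = censor_below_detection(
        df["concentration"].to_numpy(dtype=float), plate.detection_limit
    )

    kept = filter_low_bead(df, plate.min_beads)
    report.n_low_bead_removed = len(df) - len(kept)

    sample_order = list(dict.fromkeys(df["sample_id"]))
    analyte_order = list(dict.fromkeys(df["analyte"]))
    groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]

    means = pd.DataFrame(np.nan, index=sample_order, columns=analyte_order)
    counts = pd.DataFrame(0, index=sample_order, columns=analyte_order)
    for (sid, analyte), cell in kept.groupby(["sample_id", "analyte"], sort=False):
        vals = cell["concentration"].tolist()
        if len(vals) == 3:
            vals, removed = drop_discordant_replicate(vals)
            if removed is not None:
                report.n_discordant_removed += 1
        mean, n = collapse_replicates(vals)
        means.loc[sid, analyte] = mean
        counts.loc[sid, analyte] = n

    empty_samples = means.index[means.isna().all(axis=1)]
    report.samples_dropped = [str(s) for s in empty_samples]
    means = means.drop(index=empty_samples)
    counts = counts.drop(index=empty_samples)

    empty_analytes = means.columns[means.isna().all(axis=0)]
    for a in empty_analytes:
        report.analytes_dropped.append((str(a), "all_readings_removed"))
    means = means.drop(columns=empty_analytes)

    if apply_sparse_rule and len(means.columns):
        means, dropped = drop_sparse_analytes(
            means, groups, rule=sparse_rule, delta=sparse_delta
        )
        report.analytes_dropped.extend(dropped)

    counts = counts.loc[means.index, means.columns]
    clean = CleanTable(
        matrix=means, sample_groups=groups.loc[means.index], provenance=counts
    )
    return clean, report
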