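"""Reading, validation and quality screening of regional thickness tables.

A thickness table is a delimited text file with one row per subject and one
column per cortical region (mean cortical thickness in mm, e.g. one column
per Destrieux parcel), plus a leading subject-ID column.  This module loads
such tables into a validated :class:`ThicknessMatrix`, aligns the two
timepoints of a longitudinal design onto a common subject/region ordering,
flags outlying values by regional z-score, and standardizes regions for
covariance estimation on the correlation scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

# physiological sanity bounds for cortical thickness, mm
_THICKNESS_MIN = 0.0
_THICKNESS_MAX = 10.0


@dataclass
class ThicknessMatrix:
    """Subjects x regions cortical thickness for one timepoint.

    Attributes
    ----------
    subject_ids
        Ordered, unique subject identifiers (rows).
    region_labels
        Ordered, unique region labels (columns); 148 in the Destrieux
        reference atlas, but any unique label set is accepted.
    values
        (n_subjects, n_regions) float array of thickness in mm; every value
        must be finite and lie in (0, 10) mm.
    timepoint
        Label such as ``"T1"`` or ``"T2"``.
    """

    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray
    timepoint: str = "T1"

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.region_labels = [str(r) for r in self.region_labels]
        self.values = np.asarray(self.values, dtype=np.float64)
        n, p = len(self.subject_ids), len(self.region_labels)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} subjects x {p} regions"
            )
        dup_s = _duplicates(self.subject_ids)
        if dup_s:
            raise ValueError(f"duplicate subject IDs: {sorted(dup_s)}")
        dup_r = _duplicates(self.region_labels)
        if dup_r:
            raise ValueError(f"duplicate region labels: {sorted(dup_r)}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"missing/non-finite thickness at subject "
                f"{self.subject_ids[i]!r}, region {self.region_labels[j]!r}"
            )
        out = (self.values <= _THICKNESS_MIN) | (self.values >= _THICKNESS_MAX)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"thickness {self.values[i, j]:g} mm at subject "
                f"{self.subject_ids[i]!r}, region {self.region_labels[j]!r} "
                f"is outside the physiological range "
                f"({_THICKNESS_MIN}, {_THICKNESS_MAX}) mm"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject"),
            columns=self.region_labels,
        )


@dataclass
class QCReport:
    """Outlier flags from regional z-scoring of thickness values."""

    flags: list[tuple[str, str, float]]  # (subject_id, region_label, z)
    z_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=["subject", "region", "z_score"])


class AlignedTimepoints(NamedTuple):
    t1: ThicknessMatrix
    t2: ThicknessMatrix
    dropped: list[str]


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def read_thickness_table(
    path, timepoint: str = "T1", delimiter: str | None = None
) -> ThicknessMatrix:
    """Read a delimited thickness table (header = region labels, first
    column = subject ID).  The delimiter is sniffed (comma/tab) unless given.

    Duplicate subject IDs, missing cells and non-numeric cells are hard
    errors naming the offending row/column.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        index_col=0,
        dtype=str,
    )
    subjects = [str(s) for s in df.index]
    regions = [str(c) for c in df.columns]
    dup = _duplicates(subjects)
    if dup:
        raise ValueError(f"duplicate subject IDs in {path}: {sorted(dup)}")
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                raise ValueError(
                    f"missing value at subject {subjects[i]!r}, "
                    f"region {regions[j]!r} in {path}"
                )
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric value {cell!r} at subject {subjects[i]!r}, "
                    f"region {regions[j]!r} in {path}"
                ) from exc
    return ThicknessMatrix(subjects, regions, values, timepoint=timepoint)


def write_thickness_table(m: ThicknessMatrix, path, delimiter: str = ",") -> None:
    """Write a thickness table at full float precision (round-trip safe)."""
    df = m.to_frame()
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def align_timepoints(t1: ThicknessMatrix, t2: ThicknessMatrix) -> AlignedTimepoints:
    """Restrict both timepoints to the common subjects, in t1's order.

    Region label sets must match exactly (region *order* may differ and is
    harmonized to t1's order); otherwise the symmetric difference is
    reported as a hard error.  Subjects present at only one timepoint are
    dropped and reported.
    """
    r1, r2 = set(t1.region_labels), set(t2.region_labels)
    if r1 != r2:
        diff = sorted(r1.symmetric_difference(r2))
        raise ValueError(f"region label sets differ between timepoints: {diff}")
    common = set(t1.subject_ids) & set(t2.subject_ids)
    dropped = sorted(
        [s for s in t1.subject_ids if s not in common]
        + [s for s in t2.subject_ids if s not in common]
    )
    keep = [s for s in t1.subject_ids if s in common]
    f1 = t1.to_frame().loc[keep, t1.region_labels]
    f2 = t2.to_frame().loc[keep, t1.region_labels]
    a1 = ThicknessMatrix(keep, t1.region_labels, f1.to_numpy(), timepoint=t1.timepoint)
    a2 = ThicknessMatrix(keep, t1.region_labels, f2.to_numpy(), timepoint=t2.timepoint)
    return AlignedTimepoints(a1, a2, dropped)


def detect_outliers(m: ThicknessMatrix, z_threshold: float = 3.0) -> QCReport:
    """Flag thickness values whose within-region z-score is extreme.

    Per region, z = (value - region mean) / region SD across subjects, with
    the sample SD (n-1 denominator).  Entries with |z| >= ``z_threshold``
    are flagged; constant regions (SD = 0) produce no flags.  Flags are
    reported, never auto-removed.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    if m.n_subjects < 3:
        raise ValueError(
            f"outlier detection needs at least 3 subjects, got {m.n_subjects}"
        )
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    flags: list[tuple[str, str, float]] = []
    for j in range(m.n_regions):
        if sd[j] == 0:
            continue
        z = (m.values[:, j] - mean[j]) / sd[j]
        for i in np.flatnonzero(np.abs(z) >= z_threshold):
            flags.append((m.subject_ids[i], m.region_labels[j], float(z[i])))
    return QCReport(flags=flags, z_threshold=float(z_threshold))


def standardize_regions(m: ThicknessMatrix) -> pd.DataFrame:
    """Return per-region z-scores (each column mean 0, SD 1, sample SD).

    Covariance estimation consumes these standardized columns, so the lasso
    penalty rho is on the correlation scale.  Zero-variance regions are a
    hard error.
    """
    sd = m.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance region(s): {[m.region_labels[j] for j in zero]}"
        )
    z = (m.values - m.values.mean(axis=0)) / sd
    return pd.DataFrame(
        z, index=pd.Index(m.subject_ids, name="subject"), columns=m.region_labels
    )
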