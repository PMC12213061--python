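"""Mock-quality statistics: CV, absolute fold difference, Welch's t-test.

Quality is scored on a tidy abundance table along two axes:
reproducibility (per-strain coefficient of variation of batch-mean
abundances across batches) and accuracy (per-strain, per-batch absolute
fold difference against the theoretical design fraction, 1/15 for an
equally mixed 15-strain mock). Labeled condition pairs are compared by
two-sided Welch's t-tests on their pooled CV and AFD sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mockforge.errors import DomainError, InsufficientDataError

AFD_MODE_FOLD = "fold"
AFD_MODE_ABS_LOG2 = "abs_log2"


def theoretical_fraction(n_strains: int) -> float:
    """Design fraction of each strain in an equally mixed community."""
    if n_strains < 1:
        raise DomainError("n_strains must be >= 1")
    return 1.0 / n_strains


def fraction_as_percent(fraction: float, ndigits: int = 1) -> float:
    """Display rounding of a fraction to percent (e.g. 1/15 -> 6.7)."""
    return round(fraction * 100.0, ndigits)


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: sample SD (n-1) over mean x 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"CV undefined for non-positive mean {mean}")
    return float(arr.std(ddof=1) / mean * 100.0)


def afd(observed: float, expected: float, mode: str = AFD_MODE_FOLD) -> float:
    """Absolute fold difference between observed and theoretical abundance.

    ``fold`` mode folds the ratio to >= 1: ``max(o/e, e/o)``;
    ``abs_log2`` mode returns ``|log2(o/e)|``. The two satisfy
    ``fold = 2 ** abs_log2``.
    """
    if observed <= 0 or expected <= 0:
        raise DomainError(
            "AFD needs positive observed and expected abundances; "
            "zero abundances cannot be scored (exclude them upstream)"
        )
    ratio = observed / expected
    if mode == AFD_MODE_FOLD:
        return max(ratio, 1.0 / ratio)
    if mode == AFD_MODE_ABS_LOG2:
        return abs(math.log2(ratio))
    raise DomainError(f"unknown AFD mode {mode!r}")


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch's t-test: returns (t, df, p).

    ``t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch–Satterthwaite degrees of freedom. Two groups that are constant
    and equal return the degenerate convention (t=0, df=n_a+n_b-2, p=1).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise InsufficientDataError("Welch's t-test needs >= 2 values per group")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(xa.size + xb.size - 2)
        if xa.mean() == xb.mean():
            return 0.0, df, 1.0
        t = math.inf if xa.mean() > xb.mean() else -math.inf
        return t, df, 0.0
    sa, sb = va / xa.size, vb / xb.size
    t = (xa.mean() - xb.mean()) / math.sqrt(sa + sb)
    # scaled Welch–Satterthwaite form; immune to variance underflow
    wa, wb = sa / (sa + sb), sb / (sa + sb)
    df = 1.0 / (wa**2 / (xa.size - 1) + wb**2 / (xb.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class GroupTest:
    """One Welch comparison between two condition labels on one metric."""

    metric: str
    label_a: str
    label_b: str
    t: float
    df: float
    p: float

    @property
    def stars(self) -> str:
        """Significance annotation (never used for control flow)."""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


@dataclass
class QcReport:
    """Per-strain CV and AFD plus group comparison results.

    ``cv`` has columns (label, strain_id, cv_percent); ``afd`` has
    columns (label, strain_id, batch_id, afd). A label identifies one
    (condition, assay) group of the input table.
    """

    cv: pd.DataFrame
    afd: pd.DataFrame
    expected_fraction: float
    afd_mode: str
    group_tests: list[GroupTest] = field(default_factory=list)

    @property
    def per_strain_cv(self) -> dict:
        """strain_id -> CV%% if one label present, else (label, strain_id) -> CV%%."""
        if self.cv["label"].nunique() <= 1:
            return dict(zip(self.cv["strain_id"], self.cv["cv_percent"]))
        return {
            (row.label, row.strain_id): row.cv_percent for row in self.cv.itertuples()
        }

    @property
    def per_strain_afd(self) -> dict:
        if self.afd["label"].nunique() <= 1:
            return {
                (row.strain_id, row.batch_id): row.afd for row in self.afd.itertuples()
            }
        return {
            (row.label, row.strain_id, row.batch_id): row.afd
            for row in self.afd.itertuples()
        }

    def to_dict(self) -> dict:
        return {
            "expected_fraction": self.expected_fraction,
            "afd_mode": self.afd_mode,
            "cv": self.cv.to_dict(orient="records"),
            "afd": self.afd.to_dict(orient="records"),
            "group_tests": [
                {
                    "metric": g.metric,
                    "label_a": g.label_a,
                    "label_b": g.label_b,
                    "t": g.t,
                    "df": g.df,
                    "p": g.p,
                    "stars": g.stars,
                }
                for g in self.group_tests
            ],
        }


def _labels(table: pd.DataFrame) -> pd.Series:
    if "condition" in table.columns:
        return table["condition"].astype(str) + ":" + table["assay"].astype(str)
    return table["assay"].astype(str)


def qc_report(
    table: pd.DataFrame,
    expected_fraction: float,
    afd_mode: str = AFD_MODE_FOLD,
    compare: Optional[Sequence[tuple[str, str]]] = None,
) -> QcReport:
    """Score an abundance table against its theoretical composition.

    Replicates are averaged within each batch first; CV is then taken
    per strain across batch means (needs >= 2 batches) and AFD per
    (strain, batch). Zero batch-mean abundances are excluded from AFD
    with a warning. ``compare`` lists pairs of labels — ``condition:assay``
    when the table has a condition column, else the assay name — each
    tested on pooled CVs and pooled AFDs.
    """
    if expected_fraction <= 0 or expected_fraction > 1:
        raise DomainError("expected_fraction must lie in (0, 1]")
    work = table.copy()
    work["label"] = _labels(work)

    batch_means = (
        work.groupby(["label", "strain_id", "batch_id"], sort=True)["fraction"]
        .mean()
        .reset_index()
    )

    cv_rows = []
    for (label, strain), group in batch_means.groupby(["label", "strain_id"], sort=True):
        if len(group) < 2:
            raise InsufficientDataError(
                f"strain {strain!r} ({label}): needs >= 2 batches for CV, has {len(group)}"
            )
        cv_rows.append(
            {"label": label, "strain_id": strain, "cv_percent": cv_percent(group["fraction"])}
        )
    cv_frame = pd.DataFrame(cv_rows, columns=["label", "strain_id", "cv_percent"])

    afd_rows = []
    for row in batch_means.itertuples():
        if row.fraction <= 0:
            warnings.warn(
                f"strain {row.strain_id!r} batch {row.batch_id!r} ({row.label}): "
                "zero abundance excluded from AFD",
                stacklevel=2,
            )
            continue
        afd_rows.append(
            {
                "label": row.label,
                "strain_id": row.strain_id,
                "batch_id": row.batch_id,
                "afd": afd(row.fraction, expected_fraction, mode=afd_mode),
            }
        )
    afd_frame = pd.DataFrame(afd_rows, columns=["label", "strain_id", "batch_id", "afd"])

    tests: list[GroupTest] = []
    for label_a, label_b in compare or []:
        for metric, frame, column in (
            ("cv", cv_frame, "cv_percent"),
            ("afd", afd_frame, "afd"),
        ):
            series_a = frame.loc[frame["label"] == label_a, column]
            series_b = frame.loc[frame["label"] == label_b, column]
            if series_a.empty or series_b.empty:
                raise DomainError(
                    f"comparison {label_a!r} vs {label_b!r}: label not present in table"
                )
            t, df, p = welch_t(series_a.to_numpy(), series_b.to_numpy())
            tests.append(GroupTest(metric=metric, label_a=label_a, label_b=label_b, t=t, df=df, p=p))

    return QcReport(
        cv=cv_frame,
        afd=afd_frame,
        expected_fraction=expected_fraction,
        afd_mode=afd_mode,
        group_tests=tests,
    )
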