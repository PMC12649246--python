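"""Paired volumetric statistics for two-condition (e.g. frozen vs thawed)
segmentation experiments.

The experiment design: one specimen is scanned repeatedly under two
conditions, each scan is segmented tightly, and the mesh volumes are
compared pairwise.  This module reproduces the full report for such a
table: per-scan relative differences, a paired t-test with confidence
interval and Cohen's d, and per-column reproducibility summaries.

Conventions (recorded explicitly because they differ within one report):

* per-scan signed relative difference = 100 * (B - A) / B, with the
  second condition (thawed) as denominator; the per-scan display column
  is its absolute value;
* the summary over relative differences uses the *signed* mean and a
  *population* (divisor n) SD;
* raw volume columns are summarized with the sample (divisor n-1) SD;
* Cohen's d for paired data = mean difference / sample SD of differences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for invalid volume tables."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding as used in printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VolumePairTable:
    """Per-scan volume pairs for two conditions of the same object."""

    table: pd.DataFrame
    label_a: str = "frozen"
    label_b: str = "thawed"

    REQUIRED = ("scan_id", "volume_a_mm3", "volume_b_mm3")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise StatsError(f"missing columns: {missing}")
        if self.table["scan_id"].duplicated().any():
            raise StatsError("scan ids must be unique")
        vols = self.table[["volume_a_mm3", "volume_b_mm3"]].to_numpy(dtype=float)
        if not (vols > 0).all():
            raise StatsError("volumes must be positive")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def a(self) -> np.ndarray:
        return self.table["volume_a_mm3"].to_numpy(dtype=float)

    @property
    def b(self) -> np.ndarray:
        return self.table["volume_b_mm3"].to_numpy(dtype=float)

    @classmethod
    def from_volumes(cls, ids, volumes_a, volumes_b, **kw) -> "VolumePairTable":
        return cls(
            pd.DataFrame(
                {"scan_id": list(ids), "volume_a_mm3": volumes_a, "volume_b_mm3": volumes_b}
            ),
            **kw,
        )


def load_reference_table() -> VolumePairTable:
    """The packaged ten-scan frozen/thawed scaphoid volume table."""
    ref = importlib.resources.files("carposeg") / "data" / "freeze_thaw_volumes.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return VolumePairTable.from_volumes(
        df["scan_id"], df["frozen_mm3"], df["thawed_mm3"], label_a="frozen", label_b="thawed"
    )


@dataclass(frozen=True)
class RelativeDifferenceSummary:
    """Signed mean and population-SD of the per-scan relative differences (%)."""

    mean_signed_pct: float
    sd_population_pct: float
    sd_sample_pct: float


def relative_differences(
    table: VolumePairTable,
) -> tuple[pd.DataFrame, RelativeDifferenceSummary]:
    """Per-scan relative volume differences plus their summary.

    Signed difference = 100 * (B - A) / B; the display column
    ``rel_diff_abs_pct`` is its absolute value.  The summary mean is taken
    over the *signed* values and the summary SD uses the population
    convention (divisor n).
    """
    signed = 100.0 * (table.b - table.a) / table.b
    out = table.table.copy()
    out["rel_diff_signed_pct"] = signed
    out["rel_diff_abs_pct"] = np.abs(signed)
    summary = RelativeDifferenceSummary(
        mean_signed_pct=float(signed.mean()),
        sd_population_pct=float(signed.std(ddof=0)),
        sd_sample_pct=float(signed.std(ddof=1)) if len(signed) > 1 else 0.0,
    )
    return out, summary


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test with CI and effect size for volume differences (B - A)."""

    n: int
    mean_difference_mm3: float
    sd_difference_mm3: float
    t_statistic: float
    df: int
    p_value: float
    ci_low_mm3: float
    ci_high_mm3: float
    cohen_d: float


def paired_t_test(a, b, confidence: float = 0.95) -> PairedTestResult:
    """Two-sided paired t-test on differences d_i = b_i - a_i.

    t = mean(d) / (s_d / sqrt(n)) with the sample SD s_d; the CI is
    mean(d) +/- t_{(1+confidence)/2, n-1} * s_d / sqrt(n); Cohen's d for
    paired data is mean(d) / s_d.  A zero-variance, zero-mean difference
    vector is defined as t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError(f"length mismatch: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise StatsError("paired test needs n >= 2")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    se = sd / np.sqrt(n)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * np.inf
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    q = float(sps.t.ppf(0.5 + confidence / 2.0, df))
    half = q * se
    cohen = 0.0 if sd == 0.0 and mean == 0.0 else (mean / sd if sd > 0 else float(np.sign(mean)) * np.inf)
    return PairedTestResult(
        n=n,
        mean_difference_mm3=mean,
        sd_difference_mm3=sd,
        t_statistic=float(t),
        df=df,
        p_value=p,
        ci_low_mm3=mean - half,
        ci_high_mm3=mean + half,
        cohen_d=float(cohen),
    )


def column_summary(volumes) -> tuple[float, float]:
    """(mean, sample-SD) of one volume column."""
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2:
        raise StatsError("column summary needs n >= 2")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class ComparisonReport:
    """Full two-condition comparison: table, paired test, summaries."""

    table: pd.DataFrame
    test: PairedTestResult
    relative: RelativeDifferenceSummary
    mean_a_mm3: float
    sd_a_mm3: float
    mean_b_mm3: float
    sd_b_mm3: float
    label_a: str
    label_b: str

    def to_dict(self) -> dict:
        return {
            "labels": [self.label_a, self.label_b],
            "columns": {
                self.label_a: {"mean_mm3": self.mean_a_mm3, "sd_mm3": self.sd_a_mm3},
                self.label_b: {"mean_mm3": self.mean_b_mm3, "sd_mm3": self.sd_b_mm3},
            },
            "paired_test": vars(self.test).copy(),
            "relative_difference": vars(self.relative).copy(),
        }

    def format_lines(self) -> list[str]:
        """Human-readable report, rounded half-up to two decimals."""
        r = round_half_up
        t = self.test
        return [
            f"n = {t.n} scan pairs ({self.label_a} vs {self.label_b})",
            f"{self.label_a}: mean {r(self.mean_a_mm3)} mm^3 (SD {r(self.sd_a_mm3)})",
            f"{self.label_b}: mean {r(self.mean_b_mm3)} mm^3 (SD {r(self.sd_b_mm3)})",
            f"mean difference: {r(t.mean_difference_mm3)} mm^3 "
            f"(95% CI [{r(t.ci_low_mm3)}, {r(t.ci_high_mm3)}])",
            f"t({t.df}) = {r(t.t_statistic)}, p = {r(t.p_value)}, Cohen's d = {r(t.cohen_d)}",
            f"relative difference: mean {r(self.relative.mean_signed_pct)}% "
            f"(SD {r(self.relative.sd_population_pct)})",
        ]


def run_comparison(
    table: VolumePairTable | None = None,
    meshes_a=None,
    meshes_b=None,
    ids=None,
) -> ComparisonReport:
    """Build the full comparison report from a table or two mesh lists."""
    if table is None:
        if meshes_a is None or meshes_b is None:
            raise StatsError("provide either a table or both mesh lists")
        from .meshmetrics import mesh_volume

        va = [mesh_volume(m) for m in meshes_a]
        vb = [mesh_volume(m) for m in meshes_b]
        ids = list(ids) if ids is not None else list(range(1, len(va) + 1))
        table = VolumePairTable.from_volumes(ids, va, vb, label_a="A", label_b="B")
    if table.n < 2:
        raise StatsError("comparison needs at least two scan pairs")

    derived, rel = relative_differences(table)
    test = paired_t_test(table.a, table.b)
    mean_a, sd_a = column_summary(table.a)
    mean_b, sd_b = column_summary(table.b)
    return ComparisonReport(
        table=derived,
        test=test,
        relative=rel,
        mean_a_mm3=mean_a,
        sd_a_mm3=sd_a,
        mean_b_mm3=mean_b,
        sd_b_mm3=sd_b,
        label_a=table.label_a,
        label_b=table.label_b,
    )
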