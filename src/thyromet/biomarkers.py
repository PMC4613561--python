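"""Correlation-scaled loadings, critical-|r| cutoffs and change tables.

After an OPLS-DA fit, each bucket's contribution to the discrimination is
summarized two ways:

* ``r`` — the Pearson correlation of the (raw) bucket intensities with the
  predictive score t; colored on the loading plot so "warm" buckets carry
  the discrimination.
* ``coefficient`` — the covariance of the centered bucket with t divided by
  sd(t). Because this back-scales out of the unit-variance metric, strong
  peaks dominate the plot like a spectrum.

A bucket is significant when |r| exceeds the critical Pearson correlation at
the chosen alpha for the model's sample count (Student t with n-2 df). For
display the cutoff is truncated (floored toward zero) at two decimals — the
conservative convention that yields the familiar |r| > 0.29 (n = 44) and
|r| > 0.39 (n = 25) thresholds.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import OPLSDAModel, _as_matrix
from .errors import ValidationError
from .preprocess import BucketTable

_ZERO_VAR_TOL = 1e-12


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson |r| at level alpha for n samples.

    r_crit = t* / sqrt(t*^2 + (n-2)) with t* the two-sided (1-alpha)
    critical value of Student's t on n-2 degrees of freedom. Full precision;
    use :func:`display_critical_r` for the truncated display form.
    """
    if n < 3:
        raise ValidationError("critical_r requires n >= 3")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_star / math.sqrt(t_star**2 + (n - 2)))


def display_critical_r(n: int, alpha: float = 0.05) -> float:
    """Critical |r| truncated (floored toward zero) at two decimals."""
    return math.floor(critical_r(n, alpha) * 100) / 100


@dataclass
class LoadingsReport:
    """Per-bucket correlation and back-scaled coefficient against t."""

    bucket_centers: np.ndarray
    coefficient: np.ndarray
    r: np.ndarray
    significant: np.ndarray
    zero_variance: np.ndarray
    n: int
    alpha: float
    r_crit: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bucket_ppm": self.bucket_centers,
            "coefficient": self.coefficient,
            "r": self.r,
            "significant": self.significant,
            "zero_variance": self.zero_variance,
        })


def correlation_loadings(
    model: OPLSDAModel,
    X,
    alpha: float = 0.05,
    bucket_centers: np.ndarray | None = None,
) -> LoadingsReport:
    """Correlate every bucket of the training table with the predictive score.

    ``X`` must be the table the model was fitted on. Zero-variance buckets
    have undefined correlation; they are reported as r = 0 with a flag.
    """
    if isinstance(X, BucketTable) and bucket_centers is None:
        bucket_centers = X.bucket_centers
    M = _as_matrix(X)
    t = model.t
    n = t.size
    if M.shape[0] != n:
        raise ValidationError("X rows do not match the model's score length")
    if bucket_centers is None:
        bucket_centers = np.arange(M.shape[1], dtype=float)

    Xc = M - M.mean(axis=0)
    tc = t - t.mean()
    cov = Xc.T @ tc / (n - 1)
    sd_x = M.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    zero_var = sd_x <= _ZERO_VAR_TOL
    r = np.zeros(M.shape[1])
    ok = ~zero_var
    r[ok] = cov[ok] / (sd_x[ok] * sd_t)
    coefficient = cov / sd_t  # back-scaled: keeps original intensity weighting
    r_crit = critical_r(n, alpha)
    return LoadingsReport(
        bucket_centers=np.asarray(bucket_centers, dtype=float),
        coefficient=coefficient,
        r=r,
        significant=np.abs(r) > r_crit,
        zero_variance=zero_var,
        n=n,
        alpha=alpha,
        r_crit=r_crit,
    )


# ---------------------------------------------------------------------------
# metabolite change table

NOT_EVALUABLE = "not_evaluable"


def load_region_map(path: str | Path | None = None) -> dict[str, list[tuple[float, float]]]:
    """Metabolite -> list of (low, high) ppm regions.

    With no path, the bundled map (38 resonance assignments of the thyroid
    tissue metabolite set) is loaded. The CSV has columns
    metabolite, low_ppm, high_ppm with one row per region.
    """
    if path is None:
        src = resources.files("thyromet").joinpath("data/metabolite_regions.csv")
        text = src.read_text().splitlines()
    else:
        text = Path(path).read_text().splitlines()
    regions: dict[str, list[tuple[float, float]]] = {}
    for row in csv.DictReader(text):
        regions.setdefault(row["metabolite"], []).append(
            (float(row["low_ppm"]), float(row["high_ppm"])))
    return regions


def build_change_table(
    report: LoadingsReport,
    region_map: dict[str, list[tuple[float, float]]] | None = None,
    comparison: str = "",
) -> pd.DataFrame:
    """Summarize the loadings report per metabolite region.

    For each metabolite, the strongest-|r| significant bucket in its regions
    gives the reported r and the direction (up/down). Metabolites whose
    buckets all fall below the cutoff are "ns"; metabolites with no bucket in
    the report at all (e.g. the region fell in the excluded water window)
    are flagged "not_evaluable" rather than ns.
    """
    if region_map is None:
        region_map = load_region_map()
    rows = []
    c = report.bucket_centers
    for name, regions in region_map.items():
        if not regions:
            raise ValidationError(f"empty region list for {name!r}")
        in_region = np.zeros(c.size, dtype=bool)
        for lo, hi in regions:
            if lo > hi:
                raise ValidationError(f"{name!r}: region low > high")
            in_region |= (c >= lo) & (c <= hi)
        if not in_region.any():
            rows.append({"metabolite": name, "comparison": comparison,
                         "r": np.nan, "direction": NOT_EVALUABLE})
            continue
        sig = in_region & report.significant
        if not sig.any():
            rows.append({"metabolite": name, "comparison": comparison,
                         "r": np.nan, "direction": "ns"})
            continue
        idx = np.nonzero(sig)[0]
        best = idx[np.argmax(np.abs(report.r[idx]))]
        rows.append({"metabolite": name, "comparison": comparison,
                     "r": float(report.r[best]),
                     "direction": "up" if report.r[best] > 0 else "down"})
    return pd.DataFrame(rows)


def format_change_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display form: r to two decimals, em-dash for non-significant rows."""
    out = table.copy()
    out["r"] = [("—" if d in ("ns",) else d if d == NOT_EVALUABLE
                 else f"{r:+.2f}") for r, d in zip(table["r"], table["direction"])]
    return out[["metabolite", "comparison", "r"]]


# ---------------------------------------------------------------------------
# univariate comparisons (GSH/GSSG-style tables)

def univariate_ttest(a, b, alpha: float = 0.05, welch: bool = False
                     ) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; Student's (pooled variance) by default.

    Returns (t, p, significant at alpha). Welch's correction is available
    behind a flag for unequal variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), bool(p < alpha)


def compare_groups_univariate(
    df: pd.DataFrame,
    value_columns: list[str],
    pairs: list[tuple[str, str]] = (("healthy", "benign"), ("healthy", "malignant"),
                                    ("benign", "malignant")),
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise group t-tests on tidy tables with a ``group`` column."""
    rows = []
    for col in value_columns:
        for g1, g2 in pairs:
            a = df.loc[df["group"] == g1, col].to_numpy()
            b = df.loc[df["group"] == g2, col].to_numpy()
            t, p, sig = univariate_ttest(a, b, alpha=alpha, welch=welch)
            rows.append({"feature": col, "comparison": f"{g2}-vs-{g1}",
                         "mean_1": a.mean(), "mean_2": b.mean(),
                         "t": t, "p": p, "significant": sig})
    return pd.DataFrame(rows)
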