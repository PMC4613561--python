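"""Fatty-acid composition analytics downstream of GC-FID/MS quantification.

Input is a calibrated concentration table (umol of fatty acid per gram of
tissue; internal-standard calibration happens upstream). The module parses
Cx:ynZ species names, rolls concentrations up into the standard classes
(SFA, MUFA, PUFA, UFA and the n3/n6 families), computes molar percentages,
estimates delta-6 desaturase (D6D) activity as the product/precursor ratio
C18:3n6 / C18:2n6, and runs the pairwise group comparisons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, SchemaError, ValidationError

_SPECIES_RE = re.compile(r"^C(\d{1,2}):(\d{1,2})(?:n(\d{1,2}))?$")

CLASS_FEATURES = ("SFA", "UFA", "MUFA", "PUFA", "n3", "n6")


def classify_species(name: str) -> tuple[str, str]:
    """Parse a Cx:y or Cx:ynZ name into (saturation class, n-family).

    0 double bonds -> SFA, 1 -> MUFA, >=2 -> PUFA; the family is "n3"/"n6"/
    "n9" from the suffix, or "none" when absent (saturated species).
    """
    m = _SPECIES_RE.match(name.strip())
    if not m:
        raise SchemaError(f"unparseable fatty-acid name {name!r} (expected Cx:y or Cx:ynZ)")
    chain, bonds, npos = int(m.group(1)), int(m.group(2)), m.group(3)
    if chain < 2:
        raise SchemaError(f"{name!r}: implausible chain length {chain}")
    if bonds == 0:
        if npos is not None:
            raise SchemaError(f"{name!r}: saturated species cannot carry an n-position")
        return "SFA", "none"
    family = f"n{int(npos)}" if npos is not None else "none"
    return ("MUFA" if bonds == 1 else "PUFA"), family


@dataclass
class FattyAcidTable:
    """Samples x species concentration matrix (umol per g tissue)."""

    sample_ids: list[str]
    groups: np.ndarray
    species: list[str]
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.sample_ids), len(self.species)):
            raise ValidationError("concentration matrix shape mismatch")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be >= 0")
        for sp in self.species:
            classify_species(sp)  # raises SchemaError on bad names

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.species)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "group", self.groups)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FattyAcidTable":
        df = pd.read_csv(path)
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            groups=df["group"].to_numpy(),
            species=list(df.columns[2:]),
            concentrations=df.iloc[:, 2:].to_numpy(dtype=float),
        )


@dataclass
class CompositionSummary:
    """Molar percentages, class roll-ups and desaturase indices per sample."""

    sample_ids: list[str]
    groups: np.ndarray
    mol_percent: pd.DataFrame  # samples x species, sums to 100 per row
    class_percent: pd.DataFrame  # samples x (SFA, UFA, MUFA, PUFA, n3, n6)
    indices: pd.DataFrame  # samples x (D6D,)

    def features(self) -> pd.DataFrame:
        """All per-sample features side by side with group labels."""
        df = pd.concat([self.mol_percent, self.class_percent, self.indices], axis=1)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "group", self.groups)
        return df

    def group_summary(self) -> dict:
        """Mean +/- sd of every feature per group (for reporting panels)."""
        df = self.features()
        out: dict = {}
        for g, sub in df.groupby("group"):
            vals = sub.drop(columns=["sample_id", "group"])
            out[str(g)] = {c: {"mean": float(vals[c].mean()), "sd": float(vals[c].std())}
                           for c in vals.columns}
        return out


def composition_summary(table: FattyAcidTable, d6d_product: str = "C18:3n6"
                        ) -> CompositionSummary:
    """Molar percentages and class roll-ups for each sample.

    mol%_j = 100 * c_j / sum(c); class percentages sum member species, so
    SFA% + UFA% = 100 and MUFA% + PUFA% = UFA%. The D6D index is the
    concentration ratio ``d6d_product`` / C18:2n6 — by default the immediate
    product C18:3n6; pass "C20:3n6" for the downstream-product variant. The
    index is NaN where the precursor concentration is 0 or the species are
    absent from the table.
    """
    totals = table.concentrations.sum(axis=1)
    if np.any(totals <= 0):
        raise NormalizationError("zero total fatty-acid concentration in some sample")
    molp = 100.0 * table.concentrations / totals[:, None]
    mol_percent = pd.DataFrame(molp, columns=table.species)

    sat = {sp: classify_species(sp) for sp in table.species}
    cls = pd.DataFrame(index=range(len(table.sample_ids)))
    for label in ("SFA", "MUFA", "PUFA"):
        members = [sp for sp in table.species if sat[sp][0] == label]
        cls[label] = mol_percent[members].sum(axis=1) if members else 0.0
    cls["UFA"] = cls["MUFA"] + cls["PUFA"]
    for fam in ("n3", "n6"):
        members = [sp for sp in table.species if sat[sp][1] == fam]
        cls[fam] = mol_percent[members].sum(axis=1) if members else 0.0
    cls = cls[list(CLASS_FEATURES)]

    n = len(table.sample_ids)
    d6d = np.full(n, np.nan)
    if d6d_product in table.species and "C18:2n6" in table.species:
        num = table.concentrations[:, table.species.index(d6d_product)]
        den = table.concentrations[:, table.species.index("C18:2n6")]
        ok = den > 0
        d6d[ok] = num[ok] / den[ok]
    indices = pd.DataFrame({"D6D": d6d})

    return CompositionSummary(
        sample_ids=list(table.sample_ids),
        groups=table.groups,
        mol_percent=mol_percent,
        class_percent=cls,
        indices=indices,
    )


def compare_groups(
    summary: CompositionSummary,
    pairs: list[tuple[str, str]] = (("healthy", "benign"), ("benign", "malignant")),
    alpha: float = 0.05,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pairwise Student's t-tests on every species and class feature.

    Flags are per-feature at ``alpha`` with no multiple-testing correction
    by default (matching per-feature p < 0.05 reporting); set ``fdr=True``
    for Benjamini-Hochberg-adjusted flags.
    """
    df = summary.features()
    present = set(np.unique(summary.groups).tolist())
    for g1, g2 in pairs:
        missing = {g1, g2} - present
        if missing:
            raise ValidationError(f"missing group(s) {sorted(missing)}")
    feats = [c for c in df.columns if c not in ("sample_id", "group")]
    rows = []
    for g1, g2 in pairs:
        for col in feats:
            if df[col].isna().all():
                continue  # undefined index (e.g. D6D without its species)
            a = df.loc[df["group"] == g1, col].dropna().to_numpy()
            b = df.loc[df["group"] == g2, col].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValidationError(f"fewer than 2 values per group for {col!r}")
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            rows.append({"feature": col, "comparison": f"{g2}-vs-{g1}",
                         "difference": float(b.mean() - a.mean()),
                         "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if fdr:
        out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
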