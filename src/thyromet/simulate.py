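"""Synthetic thyroid-tissue data with planted, recorded group effects.

The patient spectra behind the original three-group study (healthy adjacent
tissue, benign nodules, malignant papillary carcinomas) were never deposited,
so this module generates stand-ins with the statistical structure the
downstream analysis assumes:

* 1D spectra as sums of Lorentzian metabolite peaks (NMR lines are Lorentzian
  to first order) plus i.i.d. Gaussian point noise; metabolite levels are
  log-normal across samples (concentrations are positive and right-skewed)
  with group-specific medians set by the planted effects.
* intact-tissue mode adds broad lipid envelopes at delta 0.90/1.30/2.02/5.33
  (line width x20); extract mode omits them, mirroring the absence of lipid
  resonances in extract spectra.
* fatty-acid concentration tables (umol/g) with planted class/species shifts,
  and small GSH/GSSG tables.

Every generator is deterministic for a fixed ``SimulationConfig.seed`` and
returns ground truth (sample groups, planted directions and the ppm regions
they occupy) so recovery tests can score sign accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .preprocess import Spectrum

GROUPS = ("healthy", "benign", "malignant")
COMPARISONS = ("lesion-vs-healthy", "malignant-vs-benign")

DEFAULT_PEAK_WIDTH = 0.003  # ppm, Lorentzian half-width at half-maximum
LIPID_WIDTH_FACTOR = 20.0


@dataclass(frozen=True)
class MetabolitePeakTemplate:
    """A metabolite as a set of Lorentzian lines.

    ``peaks`` holds (center ppm, relative area, HWHM width ppm) triples;
    ``base_level`` is the healthy-group median level in arbitrary units.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    base_level: float = 1.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValidationError(f"{self.name}: at least one peak required")
        for c, a, w in self.peaks:
            if not (0.5 <= c <= 9.0):
                raise ValidationError(f"{self.name}: peak center {c} outside delta 0.5-9.0")
            if a < 0 or w <= 0:
                raise ValidationError(f"{self.name}: peak areas must be >=0 and widths >0")
        if self.base_level < 0:
            raise ValidationError(f"{self.name}: base_level must be >= 0")


@dataclass(frozen=True)
class GroupEffectSpec:
    """A planted fractional change of one metabolite for one comparison.

    ``magnitude`` is the signed fractional change of the median level
    (e.g. +0.5 means 50% higher); its sign must match ``direction``.
    """

    metabolite: str
    comparison: str
    direction: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISONS:
            raise ValidationError(f"unknown comparison {self.comparison!r}")
        if self.direction not in (-1, 0, 1):
            raise ValidationError("direction must be -1, 0 or +1")
        if (self.magnitude == 0) != (self.direction == 0):
            raise ValidationError("magnitude must be 0 iff direction is 0")
        if self.magnitude != 0 and int(np.sign(self.magnitude)) != self.direction:
            raise ValidationError("magnitude sign must match direction")
        if self.magnitude <= -1:
            raise ValidationError("magnitude must be > -1 (levels stay positive)")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the generator.

    Defaults mirror the clinical design: 46 healthy adjacent, 25 benign
    (22 nodular goiter + 3 follicular adenoma), 28 malignant papillary
    carcinoma samples; spectra over delta 0.5-9.0. ``resolution`` is points
    per ppm (1000 gives 4 points per 0.004 ppm bucket). ``level_sigma`` is
    the log-normal sd of biological variation (~20% CV). ``wet_weights``
    (extract mode) may be a scalar or per-sample mg values; if None they are
    drawn uniformly in 40-60 mg around the ~50 mg protocol amount.
    """

    group_sizes: tuple[int, int, int] = (46, 25, 28)
    noise_sd: float = 2.0
    seed: int = 0
    ppm_range: tuple[float, float] = (0.5, 9.0)
    resolution: int = 1000
    tissue_mode: str = "intact"
    level_sigma: float = 0.2
    wet_weights: float | tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValidationError("each of the three groups needs >= 2 samples")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.ppm_range[0] < self.ppm_range[1]:
            raise ValidationError("ppm_range low must be < high")
        if self.tissue_mode not in ("intact", "extract"):
            raise ValidationError(f"unknown tissue_mode {self.tissue_mode!r}")
        if self.resolution < 2:
            raise ValidationError("resolution must be >= 2 points per ppm")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))


@dataclass
class GroundTruth:
    """What was planted: per-sample groups and per-comparison effect regions."""

    sample_ids: list[str]
    groups: np.ndarray
    effects: list[GroupEffectSpec]
    regions: dict[str, list[tuple[float, float, int]]]  # comparison -> (lo, hi, direction)

    def planted_directions(self, bucket_centers: np.ndarray, comparison: str) -> np.ndarray:
        """Planted sign per bucket center (0 where nothing was planted)."""
        out = np.zeros(len(bucket_centers), dtype=int)
        for lo, hi, direction in self.regions.get(comparison, []):
            out[(bucket_centers >= lo) & (bucket_centers <= hi)] = direction
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "groups": list(map(str, self.groups)),
            "effects": [vars(e) for e in self.effects],
            "regions": {k: [list(r) for r in v] for k, v in self.regions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _w(width: float | None) -> float:
    return DEFAULT_PEAK_WIDTH if width is None else width


def _t(name: str, *peaks: tuple[float, float], base: float = 1.0,
       width: float = DEFAULT_PEAK_WIDTH) -> MetabolitePeakTemplate:
    return MetabolitePeakTemplate(name, tuple((c, a, width) for c, a in peaks), base)


def default_templates(tissue_mode: str = "intact") -> list[MetabolitePeakTemplate]:
    """Built-in metabolite library (chemical shifts from standard assignments).

    The broad lipid envelope is present only in intact-tissue mode.
    """
    lib = [
        _t("isoleucine", (0.94, 0.6), (1.01, 0.4), base=0.5),
        _t("leucine", (0.96, 1.0), base=0.6),
        _t("valine", (0.99, 0.5), (1.04, 0.5), base=0.5),
        _t("lactate", (1.33, 3.0), (4.11, 1.0), base=1.5),
        _t("alanine", (1.48, 3.0), base=1.0),
        _t("lysine", (1.72, 1.0), (3.03, 1.0), base=0.6),
        _t("arginine", (1.68, 1.0), (3.24, 1.0), base=0.5),
        _t("acetate", (1.92, 1.0), base=0.4),
        _t("glutamate", (2.08, 1.0), (2.34, 1.0), base=0.9),
        _t("glutamine", (2.14, 1.0), (2.45, 1.0), base=0.8),
        _t("methionine", (2.13, 0.5), (2.64, 0.5), base=0.3),
        _t("glutathione", (2.17, 0.5), (2.55, 0.7), (2.95, 0.7), base=0.7),
        _t("succinate", (2.41, 1.0), base=0.3),
        _t("citrate", (2.54, 1.0), (2.66, 1.0), base=0.8),
        _t("choline", (3.20, 9.0), base=0.3),
        _t("phosphocholine", (3.22, 9.0), base=0.5),
        _t("glycerophosphocholine", (3.23, 9.0), base=0.5),
        _t("taurine", (3.26, 1.0), (3.42, 1.0), base=1.0),
        _t("scyllo-inositol", (3.35, 1.0), base=0.4),
        _t("myo-inositol", (3.54, 2.0), (3.61, 1.0), (4.06, 1.0), base=1.2),
        _t("glycine", (3.56, 1.0), base=0.8),
        _t("phosphoethanolamine", (3.98, 1.0), base=0.4),
        _t("uridine", (5.90, 1.0), (7.87, 1.0), base=0.2),
        _t("inosine", (6.10, 1.0), (8.24, 0.5), (8.34, 0.5), base=0.3),
        _t("fumarate", (6.52, 1.0), base=0.15),
        _t("tyrosine", (6.90, 1.0), (7.19, 1.0), base=0.3),
        _t("phenylalanine", (7.33, 1.0), (7.42, 1.0), base=0.3),
        _t("formate", (8.46, 1.0), base=0.1),
    ]
    if tissue_mode == "intact":
        lw = DEFAULT_PEAK_WIDTH * LIPID_WIDTH_FACTOR
        lib.insert(0, MetabolitePeakTemplate(
            "lipid",
            ((0.90, 3.0, lw), (1.30, 8.0, lw), (2.02, 2.0, lw), (5.33, 1.0, lw)),
            base_level=5.0,
        ))
    return lib


DEFAULT_EFFECT_MAGNITUDE = 0.5

_LESION_UP = (
    "lactate", "alanine", "leucine", "isoleucine", "valine", "lysine",
    "arginine", "glutamate", "glutamine", "methionine", "choline",
    "phosphocholine", "glycerophosphocholine", "phosphoethanolamine",
    "glutathione", "taurine", "myo-inositol", "inosine", "fumarate",
    "glycine", "tyrosine", "phenylalanine",
)
_MALIGNANT_UP = (
    "phosphocholine", "glycerophosphocholine", "phosphoethanolamine",
    "lactate", "alanine", "leucine", "isoleucine", "valine",
)
_MALIGNANT_DOWN = ("citrate", "scyllo-inositol", "myo-inositol", "inosine", "uridine")


def default_effects(magnitude: float = DEFAULT_EFFECT_MAGNITUDE,
                    tissue_mode: str = "intact") -> list[GroupEffectSpec]:
    """Planted effect pattern following the reported sign structure:
    lesions raise lactate, amino acids, choline compounds, taurine, inositols,
    glutathione and fumarate and lower lipid; malignant-vs-benign raises the
    phospho-cholines, lactate and branched amino acids and lowers citrate,
    inositols and nucleosides."""
    eff = [GroupEffectSpec(m, "lesion-vs-healthy", 1, magnitude) for m in _LESION_UP]
    if tissue_mode == "intact":
        eff.append(GroupEffectSpec("lipid", "lesion-vs-healthy", -1, -magnitude / (1 + magnitude)))
    eff += [GroupEffectSpec(m, "malignant-vs-benign", 1, magnitude) for m in _MALIGNANT_UP]
    eff += [GroupEffectSpec(m, "malignant-vs-benign", -1, -magnitude / (1 + magnitude))
            for m in _MALIGNANT_DOWN]
    return eff


def _group_labels(config: SimulationConfig) -> np.ndarray:
    return np.repeat(GROUPS, config.group_sizes)


def _level_multipliers(
    templates: Sequence[MetabolitePeakTemplate],
    effects: Iterable[GroupEffectSpec],
) -> dict[str, dict[str, float]]:
    """Per-group median multiplier for each metabolite."""
    known = {t.name for t in templates}
    mult = {g: {t.name: 1.0 for t in templates} for g in GROUPS}
    for e in effects:
        if e.metabolite not in known:
            raise ConfigurationError(f"effect names unknown metabolite {e.metabolite!r}")
        f = 1.0 + e.magnitude
        if e.comparison == "lesion-vs-healthy":
            mult["benign"][e.metabolite] *= f
            mult["malignant"][e.metabolite] *= f
        else:  # malignant-vs-benign
            mult["malignant"][e.metabolite] *= f
    return mult


def _lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line."""
    return (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def generate_spectra(
    config: SimulationConfig,
    templates: Sequence[MetabolitePeakTemplate] | None = None,
    effects: Sequence[GroupEffectSpec] | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """Generate one spectrum per sample plus the planted ground truth.

    Each spectrum is sum_m level_im * sum_peaks area * Lorentzian(c, w)
    plus N(0, noise_sd) point noise, where level_im is log-normal around the
    group median. One RNG stream per sample is derived deterministically from
    ``config.seed`` so outputs are reproducible and order-independent.
    """
    if templates is None:
        templates = default_templates(config.tissue_mode)
    if effects is None:
        effects = default_effects(tissue_mode=config.tissue_mode)
    mult = _level_multipliers(templates, effects)

    lo, hi = config.ppm_range
    n_pts = int(round((hi - lo) * config.resolution)) + 1
    ppm = np.linspace(lo, hi, n_pts)
    groups = _group_labels(config)
    n = config.n_samples

    # pre-evaluate each template's line shape once (restricted to the range)
    shapes = {}
    for t in templates:
        s = np.zeros_like(ppm)
        for c, a, w in t.peaks:
            if lo - 10 * w <= c <= hi + 10 * w:
                s += a * _lorentzian(ppm, c, w)
        shapes[t.name] = s

    parent = np.random.SeedSequence(config.seed)
    sample_streams = parent.spawn(n + 1)
    meta_rng = np.random.default_rng(sample_streams[-1])

    if config.tissue_mode == "extract":
        if config.wet_weights is None:
            weights = meta_rng.uniform(40.0, 60.0, size=n)
        else:
            weights = np.broadcast_to(np.asarray(config.wet_weights, dtype=float), (n,)).copy()
            if np.any(weights <= 0):
                raise ValidationError("wet weights must be positive")
    else:
        weights = [None] * n

    spectra: list[Spectrum] = []
    sample_ids: list[str] = []
    for i, g in enumerate(groups):
        rng = np.random.default_rng(sample_streams[i])
        intensity = np.zeros_like(ppm)
        for t in templates:
            level = t.base_level * mult[g][t.name] * rng.lognormal(0.0, config.level_sigma)
            intensity += level * shapes[t.name]
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, size=n_pts)
        scale = 1.0 if weights[i] is None else weights[i] / 1000.0  # signal ~ grams of tissue
        sid = f"S{i:03d}"
        sample_ids.append(sid)
        spectra.append(Spectrum(
            sample_id=sid, group=g, ppm=ppm, intensity=intensity * scale,
            tissue_mode=config.tissue_mode,
            wet_weight=None if weights[i] is None else float(weights[i]),
        ))

    by_name = {t.name: t for t in templates}
    regions: dict[str, list[tuple[float, float, int]]] = {c: [] for c in COMPARISONS}
    for e in effects:
        if e.direction == 0:
            continue
        for c, _a, w in by_name[e.metabolite].peaks:
            regions[e.comparison].append((c - 1.5 * w, c + 1.5 * w, e.direction))
    truth = GroundTruth(sample_ids=sample_ids, groups=groups, effects=list(effects),
                        regions=regions)
    return spectra, truth


def spectra_to_tidy_csv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    frames = [pd.DataFrame({"sample_id": s.sample_id, "group": s.group,
                            "ppm": s.ppm, "intensity": s.intensity}) for s in spectra]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def spectra_to_wide_csv(spectra: Sequence[Spectrum], path: str | Path) -> None:
    ppm = spectra[0].ppm
    df = pd.DataFrame([s.intensity for s in spectra], columns=[f"{p:.6f}" for p in ppm])
    df.insert(0, "sample_id", [s.sample_id for s in spectra])
    df.insert(1, "group", [s.group for s in spectra])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fatty-acid tables

DEFAULT_FA_BASELINE: dict[str, float] = {
    # umol per g tissue, healthy-group medians (order-of-magnitude realistic
    # for soft tissue: palmitate/oleate dominant, long-chain PUFA minor)
    "C14:0": 1.5,
    "C16:0": 30.0,
    "C16:1n7": 2.5,
    "C18:0": 15.0,
    "C18:1n9": 25.0,
    "C18:2n6": 20.0,
    "C18:3n6": 0.3,
    "C18:3n3": 0.8,
    "C20:1n9": 0.5,
    "C20:3n6": 1.2,
    "C20:4n6": 8.0,
    "C20:5n3": 0.6,
    "C22:6n3": 3.0,
}

# planted shifts replicating the reported composition pattern: benign lesions
# lose MUFA (C14:0, C16:1n7, C18:1n9, C20:1n9, C18:3n3 down) and gain SFA and
# long-chain n6/n3 PUFA; malignant lesions additionally gain C14:0, C16:0 and
# C18:3n3 and lose C20:3n6 relative to benign.
DEFAULT_FA_SPECIES_EFFECTS: dict[str, dict[str, float]] = {
    "benign": {
        "C14:0": -0.30, "C16:1n7": -0.30, "C18:1n9": -0.25, "C20:1n9": -0.30,
        "C18:3n3": -0.30, "C16:0": 0.25, "C18:0": 0.25, "C20:3n6": 0.30,
        "C20:4n6": 0.25, "C22:6n3": 0.30, "C18:3n6": 0.30,
    },
    "malignant": {
        "C14:0": -0.05, "C16:1n7": -0.30, "C18:1n9": -0.25, "C20:1n9": -0.30,
        "C18:3n3": 0.05, "C16:0": 0.55, "C18:0": 0.25, "C20:3n6": -0.10,
        "C20:4n6": 0.25, "C22:6n3": 0.30, "C18:3n6": 0.45,
    },
}


def generate_fatty_acid_table(
    config: SimulationConfig,
    class_effects: Mapping[str, Mapping[str, float]] | None = None,
    species_effects: Mapping[str, Mapping[str, float]] | None = None,
    baseline: Mapping[str, float] | None = None,
    fa_sigma: float = 0.25,
):
    """Per-sample fatty-acid concentrations (umol/g) with planted shifts.

    ``species_effects[group][species]`` and ``class_effects[group][class]``
    give fractional shifts of the group median relative to the healthy
    baseline (class shifts apply to every member species; both compose
    multiplicatively). Values are log-normal around the shifted medians.
    Returns (FattyAcidTable, ground-truth dict of per-group multipliers).
    """
    from .fatty_acids import FattyAcidTable, classify_species

    if baseline is None:
        baseline = DEFAULT_FA_BASELINE
    if species_effects is None and class_effects is None:
        species_effects = DEFAULT_FA_SPECIES_EFFECTS
    species = list(baseline)
    classes = {sp: classify_species(sp) for sp in species}

    mult = {g: {sp: 1.0 for sp in species} for g in GROUPS}
    for source, keyer in (
        (class_effects, lambda sp: {classes[sp][0], classes[sp][1]}),
        (species_effects, lambda sp: {sp}),
    ):
        if source is None:
            continue
        for g, shifts in source.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            for key, frac in shifts.items():
                if frac <= -1:
                    raise ValidationError(f"shift {frac} for {key!r} makes the mean non-positive")
                for sp in species:
                    if key in keyer(sp):
                        mult[g][sp] *= 1.0 + frac

    groups = _group_labels(config)
    parent = np.random.SeedSequence((config.seed, 0xFA))
    rng = np.random.default_rng(parent)
    rows = np.empty((config.n_samples, len(species)))
    for i, g in enumerate(groups):
        med = np.array([baseline[sp] * mult[g][sp] for sp in species])
        rows[i] = med * rng.lognormal(0.0, fa_sigma, size=len(species))
    table = FattyAcidTable(
        sample_ids=[f"S{i:03d}" for i in range(config.n_samples)],
        groups=groups,
        species=species,
        concentrations=rows,
    )
    return table, mult


def generate_glutathione_table(
    config: SimulationConfig,
    gsh_lesion_shift: float = 0.6,
    gssg_lesion_shift: float = 0.0,
    baseline_gsh: float = 1.2,
    baseline_gssg: float = 0.15,
    sigma: float = 0.25,
) -> pd.DataFrame:
    """Small GSH/GSSG table (umol/g): by default GSH is elevated in both
    lesion groups relative to healthy tissue while GSSG does not differ."""
    if gsh_lesion_shift <= -1 or gssg_lesion_shift <= -1:
        raise ValidationError("shifts must be > -1")
    groups = _group_labels(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x65)))
    lesion = groups != "healthy"
    gsh = baseline_gsh * np.where(lesion, 1 + gsh_lesion_shift, 1.0)
    gssg = baseline_gssg * np.where(lesion, 1 + gssg_lesion_shift, 1.0)
    n = config.n_samples
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "group": groups,
        "GSH": gsh * rng.lognormal(0.0, sigma, n),
        "GSSG": gssg * rng.lognormal(0.0, sigma, n),
    })
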