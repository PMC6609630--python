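"""Population and variability scale factors for PBPK extrapolation.

Adult mean enzyme kinetics are converted into (a) variability bounds, by
multiplying Vmax with the ratio of a pooled-abundance confidence bound to
the pooled mean (``SF_CI``), and (b) special-population parameters, by
abundance and MPPGL ratios (``SF_DME``, ``SF_MPPGL``), a forward IVIVE with
the population liver, and a renal-clearance scaler built from unbound
fraction and glomerular filtration rate (``SF_fu_GFR``).  Every scale factor
acts multiplicatively, so SF = 1 is always the identity.

The model-evaluation acceptance interval around an observed clinical mean
reuses the geometric CI machinery at z = 4.26 (a 99.998% interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ivive import EnzymeKinetics, Physiology, _LPH_PER_ULMINMG
from .meta import geometric_ci

__all__ = [
    "Z_ACCEPTANCE",
    "ScaleFactorSet",
    "PopulationSpec",
    "sf_ci",
    "adjust_vmax",
    "sf_population",
    "scaled_cluint",
    "scale_clr",
    "acceptance_range",
    "load_population",
]

Z_ACCEPTANCE = 4.26  #: z for the 99.998% model-evaluation interval


@dataclass
class ScaleFactorSet:
    """Multiplicative adjustment factors with mandatory provenance.

    Provenance strings keep separately derived factor sets (e.g. alcoholic-
    versus HCV-cirrhosis) from ever being conflated.
    """

    provenance: str
    SF_CI: float = 1.0
    SF_DME: float = 1.0
    SF_MPPGL: float = 1.0
    SF_fu_GFR: float = 1.0

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("a ScaleFactorSet requires a provenance string")
        for name in ("SF_CI", "SF_DME", "SF_MPPGL", "SF_fu_GFR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PopulationSpec:
    """Demographics, physiology and enzyme abundances of one population.

    ``enzyme_abundance`` maps enzyme name to ``(mean, ci_low, ci_high)`` in
    pmol/mg; bounds may be None.  GFR carries an explicit unit tag so adult
    and population values are never combined across units.
    """

    label: str
    age_years: float | None = None
    weight_kg: float | None = None
    liver_weight_g: float | None = None
    MPPGL: float | None = None
    GFR: float | None = None
    GFR_unit: str = "mL/min"
    fu_p: float | None = None
    enzyme_abundance: dict[str, tuple[float, float | None, float | None]] = \
        field(default_factory=dict)

    def __post_init__(self) -> None:
        for enz, (mean, lo, hi) in self.enzyme_abundance.items():
            if lo is not None and lo > mean:
                raise ValueError(f"{self.label}/{enz}: ci_low > mean")
            if hi is not None and hi < mean:
                raise ValueError(f"{self.label}/{enz}: ci_high < mean")

    def abundance(self, enzyme: str, bound: str = "mean") -> float:
        if enzyme not in self.enzyme_abundance:
            raise KeyError(
                f"enzyme {enzyme!r} has no abundance in population "
                f"{self.label!r}"
            )
        mean, lo, hi = self.enzyme_abundance[enzyme]
        value = {"mean": mean, "low": lo, "high": hi}[bound]
        if value is None:
            raise ValueError(
                f"{self.label}/{enzyme}: {bound} abundance bound not "
                "available"
            )
        return value


def sf_ci(ci_bound: float, WM: float) -> float:
    """Inter-laboratory variability factor: a pooled confidence bound over
    the pooled weighted mean (lower bound gives SF < 1, upper SF > 1)."""
    if ci_bound <= 0 or WM <= 0:
        raise ValueError("sf_ci requires positive CI bound and weighted mean")
    return ci_bound / WM


def adjust_vmax(Vmax: float, sf: ScaleFactorSet, mode: str) -> float:
    """Apply a scale-factor set to an adult Vmax.

    ``mode="ci"`` multiplies by SF_CI only (variability bound);
    ``mode="population"`` multiplies by SF_DME * SF_MPPGL (age/disease).
    """
    if Vmax < 0:
        raise ValueError("Vmax must be non-negative")
    if mode == "ci":
        return Vmax * sf.SF_CI
    if mode == "population":
        return Vmax * sf.SF_DME * sf.SF_MPPGL
    raise ValueError(f"unknown adjustment mode {mode!r}")


def sf_population(pop: PopulationSpec, adult: PopulationSpec, enzyme: str,
                  bound: str = "mean") -> tuple[float, float]:
    """(SF_DME, SF_MPPGL): population-to-adult abundance and MPPGL ratios."""
    adult_mean = adult.abundance(enzyme, "mean")
    if adult_mean <= 0:
        raise ValueError(f"adult mean abundance of {enzyme} must be positive")
    sf_dme = pop.abundance(enzyme, bound) / adult_mean
    if pop.MPPGL is None or adult.MPPGL is None:
        raise ValueError(
            f"MPPGL must be set explicitly on both {pop.label!r} and "
            f"{adult.label!r}"
        )
    return sf_dme, pop.MPPGL / adult.MPPGL


def scaled_cluint(adjusted_Vmax: float, kin: EnzymeKinetics,
                  physiology: Physiology, fu_mic: float) -> float:
    """Forward IVIVE: adjusted Vmax back to whole-liver CLu_int (L/h).

    Exact inverse of the adult derivation chain when every scale factor is 1
    and the adult physiology is supplied.
    """
    if kin.Km_uM <= 0:
        raise ValueError(f"{kin.enzyme}: Km must be positive")
    per_mg = (adjusted_Vmax * kin.abundance_pmol_per_mg * kin.ISEF
              / (kin.Km_uM * fu_mic))
    return per_mg * physiology.MPPGL * physiology.liver_weight_g * _LPH_PER_ULMINMG


def scale_clr(CL_R_adult: float, pop: PopulationSpec, adult: PopulationSpec
              ) -> float:
    """Renal plasma clearance scaled by the fu*GFR ratio."""
    for spec in (pop, adult):
        if spec.fu_p is None or spec.GFR is None:
            raise ValueError(
                f"population {spec.label!r} must define fu_p and GFR "
                "explicitly"
            )
    if pop.GFR_unit != adult.GFR_unit:
        raise ValueError(
            f"GFR unit mismatch: {pop.label} in {pop.GFR_unit}, "
            f"{adult.label} in {adult.GFR_unit}"
        )
    denom = adult.fu_p * adult.GFR
    if denom <= 0:
        raise ValueError("adult fu_p * GFR must be positive")
    return (pop.fu_p * pop.GFR) / denom * CL_R_adult


def acceptance_range(observed_mean: float, cv_pct: float | None, k: int,
                     z: float = Z_ACCEPTANCE) -> tuple[float, float] | None:
    """Model-evaluation interval around an observed clinical mean.

    Returns None ("not applicable") when the observed %CV is unavailable;
    otherwise the geometric interval at z = 4.26 over the k subjects whose
    variability the %CV describes.
    """
    if observed_mean <= 0:
        raise ValueError("observed mean must be positive")
    if cv_pct is None or (isinstance(cv_pct, float) and math.isnan(cv_pct)):
        return None
    return geometric_ci(observed_mean, cv_pct, k, z)


def load_population(path: str | Path) -> PopulationSpec:
    """Read a population YAML file into a :class:`PopulationSpec`.

    Fields the source leaves null stay None; downstream operations that need
    them raise rather than default silently.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    abund = {}
    for enz, spec in (raw.get("enzyme_abundance") or {}).items():
        if spec is None:
            continue
        abund[enz] = (
            float(spec["mean"]),
            None if spec.get("ci_low") is None else float(spec["ci_low"]),
            None if spec.get("ci_high") is None else float(spec["ci_high"]),
        )
    opt = lambda key: None if raw.get(key) is None else float(raw[key])
    return PopulationSpec(
        label=raw.get("label", Path(path).stem),
        age_years=opt("age_years"),
        weight_kg=opt("weight_kg"),
        liver_weight_g=opt("liver_weight_g"),
        MPPGL=opt("MPPGL_mg_per_g"),
        GFR=opt("GFR"),
        GFR_unit=raw.get("GFR_unit", "mL/min"),
        fu_p=opt("fu_p"),
        enzyme_abundance=abund,
    )
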