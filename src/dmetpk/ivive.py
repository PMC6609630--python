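"""In vitro–in vivo extrapolation of hepatic clearance to enzyme kinetics.

Starting from clinical intravenous clearance, the chain is:

1. split systemic clearance into renal and hepatic shares,
   ``CL_R = f_CL_renal * CL_IV``, ``CL_H = (1 - f_CL_renal) * CL_IV``;
2. back-calculate unbound intrinsic hepatic clearance with the well-stirred
   liver model,
   ``CLu_int_H = Q_HB * CL_H / (fu_p * (Q_HB - CL_H / BP))``;
3. partition CLu_int_H across enzyme isoforms by their fraction metabolized,
   ``CLu_int_DMEj = f_m_j * CLu_int_H / f_CL_metabolism_H`` with
   ``f_CL_metabolism_H = 1 - f_CL_renal``;
4. convert the whole-liver value to a per-mg-microsomal-protein in vitro
   intrinsic clearance (MPPGL, liver weight, and the 60e-6 factor taking
   L/h to µL/min);
5. derive the maximum reaction velocity per pmol of enzyme,
   ``Vmax_j = in_vitro_CLint_j * Km_j * fu_mic / (abundance_j * ISEF_j)``.

Units: clearances in L/h, Km in µM, abundance in pmol/mg microsomal protein,
in vitro CL_int in µL/min/mg protein, Vmax in pmol/min/pmol enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "DrugParams",
    "Physiology",
    "EnzymeKinetics",
    "back_calc_cluint_h",
    "well_stirred_forward",
    "partition_cluint",
    "invitro_clint",
    "vmax_from_clint",
    "derive_enzyme_kinetics",
    "kinetics_table",
    "load_drug",
    "load_physiology",
    "load_enzyme_table",
    "data_path",
]

# L/h -> µL/min, then per-mg normalisation: 1 L/h = 1e6/60 µL/min, i.e. the
# divisor in the whole-liver <-> per-mg conversion is MPPGL * liver_weight *
# 60e-6.  This constant appears exactly once in the package.
_LPH_PER_ULMINMG = 60.0e-6


@dataclass
class DrugParams:
    """Drug-specific clearance and binding constants.

    ``f_m`` maps enzyme isoform name to its absolute fraction of total drug
    clearance.  A nested specification (a pathway total plus percentage
    splits) can be normalised with :meth:`from_nested_fm`.
    """

    name: str
    CL_IV: float                      # intravenous plasma clearance, L/h
    f_CL_renal: float                 # fraction cleared renally, unchanged
    fu_p: float                       # unbound fraction in plasma
    BP: float                         # blood:plasma concentration ratio
    fu_mic: float = 1.0               # unbound fraction in microsomes
    f_m: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.CL_IV <= 0:
            raise ValueError("CL_IV must be positive")
        if not 0.0 <= self.f_CL_renal <= 1.0:
            raise ValueError("f_CL_renal must lie in [0, 1]")
        if not 0.0 < self.fu_p <= 1.0:
            raise ValueError("fu_p must lie in (0, 1]")
        if not 0.0 < self.fu_mic <= 1.0:
            raise ValueError("fu_mic must lie in (0, 1]")
        if self.BP <= 0:
            raise ValueError("B:P must be positive")
        total = sum(self.f_m.values()) + self.f_CL_renal
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"f_m fractions plus f_CL_renal exceed 1 ({total:.4f})"
            )

    @property
    def CL_R(self) -> float:
        """Renal plasma clearance, L/h."""
        return self.f_CL_renal * self.CL_IV

    @property
    def CL_H(self) -> float:
        """Hepatic plasma clearance (the non-renal share of CL_IV), L/h."""
        return (1.0 - self.f_CL_renal) * self.CL_IV

    @property
    def f_CL_metabolism_H(self) -> float:
        return 1.0 - self.f_CL_renal

    @classmethod
    def from_nested_fm(cls, name: str, CL_IV: float, f_CL_renal: float,
                       fu_p: float, BP: float, pathway_fm: float,
                       splits: dict[str, float], fu_mic: float = 1.0,
                       extra_fm: dict[str, float] | None = None
                       ) -> "DrugParams":
        """Build from a pathway-level f_m plus within-pathway percentage
        splits (e.g. a glucuronidation total of 0.86 split 10%/90% across two
        isoforms)."""
        total_split = sum(splits.values())
        if abs(total_split - 1.0) > 1e-6 and abs(total_split - 100.0) > 1e-4:
            raise ValueError("splits must sum to 1 (fractions) or 100 (%)")
        scale = 1.0 if abs(total_split - 1.0) <= 1e-6 else 0.01
        f_m = {enz: pathway_fm * frac * scale for enz, frac in splits.items()}
        if extra_fm:
            f_m.update(extra_fm)
        return cls(name=name, CL_IV=CL_IV, f_CL_renal=f_CL_renal, fu_p=fu_p,
                   BP=BP, fu_mic=fu_mic, f_m=f_m)


@dataclass
class Physiology:
    """System-specific constants for one population."""

    label: str
    Q_HB: float             # hepatic blood flow, L/h
    MPPGL: float            # mg microsomal protein per g liver
    liver_weight_g: float

    def __post_init__(self) -> None:
        for name in ("Q_HB", "MPPGL", "liver_weight_g"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be positive")


@dataclass
class EnzymeKinetics:
    """Per-enzyme IVIVE inputs and derived outputs."""

    enzyme: str
    Km_uM: float
    abundance_pmol_per_mg: float
    ISEF: float = 1.0
    f_m: float | None = None
    CLu_int_DME_Lh: float | None = None
    in_vitro_CLint_uL_min_mg: float | None = None
    Vmax_pmol_min_pmol: float | None = None


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------

def back_calc_cluint_h(CL_H: float, physiology: Physiology, fu_p: float,
                       BP: float) -> float:
    """Unbound intrinsic hepatic clearance from the well-stirred model.

    Valid only while hepatic blood clearance stays below liver blood flow
    (``Q_HB > CL_H / BP``); beyond that the model has no solution.
    """
    if CL_H < 0:
        raise ValueError("CL_H must be non-negative")
    cl_blood = CL_H / BP
    if physiology.Q_HB <= cl_blood:
        raise ValueError(
            f"clearance exceeds hepatic flow: CL_H/BP = {cl_blood:.3g} L/h "
            f">= Q_HB = {physiology.Q_HB:.3g} L/h"
        )
    return physiology.Q_HB * CL_H / (fu_p * (physiology.Q_HB - cl_blood))


def well_stirred_forward(CLu_int_H: float, physiology: Physiology,
                         fu_p: float, BP: float) -> float:
    """Hepatic plasma clearance from CLu_int_H (algebraic inverse of
    :func:`back_calc_cluint_h`); approaches Q_HB·BP as CLu_int_H grows."""
    if CLu_int_H < 0:
        raise ValueError("CLu_int_H must be non-negative")
    return (physiology.Q_HB * fu_p * CLu_int_H
            / (physiology.Q_HB + fu_p * CLu_int_H / BP))


def partition_cluint(CLu_int_H: float, drug: DrugParams) -> dict[str, float]:
    """Per-isoform share of intrinsic clearance,
    ``f_m_j * CLu_int_H / f_CL_metabolism_H``."""
    if drug.f_CL_metabolism_H <= 0:
        raise ValueError(
            f"{drug.name}: no hepatic pathway (f_CL_renal = 1)"
        )
    return {enz: fm * CLu_int_H / drug.f_CL_metabolism_H
            for enz, fm in drug.f_m.items()}


def invitro_clint(CLu_int_DME: float, physiology: Physiology) -> float:
    """Whole-liver L/h to µL/min per mg microsomal protein."""
    return CLu_int_DME / (physiology.MPPGL * physiology.liver_weight_g
                          * _LPH_PER_ULMINMG)


def vmax_from_clint(clint: float, kin: EnzymeKinetics, fu_mic: float) -> float:
    """Maximum velocity per pmol enzyme from in vitro intrinsic clearance.

    ``clint * Km`` has units (µL/min/mg)·(pmol/µL) = pmol/min/mg, which the
    abundance (pmol/mg) and ISEF normalise to pmol/min/pmol.
    """
    if kin.abundance_pmol_per_mg <= 0:
        raise ValueError(f"{kin.enzyme}: abundance must be positive")
    if kin.ISEF <= 0:
        raise ValueError(f"{kin.enzyme}: ISEF must be positive")
    return clint * kin.Km_uM * fu_mic / (kin.abundance_pmol_per_mg * kin.ISEF)


def derive_enzyme_kinetics(drug: DrugParams, physiology: Physiology,
                           kinetics: list[EnzymeKinetics],
                           CL_H: float | None = None
                           ) -> tuple[float, list[EnzymeKinetics]]:
    """Run the full chain for every enzyme with kinetic data.

    Returns ``(CLu_int_H, kinetics)`` with the derived fields filled in.
    Enzymes present in ``drug.f_m`` but absent from ``kinetics`` (e.g. a
    lumped minor pathway) keep their clearance share but get no Vmax.
    A user-supplied ``CL_H`` overrides the value derived from CL_IV.
    """
    cl_h = drug.CL_H if CL_H is None else CL_H
    cluint_h = back_calc_cluint_h(cl_h, physiology, drug.fu_p, drug.BP)
    shares = partition_cluint(cluint_h, drug)
    for kin in kinetics:
        if kin.enzyme not in shares:
            raise ValueError(
                f"{kin.enzyme}: no f_m declared for this enzyme in "
                f"{drug.name}"
            )
        kin.f_m = drug.f_m[kin.enzyme]
        kin.CLu_int_DME_Lh = shares[kin.enzyme]
        kin.in_vitro_CLint_uL_min_mg = invitro_clint(
            kin.CLu_int_DME_Lh, physiology)
        kin.Vmax_pmol_min_pmol = vmax_from_clint(
            kin.in_vitro_CLint_uL_min_mg, kin, drug.fu_mic)
    return cluint_h, kinetics


def kinetics_table(kinetics: list[EnzymeKinetics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "enzyme": k.enzyme, "f_m": k.f_m, "Km_uM": k.Km_uM,
        "abundance_pmol_per_mg": k.abundance_pmol_per_mg, "ISEF": k.ISEF,
        "CLu_int_DME_L_per_h": k.CLu_int_DME_Lh,
        "in_vitro_CLint_uL_min_mg": k.in_vitro_CLint_uL_min_mg,
        "Vmax_pmol_min_pmol": k.Vmax_pmol_min_pmol,
    } for k in kinetics])


# ---------------------------------------------------------------------------
# asset loading
# ---------------------------------------------------------------------------

def data_path(name: str) -> Path:
    """Path to a packaged data asset (drug/physiology/population files)."""
    return Path(__file__).parent / "data" / name


def load_drug(path: str | Path) -> DrugParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DrugParams(
        name=raw.get("name", Path(path).stem),
        CL_IV=float(raw["CL_IV_L_per_h"]),
        f_CL_renal=float(raw["f_CL_renal"]),
        fu_p=float(raw["fu_p"]),
        BP=float(raw["BP"]),
        fu_mic=float(raw.get("fu_mic", 1.0)),
        f_m={k: float(v) for k, v in (raw.get("f_m") or {}).items()},
    )


def load_physiology(path: str | Path) -> Physiology:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("Q_HB_L_per_h", "MPPGL_mg_per_g", "liver_weight_g"):
        if raw.get(key) is None:
            raise ValueError(f"{path}: required physiology field {key!r} "
                             "is missing")
    return Physiology(
        label=raw.get("label", Path(path).stem),
        Q_HB=float(raw["Q_HB_L_per_h"]),
        MPPGL=float(raw["MPPGL_mg_per_g"]),
        liver_weight_g=float(raw["liver_weight_g"]),
    )


def load_enzyme_table(path: str | Path) -> list[EnzymeKinetics]:
    """Read an enzyme kinetics CSV (enzyme, Km_uM, abundance, ISEF)."""
    df = pd.read_csv(path, comment="#")
    required = {"enzyme", "Km_uM", "abundance_pmol_per_mg"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: enzyme table must have columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(EnzymeKinetics(
            enzyme=str(row["enzyme"]),
            Km_uM=float(row["Km_uM"]),
            abundance_pmol_per_mg=float(row["abundance_pmol_per_mg"]),
            ISEF=float(row.get("ISEF", 1.0)) if "ISEF" in df.columns else 1.0,
        ))
    return out
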