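"""Core data model for literature-reported DMET protein abundance observations.

A :class:`ProteinAbundanceRecord` is one literature observation of one protein
in one tissue, together with its provenance (citation key, year), analytical
metadata (matrix, method, quantification mode, unit) and donor demographics.
Records that survive the meta-analysis inclusion filter are condensed into
:class:`StudyObservation` / :class:`StudySet`, the per-protein inputs consumed
by the meta-analysis engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TISSUES",
    "MATRICES",
    "METHODS",
    "STAT_KINDS",
    "QUANT_MODES",
    "CANONICAL_UNIT",
    "UNIT_SCALE_TO_CANONICAL",
    "ProteinAbundanceRecord",
    "StudyObservation",
    "StudySet",
]

TISSUES = ("liver", "intestine", "kidney", "brain", "lung", "other")
MATRICES = ("microsomes", "homogenate", "S9", "membrane", "other")
METHODS = (
    "LC-MS/MS",
    "Western blot",
    "ELISA",
    "LC-MS global",
    "mRNA",
    "activity",
    "other",
)
STAT_KINDS = ("mean", "median")
QUANT_MODES = ("absolute", "relative")

CANONICAL_UNIT = "pmol/mg microsomal protein"

# Trivially rescalable spellings of the canonical per-mg-microsomal-protein
# unit, mapped to the multiplicative factor that converts a value expressed
# in them into pmol/mg.  Anything not listed here is non-standard and fails
# the unit inclusion criterion; no heuristic conversion is ever attempted.
UNIT_SCALE_TO_CANONICAL = {
    "pmol/mg microsomal protein": 1.0,
    "pmol/mg protein": 1.0,
    "pmol/mg": 1.0,
    "fmol/ug protein": 1.0,
    "fmol/ug": 1.0,
    "fmol/µg protein": 1.0,
    "fmol/µg": 1.0,
    "pmol/ug": 1000.0,
    "pmol/µg": 1000.0,
    "fmol/mg": 1e-3,
}

#: absolute tolerance (percentage points) for agreement between a reported
#: %CV and 100*SD/mean — literature values are rounded, so exact equality
#: cannot be demanded.
CV_CONSISTENCY_TOL_PCT = 0.5


@dataclass
class ProteinAbundanceRecord:
    """One published abundance observation with provenance and demographics.

    ``value`` is the reported mean (or median, per ``stat_kind``) abundance in
    the verbatim ``unit``; ``value_sd``, ``value_range`` and ``value_cv_pct``
    are kept exactly as reported and may each be missing independently.
    """

    protein_name: str
    gene_name: str = ""
    uniprot_id: str | None = None
    tissue: str = "liver"
    matrix: str = "microsomes"
    stat_kind: str = "mean"
    value: float = 0.0
    value_sd: float | None = None
    value_range: tuple[float, float] | None = None
    value_cv_pct: float | None = None
    unit: str = CANONICAL_UNIT
    n_donors: int = 1
    pooled: bool = False
    method: str = "LC-MS/MS"
    quant_mode: str = "absolute"
    demographics: dict[str, str] = field(default_factory=dict)
    source: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(
                f"{self.protein_name}: abundance value must be >= 0, got {self.value}"
            )
        if self.value_sd is not None and self.value_sd < 0:
            raise ValueError(f"{self.protein_name}: SD must be >= 0")
        if self.n_donors < 1:
            raise ValueError(f"{self.protein_name}: n_donors must be >= 1")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.stat_kind not in STAT_KINDS:
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")
        if self.quant_mode not in QUANT_MODES:
            raise ValueError(f"unknown quant_mode {self.quant_mode!r}")
        if (
            self.value_cv_pct is not None
            and self.value_sd is not None
            and self.value > 0
        ):
            implied = 100.0 * self.value_sd / self.value
            if abs(self.value_cv_pct - implied) > CV_CONSISTENCY_TOL_PCT:
                raise ValueError(
                    f"{self.protein_name} ({self.source}): reported %CV "
                    f"{self.value_cv_pct:g} inconsistent with 100*SD/mean = "
                    f"{implied:.3f}"
                )

    @property
    def canonical_unit(self) -> bool:
        """True if the verbatim unit is the canonical per-mg unit or a
        power-of-ten rescaling of it.  Derived flag; ``unit`` is never
        rewritten."""
        return self.unit in UNIT_SCALE_TO_CANONICAL

    def value_in_canonical_unit(self) -> float:
        """Abundance converted to pmol/mg microsomal protein."""
        try:
            scale = UNIT_SCALE_TO_CANONICAL[self.unit]
        except KeyError:
            raise ValueError(
                f"unit {self.unit!r} is non-standard and cannot be converted"
            ) from None
        return self.value * scale

    def sd_in_canonical_unit(self) -> float | None:
        if self.value_sd is None:
            return None
        return self.value_sd * UNIT_SCALE_TO_CANONICAL[self.unit]

    @property
    def label(self) -> str:
        """Forest-plot style study label, ``"FirstAuthor, year"``."""
        if self.year is not None:
            return f"{self.source}, {self.year}"
        return self.source


@dataclass
class StudyObservation:
    """Per-study summary (mean, SD, n, CV) entering the meta-analysis.

    ``cv`` is a fraction (SD/mean), not a percentage.  ``from_median`` flags
    observations whose central value was reported as a median; they are
    pooled identically but the provenance is preserved.
    """

    label: str
    mean: float
    sd: float | None
    n: int
    cv: float | None = None
    source: str = ""
    from_median: bool = False

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"{self.label}: study mean must be > 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"{self.label}: SD must be >= 0")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")
        if self.cv is None and self.sd is not None:
            self.cv = self.sd / self.mean
        if self.cv is not None and self.sd is not None and self.cv > 0:
            implied = self.sd / self.mean
            if implied > 0 and abs(self.cv - implied) / implied > 0.005:
                raise ValueError(
                    f"{self.label}: CV {self.cv:g} inconsistent with SD/mean "
                    f"= {implied:.5f}"
                )


@dataclass
class StudySet:
    """All eligible study observations for one protein in one tissue."""

    protein: str
    tissue: str
    observations: list[StudyObservation]

    @property
    def k(self) -> int:
        """Number of studies."""
        return len(self.observations)

    @property
    def n_total(self) -> int:
        """Total number of donors across studies."""
        return sum(o.n for o in self.observations)

    @property
    def df(self) -> int:
        return self.k - 1

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"{self.protein}: a StudySet needs >= 1 study")
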