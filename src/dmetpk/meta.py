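"""Meta-analysis of study-level protein abundance data.

Two complementary poolings are performed on each study set:

* **Heterogeneity assessment** (inverse-variance weighting).  The
  fixed-effect summary is

  .. math:: \\mu_F = \\sum_j w_j X_j / \\sum_j w_j, \\qquad w_j = 1/SD_j^2,

  with Cochran's heterogeneity statistic
  :math:`Q_F = \\sum_j w_j (X_j - \\mu_F)^2`.  The random-effects model uses
  the method-of-moments (DerSimonian–Laird) between-study variance

  .. math:: \\hat\\tau^2 = \\frac{Q_F - df}{\\sum w_j - \\sum w_j^2/\\sum w_j}
            \\quad (Q_F > df;\\ \\hat\\tau^2 = 0 \\text{ otherwise}),

  re-weighting each study by :math:`w_j^* = 1/(w_j^{-1} + \\hat\\tau^2)`.
  Heterogeneity is summarized by :math:`H^2 = Q/df`,
  :math:`I^2 = \\max(0, (H^2-1)/H^2)\\cdot 100` and the upper-tail
  :math:`\\chi^2` probability of :math:`Q` at :math:`df` degrees of freedom.

* **Abundance pooling** (sample-size weighting).  The weighted mean is
  :math:`WM = \\sum_j n_j X_j / N` and the overall %CV is computed by three
  alternative estimators (methods I–III, see the individual functions),
  from which geometric confidence intervals
  :math:`\\exp[\\ln WM \\pm z\\,\\sigma/\\sqrt{k}]` with
  :math:`\\sigma = \\sqrt{\\ln[(\\%CV/100)^2 + 1]}` are derived.

Note the weights in the heterogeneity stage are the inverse of the *study
variance* :math:`SD_j^2` (between-donor spread), not of the squared standard
error — heterogeneity is judged against the biological spread reported by
each laboratory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import StudySet

__all__ = [
    "FixedEffectResult",
    "RandomEffectResult",
    "HeterogeneityIndices",
    "PooledEstimate",
    "ForestRow",
    "MetaResult",
    "InsufficientDataError",
    "fixed_effect",
    "random_effect",
    "heterogeneity_indices",
    "weighted_mean",
    "cv_method_I",
    "cv_method_II",
    "cv_method_III",
    "geometric_ci",
    "run_meta",
    "heterogeneity_table",
    "pooled_table",
    "forest_table",
]

Z_95 = 1.96  #: default z for 95% geometric confidence intervals


class InsufficientDataError(ValueError):
    """Raised when a study set lacks the fields an estimator requires."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class FixedEffectResult:
    mu_F: float
    weights: list[float]
    Q_F: float
    df: int
    k_used: int
    labels: list[str] = field(default_factory=list)


@dataclass
class RandomEffectResult:
    mu_R: float
    weights_star: list[float]
    tau2: float
    Q_R: float


@dataclass
class HeterogeneityIndices:
    H2: float
    I2_pct: float
    P_value: float
    het_class: str       # none | low | medium | high
    H2_concern: str      # considerable | intermediate | little


@dataclass
class PooledEstimate:
    WM: float
    k: int
    N: int
    z: float = Z_95
    variance_nu: float | None = None
    overall_SS: float | None = None
    cv_pct: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)


@dataclass
class ForestRow:
    label: str
    mean: float
    ci_low: float
    ci_high: float
    row_kind: str  # "study" | "method_summary"


@dataclass
class MetaResult:
    """Complete per-protein report: both pooling stages plus forest rows."""

    protein: str
    tissue: str
    k: int
    N: int
    fixed: FixedEffectResult | None
    random: RandomEffectResult | None
    het_fe: HeterogeneityIndices | None
    het_re: HeterogeneityIndices | None
    pooled: PooledEstimate
    forest_rows: list[ForestRow]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {
            "protein": self.protein,
            "tissue": self.tissue,
            "k": self.k,
            "N": self.N,
            "notes": self.notes,
        }
        if self.fixed is not None:
            d["fixed_effect"] = {
                "mu_F": self.fixed.mu_F, "Q_F": self.fixed.Q_F,
                "df": self.fixed.df, "k_used": self.fixed.k_used,
            }
        if self.random is not None:
            d["random_effect"] = {
                "mu_R": self.random.mu_R, "tau2": self.random.tau2,
                "Q_R": self.random.Q_R,
            }
        for key, het in (("heterogeneity_FE", self.het_fe),
                         ("heterogeneity_RE", self.het_re)):
            if het is not None:
                d[key] = {
                    "H2": het.H2, "I2_pct": het.I2_pct,
                    "P_value": het.P_value, "class": het.het_class,
                    "H2_concern": het.H2_concern,
                }
        d["pooled"] = {
            "WM": self.pooled.WM, "z": self.pooled.z,
            "cv_pct": self.pooled.cv_pct,
            "ci_low": self.pooled.ci_low, "ci_high": self.pooled.ci_high,
        }
        return d


# ---------------------------------------------------------------------------
# heterogeneity stage (inverse-variance weighting)
# ---------------------------------------------------------------------------

def _usable_for_variance(studies: StudySet):
    return [o for o in studies.observations if o.sd is not None and o.sd > 0]


def fixed_effect(studies: StudySet) -> FixedEffectResult:
    """Inverse-variance-weighted summary and Cochran's Q.

    Studies with missing or zero SD carry no inverse-variance weight and are
    excluded here (their count is visible via ``k_used`` versus ``k``).
    """
    usable = _usable_for_variance(studies)
    if not usable:
        raise InsufficientDataError(
            f"{studies.protein}: insufficient variance data — no study "
            "reports a positive SD"
        )
    w = np.array([1.0 / o.sd**2 for o in usable])
    x = np.array([o.mean for o in usable])
    mu_F = float(np.sum(w * x) / np.sum(w))
    Q_F = float(np.sum(w * (x - mu_F) ** 2))
    return FixedEffectResult(
        mu_F=mu_F, weights=w.tolist(), Q_F=Q_F, df=len(usable) - 1,
        k_used=len(usable), labels=[o.label for o in usable],
    )


def random_effect(studies: StudySet, fe: FixedEffectResult) -> RandomEffectResult:
    """Method-of-moments random-effects summary on the same study subset.

    When :math:`Q_F \\le df` the between-study variance estimate is zero and
    the random-effects model collapses onto the fixed-effect one
    (``mu_R == mu_F``, ``Q_R == Q_F``).
    """
    if fe.k_used < 2:
        raise InsufficientDataError(
            f"{studies.protein}: insufficient studies for a random-effects "
            f"model (k_used={fe.k_used})"
        )
    w = np.asarray(fe.weights)
    usable = _usable_for_variance(studies)
    x = np.array([o.mean for o in usable])
    if fe.Q_F <= fe.df:
        tau2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        if denom <= 0:
            raise InsufficientDataError(
                f"{studies.protein}: degenerate weight structure"
            )
        tau2 = (fe.Q_F - fe.df) / denom
    w_star = 1.0 / (1.0 / w + tau2)
    mu_R = float(np.sum(w_star * x) / np.sum(w_star))
    Q_R = float(np.sum(w_star * (x - mu_R) ** 2))
    return RandomEffectResult(
        mu_R=mu_R, weights_star=w_star.tolist(), tau2=tau2, Q_R=Q_R
    )


def heterogeneity_indices(Q: float, df: int) -> HeterogeneityIndices:
    """H², I² (floored at zero) and the χ² upper-tail P-value of Q.

    Classification follows the conventional anchors 0% / ~25% / ~50% / ~75%
    for none/low/medium/high (midpoint boundaries at 37.5 and 62.5; I² of
    exactly zero is "none"), and flags H² > 1.5 as considerable concern,
    H² < 1.2 as little.
    """
    if df < 1:
        raise InsufficientDataError(
            "heterogeneity indices are undefined for a single study (df=0)"
        )
    if Q < 0:
        raise ValueError("Q must be non-negative")
    H2 = Q / df
    I2 = max(0.0, (H2 - 1.0) / H2 * 100.0) if H2 > 0 else 0.0
    P = float(stats.chi2.sf(Q, df))
    if I2 <= 0.0:
        het_class = "none"
    elif I2 < 37.5:
        het_class = "low"
    elif I2 < 62.5:
        het_class = "medium"
    else:
        het_class = "high"
    if H2 > 1.5:
        concern = "considerable"
    elif H2 < 1.2:
        concern = "little"
    else:
        concern = "intermediate"
    return HeterogeneityIndices(
        H2=H2, I2_pct=I2, P_value=P, het_class=het_class, H2_concern=concern
    )


# ---------------------------------------------------------------------------
# pooling stage (sample-size weighting)
# ---------------------------------------------------------------------------

def weighted_mean(studies: StudySet) -> float:
    """Sample-size-weighted mean abundance, using every study (SD not
    required)."""
    n = np.array([o.n for o in studies.observations], dtype=float)
    x = np.array([o.mean for o in studies.observations])
    return float(np.sum(n * x) / np.sum(n))


def cv_method_I(studies: StudySet, WM: float) -> float:
    """Overall %CV from the between-study spread of means only.

    The pooled variance is :math:`\\nu = \\sum_j n_j (X_j - WM)^2 / N`; the
    within-study SDs do not enter.  Returns :math:`100\\sqrt{\\nu}/WM`.
    """
    if WM <= 0:
        raise InsufficientDataError("method I %CV undefined for WM <= 0")
    n = np.array([o.n for o in studies.observations], dtype=float)
    x = np.array([o.mean for o in studies.observations])
    nu = float(np.sum(n * (x - WM) ** 2) / np.sum(n))
    return 100.0 * math.sqrt(nu) / WM


def cv_method_II(studies: StudySet, WM: float) -> float:
    """Overall %CV from the pooled individual-level sum of squares.

    Treats each study as :math:`n_j` individuals with the stated mean and SD:
    overall sum of squares
    :math:`\\sum_j [(SD_j^2 + X_j^2) n_j] - N\\,WM^2`, i.e. within-study plus
    between-study variability.  Always at least the method-I value.
    """
    if WM <= 0:
        raise InsufficientDataError("method II %CV undefined for WM <= 0")
    missing = [o.label for o in studies.observations if o.sd is None]
    if missing:
        raise InsufficientDataError(
            f"method II requires SD for every study; missing for: "
            f"{', '.join(missing)}"
        )
    n = np.array([o.n for o in studies.observations], dtype=float)
    x = np.array([o.mean for o in studies.observations])
    sd = np.array([o.sd for o in studies.observations])
    N = float(np.sum(n))
    ss = float(np.sum((sd**2 + x**2) * n) - N * WM**2)
    # rounding in study summaries can push ss epsilon-negative when all
    # means coincide and SDs are zero
    ss = max(ss, 0.0)
    return 100.0 * math.sqrt(ss / N) / WM


def cv_method_III(studies: StudySet) -> float:
    """Sample-size-weighted mean of the study-level CVs, in percent."""
    cvs = []
    for o in studies.observations:
        if o.cv is not None:
            cvs.append(o.cv)
        elif o.sd is not None:
            cvs.append(o.sd / o.mean)
        else:
            raise InsufficientDataError(
                f"method III requires CV or SD for study {o.label}"
            )
    n = np.array([o.n for o in studies.observations], dtype=float)
    return float(np.sum(n * np.asarray(cvs)) / np.sum(n)) * 100.0


def geometric_ci(WM: float, cv_pct: float, k: int, z: float = Z_95
                 ) -> tuple[float, float]:
    """Geometric confidence interval around the weighted mean.

    Assumes lognormally distributed abundances: the log-scale SD is
    :math:`\\sigma = \\sqrt{\\ln[(\\%CV/100)^2 + 1]}` and the bounds are
    :math:`\\exp[\\ln WM \\pm z\\sigma/\\sqrt{k}]`.
    """
    if WM <= 0:
        raise InsufficientDataError("geometric CI undefined for WM <= 0")
    if k < 1:
        raise InsufficientDataError("geometric CI requires k >= 1")
    if cv_pct < 0:
        raise ValueError("cv_pct must be non-negative")
    sigma = math.sqrt(math.log((cv_pct / 100.0) ** 2 + 1.0))
    half = z * sigma / math.sqrt(k)
    return (WM * math.exp(-half), WM * math.exp(half))


def log_sigma(cv_pct: float) -> float:
    """Log-scale SD implied by a %CV under lognormality."""
    return math.sqrt(math.log((cv_pct / 100.0) ** 2 + 1.0))


# ---------------------------------------------------------------------------
# composite report
# ---------------------------------------------------------------------------

def run_meta(studies: StudySet, z: float = Z_95) -> MetaResult:
    """Full meta-analysis of one study set: both pooling stages plus forest
    rows.

    Components that cannot be computed from the available fields (e.g. the
    heterogeneity stage when no study reports an SD, or method II when some
    SDs are missing) are left ``None``/absent and the reason recorded in
    ``notes`` — a partial report is preferred over a hard failure.
    Per-study forest intervals are presentational only
    (mean ± z·SD/√n on the arithmetic scale) and never feed any pooling.
    """
    if studies.k < 2:
        raise InsufficientDataError(
            f"{studies.protein}: meta-analysis requires k >= 2 studies"
        )
    notes: list[str] = []
    fe = re = het_fe = het_re = None
    try:
        fe = fixed_effect(studies)
        if fe.k_used < studies.k:
            notes.append(
                f"{studies.k - fe.k_used} study(ies) without positive SD "
                "excluded from the heterogeneity stage"
            )
        re = random_effect(studies, fe)
        het_fe = heterogeneity_indices(fe.Q_F, fe.df)
        het_re = heterogeneity_indices(re.Q_R, fe.df)
    except InsufficientDataError as exc:
        notes.append(str(exc))

    WM = weighted_mean(studies)
    pooled = PooledEstimate(WM=WM, k=studies.k, N=studies.n_total, z=z)
    n = np.array([o.n for o in studies.observations], dtype=float)
    x = np.array([o.mean for o in studies.observations])
    pooled.variance_nu = float(np.sum(n * (x - WM) ** 2) / np.sum(n))
    for name, fn in (("I", lambda: cv_method_I(studies, WM)),
                     ("II", lambda: cv_method_II(studies, WM)),
                     ("III", lambda: cv_method_III(studies))):
        try:
            cv = fn()
        except InsufficientDataError as exc:
            notes.append(f"method {name}: {exc}")
            continue
        pooled.cv_pct[name] = cv
        pooled.sigma[name] = log_sigma(cv)
        lo, hi = geometric_ci(WM, cv, studies.k, z)
        pooled.ci_low[name], pooled.ci_high[name] = lo, hi
    if "II" in pooled.cv_pct:
        sd = np.array([o.sd for o in studies.observations])
        pooled.overall_SS = float(
            np.sum((sd**2 + x**2) * n) - np.sum(n) * WM**2
        )

    rows = []
    for o in studies.observations:
        half = z * (o.sd or 0.0) / math.sqrt(o.n)
        rows.append(ForestRow(
            label=o.label, mean=o.mean,
            ci_low=o.mean - half, ci_high=o.mean + half, row_kind="study",
        ))
    for name in pooled.cv_pct:
        rows.append(ForestRow(
            label=f"Method {name}", mean=WM,
            ci_low=pooled.ci_low[name], ci_high=pooled.ci_high[name],
            row_kind="method_summary",
        ))
    return MetaResult(
        protein=studies.protein, tissue=studies.tissue,
        k=studies.k, N=studies.n_total,
        fixed=fe, random=re, het_fe=het_fe, het_re=het_re,
        pooled=pooled, forest_rows=rows, notes=notes,
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def heterogeneity_table(results: list[MetaResult]) -> pd.DataFrame:
    """Flat heterogeneity summary, one row per protein (FE and RE columns)."""
    rows = []
    for r in results:
        row: dict = {"enzyme": r.protein, "tissue": r.tissue,
                     "k": r.k, "k_used": r.fixed.k_used if r.fixed else 0,
                     "df": r.fixed.df if r.fixed else None}
        if r.fixed and r.het_fe:
            row.update(Q_F=r.fixed.Q_F, H2_FE=r.het_fe.H2,
                       I2_FE_pct=r.het_fe.I2_pct, P_FE=r.het_fe.P_value,
                       class_FE=r.het_fe.het_class)
        if r.random and r.het_re:
            row.update(tau2=r.random.tau2, Q_R=r.random.Q_R,
                       H2_RE=r.het_re.H2, I2_RE_pct=r.het_re.I2_pct,
                       P_RE=r.het_re.P_value, class_RE=r.het_re.het_class)
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_table(results: list[MetaResult]) -> pd.DataFrame:
    """Weighted mean / %CV / CI summary, one row per protein and method."""
    rows = []
    for r in results:
        for m in ("I", "II", "III"):
            if m not in r.pooled.cv_pct:
                continue
            rows.append({
                "enzyme": r.protein, "tissue": r.tissue, "method": m,
                "weighted_mean": r.pooled.WM,
                "weighted_cv_pct": r.pooled.cv_pct[m],
                "ci_low": r.pooled.ci_low[m],
                "ci_high": r.pooled.ci_high[m],
                "k": r.k, "N": r.N,
            })
    return pd.DataFrame(rows)


def forest_table(result: MetaResult) -> pd.DataFrame:
    """Forest-plot data (label, mean, ci_low, ci_high, row_kind)."""
    return pd.DataFrame([{
        "label": fr.label, "mean": fr.mean, "ci_low": fr.ci_low,
        "ci_high": fr.ci_high, "row_kind": fr.row_kind,
    } for fr in result.forest_rows])
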