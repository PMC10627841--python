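"""Copy-number computation, dilution-series planning, standard-curve
regression, and absolute quantification of unknowns.

Copy numbers of a double-stranded template follow from its mass
concentration:

    copies/uL = C[ng/uL] * 1e-9 * N_A / (L[bp] * 660[g/mol/bp])

with N_A = 6.022e23.  For a circular plasmid standard L is the vector length
(pGEM-T Easy: 3,015 bp) plus the cloned amplicon length; for a synthetic
fragment L is the synthesized length itself.

A standard curve is the ordinary least-squares fit of replicate Cq values
against log10(copies) over a serial dilution series (canonically ten-fold,
10^1..10^8 copies/uL, in triplicate).  Amplification efficiency is derived
from the slope as E = 10^(-1/slope) - 1, so a slope of -3.32 means perfect
per-cycle doubling.  The detection limit is the lowest fitted standard
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmpstdError, FitError, PlanningError, QuantError

#: Avogadro's number as conventionally rounded in qPCR copy-number formulas.
AVOGADRO = 6.022e23
#: Mean molar mass of one double-stranded base pair (g/mol).
BP_WEIGHT = 660.0
#: pGEM-T Easy vector backbone length (bp).
DEFAULT_VECTOR_LENGTH = 3015

#: Efficiency window flagged as acceptable; assays can run as low as 0.70.
EFFICIENCY_RANGE = (0.7, 1.1)


@dataclass
class TemplateSpec:
    """A quantified standard template: synthetic fragment or plasmid."""

    kind: str  # {"synthetic", "plasmid"}
    concentration: float  # ng/uL
    fragment_length: int | None = None  # bp, synthetic
    amplicon_length: int | None = None  # bp, plasmid insert
    vector_length: int = DEFAULT_VECTOR_LENGTH

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic", "plasmid"):
            raise AmpstdError(f"kind must be synthetic/plasmid, got {self.kind!r}")
        if self.concentration < 0:
            raise AmpstdError("concentration must be >= 0")
        if self.kind == "synthetic":
            if not self.fragment_length or self.fragment_length < 1:
                raise AmpstdError("synthetic template needs fragment_length >= 1")
        else:
            if not self.amplicon_length or self.amplicon_length < 1:
                raise AmpstdError("plasmid template needs amplicon_length >= 1")
            if self.vector_length < 1:
                raise AmpstdError("vector_length must be >= 1")

    @property
    def template_length(self) -> int:
        if self.kind == "synthetic":
            return int(self.fragment_length)
        return int(self.vector_length) + int(self.amplicon_length)


def copies_per_ul(spec: TemplateSpec) -> float:
    """Copies per microliter of a template of known mass concentration."""
    return (
        spec.concentration * 1e-9 * AVOGADRO / (spec.template_length * BP_WEIGHT)
    )


@dataclass
class DilutionSeries:
    """A strictly geometric dilution series, highest level first."""

    levels: list[float]  # copies/uL, strictly decreasing by `fold`
    fold: float = 10.0
    replicates_per_level: int = 3

    def __post_init__(self) -> None:
        if len(self.levels) < 1 or any(lv <= 0 for lv in self.levels):
            raise AmpstdError("levels must be positive")
        if self.replicates_per_level < 1:
            raise AmpstdError("replicates_per_level must be >= 1")
        for hi, lo in zip(self.levels, self.levels[1:]):
            if not math.isclose(hi / lo, self.fold, rel_tol=1e-9):
                raise AmpstdError(
                    f"levels must decrease by exactly {self.fold}-fold"
                )

    @property
    def detection_limit(self) -> float:
        return self.levels[-1]


def plan_dilutions(
    stock: float,
    fold: float = 10.0,
    lowest: float = 1e1,
    highest: float = 1e8,
    replicates_per_level: int = 3,
    working_volume: float = 100.0,
) -> tuple[DilutionSeries, pd.DataFrame]:
    """Plan a serial dilution series from a quantified stock.

    Returns the series (``highest`` down to ``lowest`` by ``fold``; the
    defaults give the canonical eight ten-fold levels 10^8..10^1 copies/uL)
    and a per-step pipetting plan for the stated working volume (uL).
    """
    if lowest <= 0 or highest < lowest or fold <= 1:
        raise AmpstdError("need highest >= lowest > 0 and fold > 1")
    if stock < highest:
        top = fold ** math.floor(math.log(stock, fold)) if stock > 0 else 0.0
        raise PlanningError(
            f"stock at {stock:g} copies/uL cannot reach the top level "
            f"{highest:g}; highest achievable round level is {top:g}"
        )
    n_levels = int(round(math.log(highest / lowest, fold))) + 1
    levels = [highest / fold ** i for i in range(n_levels)]
    series = DilutionSeries(levels, fold=fold, replicates_per_level=replicates_per_level)

    steps = []
    template = working_volume * highest / stock
    steps.append({
        "step": 1,
        "source": "stock",
        "level_copies_per_ul": highest,
        "template_ul": template,
        "diluent_ul": working_volume - template,
    })
    for i, lv in enumerate(levels[1:], start=2):
        steps.append({
            "step": i,
            "source": f"level {levels[i - 2]:g}",
            "level_copies_per_ul": lv,
            "template_ul": working_volume / fold,
            "diluent_ul": working_volume * (1 - 1 / fold),
        })
    return series, pd.DataFrame(steps)


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10(copies) over a dilution series."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    per_level_cv: dict[float, float]  # percent, NaN with < 2 replicates
    detection_limit: float
    dropouts: dict[float, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    gene: str = ""

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.efficiency


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/slope) - 1; E = 1 is perfect per-cycle doubling."""
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    return -1.0 / math.log10(1.0 + efficiency)


def _cq_by_level(cq) -> dict[float, list[float]]:
    if isinstance(cq, pd.DataFrame):
        need = {"level", "cq"}
        if not need.issubset(cq.columns):
            raise AmpstdError(f"Cq table needs columns {sorted(need)}")
        return {
            float(lv): grp["cq"].tolist()
            for lv, grp in cq.groupby("level", sort=False)
        }
    return {float(lv): list(vals) for lv, vals in cq.items()}


def fit_standard_curve(
    series: DilutionSeries,
    cq,
    gene: str = "",
) -> StandardCurve:
    """Fit the standard curve on all replicate points (not level means).

    ``cq`` is either a mapping level -> replicate Cq list or a DataFrame with
    ``level`` and ``cq`` columns.  Missing Cq (NaN) marks a non-amplified
    replicate: it is dropped from the fit but counted per level in
    ``dropouts``.  The per-level coefficient of variation is
    100 * sd(Cq)/mean(Cq) with the sample (n-1) standard deviation.
    """
    by_level = _cq_by_level(cq)
    unknown = set(by_level) - {float(lv) for lv in series.levels}
    if unknown:
        raise AmpstdError(f"Cq given for levels not in the series: {sorted(unknown)}")

    xs, ys = [], []
    cvs: dict[float, float] = {}
    dropouts: dict[float, int] = {}
    n_levels_used = 0
    for lv in series.levels:
        reps = np.asarray(by_level.get(float(lv), []), dtype=float)
        finite = reps[np.isfinite(reps)]
        n_drop = int(reps.size - finite.size)
        if n_drop:
            dropouts[float(lv)] = n_drop
        if finite.size == 0:
            continue
        n_levels_used += 1
        xs.extend([math.log10(lv)] * finite.size)
        ys.extend(finite.tolist())
        cvs[float(lv)] = (
            100.0 * float(np.std(finite, ddof=1)) / float(np.mean(finite))
            if finite.size >= 2 else float("nan")
        )
    if n_levels_used < 3:
        raise FitError(
            f"standard curve needs >= 3 distinct levels with data, got {n_levels_used}"
        )
    if not all(np.isfinite(ys)):
        raise FitError("non-finite Cq after dropout filtering")

    fit = stats.linregress(xs, ys)
    slope, intercept = float(fit.slope), float(fit.intercept)
    flags: list[str] = []
    if slope >= 0:
        flags.append("non-quantitative curve")
        efficiency = float("nan")
    else:
        efficiency = efficiency_from_slope(slope)
        lo, hi = EFFICIENCY_RANGE
        if not lo <= efficiency <= hi:
            flags.append(f"efficiency {efficiency:.3f} outside [{lo}, {hi}]")
    if dropouts:
        flags.append("non-amplified replicates present")
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
        n_points=len(ys),
        per_level_cv=cvs,
        detection_limit=series.detection_limit,
        dropouts=dropouts,
        flags=flags,
        gene=gene,
    )


@dataclass
class ExtractionContext:
    """Parameters linking template copies back to copies per gram dry soil."""

    template_dilution_factor: float
    elution_volume: float  # uL
    soil_dry_mass: float  # g
    template_volume: float = 2.0  # uL per reaction

    def __post_init__(self) -> None:
        for name in ("template_dilution_factor", "elution_volume",
                     "soil_dry_mass", "template_volume"):
            if getattr(self, name) <= 0:
                raise AmpstdError(f"{name} must be > 0")


@dataclass
class QuantResult:
    sample_id: str
    mean_cq: float
    copies_per_ul_template: float
    below_detection: bool
    copies_per_g_dry_soil: float | None = None


def quantify_sample(
    curve: StandardCurve,
    cq_reps: Sequence[float],
    ctx: ExtractionContext | None = None,
    sample_id: str = "",
) -> QuantResult:
    """Invert the standard curve at the mean replicate Cq.

    copies/uL template = 10^((mean Cq - intercept)/slope).  With an
    :class:`ExtractionContext` the result is also expressed per gram dry
    soil as copies/uL x dilution factor x elution volume / soil mass (an
    explicit modelling assumption; the conversion is only as good as the
    supplied extraction bookkeeping).
    """
    if curve.slope >= 0:
        raise QuantError("cannot quantify against a non-quantitative curve")
    reps = np.asarray(list(cq_reps), dtype=float)
    finite = reps[np.isfinite(reps)]
    if finite.size == 0:
        raise QuantError(f"sample {sample_id!r}: no finite Cq replicate")
    mean_cq = float(np.mean(finite))
    copies = 10.0 ** ((mean_cq - curve.intercept) / curve.slope)
    per_g = None
    if ctx is not None:
        per_g = (
            copies * ctx.template_dilution_factor * ctx.elution_volume
            / ctx.soil_dry_mass
        )
    return QuantResult(
        sample_id=sample_id,
        mean_cq=mean_cq,
        copies_per_ul_template=copies,
        below_detection=copies < curve.detection_limit,
        copies_per_g_dry_soil=per_g,
    )


# ---------------------------------------------------------------------------
# Plate-table I/O

PLATE_COLUMNS = ["well", "role", "gene", "level_copies_per_ul", "sample_id",
                 "replicate", "cq"]


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a qPCR result table.  Columns: well, role {standard, sample, NC},
    gene, level_copies_per_ul (standards only), sample_id, replicate, cq
    (blank = no amplification)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise AmpstdError(f"plate table {path} lacks column(s) {missing}")
    bad_roles = set(df["role"].unique()) - {"standard", "sample", "NC"}
    if bad_roles:
        raise AmpstdError(f"unknown role(s) {sorted(bad_roles)}")
    return df


def curve_from_plate(
    plate: pd.DataFrame, gene: str, replicates_per_level: int | None = None
) -> StandardCurve:
    std = plate[(plate["role"] == "standard") & (plate["gene"] == gene)]
    if std.empty:
        raise FitError(f"no standard wells for gene {gene!r}")
    levels = sorted(std["level_copies_per_ul"].unique(), reverse=True)
    fold = levels[0] / levels[1] if len(levels) > 1 else 10.0
    reps = replicates_per_level or int(
        std.groupby("level_copies_per_ul").size().max()
    )
    series = DilutionSeries(levels, fold=fold, replicates_per_level=reps)
    table = std.rename(columns={"level_copies_per_ul": "level"})[["level", "cq"]]
    return fit_standard_curve(series, table, gene=gene)


def quantify_plate(
    plate: pd.DataFrame,
    curve: StandardCurve,
    ctx: ExtractionContext | None = None,
    per_replicate: bool = True,
) -> pd.DataFrame:
    """Quantify every sample well of ``curve.gene`` against the curve.

    With ``per_replicate`` each replicate well is inverted individually
    (needed downstream for replicate-level comparisons); per-sample means
    are always included.
    """
    sub = plate[(plate["role"] == "sample") & (plate["gene"] == curve.gene)]
    rows = []
    for sample_id, grp in sub.groupby("sample_id", sort=True):
        mean_res = quantify_sample(curve, grp["cq"], ctx, sample_id=str(sample_id))
        iterator = grp.iterrows() if per_replicate else []
        for _, w in iterator:
            if not np.isfinite(w["cq"]):
                continue
            rep_res = quantify_sample(curve, [w["cq"]], ctx, sample_id=str(sample_id))
            rows.append({
                "sample_id": sample_id,
                "gene": curve.gene,
                "replicate": w["replicate"],
                "cq": w["cq"],
                "copies_per_ul_template": rep_res.copies_per_ul_template,
                "copies_per_g_dry_soil": rep_res.copies_per_g_dry_soil,
                "sample_mean_cq": mean_res.mean_cq,
                "sample_copies_per_ul_template": mean_res.copies_per_ul_template,
                "below_detection": rep_res.below_detection,
            })
        if not per_replicate:
            rows.append({
                "sample_id": sample_id,
                "gene": curve.gene,
                "replicate": "",
                "cq": mean_res.mean_cq,
                "copies_per_ul_template": mean_res.copies_per_ul_template,
                "copies_per_g_dry_soil": mean_res.copies_per_g_dry_soil,
                "sample_mean_cq": mean_res.mean_cq,
                "sample_copies_per_ul_template": mean_res.copies_per_ul_template,
                "below_detection": mean_res.below_detection,
            })
    return pd.DataFrame(rows)


def curve_summary_frame(curves: Sequence[StandardCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        row = {
            "gene": c.gene,
            "slope": c.slope,
            "intercept": c.intercept,
            "r2": c.r_squared,
            "efficiency": c.efficiency,
            "efficiency_pct": c.efficiency_pct,
            "n_points": c.n_points,
            "detection_limit": c.detection_limit,
            "flags": "; ".join(c.flags),
        }
        for lv, cv in sorted(c.per_level_cv.items(), reverse=True):
            row[f"cv_pct_{lv:g}"] = cv
        rows.append(row)
    return pd.DataFrame(rows)


def plot_standard_curve(
    curve: StandardCurve, cq, path: str | Path
) -> None:
    """Scatter the replicate points and draw the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_level = _cq_by_level(cq)
    fig, ax = plt.subplots(figsize=(5, 4))
    xs_all, ys_all = [], []
    for lv, reps in by_level.items():
        reps = np.asarray(reps, dtype=float)
        reps = reps[np.isfinite(reps)]
        xs_all.extend([math.log10(lv)] * reps.size)
        ys_all.extend(reps.tolist())
    ax.scatter(xs_all, ys_all, s=18, color="tab:blue", label="replicates")
    grid = np.linspace(min(xs_all), max(xs_all), 50)
    ax.plot(grid, curve.intercept + curve.slope * grid, color="tab:red",
            label=f"slope {curve.slope:.3f}, E {curve.efficiency_pct:.1f}%")
    ax.set_xlabel("log10(copies/uL)")
    ax.set_ylabel("Cq")
    title = curve.gene or "standard curve"
    ax.set_title(f"{title} (R² = {curve.r_squared:.4f})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
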