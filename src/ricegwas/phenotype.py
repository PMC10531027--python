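"""Total flavonoid content (TFC) quantification and panel summaries.

TFC is measured colorimetrically against a rutin standard: absorbance at
500 nm is converted to rutin concentration through a fitted standard curve
``y = a*x + b`` (y absorbance, x mg/mL), then scaled by the extraction /
dilution bookkeeping to mg rutin equivalent per 100 g of dry brown-rice
flour. This module fits the curve, performs the conversion, averages
replicates, summarizes the panel and ranks elite germplasm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurve:
    """Linear rutin standard curve: absorbance = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    concentration_range: tuple[float, float] = (0.05, 0.25)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0,1]")


#: The two per-replication curves printed for the assay.
CURVE_REP1 = StandardCurve(slope=1.8764, intercept=-0.0054, r_squared=0.9997)
CURVE_REP2 = StandardCurve(slope=1.8503, intercept=-0.0129, r_squared=0.9995)

#: Rutin standard concentrations used to build the curve (mg/mL).
STANDARD_CONCENTRATIONS = (0.05, 0.1, 0.15, 0.2, 0.25)


@dataclass
class DilutionScheme:
    """Extraction and reaction bookkeeping for the colorimetric assay.

    Defaults: 0.5 g flour extracted in 5 mL of 50% ethanol; a 1 mL aliquot
    of supernatant is brought to a 6.2 mL reaction volume
    (1 + 0.6 NaNO2 + 0.6 Al(NO3)3 + 4 NaOH); results reported per 100 g.
    With these defaults the mg/mL -> mg/100 g multiplier is
    6.2 * (5/1) * (100/0.5) = 6200.
    """

    sample_mass: float = 0.5  # g flour
    extract_volume: float = 5.0  # mL ethanol
    aliquot_volume: float = 1.0  # mL supernatant into the reaction
    reaction_volume: float = 6.2  # mL final colored volume
    output_basis: float = 100.0  # report per this many g of flour

    def __post_init__(self) -> None:
        for name in ("sample_mass", "extract_volume", "aliquot_volume",
                     "reaction_volume", "output_basis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.aliquot_volume > self.extract_volume:
            raise ValueError("aliquot_volume cannot exceed extract_volume")

    @property
    def multiplier(self) -> float:
        """mg/mL reaction concentration -> mg per ``output_basis`` g flour."""
        return (self.reaction_volume
                * (self.extract_volume / self.aliquot_volume)
                * (self.output_basis / self.sample_mass))


@dataclass
class PhenotypeSummary:
    n: int
    min: float
    max: float
    mean: float
    cv: float  # percent, 100*sd/mean
    skewness: float  # adjusted Fisher-Pearson
    max_min_ratio: float  # rounded to 1 decimal, half away from zero


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS fit of absorbance on rutin concentration.

    Requires at least three distinct concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("concentrations are constant")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentration_range=(float(x.min()), float(x.max())),
    )


def absorbance_to_tfc(absorbance, curve: StandardCurve,
                      dilution: DilutionScheme | None = None):
    """Convert assay absorbance to TFC in mg rutin equivalent / 100 g flour.

    Concentration c = (absorbance - intercept) / slope; negative computed
    concentrations (below-blank absorbance) are clamped to 0 with a warning.
    Accepts a scalar or array and returns the matching shape.
    """
    if dilution is None:
        dilution = DilutionScheme()
    a = np.asarray(absorbance, dtype=float)
    conc = (a - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn("absorbance below blank level; concentration clamped to 0",
                      stacklevel=2)
        conc = np.maximum(conc, 0.0)
    tfc = conc * dilution.multiplier
    return float(tfc) if np.isscalar(absorbance) else tfc


def _round_half_away(x: float, decimals: int = 1) -> float:
    f = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * f + 0.5) / f)


def average_replicates(absorbance: pd.DataFrame,
                       curves: dict[int, StandardCurve] | None = None,
                       dilution: DilutionScheme | None = None) -> pd.DataFrame:
    """Per-accession TFC from a raw absorbance table.

    ``absorbance`` columns: accession, replicate, technical_rep, absorbance.
    Technical repeats are averaged first, then each field replicate's
    absorbance is converted with that replicate's own standard curve, and
    finally replicate TFC values are averaged (conversion before averaging,
    because the two replications used different curves).
    """
    if curves is None:
        curves = {1: CURVE_REP1, 2: CURVE_REP2}
    tech = (absorbance.groupby(["accession", "replicate"], sort=True)["absorbance"]
            .mean().reset_index())
    tech["tfc"] = [
        absorbance_to_tfc(a, curves.get(int(r), CURVE_REP1), dilution)
        for a, r in zip(tech["absorbance"], tech["replicate"])
    ]
    wide = tech.pivot(index="accession", columns="replicate", values="tfc")
    wide.columns = [f"rep{int(c)}" for c in wide.columns]
    wide["mean_tfc"] = wide.mean(axis=1, skipna=True)
    return wide.reset_index()


def summarize_phenotype(table: pd.DataFrame,
                        value_col: str = "mean_tfc") -> PhenotypeSummary:
    """Panel summary: min/max/mean, CV%, adjusted skewness, max/min ratio."""
    v = np.asarray(table[value_col], dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 phenotype values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("mean phenotype is 0; CV undefined")
    sd = float(v.std(ddof=1))
    skew = 0.0 if sd == 0 else float(stats.skew(v, bias=False))
    return PhenotypeSummary(
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        mean=mean,
        cv=100.0 * sd / mean,
        skewness=skew,
        max_min_ratio=_round_half_away(float(v.max()) / float(v.min()), 1),
    )


def rank_germplasm(table: pd.DataFrame, n: int,
                   value_col: str = "mean_tfc",
                   id_col: str = "accession") -> pd.DataFrame:
    """Top-``n`` accessions by mean TFC, descending; ties broken by id."""
    if n > len(table):
        raise ValueError(f"n={n} exceeds table size {len(table)}")
    ranked = table.sort_values(
        [value_col, id_col], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)
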