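"""Quantal median-effect dose-response fitting and combination analysis.

The median-effect model relates the fraction of cells affected Fa at dose D
through

    log(Fa/Fu) = m*log(D) - m*log(Dm),       Fu = 1 - Fa,

where m is the sigmoidicity slope and Dm the median-effect dose (the dose at
50% effect, i.e. the EC50).  Fitting is ordinary least squares of
log10(Fa/Fu) on log10(D).  Inverting the fitted line gives the dose for any
effect level,

    D(i) = Dm * (i / (1 - i))**(1/m),

which feeds the Chou combination index for a fixed-ratio two-drug mixture,

    CI(i) = Dac(i)/Das(i) + Dbc(i)/Dbs(i),

with Dac, Dbc the component doses in the combination producing effect i and
Das, Dbs the single-drug doses producing the same effect; CI < 1 indicates
synergism, CI about 1 additivity, CI > 1 antagonism.  The dose-reduction
indices are DRIa(i) = Das(i)/Dac(i), DRIb(i) = Dbs(i)/Dbc(i), so that
CI = 1/DRIa + 1/DRIb identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FA_EPSILON = 0.005
ADDITIVITY_BAND = (0.9, 1.1)


@dataclass
class DoseResponseSeries:
    """Per-dose fraction-affected observations for one drug in one
    environment.  ``records`` columns: dose (> 0), fa in [0, 1], and
    optionally n_events (events scored per dose, used for bootstrap
    resampling)."""

    records: pd.DataFrame
    drug: str = "drug"
    environment: str = "normoxia"

    def __post_init__(self) -> None:
        req = {"dose", "fa"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"series records need columns {sorted(req)}")
        if "n_events" not in self.records.columns:
            self.records = self.records.assign(n_events=np.nan)
        self.records = self.records.reset_index(drop=True)
        if (self.records["dose"] <= 0).any():
            raise ValueError("all doses must be > 0")
        if ((self.records["fa"] < 0) | (self.records["fa"] > 1)).any():
            raise ValueError("fa must lie in [0, 1]")


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters.

    m: unitless slope; Dm: median-effect dose (same units as input doses);
    r: Pearson correlation of the log-log regression; excluded: (dose, fa)
    points outside the usable (eps, 1-eps) effect window; warning: set when
    the fitted slope is non-positive (non-monotone response).
    """

    m: float
    Dm: float
    r: float
    n_points: int
    intercept: float = 0.0
    excluded: list = field(default_factory=list)
    warning: str | None = None

    def effect_at_dose(self, dose: float | np.ndarray) -> float | np.ndarray:
        return effect_at_dose(self, dose)

    def dose_for_effect(self, fa: float | np.ndarray) -> float | np.ndarray:
        return dose_for_effect(self, fa)

    @property
    def ec50(self) -> float:
        """EC50 equals Dm under the median-effect model."""
        return self.Dm


def fit_median_effect(
    series: DoseResponseSeries, epsilon: float = DEFAULT_FA_EPSILON
) -> MedianEffectFit:
    """OLS fit of log10(fa/(1-fa)) on log10(dose).

    Points with fa outside (epsilon, 1-epsilon) are excluded (not clamped:
    clamping saturated points would bias the slope) and recorded on the fit.
    Requires at least two usable points at distinct doses.  A non-positive
    fitted slope is flagged with a warning rather than rejected.
    """
    rec = series.records
    usable = (rec["fa"] > epsilon) & (rec["fa"] < 1 - epsilon)
    excluded = list(rec.loc[~usable, ["dose", "fa"]].itertuples(index=False, name=None))
    rec = rec.loc[usable]
    if len(rec) < 2:
        raise ValueError(
            f"need >=2 points with fa in ({epsilon}, {1 - epsilon}); "
            f"got {len(rec)} usable of {len(series.records)}"
        )
    x = np.log10(rec["dose"].to_numpy())
    y = np.log10(rec["fa"].to_numpy() / (1 - rec["fa"].to_numpy()))
    if np.ptp(x) < 1e-12:
        raise ValueError("all usable doses identical: zero variance in log-dose")
    res = stats.linregress(x, y)
    m = float(res.slope)
    warning = None
    if m <= 0:
        warning = "non-positive slope: response is not monotone increasing"
        dm = float("nan")
    else:
        dm = float(10 ** (-res.intercept / m))
    return MedianEffectFit(
        m=m,
        Dm=dm,
        r=float(res.rvalue),
        n_points=len(rec),
        intercept=float(res.intercept),
        excluded=excluded,
        warning=warning,
    )


def effect_at_dose(fit: MedianEffectFit, dose):
    """Fraction affected at a dose: fa = 1 / (1 + (Dm/D)**m)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be > 0")
    out = 1.0 / (1.0 + (fit.Dm / dose) ** fit.m)
    return float(out) if out.ndim == 0 else out


def dose_for_effect(fit: MedianEffectFit, fa):
    """Dose producing effect fa: D = Dm * (fa/(1-fa))**(1/m).

    dose_for_effect(fit, 0.5) == Dm == EC50 for any slope.
    """
    fa = np.asarray(fa, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValueError("fa must lie strictly in (0, 1)")
    if not np.isfinite(fit.Dm) or fit.m <= 0:
        raise ValueError("fit is not invertible (non-positive slope)")
    out = fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
    return float(out) if out.ndim == 0 else out


@dataclass
class CITable:
    """Per-effect-level combination-index / dose-reduction-index records for
    a fixed-ratio combination.  ``table`` columns: level, Dac, Dbc, Das, Dbs,
    CI, DRIa, DRIb, interaction."""

    table: pd.DataFrame
    ratio: tuple[float, float]
    additivity_band: tuple[float, float] = ADDITIVITY_BAND


def compute_ci(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float],
    levels: Sequence[float],
    additivity_band: tuple[float, float] = ADDITIVITY_BAND,
) -> CITable:
    """Combination index and dose-reduction indices over effect levels.

    ``fit_combo`` must have been fitted on the TOTAL combination dose at the
    stated fixed a:b ratio (proportions summing to 1); the ratio is declared
    by the caller, never inferred.  For each level i the total combination
    dose is split by the ratio into component doses Dac, Dbc and compared
    with the single-drug doses Das, Dbs producing the same effect.
    """
    ra, rb = ratio
    if not np.isclose(ra + rb, 1.0, atol=1e-9) or ra < 0 or rb < 0:
        raise ValueError(f"ratio must be non-negative proportions summing to 1, got {ratio}")
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("effect levels must lie strictly in (0, 1)")
    dc = dose_for_effect(fit_combo, levels)
    dac, dbc = ra * dc, rb * dc
    das = dose_for_effect(fit_a, levels)
    dbs = dose_for_effect(fit_b, levels)
    ci = dac / das + dbc / dbs
    with np.errstate(divide="ignore"):
        dria = das / dac
        drib = dbs / dbc
    lo, hi = additivity_band
    interaction = np.where(ci < lo, "synergism", np.where(ci > hi, "antagonism", "additivity"))
    table = pd.DataFrame(
        {
            "level": levels,
            "Dac": dac,
            "Dbc": dbc,
            "Das": das,
            "Dbs": dbs,
            "CI": ci,
            "DRIa": dria,
            "DRIb": drib,
            "interaction": interaction,
        }
    )
    return CITable(table=table, ratio=(ra, rb), additivity_band=additivity_band)


@dataclass
class BootstrapResult:
    point: MedianEffectFit
    samples: pd.DataFrame  # columns m, Dm per successful replicate
    n_requested: int
    n_failed: int

    def percentile_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        if self.samples.empty:
            raise ValueError("no bootstrap samples (n_boot = 0?)")
        a = (1 - level) / 2
        lo, hi = np.quantile(self.samples[param], [a, 1 - a])
        return float(lo), float(hi)


def bootstrap_fit(
    series: DoseResponseSeries,
    n_boot: int,
    seed: int,
    epsilon: float = DEFAULT_FA_EPSILON,
) -> BootstrapResult:
    """Event-level binomial bootstrap of the median-effect fit.

    At each dose, the observed fa with n_events scored cells is resampled as
    Binomial(n_events, fa)/n_events and the model refit.  When n_events is
    missing the dose points themselves are resampled with replacement (a
    cruder case-resampling bootstrap) and a warning is attached.  Replicates
    whose resample is unfittable (e.g. all fa saturated) are dropped and
    counted.  Percentile intervals come from ``percentile_interval``.
    """
    import warnings as _warnings

    point = fit_median_effect(series, epsilon=epsilon)
    rng = np.random.default_rng(seed)
    rec = series.records
    have_n = rec["n_events"].notna().all()
    if not have_n:
        _warnings.warn(
            "n_events missing: falling back to resampling over dose points"
        )
    rows, n_failed = [], 0
    for _ in range(n_boot):
        if have_n:
            n = rec["n_events"].to_numpy(dtype=float).astype(int)
            fa_b = rng.binomial(n, rec["fa"].to_numpy()) / n
            boot = rec.assign(fa=fa_b)
        else:
            boot = rec.sample(n=len(rec), replace=True, random_state=rng)
        try:
            f = fit_median_effect(
                DoseResponseSeries(boot, series.drug, series.environment),
                epsilon=epsilon,
            )
        except ValueError:
            n_failed += 1
            continue
        rows.append({"m": f.m, "Dm": f.Dm})
    return BootstrapResult(
        point=point,
        samples=pd.DataFrame(rows, columns=["m", "Dm"]),
        n_requested=n_boot,
        n_failed=n_failed,
    )
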