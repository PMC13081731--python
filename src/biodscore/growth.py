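"""In vivo growth and time-to-event analysis.

Implements the preclinical efficacy layer: caliper tumor volume
(L·W²/2), tumor growth inhibition (TGI) at the latest day all animals
remain on study, one-sided baseline-adjusted ANCOVA on log volumes,
genotype×treatment interaction ANOVA (no baseline adjustment), event
derivation at a 1500 mm³ volume threshold, Kaplan–Meier estimation,
one-sided log-rank tests, and four-parameter-logistic confluency fits
with one-sided slope comparison.

One-sided alternatives are encoded by signed statistics: an effect in the
hypothesized direction (treatment inhibits growth / delays events) gives
p < 0.5, a wrong-direction effect gives p > 0.5.  No multiplicity
correction is applied anywhere in this module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

__all__ = [
    "EVENT_THRESHOLD_MM3",
    "TGIResult",
    "FourPLFit",
    "tumor_volume",
    "compute_tgi",
    "ancova_log_tgi",
    "anova_interaction",
    "derive_events",
    "km_curve",
    "logrank",
    "fit_4pl",
    "compare_slopes",
    "four_pl",
]

EVENT_THRESHOLD_MM3 = 1500.0


@dataclass(frozen=True)
class TGIResult:
    tgi_percent: float
    reference_day: int
    method: str  # "arithmetic" | "geometric"
    p_one_sided: float
    n_control: int
    n_treated: int


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    slope: float
    inflection: float
    rss: float
    converged: bool


def tumor_volume(length_mm, width_mm):
    """Caliper (ellipsoid-proxy) tumor volume: (L·W²)/2 in mm³.

    L is the longest dimension and W the longest perpendicular one, so
    L >= W > 0 is required.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(width_mm <= 0):
        raise ValueError("width must be positive")
    if np.any(width_mm > length_mm):
        raise ValueError("width exceeds length; L is defined as the longest dimension")
    v = length_mm * width_mm**2 / 2.0
    return float(v) if v.ndim == 0 else v


def _reference_day(study: pd.DataFrame) -> int:
    """Latest study day on which every animal still has a measurement."""
    per_animal_last = study.groupby("animal")["day"].max()
    common = int(per_animal_last.min())
    days_present = set(study["day"].unique())
    candidates = [d for d in days_present if d <= common and
                  study[study["day"] == d]["animal"].nunique() == study["animal"].nunique()]
    if not candidates:
        raise ValueError("no study day has measurements for all animals")
    return int(max(candidates))


def _volumes_at(study: pd.DataFrame, group: str, day: int) -> np.ndarray:
    sel = study[(study["group"] == group) & (study["day"] == day)]
    return sel["volume_mm3"].to_numpy(dtype=float)


def compute_tgi(
    study: pd.DataFrame,
    treated: str,
    control: str,
    method: str = "arithmetic",
    reference_day: int | None = None,
) -> TGIResult:
    """Tumor growth inhibition (%) of ``treated`` versus ``control``.

    Default: TGI% = 100·(1 − mean V_treated / mean V_control) at the latest
    day all animals remain on study (arithmetic group means; the geometric
    variant uses geometric means).  Negative values are allowed — a
    faster-growing treated group yields TGI < 0.  The one-sided p-value
    comes from the baseline-adjusted log-volume ANCOVA.
    """
    if method not in ("arithmetic", "geometric"):
        raise ValueError("method must be 'arithmetic' or 'geometric'")
    day = _reference_day(study) if reference_day is None else int(reference_day)
    vt = _volumes_at(study, treated, day)
    vc = _volumes_at(study, control, day)
    if len(vt) == 0 or len(vc) == 0:
        raise ValueError(f"a group has no measurements on day {day}")
    if method == "arithmetic":
        ratio = vt.mean() / vc.mean()
    else:
        ratio = np.exp(np.log(vt).mean() - np.log(vc).mean())
    try:
        p = ancova_log_tgi(study, treated, control, reference_day=day)
    except ValueError as exc:
        warnings.warn(f"ANCOVA p-value unavailable: {exc}", stacklevel=2)
        p = float("nan")
    return TGIResult(
        tgi_percent=100.0 * (1.0 - ratio),
        reference_day=day,
        method=method,
        p_one_sided=p,
        n_control=len(vc),
        n_treated=len(vt),
    )


def ancova_log_tgi(
    study: pd.DataFrame,
    treated: str,
    control: str,
    reference_day: int | None = None,
    baseline_day: int | None = None,
) -> float:
    """One-sided baseline-adjusted ANCOVA p for growth inhibition.

    Fits log V_ref ~ group + log V_baseline by OLS and tests the treated
    coefficient against the one-sided alternative "treated < control".
    Baseline defaults to each animal's earliest measured day (the day of
    first dose in a simulated study); the reference day defaults to the
    latest day common to all animals.
    """
    sub = study[study["group"].isin([treated, control])]
    day = _reference_day(sub) if reference_day is None else int(reference_day)
    base_day = int(sub["day"].min()) if baseline_day is None else int(baseline_day)
    if day == base_day:
        raise ValueError("reference day equals baseline day; no growth to compare")
    ref = sub[sub["day"] == day].set_index("animal")
    base = sub[sub["day"] == base_day].set_index("animal")
    animals = ref.index.intersection(base.index)
    if len(animals) < 4:
        raise ValueError("need at least 4 animals with baseline and reference measurements")
    y = np.log(ref.loc[animals, "volume_mm3"].to_numpy(dtype=float))
    logv0 = np.log(base.loc[animals, "volume_mm3"].to_numpy(dtype=float))
    is_treated = (ref.loc[animals, "group"] == treated).to_numpy(dtype=float)
    if is_treated.min() == is_treated.max():
        raise ValueError("both groups must be present at the reference day")
    if np.ptp(logv0) == 0:
        warnings.warn(
            "baseline volumes are constant; ANCOVA reduces to a t-test on "
            "log reference volumes", stacklevel=2,
        )
        X = sm.add_constant(is_treated)
    else:
        X = sm.add_constant(np.column_stack([is_treated, logv0]))
    res = sm.OLS(y, X).fit()
    if res.df_resid < 1 or not np.isfinite(res.bse[1]) or res.bse[1] == 0:
        raise ValueError("ANCOVA design is collinear or has insufficient residual df")
    tval = res.params[1] / res.bse[1]
    # alternative: treated < control on the log scale
    return float(stats.t.cdf(tval, res.df_resid))


def anova_interaction(
    study: pd.DataFrame,
    treated: str,
    control: str,
    wildtype: str = "wildtype",
    reference_day: int | None = None,
) -> float:
    """One-sided interaction p for "treatment inhibits growth more in the
    wildtype genotype".

    Two-way OLS on log reference-day volumes, log V ~ treat + genotype +
    treat:genotype, with *no* baseline covariate (so intrinsic growth
    differences between genotypes remain in the model).  With treat = 1 for
    the treated group and geno = 1 for the non-wildtype genotype, the
    treatment effect is β_t in wildtype and β_t + β_int otherwise; stronger
    inhibition in wildtype means β_int > 0, and the one-sided p is
    P(T > t_int).
    """
    sub = study[study["group"].isin([treated, control])]
    genos = sub["genotype"].unique()
    if len(genos) != 2 or wildtype not in genos:
        raise ValueError(f"need exactly two genotypes including {wildtype!r}, got {list(genos)}")
    day = _reference_day(sub) if reference_day is None else int(reference_day)
    ref = sub[sub["day"] == day]
    y = np.log(ref["volume_mm3"].to_numpy(dtype=float))
    treat = (ref["group"] == treated).to_numpy(dtype=float)
    geno = (ref["genotype"] != wildtype).to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([treat, geno, treat * geno]))
    res = sm.OLS(y, X).fit()
    if res.df_resid < 1 or not np.isfinite(res.bse[3]) or res.bse[3] == 0:
        raise ValueError("interaction design is collinear or has insufficient residual df")
    tval = res.params[3] / res.bse[3]
    return float(stats.t.sf(tval, res.df_resid))


def derive_events(study: pd.DataFrame, threshold: float = EVENT_THRESHOLD_MM3) -> pd.DataFrame:
    """Time-to-event table from a growth study.

    The event time is the first measured day with volume >= ``threshold``
    (1500 mm³ by default); an animal whose series never crosses is censored
    at its last measured day.  A non-monotone series that crosses and later
    regresses still scores the event at the first crossing — caliper data
    are interval-observed, so no interpolation between days is attempted.

    Returns columns animal, group, time_days, event (bool).
    """
    rows = []
    for animal, ser in study.sort_values("day").groupby("animal", sort=False):
        crossed = ser[ser["volume_mm3"] >= threshold]
        group = ser["group"].iloc[0]
        if len(crossed):
            rows.append((animal, group, int(crossed["day"].iloc[0]), True))
        else:
            rows.append((animal, group, int(ser["day"].iloc[-1]), False))
    return pd.DataFrame(rows, columns=["animal", "group", "time_days", "event"])


def km_curve(tbl: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve.

    Returns a step table with columns time_days and survival, starting at
    (0, 1).  Tied events at a time are handled simultaneously (standard
    product-limit convention).
    """
    if group is not None:
        tbl = tbl[tbl["group"] == group]
    if len(tbl) == 0:
        raise ValueError("no animals in the requested group")
    kmf = KaplanMeierFitter()
    kmf.fit(tbl["time_days"], event_observed=tbl["event"].astype(bool))
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time_days", "survival"]
    return out


def _logrank_z(times: np.ndarray, events: np.ndarray, in_treated: np.ndarray) -> float:
    """Signed log-rank deviate Z = (O₁−E₁)/√V over the treated group.

    Negative Z means the treated group accrues events later than expected
    under the null (the hypothesized benefit direction).
    """
    obs = exp = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_treated).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & in_treated).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float((obs - exp) / np.sqrt(var))


def logrank(
    tbl: pd.DataFrame,
    treated: str,
    control: str,
    method: str = "auto",
) -> float:
    """One-sided log-rank p: alternative "treated reaches events later".

    The asymptotic p is Φ(Z) of the signed deviate, so a wrong-direction
    difference (treated progressing sooner) yields p > 0.5 and Z² equals
    the classical two-group log-rank chi-square.  With ``method='exact'``
    (auto-selected when the two groups total <= 10 animals) the p-value is
    the exhaustive group-label permutation probability P(Z_perm <= Z_obs),
    which is reliable at the tiny group sizes where the normal
    approximation is not.
    """
    sub = tbl[tbl["group"].isin([treated, control])]
    times = sub["time_days"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=bool)
    in_treated = (sub["group"] == treated).to_numpy(dtype=bool)
    n1 = int(in_treated.sum())
    if n1 == 0 or n1 == len(sub):
        raise ValueError("both groups must be non-empty")
    z = _logrank_z(times, events, in_treated)
    if method == "auto":
        method = "exact" if len(sub) <= 10 else "asymptotic"
    if method == "asymptotic":
        return float(stats.norm.cdf(z))
    if method != "exact":
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    zs = []
    for idx in itertools.combinations(range(len(sub)), n1):
        lab = np.zeros(len(sub), dtype=bool)
        lab[list(idx)] = True
        zs.append(_logrank_z(times, events, lab))
    zs = np.asarray(zs)
    return float(np.mean(zs <= z + 1e-12))


def four_pl(t, bottom, top, slope, inflection):
    """Four-parameter logistic in Hill form on the time axis:

        c(t) = bottom + (top − bottom) / (1 + (t / inflection)^(−slope))

    For slope > 0 the curve rises from ``bottom`` at t → 0 to ``top`` as
    t → ∞, with half-maximal response at t = inflection; the Hill
    coefficient ``slope`` sets the steepness.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio = np.where(t > 0, (t / inflection) ** (-slope), np.inf if slope > 0 else 0.0)
        out = bottom + (top - bottom) / (1.0 + ratio)
    return out


def fit_4pl(times, confluencies) -> FourPLFit:
    """Least-squares 4PL fit of a confluency time-course.

    Multi-start over Hill slopes {±0.5, ±2, ±5} with the inflection seeded
    at the median time; the best residual sum of squares wins.  A constant
    series (or any fit that collapses top onto bottom) is returned with
    ``converged=False`` — the slope of a degenerate fit is meaningless and
    must not enter a slope comparison.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(confluencies, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    span = c.max() - c.min()
    if span <= 1e-12 * max(1.0, abs(c.max())):
        return FourPLFit(c.min(), c.max(), 0.0, float(np.median(t[t > 0]) if (t > 0).any() else 1.0),
                         rss=0.0, converged=False)
    t_pos = t[t > 0]
    infl0 = float(np.median(t_pos)) if len(t_pos) else 1.0
    best = None
    for s0 in (0.5, 2.0, 5.0, -0.5, -2.0, -5.0):
        p0 = (c.min(), c.max(), s0, infl0)
        try:
            popt, _ = optimize.curve_fit(
                four_pl, t, c, p0=p0,
                bounds=([-np.inf, -np.inf, -50.0, 1e-9],
                        [np.inf, np.inf, 50.0, np.inf]),
                maxfev=20_000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((four_pl(t, *popt) - c) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, rss=np.inf, converged=False)
    (bottom, top, slope, infl), rss = best
    if top < bottom:  # canonicalize: rising parameterization
        bottom, top, slope = top, bottom, -slope
    degenerate = (top - bottom) <= 1e-6 * span
    return FourPLFit(float(bottom), float(top), float(slope), float(infl),
                     rss=rss, converged=not degenerate)


def compare_slopes(fits_treated, fits_control, alternative: str = "less") -> float:
    """One-sided comparison of per-replicate 4PL Hill slopes.

    Accepts sequences of FourPLFit (non-converged fits are dropped with a
    warning) or raw slope arrays.  Default alternative "less": treatment
    delays growth, i.e. treated slopes are smaller than control slopes
    (shallower confluency rise).  Welch two-sample t-test.  With very few
    replicates per arm (the typical n = 2 in vitro design) the attainable
    p is bounded away from 0 — reported as computed, never clipped.
    """
    st = _slopes(fits_treated)
    sc = _slopes(fits_control)
    if len(st) < 2 or len(sc) < 2:
        raise ValueError("need at least 2 converged replicate fits per arm")
    res = stats.ttest_ind(st, sc, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def _slopes(fits) -> np.ndarray:
    fits = list(fits)
    if fits and isinstance(fits[0], FourPLFit):
        dropped = sum(not f.converged for f in fits)
        if dropped:
            warnings.warn(f"dropping {dropped} non-converged 4PL fits", stacklevel=3)
        return np.array([f.slope for f in fits if f.converged], dtype=float)
    return np.asarray(fits, dtype=float)
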