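"""Non-compartmental analysis and model-performance statistics.

Implements the exposure metrics (AUC to the last sample, AUC extrapolated to
infinity, Cmax/tmax), the mean relative deviation (MRD) of predicted vs
observed concentration profiles, the geometric mean fold error (GMFE) of PK
parameters, the hydroxybupropion/bupropion metabolite-parent ratio and the
DGI/DDI/DDGI effect ratio built from it, plus the two acceptance checks used
to judge interaction predictions: the 2-fold criterion and the Guest limits
with 1.25-fold variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConcentrationProfile:
    """A concentration-time profile (times in h, concentrations in ng/mL)."""

    times: np.ndarray
    values: np.ndarray
    compound: str = ""
    lloq: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class PKSummary:
    """Non-compartmental exposure summary of one profile."""

    auc_last: float                    # ng·h/mL
    cmax: float                        # ng/mL
    tmax: float                        # h
    auc_inf: float | None = None       # ng·h/mL
    lambda_z: float | None = None      # 1/h
    lambda_z_r2: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class RatioSet:
    """Metabolite-parent ratio and interaction effect ratio for one scenario."""

    pk_hbup_bup: float
    effect_ratio: float
    context: str                        # DGI | DDI | DDGI
    parameter: str = "AUC_last"         # AUC_last | AUC_inf | Cmax

    def __post_init__(self):
        if self.pk_hbup_bup <= 0 or self.effect_ratio <= 0:
            raise ValueError("ratios must be positive")


def auc_last(profile: ConcentrationProfile) -> float:
    """Linear-trapezoid AUC from the first to the last sample (ng·h/mL)."""
    if len(profile.times) < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(profile.values, profile.times))


def lambda_z_fit(profile: ConcentrationProfile, n_range=(3, 8)):
    """Terminal slope by log-linear regression.

    The number of terminal points is chosen within ``n_range`` to maximize the
    adjusted r² of the regression. Returns ``(lambda_z per h, r2_adj, n_used)``.
    """
    mask = profile.values > 0
    t, c = profile.times[mask], profile.values[mask]
    if len(t) < 3:
        raise ValueError("lambda_z needs at least 3 positive terminal points")
    best = None
    for n in range(n_range[0], min(n_range[1], len(t)) + 1):
        tt, lc = t[-n:], np.log(c[-n:])
        slope, intercept = np.polyfit(tt, lc, 1)
        resid = lc - (slope * tt + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and (best is None or r2_adj > best[1]):
            best = (-slope, r2_adj, n)
    if best is None:
        raise ValueError("no negative terminal slope found")
    return best


def auc_inf(profile: ConcentrationProfile, r2_threshold: float = 0.9) -> PKSummary:
    """AUC extrapolated to infinity: AUC_last + C_last / lambda_z.

    A poorly determined terminal phase (adjusted r² below the threshold) is
    flagged rather than rejected.
    """
    base = auc_last(profile)
    flags: list[str] = []
    lz = r2 = None
    extra = 0.0
    c_last = profile.values[-1]
    if c_last > 0:
        lz, r2, _ = lambda_z_fit(profile)
        if r2 < r2_threshold:
            flags.append("terminal_phase_poorly_determined")
        extra = float(c_last / lz)
    summary = nca(profile)
    return PKSummary(
        auc_last=base,
        cmax=summary.cmax,
        tmax=summary.tmax,
        auc_inf=base + extra,
        lambda_z=lz,
        lambda_z_r2=r2,
        flags=tuple(flags),
    )


def nca(profile: ConcentrationProfile) -> PKSummary:
    """Basic non-compartmental summary (AUC_last, Cmax, tmax)."""
    imax = int(np.argmax(profile.values))
    return PKSummary(
        auc_last=auc_last(profile),
        cmax=float(profile.values[imax]),
        tmax=float(profile.times[imax]),
    )


def mrd(observed: ConcentrationProfile, predicted: ConcentrationProfile) -> float:
    """Mean relative deviation of a predicted vs an observed profile.

    ``MRD = 10**x`` with ``x = sqrt(sum((log10 c_hat - log10 c)^2) / k)``.
    Pairs in which either concentration is zero (or below the LLOQ of the
    observed profile) are excluded and k reduced accordingly.
    """
    if len(observed.times) != len(predicted.times) or np.any(
        np.abs(observed.times - predicted.times) > 1e-9
    ):
        raise ValueError("profiles must share the sampling times")
    obs, pred = observed.values, predicted.values
    mask = (obs > 0) & (pred > 0)
    if observed.lloq is not None:
        mask &= obs >= observed.lloq
    k = int(mask.sum())
    if k == 0:
        raise ValueError("MRD undefined: no usable concentration pairs")
    x = np.sqrt(np.mean((np.log10(pred[mask]) - np.log10(obs[mask])) ** 2))
    return float(10.0**x)


def gmfe(pairs) -> float:
    """Geometric mean fold error of predicted/observed PK parameter pairs.

    ``GMFE = 10**x`` with ``x = mean(|log10(pred/obs)|)``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("GMFE needs at least one pair")
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise ValueError("GMFE requires positive values")
        logs.append(abs(np.log10(pred / obs)))
    return float(10.0 ** np.mean(logs))


def hbup_bup_ratio(hbup: PKSummary, bup: PKSummary, parameter: str = "AUC_last") -> float:
    """Metabolite-parent exposure ratio ``HBup_PK / Bup_PK``."""
    attr = {"AUC_last": "auc_last", "AUC_inf": "auc_inf", "Cmax": "cmax"}.get(parameter)
    if attr is None:
        raise ValueError(f"unknown PK parameter: {parameter!r}")
    num, den = getattr(hbup, attr), getattr(bup, attr)
    if num is None or den is None:
        raise ValueError(f"{parameter} missing from one of the summaries")
    if num <= 0 or den <= 0:
        raise ValueError("PK parameters must be positive")
    return float(num / den)


def effect_ratio(interaction_ratio: float, reference_ratio: float) -> float:
    """Interaction effect ratio: metabolite-parent ratio vs the reference arm."""
    if interaction_ratio <= 0 or reference_ratio <= 0:
        raise ValueError("ratios must be positive")
    return float(interaction_ratio / reference_ratio)


def guest_limits(observed_ratio: float, delta: float = 1.25) -> tuple[float, float]:
    """Acceptance bounds on predicted/observed interaction ratios (Guest).

    ``L = (delta + 2 (R - 1)) / R`` with R the observed ratio folded to >= 1;
    the bounds tighten to ``delta`` as R approaches 1 and widen toward 2-fold
    for strong interactions. Returns ``(1/L, L)``.
    """
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be positive")
    r = observed_ratio if observed_ratio >= 1 else 1.0 / observed_ratio
    limit = (delta + 2.0 * (r - 1.0)) / r
    return (1.0 / limit, limit)


def within_twofold(value: float) -> bool:
    """2-fold acceptance on a fold-error style statistic (MRD, GMFE, ratio)."""
    if value <= 0:
        raise ValueError("value must be positive")
    folded = value if value >= 1 else 1.0 / value
    return bool(folded <= 2.0)


def within_guest(predicted_ratio: float, observed_ratio: float, delta: float = 1.25) -> bool:
    """Whether predicted/observed falls inside the Guest acceptance bounds."""
    lo, hi = guest_limits(observed_ratio, delta)
    q = predicted_ratio / observed_ratio
    return bool(lo <= q <= hi)
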