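"""15N relaxation: monoexponential rate fitting, per-domain R2/R1 statistics,
apparent rotational correlation times and free-vs-bound comparison.

Rates come from three-point pseudo-3D decay series fit to I(t) = I0*exp(-R*t)
with Monte-Carlo (signal-to-noise based) error propagation. The apparent
correlation time of a domain follows from its trimmed mean R2/R1 through

    tau_c ~= sqrt(6*R2/R1 - 7) / (4*pi*nuN)

where nuN is the 15N resonance frequency in Hz. This expression, valid for
slow isotropic tumbling where J(0) and J(wN) dominate, is zero at the
small-molecule fixed point R2/R1 = 7/6 and increases monotonically. Trimming
retains residues within one SD of the domain mean, excluding conformational
exchange and fast internal motion from the tumbling estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, ValidationError
from .io_formats import DomainMap, ResidueID

logger = logging.getLogger(__name__)

# |gamma(15N)| / gamma(1H): converts a 1H field in MHz to the 15N frequency
GAMMA_RATIO_N15 = 0.1013756

# delay lists of the TROSY-based experiments (seconds)
DELAYS_R1 = (0.020, 0.300, 0.600)
DELAYS_R2 = (0.00865, 0.01696, 0.03392)

MIN_RATIO = 7.0 / 6.0


@dataclass
class DecaySeries:
    residue: ResidueID
    delays: np.ndarray
    intensities: np.ndarray
    noise_sigma: float
    experiment: str  # "R1" or "R2"

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.delays) != len(self.intensities) or len(self.delays) < 3:
            raise ValidationError("need >= 3 (delay, intensity) points")
        if np.any(np.diff(self.delays) <= 0):
            raise ValidationError("delays must be strictly increasing")
        if self.experiment not in ("R1", "R2"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")


@dataclass
class RateFit:
    rate: float
    sigma: float
    i0: float
    degenerate: bool = False


@dataclass
class RateRecord:
    residue: ResidueID
    r1: float
    r1_sigma: float
    r2: float
    r2_sigma: float
    exchange_flag: bool = False

    @property
    def ratio(self) -> float:
        return self.r2 / self.r1

    @property
    def ratio_sigma(self) -> float:
        return self.ratio * math.hypot(self.r1_sigma / self.r1,
                                       self.r2_sigma / self.r2)


@dataclass
class DomainDynamics:
    domain: str
    n_available: int
    n_used: int
    mean_ratio: float
    sd_ratio: float
    tauc_ns: float
    tauc_sigma_ns: float
    nu_n_hz: float


def fit_monoexponential(series: DecaySeries, n_mc: int = 200,
                        seed: int = 0) -> RateFit:
    """Fit I(t) = I0*exp(-R*t); sigma(R) from Monte-Carlo noise resampling.

    A two-parameter fit initialized from a log-linear regression over the
    positive points. Constant intensity series return rate 0 flagged
    degenerate. Individual non-positive intensities are tolerated (noise can
    push a late delay point below zero) as long as at least two points are
    positive; otherwise there is no decaying signal to fit.
    """
    t, y = series.delays, series.intensities
    pos = y > 0
    if pos.sum() < 2:
        raise FitError(f"residue {series.residue}: fewer than two positive "
                       "intensities")
    if np.allclose(y, y[0]):
        return RateFit(rate=0.0, sigma=0.0, i0=float(y[0]), degenerate=True)

    def model(t_, i0, r):
        return i0 * np.exp(-r * t_)

    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    p0 = (math.exp(intercept), max(-slope, 1e-9))

    def _fit(yy):
        popt, _ = curve_fit(model, t, yy, p0=p0, maxfev=10000)
        return popt

    try:
        i0, rate = _fit(y)
    except RuntimeError as exc:
        raise FitError(f"residue {series.residue}: {exc}") from exc
    degenerate = rate < 0
    rate = max(rate, 0.0)

    sigma = 0.0
    if series.noise_sigma > 0 and n_mc > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_mc):
            yy = y + rng.normal(0.0, series.noise_sigma, size=y.shape)
            try:
                draws.append(_fit(yy)[1])
            except RuntimeError:
                continue
        if len(draws) >= 10:
            sigma = float(np.std(draws, ddof=1))
        else:
            sigma = float("nan")
    return RateFit(rate=float(rate), sigma=sigma, i0=float(i0),
                   degenerate=degenerate)


def fit_rates(r1_series: Sequence[DecaySeries], r2_series: Sequence[DecaySeries],
              n_mc: int = 200, seed: int = 0) -> list[RateRecord]:
    """Fit paired R1/R2 series and assemble per-residue rate records."""
    r1_by = {s.residue.number: s for s in r1_series}
    r2_by = {s.residue.number: s for s in r2_series}
    records = []
    for num in sorted(set(r1_by) & set(r2_by)):
        f1 = fit_monoexponential(r1_by[num], n_mc=n_mc, seed=seed + 2 * num)
        f2 = fit_monoexponential(r2_by[num], n_mc=n_mc, seed=seed + 2 * num + 1)
        if f1.degenerate or f2.degenerate or f1.rate <= 0 or f2.rate <= 0:
            logger.warning("residue %d dropped: degenerate decay fit", num)
            continue
        records.append(
            RateRecord(residue=r1_by[num].residue, r1=f1.rate, r1_sigma=f1.sigma,
                       r2=f2.rate, r2_sigma=f2.sigma)
        )
    return records


def nu_n_from_field(nu_h_mhz: float, gamma_ratio: float = GAMMA_RATIO_N15) -> float:
    """15N resonance frequency in Hz from the 1H field in MHz."""
    return nu_h_mhz * 1e6 * gamma_ratio


def tauc_from_ratio(ratio: float, nu_h_mhz: float,
                    gamma_ratio: float = GAMMA_RATIO_N15) -> float:
    """Apparent rotational correlation time (ns) from an R2/R1 ratio."""
    if ratio < MIN_RATIO:
        raise ValidationError(
            f"R2/R1 = {ratio} < 7/6: outside the slow-tumbling expression's domain"
        )
    nu_n = nu_n_from_field(nu_h_mhz, gamma_ratio)
    tau_s = math.sqrt(6.0 * ratio - 7.0) / (4.0 * math.pi * nu_n)
    return tau_s * 1e9


def ratio_from_tauc(tauc_ns: float, nu_h_mhz: float,
                    gamma_ratio: float = GAMMA_RATIO_N15) -> float:
    """Algebraic inverse of :func:`tauc_from_ratio`."""
    if tauc_ns < 0:
        raise ValidationError("tau_c must be non-negative")
    nu_n = nu_n_from_field(nu_h_mhz, gamma_ratio)
    x = 4.0 * math.pi * nu_n * tauc_ns * 1e-9
    return (x * x + 7.0) / 6.0


def flag_exchange(records: Sequence[RateRecord], domains: DomainMap) -> None:
    """Flag residues with R2/R1 above (untrimmed) domain mean + 1 SD in place.

    High R2/R1 relative to the domain marks microsecond-millisecond
    conformational exchange contributions to R2.
    """
    for dom in domains:
        in_dom = [r for r in records if r.residue.number in dom]
        if len(in_dom) < 2:
            continue
        ratios = np.array([r.ratio for r in in_dom])
        cutoff = ratios.mean() + ratios.std(ddof=1)
        for r in in_dom:
            r.exchange_flag = r.ratio > cutoff


def _trim_one_sd(ratios: np.ndarray) -> np.ndarray:
    """Single-pass retention of values within 1 sample SD of the mean."""
    if len(ratios) < 2:
        return ratios
    mean, sd = ratios.mean(), ratios.std(ddof=1)
    return ratios[np.abs(ratios - mean) <= sd]


def domain_dynamics(records: Sequence[RateRecord], domains: DomainMap,
                    nu_h_mhz: float,
                    gamma_ratio: float = GAMMA_RATIO_N15) -> list[DomainDynamics]:
    """Trimmed per-domain R2/R1 and the apparent correlation time.

    Per domain: retain ratios within one SD of the mean (one pass), recompute
    the mean, convert to tau_c_app, and propagate the trimmed-ratio SD to
    sigma(tau_c) at first order. Domains with fewer than 2 usable records are
    skipped with a warning.
    """
    nu_n = nu_n_from_field(nu_h_mhz, gamma_ratio)
    out = []
    for dom in domains:
        ratios = np.array([r.ratio for r in records if r.residue.number in dom])
        if len(ratios) < 2:
            logger.warning("domain %s skipped: %d record(s)", dom.name, len(ratios))
            continue
        kept = _trim_one_sd(ratios)
        mean = float(kept.mean())
        sd = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
        if mean < MIN_RATIO:
            logger.warning("domain %s skipped: trimmed mean ratio %.2f < 7/6",
                           dom.name, mean)
            continue
        tauc = tauc_from_ratio(mean, nu_h_mhz, gamma_ratio)
        # d(tau)/d(ratio) = 3 / (4*pi*nuN*sqrt(6*ratio - 7)), in seconds
        dtau_dr = 3.0 / (4.0 * math.pi * nu_n * math.sqrt(6.0 * mean - 7.0))
        out.append(
            DomainDynamics(
                domain=dom.name, n_available=len(ratios), n_used=len(kept),
                mean_ratio=mean, sd_ratio=sd, tauc_ns=tauc,
                tauc_sigma_ns=dtau_dr * sd * 1e9, nu_n_hz=nu_n,
            )
        )
    return out


def write_decay_series(series: Sequence[DecaySeries], path) -> None:
    """Long-format CSV: one row per (residue, experiment, delay) point."""
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["residue", "aa", "experiment", "noise_sigma",
                    "delay_s", "intensity"])
        for s in series:
            for t, y in zip(s.delays, s.intensities):
                w.writerow([s.residue.number, s.residue.aa, s.experiment,
                            f"{s.noise_sigma:.6g}", f"{t:.6g}", f"{y:.6g}"])


def read_decay_series(path) -> list[DecaySeries]:
    """Read the long-format decay CSV written by :func:`write_decay_series`."""
    import csv as _csv

    groups: dict[tuple, dict] = {}
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            key = (int(row["residue"]), row["experiment"])
            g = groups.setdefault(
                key, {"aa": row["aa"], "noise": float(row["noise_sigma"]),
                      "t": [], "y": []}
            )
            g["t"].append(float(row["delay_s"]))
            g["y"].append(float(row["intensity"]))
    out = []
    for (num, exp), g in sorted(groups.items()):
        out.append(
            DecaySeries(ResidueID(number=num, aa=g["aa"]), np.array(g["t"]),
                        np.array(g["y"]), g["noise"], exp)
        )
    return out


def write_rate_records(records: Sequence[RateRecord], path) -> None:
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["residue", "aa", "r1", "r1_sigma", "r2", "r2_sigma",
                    "ratio", "ratio_sigma", "exchange_flag"])
        for r in records:
            w.writerow([r.residue.number, r.residue.aa,
                        f"{r.r1:.6g}", f"{r.r1_sigma:.6g}",
                        f"{r.r2:.6g}", f"{r.r2_sigma:.6g}",
                        f"{r.ratio:.6g}", f"{r.ratio_sigma:.6g}",
                        int(r.exchange_flag)])


def read_rate_records(path) -> list[RateRecord]:
    import csv as _csv

    out = []
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            rec = RateRecord(
                residue=ResidueID(number=int(row["residue"]), aa=row["aa"]),
                r1=float(row["r1"]), r1_sigma=float(row["r1_sigma"]),
                r2=float(row["r2"]), r2_sigma=float(row["r2_sigma"]),
                exchange_flag=bool(int(row.get("exchange_flag", 0))),
            )
            out.append(rec)
    return out


def compare_conditions(free: Sequence[RateRecord], bound: Sequence[RateRecord],
                       domain: str, domains: DomainMap,
                       min_n: int = 5) -> tuple[float, float, float]:
    """Welch's t-test on trimmed per-residue R2/R1 of one domain, free vs bound.

    Returns (difference of trimmed means: bound - free, t statistic, p value).
    """
    dom = next((d for d in domains if d.name == domain), None)
    if dom is None:
        raise ValidationError(f"unknown domain {domain!r}")
    a = np.array([r.ratio for r in free if r.residue.number in dom])
    b = np.array([r.ratio for r in bound if r.residue.number in dom])
    if len(a) < min_n or len(b) < min_n:
        raise InsufficientDataError(
            f"domain {domain}: need >= {min_n} records per condition "
            f"(got {len(a)} free, {len(b)} bound)"
        )
    a, b = _trim_one_sd(a), _trim_one_sd(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(b, a, equal_var=False)
    if math.isnan(p):  # both samples degenerate (zero variance, equal means)
        t, p = 0.0, 1.0
    return float(b.mean() - a.mean()), float(t), float(p)
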