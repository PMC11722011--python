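"""Chemical-shift-perturbation mapping and fast-exchange K_D fitting.

The combined perturbation per backbone amide is
``CSP = sqrt((ddN/10)^2 + ddH^2)`` and a residue is called significant when
its CSP exceeds the mean plus ``k`` standard deviations of the whole-protein
CSP set (k = 1 by default). In the fast-exchange regime the observed shift is
the population-weighted average of the free and bound positions, so a
titration traces a straight line whose fractional progress follows the exact
two-state (quadratic) binding isotherm — a necessity at millimolar K_D where
ligand depletion is not negligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, ValidationError
from .io_formats import DomainMap, Peak, PeakList, ResidueID

logger = logging.getLogger(__name__)

N15_SCALE = 10.0  # weighting divisor for the 15N dimension


@dataclass
class CSPRecord:
    residue: ResidueID
    d_h: float
    d_n: float
    csp: float
    significant: bool = False


@dataclass
class MatchResult:
    pairs: list[tuple[Peak, Peak]]
    only_in_a: list[ResidueID]
    only_in_b: list[ResidueID]
    excluded: list[ResidueID]  # overlapped in either list


@dataclass
class TitrationSeries:
    """Peak lists at strictly increasing ligand concentrations, first point free."""

    points: list[tuple[PeakList, float]]
    protein_conc: float

    def __post_init__(self):
        concs = [c for _, c in self.points]
        if concs and concs[0] != 0.0:
            raise ValidationError("first titration point must be ligand-free")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError("ligand concentrations must be strictly increasing")
        if self.protein_conc <= 0:
            raise ValidationError("protein concentration must be positive")


@dataclass
class BindingFit:
    kd: float
    kd_sigma: float
    ddmax: dict[int, float]  # residue number -> limiting combined shift (ppm)
    residuals: np.ndarray = field(repr=False, default=None)


def compute_csp(d_h: float, d_n: float) -> float:
    """Combined amide shift change: sqrt((d_n/10)^2 + d_h^2), in ppm."""
    if not (math.isfinite(d_h) and math.isfinite(d_n)):
        raise ValidationError("shift differences must be finite")
    return math.hypot(d_h, d_n / N15_SCALE)


def match_peaks(a: PeakList, b: PeakList, tol_h: float = 0.2,
                tol_n: float = 2.0) -> MatchResult:
    """Pair assigned peaks of two conditions by residue identity.

    Overlapped peaks on either side are excluded (and reported); residues
    present in only one list are reported, never fabricated. Pairs whose
    movement exceeds the stated tolerances are logged as suspicious but kept —
    in fast exchange large moves are real.
    """
    a_ok, b_ok = a.assigned(), b.assigned()
    a_all = a.assigned(statuses=("ok", "overlapped", "disappeared"))
    b_all = b.assigned(statuses=("ok", "overlapped", "disappeared"))
    pairs, excluded = [], []
    for num in sorted(set(a_all) & set(b_all)):
        pa, pb = a_all[num], b_all[num]
        if pa.status == "overlapped" or pb.status == "overlapped":
            excluded.append(pa.assignment or pb.assignment)
            logger.info("residue %d excluded from matching (overlapped)", num)
            continue
        pairs.append((pa, pb))
        if pa.status == pb.status == "ok" and (
            abs(pa.h_ppm - pb.h_ppm) > tol_h or abs(pa.n_ppm - pb.n_ppm) > tol_n
        ):
            logger.warning("residue %d moved beyond matching tolerance", num)
    only_a = [a_all[n].assignment for n in sorted(set(a_all) - set(b_all))]
    only_b = [b_all[n].assignment for n in sorted(set(b_all) - set(a_all))]
    return MatchResult(pairs=pairs, only_in_a=only_a, only_in_b=only_b,
                       excluded=excluded)


def significance_threshold(records: Sequence[CSPRecord], k: float = 1.0) -> float:
    """mean + k*SD of the CSP set; sets each record's ``significant`` flag.

    The statistics are taken over the whole matched, non-overlapped residue
    set (one threshold per comparison) using the population SD.
    """
    if len(records) < 3:
        raise InsufficientDataError(
            f"need >= 3 CSP records for a threshold, got {len(records)}"
        )
    csps = np.array([r.csp for r in records], dtype=float)
    thr = float(csps.mean() + k * csps.std(ddof=0))
    for r in records:
        r.significant = r.csp > thr
    return thr


def csp_profile(free: PeakList, bound: PeakList,
                domains: Optional[DomainMap] = None, k: float = 1.0):
    """Per-residue CSP records between two conditions plus a per-domain summary.

    Returns ``(records, threshold, summary)`` where summary maps domain name to
    the sorted significant residue numbers in it.
    """
    match = match_peaks(free, bound)
    records = []
    for pf, pb in match.pairs:
        if pf.status != "ok" or pb.status != "ok":
            continue  # disappeared peaks carry no shift information
        d_h = pb.h_ppm - pf.h_ppm
        d_n = pb.n_ppm - pf.n_ppm
        records.append(
            CSPRecord(residue=pf.assignment, d_h=d_h, d_n=d_n,
                      csp=compute_csp(d_h, d_n))
        )
    threshold = significance_threshold(records, k=k)
    summary: dict[str, list[int]] = {}
    if domains is not None:
        for r in records:
            if not r.significant:
                continue
            name = domains.domain_of(r.residue.number) or "unmapped"
            summary.setdefault(name, []).append(r.residue.number)
        for v in summary.values():
            v.sort()
    return records, threshold, summary


def fraction_bound(p_total: float, l_total: float, kd: float) -> float:
    """Exact two-state bound fraction of the protein from the quadratic isotherm.

    f = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 P)
    """
    s = p_total + l_total + kd
    disc = s * s - 4.0 * p_total * l_total
    # conjugate form of the quadratic root: no cancellation as P -> 0
    return 2.0 * l_total / (s + math.sqrt(max(disc, 0.0)))


def fit_kd_fast_exchange(series: TitrationSeries,
                         min_total_shift: float = 1e-6) -> BindingFit:
    """Global (shared-K_D) fit of a fast-exchange titration.

    The observed per-residue combined shift at each point is modelled as
    ``f_bound(P, L, Kd) * ddmax_residue``. All residues whose total movement
    exceeds ``min_total_shift`` share one K_D; the limiting shifts are free
    per-residue amplitudes. K_D uncertainty is the asymptotic (Jacobian-based)
    standard error.
    """
    if len(series.points) < 4:
        raise InsufficientDataError("need >= 4 titration points")
    free_list = series.points[0][0]
    concs = np.array([c for _, c in series.points])
    free_peaks = free_list.assigned()

    # observed combined shift (relative to the free point) per residue/point
    obs: dict[int, np.ndarray] = {}
    for num, p0 in free_peaks.items():
        y = [0.0]
        complete = True
        for plist, _ in series.points[1:]:
            pk = plist.assigned().get(num)
            if pk is None:
                complete = False
                break
            y.append(compute_csp(pk.h_ppm - p0.h_ppm, pk.n_ppm - p0.n_ppm))
        if complete:
            obs[num] = np.asarray(y)
    movers = {n: y for n, y in obs.items() if y.max() > min_total_shift}
    if not movers:
        raise FitError("no residue moves during the titration; K_D unidentifiable")

    nums = sorted(movers)
    Y = np.stack([movers[n] for n in nums])  # (n_res, n_points)
    P = series.protein_conc

    def fractions(kd):
        return np.array([fraction_bound(P, L, kd) for L in concs])

    def residuals(x):
        kd = math.exp(x[0])
        f = fractions(kd)
        dd = x[1:]
        return (dd[:, None] * f[None, :] - Y).ravel()

    # initialize ddmax from the last point assuming ~60% saturation, kd ~ P
    x0 = np.concatenate([[math.log(P)], Y[:, -1] / 0.6])
    sol = least_squares(residuals, x0, method="lm", max_nfev=20000)
    if not sol.success:
        raise FitError("K_D fit did not converge", residuals=sol.fun)
    kd = math.exp(sol.x[0])

    # asymptotic covariance from the Jacobian at the solution
    dof = max(Y.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        kd_sigma = kd * math.sqrt(max(cov[0, 0], 0.0))  # delta method on log Kd
    except np.linalg.LinAlgError:
        raise FitError("singular Jacobian; K_D unidentifiable", residuals=sol.fun)
    if not math.isfinite(kd_sigma):
        kd_sigma = float("inf")
    ddmax = {n: float(d) for n, d in zip(nums, sol.x[1:])}
    return BindingFit(kd=kd, kd_sigma=kd_sigma, ddmax=ddmax, residuals=sol.fun)
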