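"""Paramagnetic relaxation enhancement: normalization, distance calibration,
docking restraints and site classification.

The raw observable is the intensity ratio Ipara/Idia of each backbone amide
between spectra acquired with the spin label oxidized (paramagnetic) and
reduced (diamagnetic). Because differential longitudinal relaxation during
the recycle delay can push raw ratios above one, a dataset-wide correction
factor alpha rescales them so that residues far from the paramagnetic
center average to PRE = 1. Calibration to distance is linear between 12 and
30 A: PRE = 0 means the amide is closer than 12 A (signal broadened away),
PRE >= 1 means farther than 30 A.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (ConfigurationError, NormalizationError, ValidationError)
from .io_formats import DistanceRestraint, DomainMap, PeakList, ResidueID

logger = logging.getLogger(__name__)

# linear calibration window (Angstrom)
D_MIN = 12.0
D_MAX = 30.0
D_CONTACT = 1.8          # van der Waals lower bound for a vanished peak
UPPER_PAD = 3.0          # slack added to d_calc for the restraint upper bound
PRE_UNRESTRAINED = 0.8   # at or above this, no restraint is generated

# region-specific significance cutoffs for full-length Sis1 site mapping:
# flexible N-terminal half vs the more compact C-terminal half
DEFAULT_PRE_CUTOFFS = [(1, 182, 0.88), (183, 352, 0.70)]


@dataclass
class PRERecord:
    residue: ResidueID
    i_para: float
    i_dia: float
    raw_ratio: float = None
    pre: Optional[float] = None
    in_reference: bool = False
    status: str = "ok"

    def __post_init__(self):
        if self.status == "ok" and self.i_dia <= 0:
            raise ValidationError(
                f"residue {self.residue}: diamagnetic intensity must be positive"
            )
        if self.raw_ratio is None:
            self.raw_ratio = 0.0 if self.status == "disappeared" else (
                self.i_para / self.i_dia
            )


def records_from_peaklists(para: PeakList, dia: PeakList) -> list[PRERecord]:
    """Pair paramagnetic/diamagnetic lists by assignment into PRE records.

    Overlapped peaks in either list are excluded. A peak present in the
    diamagnetic list but disappeared in the paramagnetic one gets
    raw_ratio = 0 (complete broadening).
    """
    dia_ok = dia.assigned()
    para_all = para.assigned(statuses=("ok", "disappeared"))
    out = []
    for num in sorted(set(dia_ok) & set(para_all)):
        pd, pp = dia_ok[num], para_all[num]
        status = "disappeared" if pp.status == "disappeared" else "ok"
        out.append(
            PRERecord(residue=pd.assignment, i_para=pp.intensity,
                      i_dia=pd.intensity, status=status)
        )
    return out


def _auto_reference(records: Sequence[PRERecord], passes: int = 2,
                    clip: float = 0.8) -> list[PRERecord]:
    """Iterative sigma-clipping stand-in for "residues distant from the label".

    Starting from all ok-status records, drop those whose raw ratio falls below
    ``clip`` times the current mean, twice. The survivors approximate the
    unaffected (distant) residues without needing a structure.
    """
    ref = [r for r in records if r.status == "ok"]
    for _ in range(passes):
        if not ref:
            break
        mean = float(np.mean([r.raw_ratio for r in ref]))
        ref = [r for r in ref if r.raw_ratio >= clip * mean]
    return ref


def normalize_pre(records: Sequence[PRERecord],
                  reference: "str | Iterable[int]" = "auto"):
    """Scale raw ratios so the reference set averages exactly PRE = 1.

    Returns ``(alpha, records)`` with ``pre = alpha * raw_ratio`` on every
    record and ``in_reference`` set on the reference residues. ``reference``
    is either ``"auto"`` (iterative clipping, see above) or an explicit set of
    residue numbers, all of which must be present.
    """
    records = list(records)
    if len(records) < 5:
        raise NormalizationError(f"need >= 5 PRE records, got {len(records)}")
    if reference == "auto":
        ref = _auto_reference(records)
    else:
        wanted = set(reference)
        by_num = {r.residue.number: r for r in records}
        missing = sorted(wanted - set(by_num))
        if missing:
            raise NormalizationError(f"reference residues missing from data: {missing}")
        ref = [by_num[n] for n in sorted(wanted)]
    if not ref:
        raise NormalizationError("empty reference set after selection")
    mean_raw = float(np.mean([r.raw_ratio for r in ref]))
    if mean_raw <= 0:
        raise NormalizationError("reference mean raw ratio is non-positive")
    alpha = 1.0 / mean_raw
    ref_ids = {id(r) for r in ref}
    for r in records:
        r.pre = alpha * r.raw_ratio
        r.in_reference = id(r) in ref_ids
    logger.info("PRE normalization: alpha = %.4f over %d reference residues",
                alpha, len(ref))
    return alpha, records


def pre_to_distance(pre: float) -> float:
    """Linear PRE->distance calibration, d = 12 + 18*min(pre, 1) Angstrom."""
    if pre < 0 or not math.isfinite(pre):
        raise ValidationError(f"PRE must be non-negative and finite, got {pre}")
    return D_MIN + (D_MAX - D_MIN) * min(pre, 1.0)


def distance_to_pre(d: float) -> float:
    """Inverse calibration on [12, 30] A, clamped outside."""
    return min(max((d - D_MIN) / (D_MAX - D_MIN), 0.0), 1.0)


def restraint_from_pre(record: PRERecord,
                       label_site: tuple[ResidueID, str],
                       amide_atom: str = "H") -> Optional[DistanceRestraint]:
    """Semiquantitative docking restraint from one normalized PRE value.

    Vanished peak or PRE = 0 -> [1.8, 12] A; 0 < PRE < 0.8 ->
    [12, d_calc + 3] A; PRE >= 0.8 -> no restraint (too weak to place).
    """
    if record.pre is None:
        raise ValidationError("record must be normalized before restraint generation")
    pre = record.pre
    if record.status == "disappeared" or pre == 0.0:
        lower, upper = D_CONTACT, D_MIN
    elif pre < PRE_UNRESTRAINED:
        lower, upper = D_MIN, pre_to_distance(pre) + UPPER_PAD
    else:
        return None
    return DistanceRestraint(
        site_a=label_site,
        site_b=(record.residue, amide_atom),
        lower=lower,
        upper=upper,
        source_pre=pre,
    )


def restraints_from_records(records: Sequence[PRERecord],
                            label_site: tuple[ResidueID, str],
                            amide_atom: str = "H") -> list[DistanceRestraint]:
    out = []
    for r in records:
        restraint = restraint_from_pre(r, label_site, amide_atom=amide_atom)
        if restraint is not None:
            out.append(restraint)
    return out


def classify_pre_sites(records: Sequence[PRERecord],
                       cutoffs: Sequence[tuple[int, int, float]] = None,
                       domains: Optional[DomainMap] = None):
    """Residues whose PRE falls strictly below the region cutoff containing them.

    ``cutoffs`` is a list of (start, end, cutoff) residue ranges covering the
    sequence; defaults to the full-length Sis1 values 0.88 (1-182) / 0.70
    (183-352). Returns the flagged residue-number set, or a dict grouped by
    domain if a DomainMap is given.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_PRE_CUTOFFS
    flagged = set()
    for r in records:
        if r.pre is None:
            raise ValidationError("records must be normalized before classification")
        num = r.residue.number
        for start, end, cut in cutoffs:
            if start <= num <= end:
                if r.pre < cut:
                    flagged.add(num)
                break
        else:
            raise ConfigurationError(
                f"residue {num} is outside every PRE cutoff range"
            )
    if domains is None:
        return flagged
    grouped: dict[str, list[int]] = {}
    for num in sorted(flagged):
        grouped.setdefault(domains.domain_of(num) or "unmapped", []).append(num)
    return grouped
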