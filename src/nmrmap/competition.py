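"""Binding-site competition classification across three titration conditions.

Given peak lists for the free protein, protein + client, and
protein + client + competitor, each matched residue is classified:

* ``broadened``   — peak present in the free spectrum but disappeared in a
  ligand condition (exchange broadening; carries no shift information).
* ``none``        — client-induced CSP below the significance threshold.
* ``competitive`` — significant client CSP that grows further when the
  competitor is added (the competitor keeps pulling the population at the
  same site).
* ``client_only`` — significant client CSP that does not grow.

The significance threshold is the mean + k*SD of the client-vs-free CSP set,
the same rule used for single-ligand mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .csp import compute_csp, match_peaks, significance_threshold, CSPRecord
from .errors import ValidationError
from .io_formats import DomainMap, PeakList, ResidueID

CLASSES = ("none", "client_only", "competitive", "broadened")


@dataclass
class CompetitionRecord:
    residue: ResidueID
    csp_client: Optional[float]
    csp_both: Optional[float]
    klass: str

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValidationError(f"unknown class {self.klass!r}")


def competition_profile(free: PeakList, plus_client: PeakList,
                        plus_both: PeakList, domains: Optional[DomainMap] = None,
                        k: float = 1.0, margin: float = 0.0):
    """Classify every matched residue; returns (records, threshold, summary).

    ``margin`` (ppm) is the excess csp_both must show over csp_client to call
    competition; 0 by default (strict inequality). The summary groups
    competitive residues by domain when a DomainMap is given.
    """
    if free is None or plus_client is None or plus_both is None:
        raise ValidationError("all three conditions are required")
    free_ok = free.assigned()
    client_all = plus_client.assigned(statuses=("ok", "disappeared"))
    both_all = plus_both.assigned(statuses=("ok", "disappeared"))

    # threshold from the client-vs-free comparison over shift-bearing residues
    csp_client: dict[int, float] = {}
    for num, p0 in free_ok.items():
        pc = client_all.get(num)
        if pc is not None and pc.status == "ok":
            csp_client[num] = compute_csp(pc.h_ppm - p0.h_ppm, pc.n_ppm - p0.n_ppm)
    client_records = [
        CSPRecord(residue=free_ok[n].assignment, d_h=0.0, d_n=0.0, csp=v)
        for n, v in csp_client.items()
    ]
    threshold = significance_threshold(client_records, k=k)

    records = []
    for num in sorted(set(free_ok) & set(client_all) & set(both_all)):
        p0, pc, pb = free_ok[num], client_all[num], both_all[num]
        rid = p0.assignment
        if pc.status == "disappeared" or pb.status == "disappeared":
            cc = csp_client.get(num)
            records.append(CompetitionRecord(rid, cc, None, "broadened"))
            continue
        cc = csp_client[num]
        cb = compute_csp(pb.h_ppm - p0.h_ppm, pb.n_ppm - p0.n_ppm)
        if cc <= threshold:
            klass = "none"
        elif cb > cc + margin:
            klass = "competitive"
        else:
            klass = "client_only"
        records.append(CompetitionRecord(rid, cc, cb, klass))

    summary: dict[str, list[int]] = {}
    if domains is not None:
        for r in records:
            if r.klass == "competitive":
                name = domains.domain_of(r.residue.number) or "unmapped"
                summary.setdefault(name, []).append(r.residue.number)
        for v in summary.values():
            v.sort()
    return records, threshold, summary
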