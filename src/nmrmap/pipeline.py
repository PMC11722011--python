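"""End-to-end pipeline: wire the analysis stages from a single YAML config.

The pipeline covers the three analyses of the study design: ligand mapping
(CSP + significance), spin-label mapping (PRE normalization, site
classification, docking restraints), interdomain dynamics (R1/R2 fitting,
per-domain tau_c, free-vs-bound comparison), and three-condition competition
classification. Every threshold, alpha, trimmed count and exclusion is logged
so flag decisions can be re-derived from the run log.
"""

from __future__ import annotations

import csv as _csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import competition as _competition
from . import csp as _csp
from . import pre as _pre
from . import relaxation as _relax
from .errors import ValidationError
from .io_formats import (DomainMap, ResidueID, SIS1_DOMAINS, read_peaklist,
                         write_restraint_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    domains: Optional[str] = None      # YAML path; None -> Sis1 architecture
    field_h_mhz: float = 900.0
    seed: int = 0
    csp_k: float = 1.0
    dialect: str = "csv"
    csp: dict = field(default_factory=dict)          # {free, bound}
    pre: dict = field(default_factory=dict)          # {para, dia, label_residue,
    #                                                   cutoffs, reference}
    relax: dict = field(default_factory=dict)        # {series, series_bound,
    #                                                   compare_domain}
    competition: dict = field(default_factory=dict)  # {free, client, both}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def validate(self) -> None:
        if self.csp_k <= 0:
            raise ValidationError("csp_k must be positive")
        paths = [self.domains] if self.domains else []
        paths += [self.csp.get("free"), self.csp.get("bound"),
                  self.pre.get("para"), self.pre.get("dia"),
                  self.relax.get("series"), self.relax.get("series_bound"),
                  self.competition.get("free"), self.competition.get("client"),
                  self.competition.get("both")]
        missing = [p for p in paths if p and not Path(p).is_file()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    def domain_map(self) -> DomainMap:
        return DomainMap.from_yaml(self.domains) if self.domains else SIS1_DOMAINS


def _write_csp_csv(records, path):
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["residue", "aa", "d_h", "d_n", "csp", "significant"])
        for r in records:
            w.writerow([r.residue.number, r.residue.aa, f"{r.d_h:.4f}",
                        f"{r.d_n:.4f}", f"{r.csp:.5f}", int(r.significant)])


def _write_pre_csv(records, alpha, path):
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["residue", "aa", "i_para", "i_dia", "raw_ratio", "pre",
                    "in_reference", "status", "alpha"])
        for r in records:
            w.writerow([r.residue.number, r.residue.aa, f"{r.i_para:.6g}",
                        f"{r.i_dia:.6g}", f"{r.raw_ratio:.5f}",
                        f"{r.pre:.5f}", int(r.in_reference), r.status,
                        f"{alpha:.5f}"])


def _write_domain_csv(dyn, path):
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["domain", "n_available", "n_used", "mean_ratio", "sd_ratio",
                    "tauc_ns", "tauc_sigma_ns"])
        for d in dyn:
            w.writerow([d.domain, d.n_available, d.n_used,
                        f"{d.mean_ratio:.3f}", f"{d.sd_ratio:.3f}",
                        f"{d.tauc_ns:.3f}", f"{d.tauc_sigma_ns:.3f}"])


def _write_competition_csv(records, path):
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["residue", "aa", "csp_client", "csp_both", "class"])
        for r in records:
            w.writerow([
                r.residue.number, r.residue.aa,
                "" if r.csp_client is None else f"{r.csp_client:.5f}",
                "" if r.csp_both is None else f"{r.csp_both:.5f}",
                r.klass,
            ])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns {stage: output path(s)}.

    Deterministic given the config and seed; aborts on the first stage error
    with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    domains = config.domain_map()
    produced: dict = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("nmrmap")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        if config.csp:
            _run_stage("csp", _stage_csp, config, domains, out, produced)
        if config.pre:
            _run_stage("pre", _stage_pre, config, domains, out, produced)
        if config.relax:
            _run_stage("relax", _stage_relax, config, domains, out, produced)
        if config.competition:
            _run_stage("competition", _stage_competition, config, domains, out,
                       produced)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    produced["log"] = str(log_path)
    return produced


def _run_stage(name, fn, config, domains, out, produced):
    try:
        produced[name] = fn(config, domains, out)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def _stage_csp(config, domains, out):
    free = read_peaklist(config.csp["free"], dialect=config.dialect)
    bound = read_peaklist(config.csp["bound"], dialect=config.dialect)
    records, threshold, summary = _csp.csp_profile(free, bound, domains,
                                                   k=config.csp_k)
    logger.info("csp: threshold = %.5f ppm over %d residues (k=%.2f)",
                threshold, len(records), config.csp_k)
    logger.info("csp: significant residues by domain: %s", summary)
    path = out / "csp.csv"
    _write_csp_csv(records, path)
    return str(path)


def _stage_pre(config, domains, out):
    para = read_peaklist(config.pre["para"], dialect=config.dialect)
    dia = read_peaklist(config.pre["dia"], dialect=config.dialect)
    records = _pre.records_from_peaklists(para, dia)
    reference = config.pre.get("reference", "auto")
    alpha, records = _pre.normalize_pre(records, reference=reference)
    logger.info("pre: alpha = %.4f, %d records", alpha, len(records))
    cutoffs = [tuple(c) for c in config.pre.get("cutoffs", [])] or None
    flagged = _pre.classify_pre_sites(records, cutoffs=cutoffs, domains=domains)
    logger.info("pre: affected residues by domain: %s", flagged)
    label_res = int(config.pre.get("label_residue", 1))
    label_site = (ResidueID(number=label_res), config.pre.get("label_atom", "N"))
    restraints = _pre.restraints_from_records(records, label_site)
    csv_path = out / "pre.csv"
    _write_pre_csv(records, alpha, csv_path)
    outputs = {"csv": str(csv_path)}
    if restraints:
        tbl_path = out / "restraints.tbl"
        write_restraint_table(restraints, tbl_path, dialect="cns_tbl")
        outputs["tbl"] = str(tbl_path)
        logger.info("pre: %d restraints written", len(restraints))
    return outputs


def _stage_relax(config, domains, out):
    series = _relax.read_decay_series(config.relax["series"])
    r1 = [s for s in series if s.experiment == "R1"]
    r2 = [s for s in series if s.experiment == "R2"]
    records = _relax.fit_rates(r1, r2, seed=config.seed)
    _relax.flag_exchange(records, domains)
    dyn = _relax.domain_dynamics(records, domains, config.field_h_mhz)
    for d in dyn:
        logger.info("relax: %s n=%d/%d ratio=%.2f+-%.2f tauc=%.2f+-%.2f ns",
                    d.domain, d.n_used, d.n_available, d.mean_ratio,
                    d.sd_ratio, d.tauc_ns, d.tauc_sigma_ns)
    rates_path = out / "rates.csv"
    _relax.write_rate_records(records, rates_path)
    dyn_path = out / "domain_dynamics.csv"
    _write_domain_csv(dyn, dyn_path)
    outputs = {"rates": str(rates_path), "domains": str(dyn_path)}

    if config.relax.get("series_bound"):
        series_b = _relax.read_decay_series(config.relax["series_bound"])
        rec_b = _relax.fit_rates([s for s in series_b if s.experiment == "R1"],
                                 [s for s in series_b if s.experiment == "R2"],
                                 seed=config.seed)
        rows = []
        for dom in domains:
            try:
                delta, t, p = _relax.compare_conditions(records, rec_b,
                                                        dom.name, domains)
            except Exception as exc:  # insufficient n in small test sets
                logger.info("relax-compare: %s skipped (%s)", dom.name, exc)
                continue
            rows.append((dom.name, delta, t, p))
            logger.info("relax-compare: %s delta=%.3f t=%.3f p=%.4f",
                        dom.name, delta, t, p)
        cmp_path = out / "compare.csv"
        with open(cmp_path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["domain", "delta_mean_ratio", "t", "p"])
            for name, delta, t, p in rows:
                w.writerow([name, f"{delta:.4f}", f"{t:.4f}", f"{p:.6g}"])
        outputs["compare"] = str(cmp_path)
    return outputs


def _stage_competition(config, domains, out):
    free = read_peaklist(config.competition["free"], dialect=config.dialect)
    client = read_peaklist(config.competition["client"], dialect=config.dialect)
    both = read_peaklist(config.competition["both"], dialect=config.dialect)
    records, threshold, summary = _competition.competition_profile(
        free, client, both, domains, k=config.csp_k,
        margin=float(config.competition.get("margin", 0.0)))
    logger.info("competition: threshold = %.5f ppm; competitive by domain: %s",
                threshold, summary)
    path = out / "competition.csv"
    _write_competition_csv(records, path)
    return str(path)
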