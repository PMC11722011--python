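"""Readers and writers for peak lists, coordinates and restraint tables.

Every other module consumes only the domain types defined here: assigned
2D 1H-15N peak lists (Sparky text or headered CSV), PDB coordinate models,
a residue->domain map, and CNS-style distance-restraint tables. Residue
numbering is 1-based and ranges are inclusive throughout.
"""

from __future__ import annotations

import csv as _csv
import io
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .errors import EmptyStructureError, ValidationError

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

PEAK_STATUSES = ("ok", "overlapped", "disappeared")


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue in 1-based sequence numbering with a one-letter code."""

    number: int
    aa: str = "X"
    chain: str = "A"

    def __post_init__(self):
        if self.number < 1:
            raise ValidationError(f"residue number must be >= 1, got {self.number}")
        if self.aa not in AA_ALPHABET:
            raise ValidationError(f"unknown one-letter code {self.aa!r}")

    def __str__(self):
        return f"{self.aa}{self.number}"


@dataclass
class Peak:
    """One backbone amide cross-peak of a 2D 1H-15N correlation spectrum."""

    h_ppm: float
    n_ppm: float
    intensity: float
    assignment: Optional[ResidueID] = None
    status: str = "ok"

    def __post_init__(self):
        if self.status not in PEAK_STATUSES:
            raise ValidationError(f"unknown peak status {self.status!r}")
        if self.status == "disappeared":
            # broadened-out peaks contribute zero signal to intensity ratios
            self.intensity = 0.0
        if not _finite(self.intensity):
            raise ValidationError("peak intensity must be finite")


@dataclass
class PeakList:
    """An assigned peak list for one sample condition."""

    label: str
    peaks: list[Peak] = field(default_factory=list)
    condition: dict = field(default_factory=dict)
    field_h_mhz: Optional[float] = None
    temperature_k: Optional[float] = None

    def __post_init__(self):
        seen = {}
        for p in self.peaks:
            if p.assignment is None or p.status != "ok":
                continue
            key = (p.assignment.chain, p.assignment.number)
            if key in seen:
                raise ValidationError(
                    f"duplicate assignment for residue {p.assignment}"
                )
            seen[key] = p

    def assigned(self, statuses: Sequence[str] = ("ok",)) -> dict[int, Peak]:
        """Map residue number -> peak for assigned peaks with the given statuses."""
        return {
            p.assignment.number: p
            for p in self.peaks
            if p.assignment is not None and p.status in statuses
        }


@dataclass(frozen=True)
class DomainRange:
    name: str
    start: int
    end: int

    def __contains__(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end


class DomainMap:
    """Ordered, non-overlapping residue ranges naming the protein's domains."""

    def __init__(self, ranges: Iterable[tuple[str, int, int]]):
        self.ranges = [DomainRange(n, s, e) for n, s, e in ranges]
        prev_end = 0
        for r in self.ranges:
            if r.start > r.end:
                raise ValidationError(f"domain {r.name}: start {r.start} > end {r.end}")
            if r.start <= prev_end:
                raise ValidationError(
                    f"domain {r.name} overlaps or is out of order (starts at {r.start})"
                )
            prev_end = r.end

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self):
        return len(self.ranges)

    def domain_of(self, resnum: int) -> Optional[str]:
        for r in self.ranges:
            if resnum in r:
                return r.name
        return None

    @classmethod
    def from_yaml(cls, path) -> "DomainMap":
        doc = yaml.safe_load(Path(path).read_text())
        items = doc["domains"] if isinstance(doc, dict) else doc
        return cls((d["name"], int(d["start"]), int(d["end"])) for d in items)

    def to_yaml(self, path) -> None:
        doc = {
            "domains": [
                {"name": r.name, "start": r.start, "end": r.end} for r in self.ranges
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# Sis1 (UniProt P25294) domain architecture used throughout the analyses.
SIS1_DOMAINS = DomainMap(
    [
        ("J-domain", 1, 72),
        ("GF", 73, 121),
        ("GM", 122, 178),
        ("CTDI", 179, 257),
        ("CTDII", 258, 335),
        ("DD", 336, 352),
    ]
)


@dataclass
class StructureModel:
    """One coordinate model: (residue, atom name, x, y, z) in Angstrom."""

    model_index: int
    atoms: list[tuple[ResidueID, str, float, float, float]]

    def coords(self, residues: Optional[range] = None, atom_name: str = "CA"):
        """Ordered (resnum, xyz) for the selection; sorted by residue number."""
        out = []
        for rid, name, x, y, z in self.atoms:
            if name != atom_name:
                continue
            if residues is not None and rid.number not in residues:
                continue
            out.append((rid.number, (x, y, z)))
        out.sort(key=lambda t: t[0])
        return out


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

_SPARKY_ASSIGN = re.compile(r"^([A-Z])(\d+)N-?H?N?$", re.IGNORECASE)

_CSV_COLUMNS = ("residue", "aa", "h_ppm", "n_ppm", "intensity", "status")


def _finite(x) -> bool:
    try:
        return x == x and abs(x) != float("inf")
    except TypeError:
        return False


def _parse_sparky_assignment(token: str) -> Optional[ResidueID]:
    m = _SPARKY_ASSIGN.match(token.strip())
    if not m:
        return None
    aa = m.group(1).upper()
    if aa not in AA_ALPHABET:
        return None
    return ResidueID(number=int(m.group(2)), aa=aa)


def read_peaklist(path, dialect: str = "csv", label: Optional[str] = None) -> PeakList:
    """Read an assigned peak list.

    Sparky dialect: whitespace columns ``assignment w1 w2 height`` with w1 the
    15N shift and w2 the 1H shift. CSV dialect: headered columns
    ``residue, aa, h_ppm, n_ppm, intensity[, status]``. Rows whose assignment
    cannot be parsed become unassigned peaks and are logged; a residue assigned
    twice raises a validation error naming it.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"peak list not found: {path}")
    text = path.read_text()
    label = label or path.stem
    if dialect == "sparky":
        peaks = _parse_sparky(text, str(path))
    elif dialect == "csv":
        peaks = _parse_peak_csv(text, str(path))
    else:
        raise ValidationError(f"unknown peak-list dialect {dialect!r}")
    return PeakList(label=label, peaks=peaks)


def _parse_sparky(text: str, source: str) -> list[Peak]:
    peaks = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            logger.warning("%s:%d: short row rejected: %r", source, lineno, line)
            continue
        assignment = _parse_sparky_assignment(parts[0])
        if assignment is None:
            logger.warning(
                "%s:%d: unparsable assignment %r -> unassigned peak",
                source, lineno, parts[0],
            )
        try:
            n_ppm = float(parts[1])
            h_ppm = float(parts[2])
            intensity = float(parts[3]) if len(parts) > 3 else 0.0
        except ValueError:
            logger.warning("%s:%d: non-numeric row rejected: %r", source, lineno, line)
            continue
        peaks.append(Peak(h_ppm=h_ppm, n_ppm=n_ppm, intensity=intensity,
                          assignment=assignment))
    return peaks


def _parse_peak_csv(text: str, source: str) -> list[Peak]:
    reader = _csv.DictReader(io.StringIO(text))
    missing = [c for c in _CSV_COLUMNS[:5] if c not in (reader.fieldnames or ())]
    if missing:
        raise ValidationError(f"{source}: missing CSV columns {missing}")
    peaks = []
    for lineno, row in enumerate(reader, start=2):
        try:
            number = int(row["residue"])
            aa = (row["aa"] or "X").strip().upper()
            assignment = ResidueID(number=number, aa=aa)
        except (ValueError, ValidationError):
            assignment = None
            logger.warning("%s:%d: unparsable assignment -> unassigned", source, lineno)
        status = (row.get("status") or "ok").strip() or "ok"
        peaks.append(
            Peak(
                h_ppm=float(row["h_ppm"]),
                n_ppm=float(row["n_ppm"]),
                intensity=float(row["intensity"]),
                assignment=assignment,
                status=status,
            )
        )
    return peaks


def write_peaklist(peaklist: PeakList, path) -> None:
    """Write the CSV dialect; ppm to 3 decimals, intensities to 6 significant digits."""
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for p in peaklist.peaks:
            rid = p.assignment
            w.writerow(
                [
                    rid.number if rid else "",
                    rid.aa if rid else "X",
                    f"{p.h_ppm:.3f}",
                    f"{p.n_ppm:.3f}",
                    f"{p.intensity:.6g}",
                    p.status,
                ]
            )


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def read_pdb_models(path, chain: Optional[str] = None) -> list[StructureModel]:
    """Parse all models of a PDB file into StructureModel objects.

    Only ATOM records are retained. By default the first chain of each model
    is used (the deposited J-domain structures are single-chain); pass
    ``chain`` to select another. Raises if no ATOM record survives.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    models = []
    for i, model in enumerate(structure, start=1):
        chains = list(model)
        if not chains:
            continue
        if chain is None:
            sel = chains[0]
        else:
            matches = [c for c in chains if c.id == chain]
            if not matches:
                continue
            sel = matches[0]
        atoms = []
        for residue in sel:
            hetflag, resseq, _icode = residue.id
            if hetflag != " ":  # skip HETATM and waters
                continue
            aa = _THREE_TO_ONE.get(residue.get_resname().strip(), "X")
            rid = ResidueID(number=resseq, aa=aa, chain=sel.id if sel.id.strip() else "A")
            for atom in residue:
                x, y, z = atom.coord
                atoms.append((rid, atom.get_name(), float(x), float(y), float(z)))
        if atoms:
            models.append(StructureModel(model_index=i, atoms=atoms))
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return models


# ---------------------------------------------------------------------------
# distance restraints
# ---------------------------------------------------------------------------


@dataclass
class DistanceRestraint:
    """A semiquantitative docking restraint between the spin-label site and an amide.

    Bounds are in Angstrom and must lie within the calibrated window
    [1.8, 33.0] (van der Waals contact up to the longest derivable upper
    bound, 30 + 3 A).
    """

    site_a: tuple[ResidueID, str]
    site_b: tuple[ResidueID, str]
    lower: float
    upper: float
    source_pre: Optional[float] = None

    def __post_init__(self):
        if not (1.8 <= self.lower <= self.upper <= 33.0):
            raise ValidationError(
                f"restraint bounds [{self.lower}, {self.upper}] violate "
                "1.8 <= lower <= upper <= 33.0"
            )


def write_restraint_table(restraints: Sequence[DistanceRestraint], path,
                          dialect: str = "cns_tbl") -> None:
    """Write restraints as CNS assign statements or as an explicit-bounds CSV."""
    restraints = list(restraints)
    if not restraints:
        raise ValidationError("refusing to write an empty restraint table")
    if dialect == "cns_tbl":
        lines = []
        for r in restraints:
            d = r.lower
            dplus = r.upper - r.lower
            lines.append(
                f"assign (resid {r.site_a[0].number} and name {r.site_a[1]}) "
                f"(resid {r.site_b[0].number} and name {r.site_b[1]}) "
                f"{d:.1f} 0.0 {dplus:.1f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["res_a", "atom_a", "res_b", "aa_b", "atom_b",
                        "lower", "upper", "source_pre"])
            for r in restraints:
                w.writerow(
                    [
                        r.site_a[0].number, r.site_a[1],
                        r.site_b[0].number, r.site_b[0].aa, r.site_b[1],
                        f"{r.lower:.3f}", f"{r.upper:.3f}",
                        "" if r.source_pre is None else f"{r.source_pre:.6g}",
                    ]
                )
    else:
        raise ValidationError(f"unknown restraint dialect {dialect!r}")


_ASSIGN = re.compile(
    r"assign\s*\(resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s*"
    r"\(resid\s+(\d+)\s+and\s+name\s+(\S+)\)\s*"
    r"([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)"
)


def read_restraint_table(path, dialect: str = "cns_tbl") -> list[DistanceRestraint]:
    text = Path(path).read_text()
    out = []
    if dialect == "cns_tbl":
        for m in _ASSIGN.finditer(text):
            ra, na, rb, nb, d, dminus, dplus = m.groups()
            d, dminus, dplus = float(d), float(dminus), float(dplus)
            out.append(
                DistanceRestraint(
                    site_a=(ResidueID(number=int(ra)), na),
                    site_b=(ResidueID(number=int(rb)), nb),
                    lower=d - dminus,
                    upper=d + dplus,
                )
            )
    elif dialect == "csv":
        for row in _csv.DictReader(io.StringIO(text)):
            src = row.get("source_pre") or None
            out.append(
                DistanceRestraint(
                    site_a=(ResidueID(number=int(row["res_a"])), row["atom_a"]),
                    site_b=(ResidueID(number=int(row["res_b"]),
                                      aa=row.get("aa_b") or "X"), row["atom_b"]),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    source_pre=float(src) if src else None,
                )
            )
    else:
        raise ValidationError(f"unknown restraint dialect {dialect!r}")
    return out
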