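"""Data model and I/O for SNP panels and case-control cohort tables.

A *panel* is the ordered list of biallelic SNPs typed in the study, each
with a gene symbol, dbSNP rsID and a major/minor allele pair.  A *cohort
table* holds one record per subject: an identifier, binary allergy status,
sex, age and one genotype call per panel SNP.

Genotype text is canonicalized major-allele-first ("G/C", never "C/G"),
so every heterozygote has exactly one rendering.  Missing calls are
stored as ``None`` and rendered as ``./.`` on output.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
MISSING_TOKENS = frozenset({"", "./.", ".", "NA", "na", "N/A", "-", "--"})

#: rsID spellings accepted on input and normalized to the canonical form.
RSID_ALIASES = {"rs24030561": "rs2430561", "rs 24030561": "rs2430561"}


class PanelValidationError(ValueError):
    """Raised when a SNP panel violates its invariants."""


class CohortValidationError(ValueError):
    """Raised when a cohort file cannot be interpreted."""


@dataclass(frozen=True)
class SnpDef:
    """One biallelic locus: gene symbol, rsID and its two alleles."""

    gene: str
    rsid: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        for allele in (self.major_allele, self.minor_allele):
            if allele not in VALID_ALLELES:
                raise PanelValidationError(
                    f"{self.rsid}: allele {allele!r} not a nucleotide"
                )
        if self.major_allele == self.minor_allele:
            raise PanelValidationError(
                f"{self.rsid}: major and minor alleles are identical"
            )

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """The three canonical genotype strings (major hom, het, minor hom)."""
        a, b = self.major_allele, self.minor_allele
        return (f"{a}/{a}", f"{a}/{b}", f"{b}/{b}")


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, non-empty collection of SNP definitions."""

    snps: tuple[SnpDef, ...]

    def __post_init__(self) -> None:
        if not self.snps:
            raise PanelValidationError("panel has no SNPs")
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate rsIDs in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def get(self, rsid: str) -> SnpDef:
        rsid = RSID_ALIASES.get(rsid, rsid)
        for snp in self.snps:
            if snp.rsid == rsid:
                return snp
        raise KeyError(f"rsID {rsid!r} not in panel")

    def __contains__(self, rsid: str) -> bool:
        try:
            self.get(rsid)
            return True
        except KeyError:
            return False


def canonical_genotype(snp: SnpDef, text: str) -> Optional[str]:
    """Canonicalize a genotype string major-allele-first.

    ``"C/G"`` and ``"G/C"`` are the same unordered call and canonicalize
    identically.  Returns ``None`` for missing markers or calls containing
    an allele this SNP does not have (off-panel calls are treated as
    missing by the readers, with a warning).
    """
    text = text.strip()
    if text in MISSING_TOKENS:
        return None
    sep = "/" if "/" in text else ("|" if "|" in text else None)
    if sep is None:
        if len(text) == 2:  # bare "GC" style
            alleles = [text[0], text[1]]
        else:
            return None
    else:
        alleles = text.upper().split(sep)
    if len(alleles) != 2:
        return None
    alleles = [a.strip().upper() for a in alleles]
    valid = {snp.major_allele, snp.minor_allele}
    if not set(alleles) <= valid:
        return None
    # major-first ordering; heterozygote has a single rendering
    alleles.sort(key=lambda a: 0 if a == snp.major_allele else 1)
    return f"{alleles[0]}/{alleles[1]}"


@dataclass
class CohortRecord:
    """One subject: status, demographics and genotype calls keyed by rsID."""

    subject_id: str
    status: bool  # True = allergic (case)
    sex: str = "unknown"  # "F" / "M" / "unknown"
    age: Optional[float] = None
    genotypes: dict[str, Optional[str]] = field(default_factory=dict)


@dataclass
class CohortTable:
    """A case-control cohort together with the panel its genotypes refer to."""

    records: list[CohortRecord]
    panel: SnpPanel

    @property
    def n_cases(self) -> int:
        return sum(1 for r in self.records if r.status)

    @property
    def n_controls(self) -> int:
        return sum(1 for r in self.records if not r.status)

    def __len__(self) -> int:
        return len(self.records)

    def cases(self) -> list[CohortRecord]:
        return [r for r in self.records if r.status]

    def controls(self) -> list[CohortRecord]:
        return [r for r in self.records if not r.status]


# ---------------------------------------------------------------------------
# panel I/O


def load_panel(path: Union[str, Path, None] = None) -> SnpPanel:
    """Load a SNP panel from a JSON file.

    The file is a JSON array of objects with keys ``gene``, ``rsid``,
    ``major`` and ``minor``.  With no argument, the packaged default
    13-SNP cytokine/receptor panel is loaded.
    """
    if path is None:
        text = (
            resources.files("snprulemine.data").joinpath("default_panel.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    if not isinstance(raw, list):
        raise PanelValidationError("panel file must contain a JSON array")
    snps = tuple(
        SnpDef(
            gene=str(entry["gene"]),
            rsid=str(entry["rsid"]),
            major_allele=str(entry["major"]).upper(),
            minor_allele=str(entry["minor"]).upper(),
        )
        for entry in raw
    )
    return SnpPanel(snps)


# ---------------------------------------------------------------------------
# cohort I/O

_STATUS_TRUE = {"yes", "y", "1", "true", "case", "allergic"}
_STATUS_FALSE = {"no", "n", "0", "false", "control"}


def _parse_status(token: str) -> bool:
    t = token.strip().lower()
    if t in _STATUS_TRUE:
        return True
    if t in _STATUS_FALSE:
        return False
    raise CohortValidationError(f"unparseable status value {token!r}")


def _parse_sex(token: str) -> str:
    t = token.strip().upper()
    if t in {"F", "FEMALE", "W"}:
        return "F"
    if t in {"M", "MALE"}:
        return "M"
    return "unknown"


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cohort(path: Union[str, Path], panel: SnpPanel) -> CohortTable:
    """Read a delimited cohort table (comma or tab, sniffed from the header).

    Expected header: ``subject_id, status, sex, age, <rsid>, <rsid>, ...``.
    Genotype strings are canonicalized major-allele-first; unparseable or
    off-panel calls become missing (logged).  Unknown rsID columns are a
    hard error; a missing status column is a hard error.
    """
    text = Path(path).read_text(encoding="utf-8")
    return _read_cohort_text(text, panel)


def _read_cohort_text(text: str, panel: SnpPanel) -> CohortTable:
    lines = text.splitlines()
    if not lines:
        raise CohortValidationError("empty cohort file")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    header = [h.strip() for h in next(reader)]
    lowered = [h.lower() for h in header]
    if "status" not in lowered:
        raise CohortValidationError("cohort file has no 'status' column")

    meta_cols = {"subject_id", "status", "sex", "age"}
    geno_cols: dict[int, str] = {}
    unknown: list[str] = []
    for idx, name in enumerate(header):
        if name.lower() in meta_cols:
            continue
        canonical_rsid = RSID_ALIASES.get(name, name)
        if canonical_rsid in panel:
            geno_cols[idx] = panel.get(canonical_rsid).rsid
        else:
            unknown.append(name)
    if unknown:
        raise CohortValidationError(
            f"cohort columns not in panel: {unknown} (panel rsIDs: {list(panel.rsids)})"
        )

    id_idx = lowered.index("subject_id") if "subject_id" in lowered else None
    status_idx = lowered.index("status")
    sex_idx = lowered.index("sex") if "sex" in lowered else None
    age_idx = lowered.index("age") if "age" in lowered else None

    records: list[CohortRecord] = []
    for row_num, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        subject_id = row[id_idx].strip() if id_idx is not None else f"S{row_num - 1}"
        status = _parse_status(row[status_idx])
        sex = _parse_sex(row[sex_idx]) if sex_idx is not None else "unknown"
        age: Optional[float] = None
        if age_idx is not None and row[age_idx].strip() not in MISSING_TOKENS:
            try:
                age = float(row[age_idx])
            except ValueError:
                logger.warning("row %d: unparseable age %r, treated as missing",
                               row_num, row[age_idx])
        genotypes: dict[str, Optional[str]] = {}
        for idx, rsid in geno_cols.items():
            raw = row[idx] if idx < len(row) else ""
            call = canonical_genotype(panel.get(rsid), raw)
            if call is None and raw.strip() not in MISSING_TOKENS:
                logger.warning(
                    "row %d: genotype %r invalid for %s, treated as missing",
                    row_num, raw, rsid,
                )
            genotypes[rsid] = call
        records.append(CohortRecord(subject_id, status, sex, age, genotypes))
    return CohortTable(records=records, panel=panel)


def write_cohort(table: CohortTable, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write a cohort table in the delimited format `read_cohort` accepts."""
    rsids = table.panel.rsids
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["subject_id", "status", "sex", "age", *rsids])
        for rec in table.records:
            writer.writerow(
                [
                    rec.subject_id,
                    "Yes" if rec.status else "No",
                    rec.sex if rec.sex != "unknown" else "",
                    "" if rec.age is None else f"{rec.age:g}",
                    *[rec.genotypes.get(r) or "./." for r in rsids],
                ]
            )


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Outcome of cohort validation: per-SNP missingness plus any errors."""

    n_records: int
    n_cases: int
    n_controls: int
    missing_per_snp: dict[str, int]
    duplicate_ids: list[str]
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_cohort(table: CohortTable) -> ValidationReport:
    """Check cohort invariants and summarize per-SNP missingness.

    Errors (duplicate subject ids, genotype keys outside the panel) make
    ``report.ok`` false; missing genotypes are warnings only.
    """
    errors: list[str] = []
    warnings: list[str] = []

    seen: set[str] = set()
    dupes: list[str] = []
    for rec in table.records:
        if rec.subject_id in seen:
            dupes.append(rec.subject_id)
        seen.add(rec.subject_id)
    if dupes:
        errors.append(f"duplicate subject ids: {sorted(set(dupes))}")

    panel_rsids = set(table.panel.rsids)
    missing = {rsid: 0 for rsid in table.panel.rsids}
    for rec in table.records:
        extra = set(rec.genotypes) - panel_rsids
        if extra:
            errors.append(f"{rec.subject_id}: genotype keys not in panel: {sorted(extra)}")
        for rsid in table.panel.rsids:
            if rec.genotypes.get(rsid) is None:
                missing[rsid] += 1
    for rsid, n in missing.items():
        if n:
            warnings.append(f"{rsid}: {n} missing calls")

    return ValidationReport(
        n_records=len(table),
        n_cases=table.n_cases,
        n_controls=table.n_controls,
        missing_per_snp=missing,
        duplicate_ids=sorted(set(dupes)),
        errors=errors,
        warnings=warnings,
    )
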