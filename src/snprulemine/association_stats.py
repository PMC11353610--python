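"""Single-SNP case-control association statistics.

For each biallelic SNP the module produces allele and genotype counts per
group, a Pearson chi-square test of Hardy-Weinberg equilibrium (HWE),
Fisher exact p-values, and crude (unadjusted) odds ratios with Woolf
95% confidence intervals, under allelic, per-genotype (one-vs-rest),
dominant and recessive codings.

All odds ratios here are crude 2x2 cross-products.  No covariate
adjustment and no multiple-testing correction is applied to the reported
p-values (a Bonferroni column is emitted in the full report for
information only).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, SnpDef

Z_95 = 1.96  # conventional two-sided 95% normal quantile


@dataclass(frozen=True)
class Contingency2x2:
    """Exposure (rows: present/absent) by outcome (cols: case/control).

    a = exposed cases, b = exposed controls,
    c = unexposed cases, d = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class AlleleCounts:
    """Major/minor allele counts for one group at one SNP."""

    major: int
    minor: int

    @property
    def total(self) -> int:
        return self.major + self.minor


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts (major hom, het, minor hom) for one group."""

    hom_major: int
    het: int
    hom_minor: int

    @property
    def n(self) -> int:
        return self.hom_major + self.het + self.hom_minor

    @property
    def minor_allele_count(self) -> int:
        return self.het + 2 * self.hom_minor


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    monomorphic: bool = False


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    orientation: str
    degenerate: bool = False


def _degenerate_result(orientation: str) -> AssociationResult:
    return AssociationResult(math.nan, math.nan, math.nan, math.nan,
                             orientation, degenerate=True)


def count_genotypes(table: CohortTable, rsid: str, group: Literal["case", "control"]) -> GenotypeCounts:
    """Genotype class counts over non-missing calls in one group."""
    snp = table.panel.get(rsid)
    hom_major, het, hom_minor = snp.genotypes
    recs = table.cases() if group == "case" else table.controls()
    counts = {hom_major: 0, het: 0, hom_minor: 0}
    for rec in recs:
        call = rec.genotypes.get(snp.rsid)
        if call is not None:
            counts[call] += 1
    return GenotypeCounts(counts[hom_major], counts[het], counts[hom_minor])


def count_alleles(table: CohortTable, rsid: str, group: Literal["case", "control"]) -> AlleleCounts:
    """Major/minor allele counts; each non-missing subject contributes 2."""
    g = count_genotypes(table, rsid, group)
    return AlleleCounts(major=2 * g.hom_major + g.het, minor=g.het + 2 * g.hom_minor)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the observed allele frequencies
    (n*p^2, 2npq, n*q^2); the statistic has 1 degree of freedom because one
    allele frequency is estimated.  A monomorphic SNP is flagged and
    reported with p = 1.
    """
    n = counts.n
    if n == 0:
        raise ValueError("empty group")
    q = counts.minor_allele_count / (2 * n)
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1, 1.0, expected, monomorphic=True)
    observed = (counts.hom_major, counts.het, counts.hom_minor)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi2, 1, float(stats.chi2.sf(chi2, df=1)), expected)


def fisher_exact(t: Contingency2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of tables (at fixed margins) no more
    probable than the observed one.  A table with a zero margin carries no
    information and returns p = 1.
    """
    if (t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0):
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio_woolf(t: Contingency2x2, haldane: bool = False) -> AssociationResult:
    """Crude odds ratio with a Woolf (log-normal) 95% confidence interval.

    OR = ad/bc; CI = exp(ln OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)).
    With a zero cell the OR is 0 or +inf and the CI undefined unless
    ``haldane`` is set, which adds 0.5 to every cell (Haldane-Anscombe).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    p = fisher_exact(t)
    if min(t.a, t.b, t.c, t.d) == 0:
        if haldane:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            if t.a * t.d == 0 and t.b * t.c == 0:
                return AssociationResult(math.nan, math.nan, math.nan, p,
                                         "exposure-vs-rest", degenerate=True)
            or_ = math.inf if t.b * t.c == 0 else 0.0
            return AssociationResult(or_, math.nan, math.nan, p,
                                     "exposure-vs-rest", degenerate=True)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssociationResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - Z_95 * se),
        ci_high=math.exp(math.log(or_) + Z_95 * se),
        p_value=p,
        orientation="exposure-vs-rest",
    )


def allele_association(table: CohortTable, rsid: str, reference_allele: Optional[str] = None,
                       haldane: bool = False) -> AssociationResult:
    """Allelic odds ratio: reference allele as exposure, cases vs controls.

    Defaults to the panel's major allele as reference.  OR orientation is
    (case ref / case other) / (control ref / control other).
    """
    snp = table.panel.get(rsid)
    if reference_allele is None:
        reference_allele = snp.major_allele
    if reference_allele not in (snp.major_allele, snp.minor_allele):
        raise ValueError(f"{reference_allele!r} is not an allele of {rsid}")
    case = count_alleles(table, rsid, "case")
    ctrl = count_alleles(table, rsid, "control")
    if case.total + ctrl.total == 0:
        return _degenerate_result(f"allele {reference_allele} vs other")
    if reference_allele == snp.major_allele:
        t = Contingency2x2(case.major, ctrl.major, case.minor, ctrl.minor)
    else:
        t = Contingency2x2(case.minor, ctrl.minor, case.major, ctrl.major)
    res = odds_ratio_woolf(t, haldane=haldane)
    degenerate = res.degenerate or case.minor + ctrl.minor == 0 or case.major + ctrl.major == 0
    return AssociationResult(res.odds_ratio, res.ci_low, res.ci_high, res.p_value,
                             orientation=f"allele {reference_allele} vs other",
                             degenerate=degenerate)


def genotype_association(table: CohortTable, rsid: str, genotype: str,
                         haldane: bool = False) -> AssociationResult:
    """Crude one-vs-rest genotype odds ratio (subjects with the genotype
    as exposure, all other non-missing subjects as reference)."""
    snp = table.panel.get(rsid)
    if genotype not in snp.genotypes:
        raise ValueError(f"{genotype!r} is not a genotype of {rsid}")
    case = count_genotypes(table, rsid, "case")
    ctrl = count_genotypes(table, rsid, "control")
    if case.n + ctrl.n == 0:
        return _degenerate_result(f"genotype {genotype} vs rest")
    idx = snp.genotypes.index(genotype)
    case_counts = (case.hom_major, case.het, case.hom_minor)
    ctrl_counts = (ctrl.hom_major, ctrl.het, ctrl.hom_minor)
    a = case_counts[idx]
    b = ctrl_counts[idx]
    t = Contingency2x2(a, b, case.n - a, ctrl.n - b)
    res = odds_ratio_woolf(t, haldane=haldane)
    return AssociationResult(res.odds_ratio, res.ci_low, res.ci_high, res.p_value,
                             orientation=f"genotype {genotype} vs rest",
                             degenerate=res.degenerate or (a + b == 0))


def model_association(table: CohortTable, rsid: str,
                      model: Literal["dominant", "recessive"],
                      haldane: bool = False) -> AssociationResult:
    """Collapsed genetic-model odds ratio.

    dominant: minor-allele carriers (het + minor hom) vs major homozygotes;
    recessive: minor homozygotes vs carriers of the major allele.
    """
    case = count_genotypes(table, rsid, "case")
    ctrl = count_genotypes(table, rsid, "control")
    if case.n + ctrl.n == 0:
        return _degenerate_result(f"{model} (minor-allele coding)")
    if model == "dominant":
        a, b = case.het + case.hom_minor, ctrl.het + ctrl.hom_minor
    elif model == "recessive":
        a, b = case.hom_minor, ctrl.hom_minor
    else:
        raise ValueError(f"unknown model {model!r}")
    t = Contingency2x2(a, b, case.n - a, ctrl.n - b)
    res = odds_ratio_woolf(t, haldane=haldane)
    return AssociationResult(res.odds_ratio, res.ci_low, res.ci_high, res.p_value,
                             orientation=f"{model} (minor-allele coding)",
                             degenerate=res.degenerate)


def association_table(table: CohortTable) -> pd.DataFrame:
    """Per-SNP association report: allele and genotype rows for every
    panel SNP, with counts, frequencies, crude OR (Woolf 95% CI), Fisher
    p-value, per-group HWE p-values and a Bonferroni-adjusted p column
    (informational; the primary p-values are unadjusted)."""
    rows = []
    n_tests = 4 * len(table.panel)  # allele + three genotype rows per SNP
    for snp in table.panel:
        case_g = count_genotypes(table, snp.rsid, "case")
        ctrl_g = count_genotypes(table, snp.rsid, "control")
        case_a = count_alleles(table, snp.rsid, "case")
        ctrl_a = count_alleles(table, snp.rsid, "control")
        hwe_case = hwe_test(case_g) if case_g.n else None
        hwe_ctrl = hwe_test(ctrl_g) if ctrl_g.n else None

        def _row(level, label, n_ctrl, f_ctrl, n_case, f_case, assoc):
            rows.append({
                "gene": snp.gene, "rsid": snp.rsid, "level": level, "label": label,
                "controls_n": n_ctrl, "controls_freq": f_ctrl,
                "cases_n": n_case, "cases_freq": f_case,
                "odds_ratio": assoc.odds_ratio if assoc else math.nan,
                "ci_low": assoc.ci_low if assoc else math.nan,
                "ci_high": assoc.ci_high if assoc else math.nan,
                "p_value": assoc.p_value if assoc else math.nan,
                "p_bonferroni": min(1.0, assoc.p_value * n_tests) if assoc else math.nan,
                "hwe_p_controls": hwe_ctrl.p_value if hwe_ctrl else math.nan,
                "hwe_p_cases": hwe_case.p_value if hwe_case else math.nan,
            })

        major_assoc = allele_association(table, snp.rsid, snp.major_allele)
        _row("allele", snp.major_allele,
             ctrl_a.major, ctrl_a.major / ctrl_a.total if ctrl_a.total else math.nan,
             case_a.major, case_a.major / case_a.total if case_a.total else math.nan,
             major_assoc)
        _row("allele", snp.minor_allele,
             ctrl_a.minor, ctrl_a.minor / ctrl_a.total if ctrl_a.total else math.nan,
             case_a.minor, case_a.minor / case_a.total if case_a.total else math.nan,
             None)
        ctrl_counts = (ctrl_g.hom_major, ctrl_g.het, ctrl_g.hom_minor)
        case_counts = (case_g.hom_major, case_g.het, case_g.hom_minor)
        for i, gt in enumerate(snp.genotypes):
            assoc = genotype_association(table, snp.rsid, gt)
            _row("genotype", gt,
                 ctrl_counts[i], ctrl_counts[i] / ctrl_g.n if ctrl_g.n else math.nan,
                 case_counts[i], case_counts[i] / case_g.n if case_g.n else math.nan,
                 assoc)
    return pd.DataFrame(rows)


def write_association_report(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    """Write the association table as TSV (rounded: 2 d.p. frequencies and
    ORs) and/or JSON (full precision)."""
    if tsv_path is not None:
        out = df.copy()
        for col in ("controls_freq", "cases_freq", "odds_ratio", "ci_low", "ci_high"):
            out[col] = out[col].round(2)
        for col in ("p_value", "p_bonferroni", "hwe_p_controls", "hwe_p_cases"):
            out[col] = out[col].map(lambda p: f"{p:.4g}" if p == p else "")
        out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)
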