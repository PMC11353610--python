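"""Synthetic case-control genotype cohorts with known planted structure.

Controls are drawn at Hardy-Weinberg equilibrium (two independent allele
draws) from per-SNP control minor-allele frequencies; cases likewise from
case frequencies.  On top of that background, each *planted cluster* — a
multi-locus genotype pattern with a target rule confidence and support —
is written into a solved fraction of cases (and a smaller "leak" fraction
of controls), so that the rule (pattern => allergic) has known expected
mining metrics.  This gives every pipeline stage a ground truth to
recover.

The planted fractions are solved by expected-count inversion, including
the HWE background coincidence probability (the chance a non-planted
subject carries the whole pattern anyway):

    E[n_xy] = pi * n_cases + (1 - pi) * n_cases * p_bg_case   = support * m
    E[n_x]  = E[n_xy] + lam * n_ctrl + (1 - lam) * n_ctrl * p_bg_ctrl
            = E[n_xy] / confidence

Loci are simulated independently (no linkage disequilibrium) and planting
overwrites background genotypes; overlapping clusters are resolved by
later-cluster precedence.  Same seed, same cohort, byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .cohort_io import CohortRecord, CohortTable, SnpDef, SnpPanel, load_panel

logger = logging.getLogger(__name__)

#: Cohort composition defaults: study-sized groups.
DEFAULT_N_CASES = 308
DEFAULT_N_CONTROLS = 205

#: Demographics used for the simulated sex/age columns (fraction of women
#: and age mean/sd per group; age is truncated at adult recruitment age).
DEMOGRAPHICS = {
    "case": {"frac_female": 0.5422, "age_mean": 51.03, "age_sd": 10.01},
    "control": {"frac_female": 0.5707, "age_mean": 49.78, "age_sd": 12.32},
}
MIN_AGE = 18.0


class UnsatisfiableTargets(ValueError):
    """Raised when a planted cluster's targets cannot be realized."""


@dataclass(frozen=True)
class PlantedCluster:
    """A multi-SNP genotype pattern with target rule metrics.

    ``genotype_pattern`` maps rsID -> required canonical genotype (e.g.
    {"rs2834167": "G/G", "rs2243250": "C/C"}).  ``target_support`` and
    ``target_confidence`` are the support and confidence the mined rule
    (pattern => allergic) should have in expectation.
    """

    genotype_pattern: Mapping[str, str]
    target_confidence: float
    target_support: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.target_confidence <= 1.0):
            raise ValueError("target_confidence must be in (0, 1]")
        if not (0.0 < self.target_support <= 1.0):
            raise ValueError("target_support must be in (0, 1]")
        if self.target_support > self.target_confidence:
            raise ValueError("target_support cannot exceed target_confidence")
        if not self.genotype_pattern:
            raise ValueError("empty genotype pattern")


@dataclass
class SimulationConfig:
    panel: SnpPanel
    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    #: rsid -> {"control": maf, "case": maf}; minor-allele frequencies.
    minor_allele_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    clusters: Sequence[PlantedCluster] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        for rsid, freqs in self.minor_allele_freqs.items():
            if rsid not in self.panel:
                raise ValueError(f"frequency given for unknown rsID {rsid}")
            for grp in ("control", "case"):
                f = freqs[grp]
                if not (0.0 < f < 1.0):
                    raise ValueError(f"{rsid} {grp} maf {f} outside (0, 1)")
        for cl in self.clusters:
            for rsid, gt in cl.genotype_pattern.items():
                snp = self.panel.get(rsid)  # KeyError if absent
                if gt not in snp.genotypes:
                    raise ValueError(f"pattern genotype {gt!r} invalid for {rsid}")

    @property
    def m(self) -> int:
        return self.n_cases + self.n_controls

    def maf(self, rsid: str, group: str) -> float:
        freqs = self.minor_allele_freqs.get(rsid)
        if freqs is None:
            return 0.3  # generic common-variant default
        return float(freqs[group])


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """(major hom, het, minor hom) probabilities under HWE."""
    q = maf
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def genotype_probability(snp: SnpDef, genotype: str, maf: float) -> float:
    """HWE probability of one canonical genotype at minor-allele freq maf."""
    probs = dict(zip(snp.genotypes, hwe_genotype_probs(maf)))
    return probs[genotype]


def simulate_genotype(snp: SnpDef, maf: float, rng: np.random.Generator) -> str:
    """Draw one genotype: two independent alleles, minor with prob maf."""
    if not (0.0 < maf < 1.0):
        raise ValueError("maf must be in (0, 1)")
    n_minor = int(rng.random() < maf) + int(rng.random() < maf)
    return snp.genotypes[n_minor]


def _background_pattern_prob(config: SimulationConfig, cluster: PlantedCluster,
                             group: str) -> float:
    p = 1.0
    for rsid, gt in cluster.genotype_pattern.items():
        p *= genotype_probability(config.panel.get(rsid), gt, config.maf(rsid, group))
    return p


def solve_planting(config: SimulationConfig, cluster: PlantedCluster) -> tuple[float, float]:
    """Solve (pi, lam): the case fraction and control leak fraction to plant.

    Inverts the expected-count equations in the module docstring.  A
    *negative* solved fraction means the HWE background alone produces more
    carriers than the target allows; the simulator then thins background
    carriers instead of planting, with the per-carrier breaking probability
    that makes the expected carrier count hit the target.  Targets needing
    more carriers than the group holds raise ``UnsatisfiableTargets``.
    """
    s, c = cluster.target_support, cluster.target_confidence
    m, n_cases, n_ctrl = config.m, config.n_cases, config.n_controls
    target_nxy = s * m
    if target_nxy > n_cases:
        raise UnsatisfiableTargets(
            f"support {s} needs {target_nxy:.0f} case carriers but only "
            f"{n_cases} cases exist")
    p_case = _background_pattern_prob(config, cluster, "case")
    p_ctrl = _background_pattern_prob(config, cluster, "control")
    pi = (target_nxy - n_cases * p_case) / (n_cases * (1.0 - p_case))
    if pi > 1.0:
        raise UnsatisfiableTargets(f"cluster needs case fraction {pi:.3f} > 1")
    target_leak = target_nxy * (1.0 / c - 1.0)  # expected control carriers
    lam = (target_leak - n_ctrl * p_ctrl) / (n_ctrl * (1.0 - p_ctrl))
    if lam > 1.0:
        raise UnsatisfiableTargets(f"cluster needs control leak {lam:.3f} > 1")
    return pi, lam


def expected_rule_counts(config: SimulationConfig, cluster: PlantedCluster,
                         pi: Optional[float] = None, lam: Optional[float] = None
                         ) -> tuple[float, float, float]:
    """Closed-form (E[n_xy], E[n_x], E[n_y]) for a cluster's rule.

    With ``pi``/``lam`` omitted, the solved planting fractions are used;
    pass explicit values (e.g. 0) to get pure-background expectations.
    """
    if pi is None or lam is None:
        solved_pi, solved_lam = solve_planting(config, cluster)
        pi = solved_pi if pi is None else pi
        lam = solved_lam if lam is None else lam
    p_case = _background_pattern_prob(config, cluster, "case")
    p_ctrl = _background_pattern_prob(config, cluster, "control")
    e_nxy = pi * config.n_cases + (1.0 - pi) * config.n_cases * p_case
    e_nx = e_nxy + lam * config.n_controls + (1.0 - lam) * config.n_controls * p_ctrl
    return (e_nxy, e_nx, float(config.n_cases))


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a full cohort table per the config; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel

    def _make_group(n: int, group: str, prefix: str) -> list[CohortRecord]:
        demo = DEMOGRAPHICS[group]
        recs = []
        for i in range(n):
            sex = "F" if rng.random() < demo["frac_female"] else "M"
            age = max(MIN_AGE, float(rng.normal(demo["age_mean"], demo["age_sd"])))
            genotypes = {
                snp.rsid: simulate_genotype(snp, config.maf(snp.rsid, group), rng)
                for snp in panel
            }
            recs.append(CohortRecord(f"{prefix}{i + 1:04d}", group == "case",
                                     sex, round(age, 1), genotypes))
        return recs

    cases = _make_group(config.n_cases, "case", "case_")
    controls = _make_group(config.n_controls, "control", "ctrl_")

    planted_case_ids: set[int] = set()
    for cluster in config.clusters:
        pi, lam = solve_planting(config, cluster)
        target_nxy = cluster.target_support * config.m
        target_leak = target_nxy * (1.0 / cluster.target_confidence - 1.0)
        if pi >= 0.0:
            case_idx = rng.choice(config.n_cases, size=int(round(pi * config.n_cases)),
                                  replace=False)
            overlap = planted_case_ids & set(case_idx.tolist())
            if overlap:
                logger.info("cluster %s overwrites %d case(s) planted by an earlier "
                            "cluster (later-cluster precedence)",
                            cluster.label or "?", len(overlap))
            planted_case_ids |= set(case_idx.tolist())
            for idx in case_idx:
                cases[idx].genotypes.update(cluster.genotype_pattern)
        else:
            _thin_pattern_carriers(cases, cluster, config, rng, "case", target_nxy)
        if lam >= 0.0:
            ctrl_idx = rng.choice(config.n_controls,
                                  size=int(round(lam * config.n_controls)), replace=False)
            for idx in ctrl_idx:
                controls[idx].genotypes.update(cluster.genotype_pattern)
        else:
            _thin_pattern_carriers(controls, cluster, config, rng, "control", target_leak)

    return CohortTable(records=cases + controls, panel=panel)


def _thin_pattern_carriers(records: list[CohortRecord], cluster: PlantedCluster,
                           config: SimulationConfig, rng: np.random.Generator,
                           group: str, target_count: float) -> None:
    """Break background pattern carriers down to an expected target count.

    Each carrier is independently broken (one pattern SNP redrawn until it no
    longer matches) with the probability that makes the expected surviving
    carrier count equal ``target_count`` — expectation-based, like planting.
    """
    rsids = list(cluster.genotype_pattern)
    carriers = [r for r in records
                if all(r.genotypes.get(k) == cluster.genotype_pattern[k] for k in rsids)]
    expected = len(records) * _background_pattern_prob(config, cluster, group)
    p_break = 1.0 if expected <= 0 else min(1.0, max(0.0, 1.0 - target_count / expected))
    for rec in carriers:
        if rng.random() < p_break:
            rsid = rsids[int(rng.integers(len(rsids)))]
            snp = config.panel.get(rsid)
            pattern_gt = cluster.genotype_pattern[rsid]
            call = pattern_gt
            while call == pattern_gt:
                call = simulate_genotype(snp, config.maf(rsid, group), rng)
            rec.genotypes[rsid] = call


def recovery_benchmark_config(seed: int = 0) -> SimulationConfig:
    """Parameter-recovery validation scenario: three disjoint planted
    clusters of 2, 3 and 4 SNPs at confidence 0.97 and support 0.14-0.15,
    on the study-like allele frequencies.  The full pipeline should mine
    each planted antecedent at the default thresholds in nearly every
    seeded replicate (see docs for the expected recovery rate)."""
    base = load_config()
    clusters = (
        PlantedCluster({"rs2834167": "G/G", "rs2834213": "A/G"},
                       target_confidence=0.97, target_support=0.15, label="bench2"),
        PlantedCluster({"rs564481": "T/T", "rs1800795": "G/G", "rs1800925": "C/C"},
                       target_confidence=0.97, target_support=0.14, label="bench3"),
        PlantedCluster({"rs2243250": "C/C", "rs1801275": "A/A",
                        "rs1800896": "A/A", "rs577912": "C/C"},
                       target_confidence=0.97, target_support=0.14, label="bench4"),
    )
    return SimulationConfig(panel=base.panel, n_cases=base.n_cases,
                            n_controls=base.n_controls,
                            minor_allele_freqs=base.minor_allele_freqs,
                            clusters=clusters, seed=seed)


# ---------------------------------------------------------------------------
# config file I/O


def config_from_dict(raw: dict, panel: Optional[SnpPanel] = None) -> SimulationConfig:
    if panel is None:
        panel_path = raw.get("panel")
        panel = load_panel(panel_path)
    clusters = tuple(
        PlantedCluster(
            genotype_pattern=dict(c["pattern"]),
            target_confidence=float(c["confidence"]),
            target_support=float(c["support"]),
            label=str(c.get("label", "")),
        )
        for c in raw.get("clusters", [])
    )
    return SimulationConfig(
        panel=panel,
        n_cases=int(raw.get("n_cases", DEFAULT_N_CASES)),
        n_controls=int(raw.get("n_controls", DEFAULT_N_CONTROLS)),
        minor_allele_freqs=raw.get("freqs", {}),
        clusters=clusters,
        seed=int(raw.get("seed", 0)),
    )


def load_config(path: Union[str, Path, None] = None,
                panel: Optional[SnpPanel] = None) -> SimulationConfig:
    """Load a simulation config from YAML; defaults to the packaged config
    that mirrors the study's group sizes, control/case allele frequencies
    and three representative planted genotype clusters."""
    if path is None:
        text = (resources.files("snprulemine.data")
                .joinpath("study_like.yaml").read_text())
    else:
        text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text), panel=panel)
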