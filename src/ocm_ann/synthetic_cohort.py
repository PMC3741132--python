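"""Synthetic case-control cohorts matched to published group marginals.

The packaged parameterization reproduces the per-group genotype frequencies
and biomarker mean / 95%-CI summaries of the study population (n = 40 per
group).  Biomarkers are drawn from a lognormal moment-matched to the printed
mean and the CI-derived standard deviation, which guarantees positivity while
preserving the mean in expectation.  Optional pairwise rank-correlation
targets are imposed through a Gaussian copula on the latent draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import (
    BIOMARKER_COLUMNS,
    GROUP_AD,
    GROUP_CONTROL,
    GENOTYPE_SUFFIXES,
    PolymorphismDef,
    SubjectRecord,
    load_default_panel,
)

__all__ = [
    "Z95",
    "BiomarkerParams",
    "GroupMarginals",
    "CouplingSpec",
    "derive_sd",
    "table1_marginals",
    "generate_cohort",
    "generate_group",
    "planted_signal_cohort",
    "summarize_cohort",
]

#: two-sided 95% normal quantile used to convert CI half-widths to SDs
Z95 = 1.959964

BIOMARKER_FIELDS = ("folate", "homocysteine", "vitamin_b12")


def derive_sd(half_width: float, n: int) -> float:
    """SD implied by a normal-theory 95% CI half-width at sample size n."""
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return half_width * math.sqrt(n) / Z95


@dataclass(frozen=True)
class BiomarkerParams:
    mean: float
    ci_half_width: float
    n: int

    @property
    def sd(self) -> float:
        return derive_sd(self.ci_half_width, self.n)


@dataclass
class GroupMarginals:
    """Per-group marginal distributions: genotype triples + biomarker moments.

    ``genotype_freqs`` holds (wild, het, mut) probabilities as printed; they
    may sum to slightly more or less than 1 due to rounding and are
    renormalized on access.
    """

    group: str
    genotype_freqs: dict[str, tuple[float, float, float]]
    biomarker_params: dict[str, BiomarkerParams]

    def normalized_freqs(self, name: str) -> np.ndarray:
        triple = np.asarray(self.genotype_freqs[name], dtype=float)
        if np.any(triple < 0):
            raise ValueError(f"{name}: negative genotype frequency")
        total = triple.sum()
        if total <= 0:
            raise ValueError(f"{name}: genotype frequencies sum to zero")
        return triple / total


# Printed per-group summaries: biomarkers as (mean, 95% CI half-width),
# genotype triples as (wild, het, mut) percentages.
_AD_BIOMARKERS = {"folate": (6.2, 1.8), "homocysteine": (22.3, 4.7), "vitamin_b12": (401.3, 78.2)}
_CT_BIOMARKERS = {"folate": (6.8, 1.2), "homocysteine": (16.2, 1.7), "vitamin_b12": (404.9, 73.5)}
_AD_GENOTYPES = {
    "MTHFR_C677T": (28, 40, 32),
    "MTHFR_A1298C": (45, 55, 0),
    "TYMS_28bp": (32, 45, 23),
    "TYMS_6bp": (15, 57, 28),
    "MTRR_A66G": (23, 43, 35),
    "MTR_A2756G": (82, 15, 3),
    "RFC1_A80G": (22, 60, 18),
    "DNMT3B_149CT": (45, 47, 8),
    "DNMT3B_579GT": (48, 47, 5),
}
_CT_GENOTYPES = {
    "MTHFR_C677T": (38, 47, 15),
    "MTHFR_A1298C": (60, 40, 0),
    "TYMS_28bp": (20, 57, 23),
    "TYMS_6bp": (35, 53, 13),
    "MTRR_A66G": (25, 52, 23),
    "MTR_A2756G": (87, 13, 0),
    "RFC1_A80G": (10, 62, 28),
    "DNMT3B_149CT": (50, 40, 10),
    "DNMT3B_579GT": (62, 28, 10),
}


def table1_marginals(n: int = 40) -> tuple[GroupMarginals, GroupMarginals]:
    """The packaged study parameterization (AD marginals, control marginals)."""

    def build(group: str, bio: dict, geno: dict) -> GroupMarginals:
        return GroupMarginals(
            group=group,
            genotype_freqs={k: tuple(x / 100.0 for x in v) for k, v in geno.items()},
            biomarker_params={
                k: BiomarkerParams(mean=m, ci_half_width=hw, n=n) for k, (m, hw) in bio.items()
            },
        )

    return (
        build(GROUP_AD, _AD_BIOMARKERS, _AD_GENOTYPES),
        build(GROUP_CONTROL, _CT_BIOMARKERS, _CT_GENOTYPES),
    )


@dataclass
class CouplingSpec:
    """Pairwise Spearman rank-correlation targets between latent variables.

    Keys are unordered pairs of variable names; biomarkers use their field
    names (``folate`` etc.) and polymorphisms couple through their latent
    genotype dosage.  Empty spec means full independence.
    """

    targets: dict[frozenset, float] = field(default_factory=dict)
    max_repair_shift: float = 0.1

    @classmethod
    def independence(cls) -> "CouplingSpec":
        return cls()

    @classmethod
    def literature(cls) -> "CouplingSpec":
        """Directionally motivated preset: folate vs hcy -0.5, folate vs B12 +0.5."""
        return cls(targets={
            frozenset(("folate", "homocysteine")): -0.5,
            frozenset(("folate", "vitamin_b12")): +0.5,
        })

    def set(self, a: str, b: str, rho: float) -> "CouplingSpec":
        if not -1.0 < rho < 1.0:
            raise ValueError(f"rank correlation must be in (-1, 1), got {rho}")
        self.targets[frozenset((a, b))] = rho
        return self

    def latent_correlation(self, variables: list[str]) -> np.ndarray:
        """Pearson latent correlation matrix (nearest-PSD repaired)."""
        p = len(variables)
        corr = np.eye(p)
        index = {v: i for i, v in enumerate(variables)}
        for pair, rho_s in self.targets.items():
            a, b = sorted(pair)
            if a not in index or b not in index:
                raise ValueError(f"unknown coupling variable in pair ({a}, {b})")
            # Spearman -> Pearson for bivariate normal latents
            rho = 2.0 * math.sin(math.pi * rho_s / 6.0)
            corr[index[a], index[b]] = corr[index[b], index[a]] = rho
        repaired = _nearest_psd_correlation(corr)
        shift = np.max(np.abs(repaired - corr))
        if shift > self.max_repair_shift:
            raise ValueError(
                f"coupling targets infeasible: PSD repair moved an entry by {shift:.3f} "
                f"(> {self.max_repair_shift})"
            )
        return repaired


def _nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    fixed = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_group(
    marginals: GroupMarginals,
    n: int,
    rng: np.random.Generator,
    panel: list[PolymorphismDef],
    coupling: CouplingSpec | None = None,
) -> list[SubjectRecord]:
    """Draw n subjects for one group via a Gaussian copula over the latents."""
    coupling = coupling or CouplingSpec.independence()
    variables = list(BIOMARKER_FIELDS) + [p.name for p in panel]
    corr = coupling.latent_correlation(variables)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(variables)))
    z = rng.standard_normal((n, len(variables))) @ chol.T

    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(BIOMARKER_FIELDS):
        params = marginals.biomarker_params[name]
        mu, sigma = _lognormal_params(params.mean, params.sd)
        columns[name] = np.exp(mu + sigma * z[:, j])

    genotype_columns: dict[str, list[str]] = {}
    for j, poly in enumerate(panel, start=len(BIOMARKER_FIELDS)):
        probs = marginals.normalized_freqs(poly.name)
        cuts = np.cumsum(probs)[:2]
        u = stats.norm.cdf(z[:, j])
        idx = np.searchsorted(cuts, u, side="left")
        genotype_columns[poly.name] = [poly.labels[i] for i in idx]

    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"{marginals.group}_{i:05d}",
                group=marginals.group,
                genotypes={name: genotype_columns[name][i] for name in genotype_columns},
                folate=float(columns["folate"][i]),
                homocysteine=float(columns["homocysteine"][i]),
                vitamin_b12=float(columns["vitamin_b12"][i]),
            )
        )
    return records


def generate_cohort(
    marginals_ad: GroupMarginals,
    marginals_control: GroupMarginals,
    n_per_group: int,
    seed: int,
    coupling: CouplingSpec | None = None,
    panel: list[PolymorphismDef] | None = None,
) -> list[SubjectRecord]:
    """Reproducible synthetic cohort: AD block followed by control block."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if panel is None:
        panel = load_default_panel()
    rng = np.random.default_rng(seed)
    ad = generate_group(marginals_ad, n_per_group, rng, panel, coupling)
    control = generate_group(marginals_control, n_per_group, rng, panel, coupling)
    return ad + control


def planted_signal_cohort(
    n_per_group: int,
    n_informative: int,
    n_noise: int,
    effect: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benchmark matrix with known informative columns.

    Informative columns are N(effect, 1) for AD rows and N(0, 1) for
    controls; noise columns are N(0, 1) for both.  Returns (X, labels,
    truth mask) with AD rows first.
    """
    if n_per_group < 1 or n_informative < 0 or n_noise < 0 or effect < 0:
        raise ValueError("counts must be >= 0 (n_per_group >= 1), effect >= 0")
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    x = rng.standard_normal((2 * n_per_group, p))
    x[:n_per_group, :n_informative] += effect
    labels = np.asarray([GROUP_AD] * n_per_group + [GROUP_CONTROL] * n_per_group, dtype=object)
    mask = np.zeros(p, dtype=bool)
    mask[:n_informative] = True
    return x, labels, mask


def summarize_cohort(
    cohort: list[SubjectRecord], panel: list[PolymorphismDef] | None = None
) -> pd.DataFrame:
    """Per-group summary mirroring the published table layout.

    Biomarker rows report mean and normal-theory 95% CI half-width; genotype
    rows report percentages with a binomial-proportion CI half-width.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if panel is None:
        panel = load_default_panel()
    rows = []
    groups = {
        GROUP_AD: [r for r in cohort if r.group == GROUP_AD],
        GROUP_CONTROL: [r for r in cohort if r.group == GROUP_CONTROL],
    }

    def stats_for(records: list[SubjectRecord], attr: str) -> tuple[float, float]:
        values = np.asarray([getattr(r, attr) for r in records], dtype=float)
        if len(values) == 0:
            return math.nan, math.nan
        hw = Z95 * values.std(ddof=1) / math.sqrt(len(values)) if len(values) > 1 else math.nan
        return float(values.mean()), float(hw)

    for display, attr in BIOMARKER_COLUMNS.items():
        ad_m, ad_hw = stats_for(groups[GROUP_AD], attr)
        ct_m, ct_hw = stats_for(groups[GROUP_CONTROL], attr)
        rows.append({
            "parameter": display, "kind": "biomarker",
            "ad_mean": ad_m, "ad_ci95": ad_hw,
            "control_mean": ct_m, "control_ci95": ct_hw,
        })
    for poly in panel:
        for label, suffix in zip(poly.labels, GENOTYPE_SUFFIXES):
            entry = {"parameter": f"{poly.name}_{suffix} ({label})", "kind": "genotype"}
            for key, group in (("ad", GROUP_AD), ("control", GROUP_CONTROL)):
                records = groups[group]
                if records:
                    p_hat = sum(r.genotypes[poly.name] == label for r in records) / len(records)
                    hw = Z95 * math.sqrt(p_hat * (1 - p_hat) / len(records)) * 100.0
                else:
                    p_hat, hw = math.nan, math.nan
                entry[f"{key}_mean"] = 100.0 * p_hat
                entry[f"{key}_ci95"] = hw
            rows.append(entry)
    return pd.DataFrame(rows)
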