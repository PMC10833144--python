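"""Seeded synthetic CE-MS cohort generator.

Intensities follow a zero-inflated log-normal model: peptide ``j`` in group
``g`` is detected with probability ``pi[g]`` and, when detected, its
intensity is ``LogNormal(mu[g], sigma)``; non-detections are exact zeros.
The analytic group mean is therefore ``pi * exp(mu + sigma**2 / 2)``, and
calibration inverts that identity so each generated group reproduces the
target panel mean exactly in expectation.

Clinical covariates are drawn from per-group published summary statistics:
normal for mean/sd variables, log-normal matched to median/IQR variables,
Bernoulli for counts, and a [0, 100]-truncated normal for IFTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    GROUPS,
    IntensityDataset,
    PanelPeptide,
    load_cohort_characteristics,
    load_etiology_fixture,
)

#: Standard-normal quantile spanned by half an interquartile range.
_IQR_HALF_WIDTH = 0.6744897501960817


@dataclass(frozen=True)
class PeptideGeneratorSpec:
    """Per-peptide generator parameters: detection probability and log-scale
    location per group, with a shared log-scale spread."""

    peptide_id: str
    pi: Mapping[str, float]      # detection probability per group
    mu: Mapping[str, float]      # log-scale location per group (given detected)
    sigma: float

    def analytic_mean(self, group: str) -> float:
        p = self.pi[group]
        if p == 0.0:
            return 0.0
        return p * math.exp(self.mu[group] + self.sigma**2 / 2.0)


@dataclass
class CohortConfig:
    """Sizes, noise and background settings of a simulated cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"pFSGS": 19, "sFSGS": 44, "NC": 98, "CKD_other": 100}
    )
    independent_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 110, "CKD_other": 170}
    )
    n_background_peptides: int = 4000
    sigma: float = 1.0
    detection_m0: float = 50.0
    background_pi_range: tuple[float, float] = (0.05, 0.95)
    background_log_mean: float = math.log(150.0)
    background_log_sd: float = 1.5
    simulate_covariates: bool = True

    def __post_init__(self) -> None:
        for name, sizes in (("group_sizes", self.group_sizes),
                            ("independent_sizes", self.independent_sizes)):
            for g, n in sizes.items():
                if g not in GROUPS:
                    raise ValueError(f"{name}: unknown group {g!r}")
                if n < 0:
                    raise ValueError(f"{name}: negative size for {g}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def saturating_detection_rule(mean: float, m0: float = 50.0) -> float:
    """Detection probability increasing with abundance: ``mean / (mean + m0)``."""
    if mean <= 0:
        return 0.0
    return min(1.0, mean / (mean + m0))


def calibrate_from_panel(
    panel: Sequence[PanelPeptide],
    sigma: float = 1.0,
    detection_m0: float = 50.0,
) -> list[PeptideGeneratorSpec]:
    """Choose ``(pi, mu)`` per peptide and group so the analytic zero-inflated
    log-normal mean equals each panel group mean exactly.

    A group mean of 0 forces ``pi = 0`` (the peptide is never detected there).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    specs = []
    for pep in panel:
        pi: dict[str, float] = {}
        mu: dict[str, float] = {}
        for g in GROUPS:
            target = pep.group_mean(g)
            if target == 0.0:
                pi[g], mu[g] = 0.0, 0.0
            else:
                p = saturating_detection_rule(target, detection_m0)
                pi[g] = p
                mu[g] = math.log(target / p) - sigma**2 / 2.0
        specs.append(PeptideGeneratorSpec(pep.peptide_id, pi, mu, sigma))
    return specs


def _background_specs(
    config: CohortConfig, rng: np.random.Generator, group_invariant_groups: Sequence[str]
) -> list[PeptideGeneratorSpec]:
    lo, hi = config.background_pi_range
    specs = []
    for i in range(config.n_background_peptides):
        p = float(rng.uniform(lo, hi))
        m = float(rng.normal(config.background_log_mean, config.background_log_sd))
        specs.append(
            PeptideGeneratorSpec(
                peptide_id=f"bg{i:05d}",
                pi={g: p for g in group_invariant_groups},
                mu={g: m for g in group_invariant_groups},
                sigma=config.sigma,
            )
        )
    return specs


def _draw_intensities(
    specs: Sequence[PeptideGeneratorSpec],
    groups: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(groups)
    out = np.zeros((n, len(specs)))
    group_arr = np.asarray(groups)
    for j, spec in enumerate(specs):
        for g in set(groups):
            mask = group_arr == g
            k = int(mask.sum())
            pi = spec.pi[g]
            if pi == 0.0:
                continue
            detected = rng.random(k) < pi
            vals = np.zeros(k)
            nd = int(detected.sum())
            if nd:
                vals[detected] = rng.lognormal(spec.mu[g], spec.sigma, size=nd)
            out[mask, j] = vals
    return out


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _lognormal_from_median_iqr(
    rng: np.random.Generator, median: float, q1: float, q3: float, size: int
) -> np.ndarray:
    mu = math.log(max(median, 1e-9))
    if q3 > q1 > 0:
        s = math.log(q3 / q1) / (2.0 * _IQR_HALF_WIDTH)
    else:
        s = 0.25
    return rng.lognormal(mu, s, size=size)


def _draw_covariates(
    groups: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    summaries = load_cohort_characteristics()
    group_arr = np.asarray(groups)
    n = len(groups)
    cov = pd.DataFrame(
        {
            "proteinuria": np.zeros(n),
            "egfr": np.zeros(n),
            "age": np.zeros(n),
            "sex": np.empty(n, dtype=object),
            "ifta": np.full(n, np.nan),
        }
    )
    for g in dict.fromkeys(groups):
        mask = group_arr == g
        k = int(mask.sum())
        summ = summaries[g]
        age = summ["age"]
        cov.loc[mask, "age"] = rng.normal(age["mean"], age["sd"], size=k)
        eg = summ["egfr"]
        cov.loc[mask, "egfr"] = _lognormal_from_median_iqr(
            rng, eg["median"], eg["q1"], eg["q3"], k
        )
        pr = summ["proteinuria"]
        cov.loc[mask, "proteinuria"] = _lognormal_from_median_iqr(
            rng, pr["median"], pr["q1"], pr["q3"], k
        )
        male_frac = summ["sex_male"]["count"] / summ["n"]
        cov.loc[mask, "sex"] = np.where(rng.random(k) < male_frac, "M", "F")
        if summ.get("ifta"):
            it = summ["ifta"]
            cov.loc[mask, "ifta"] = _truncnorm_draw(
                rng, it["mean"], max(it["sd"], 1e-6), 0.0, 100.0, k
            )
    return cov


def _draw_etiologies(
    groups: Sequence[str], rng: np.random.Generator, which: str
) -> list[str | None]:
    counts = load_etiology_fixture(which)
    codes = list(counts)
    weights = np.array([counts[c] for c in codes], dtype=float)
    weights /= weights.sum()
    out: list[str | None] = []
    for g in groups:
        if g == "CKD_other":
            out.append(str(rng.choice(codes, p=weights)))
        else:
            out.append(None)
    return out


def _assemble(
    config: CohortConfig,
    specs: Sequence[PeptideGeneratorSpec],
    sizes: Mapping[str, int],
    rng: np.random.Generator,
    prefix: str,
    etiology_table: str,
) -> IntensityDataset:
    groups: list[str] = []
    for g in GROUPS:
        groups.extend([g] * sizes.get(g, 0))
    sample_ids = [f"{prefix}{i:04d}" for i in range(len(groups))]
    all_specs = list(specs) + _background_specs(config, rng, GROUPS)
    matrix = _draw_intensities(all_specs, groups, rng)
    covariates = _draw_covariates(groups, rng) if config.simulate_covariates else None
    if covariates is not None:
        covariates.index = sample_ids
    return IntensityDataset(
        sample_ids=sample_ids,
        peptide_ids=[s.peptide_id for s in all_specs],
        intensities=matrix,
        group=groups,
        etiology=_draw_etiologies(groups, rng, etiology_table),
        covariates=covariates,
    )


def generate_cohort(
    config: CohortConfig,
    specs: Sequence[PeptideGeneratorSpec],
    seed: int,
    independent: bool = False,
) -> IntensityDataset:
    """Generate a seeded cohort with planted group-specific panel peptides.

    ``independent=True`` draws the held-out control arms (NC / CKD_other
    only, independent sizes and etiology mix) from the same generator specs.
    Identical ``(config, specs, seed, independent)`` yields identical output.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    if independent:
        return _assemble(
            config, specs, config.independent_sizes, rng, "ind", "independent"
        )
    return _assemble(config, specs, config.group_sizes, rng, "trn", "matched")


def generate_null_cohort(
    config: CohortConfig,
    specs: Sequence[PeptideGeneratorSpec],
    seed: int,
) -> IntensityDataset:
    """As :func:`generate_cohort` but with every peptide group-invariant.

    Each planted peptide keeps its marginal scale (parameters of the first
    group with nonzero detection) but uses the same ``(pi, mu)`` in every
    group, so no peptide carries any real signal.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    flattened = []
    for spec in specs:
        ref = next((g for g in GROUPS if spec.pi[g] > 0), GROUPS[0])
        flattened.append(
            PeptideGeneratorSpec(
                peptide_id=spec.peptide_id,
                pi={g: spec.pi[ref] for g in GROUPS},
                mu={g: spec.mu[ref] for g in GROUPS},
                sigma=spec.sigma,
            )
        )
    rng = np.random.default_rng(seed)
    return _assemble(config, flattened, config.group_sizes, rng, "nul", "matched")
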