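"""Clinical-validation arm: patient records, RA/VC dichotomization,
territory stratification, nonparametric statistics and a synthetic cohort.

Patients are dichotomized to match the model's two anatomies: anomalous
drainage directly to the right atrium (or within 2 cm of it) maps to the
RA group; right-sided drainage more than 2 cm from the RA and every
left-sided (vertical-vein) drainage maps to the VC group.  The extent of
anomalous drainage is graded in lung territories (three per lung, the
lingula counted with the left upper territory), 1-3 territories per
patient.

The synthetic generator emulates the published cohort structure exactly
(stratum counts, missingness pattern) and draws Qp/Qs from log-normal
distributions moment-matched to the published per-stratum median and
interquartile range; it stands in for the unavailable retrospective
patient data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heart import ConfigurationError

__all__ = [
    "CohortValidationError",
    "PatientRecord",
    "CohortSummary",
    "SyntheticCohortConfig",
    "StratumSpec",
    "categorize_model_variant",
    "summarize_cohort",
    "rank_sum_test",
    "kruskal_wallis",
    "correlations",
    "generate_synthetic_cohort",
    "records_to_frame",
    "frame_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
]


class CohortValidationError(ValueError):
    """A patient record violates an inclusion criterion or is incomplete."""


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical-validation table.

    ``clinical_variant``: "SVC" (right drainage to a vena cava), "RA"
    (right drainage directly to the right atrium) or "L" (left drainage
    via a vertical vein).  ``distance_to_ra_cm`` is required for
    right-sided variants and absent for "L".  ``pvr_wu`` must be <= 3
    (higher resistances are an exclusion criterion).
    """

    id: str
    age: float
    sex: str  # "F" | "M"
    clinical_variant: str  # "SVC" | "RA" | "L"
    n_territories: int
    distance_to_ra_cm: float | None = None
    qp_qs_invasive: float | None = None
    qp_qs_cmr: float | None = None
    pvr_wu: float | None = None
    pa_mmhg: float | None = None
    ra_mmhg: float | None = None

    def __post_init__(self) -> None:
        if self.clinical_variant not in ("SVC", "RA", "L"):
            raise CohortValidationError(
                f"{self.id}: unknown clinical variant {self.clinical_variant!r}"
            )
        if self.sex not in ("F", "M"):
            raise CohortValidationError(f"{self.id}: sex must be 'F' or 'M'")
        if self.n_territories not in (1, 2, 3):
            raise CohortValidationError(
                f"{self.id}: n_territories must be 1..3, got {self.n_territories}"
            )
        if self.qp_qs_invasive is None and self.qp_qs_cmr is None:
            raise CohortValidationError(
                f"{self.id}: at least one Qp/Qs estimation (invasive or CMR) is required"
            )
        if self.pvr_wu is not None and self.pvr_wu > 3.0:
            raise CohortValidationError(
                f"{self.id}: PVR {self.pvr_wu} WU exceeds the 3 WU inclusion limit"
            )
        if self.clinical_variant == "L" and self.distance_to_ra_cm is not None:
            raise CohortValidationError(
                f"{self.id}: distance to RA is undefined for left-sided drainage"
            )


def categorize_model_variant(record: PatientRecord, permissive: bool = False) -> str:
    """Map a patient to the model's RA or VC anatomy.

    Left-sided drainage is always VC.  Right-sided drainage is RA when
    direct or within 2 cm of the right atrium, VC beyond 2 cm.  A
    right-sided record with no recorded distance is a validation error
    unless ``permissive``, in which case the clinical label decides
    (SVC -> VC, RA -> RA).
    """
    if record.clinical_variant == "L":
        return "VC"
    if record.distance_to_ra_cm is None:
        if permissive:
            return "VC" if record.clinical_variant == "SVC" else "RA"
        raise CohortValidationError(
            f"{record.id}: right-sided drainage without a distance to the RA "
            "(pass permissive=True to fall back to the clinical label)"
        )
    return "RA" if record.distance_to_ra_cm <= 2.0 else "VC"


# ---------------------------------------------------------------------------
# Nonparametric statistics
# ---------------------------------------------------------------------------

class TestResult(NamedTuple):
    statistic: float
    p_value: float


class CorrelationResult(NamedTuple):
    pearson_r: float | None
    spearman_rho: float | None
    pearson_p: float | None
    spearman_p: float | None


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    For combined n <= 12 without ties the p-value is exact (full
    enumeration of rank assignments); otherwise the normal approximation
    with tie correction is used.  Returns the rank-sum W of the first
    group and the p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ConfigurationError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        w = len(a) * (len(pooled) + 1) / 2.0
        return TestResult(float(w), 1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
    return TestResult(w, float(min(res.pvalue, 1.0)))


def _kw_statistic(groups: list[np.ndarray]) -> float:
    return float(stats.kruskal(*groups).statistic)


def kruskal_wallis(groups: Sequence[Sequence[float]], method: str = "auto") -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    ``method``: "asymptotic" (chi-square, k-1 df), "exact" (full
    enumeration of group assignments, total n <= 10), or "auto" (exact
    when feasible).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ConfigurationError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0)
    n_total = len(pooled)
    if method == "auto":
        method = "exact" if n_total <= 10 else "asymptotic"
    if method == "asymptotic":
        res = stats.kruskal(*gs)
        return TestResult(float(res.statistic), float(res.pvalue))
    if method != "exact":
        raise ConfigurationError(f"unknown method {method!r}")
    if n_total > 10:
        raise ConfigurationError("exact enumeration limited to total n <= 10")
    h_obs = _kw_statistic(gs)
    sizes = [len(g) for g in gs]
    idx_all = list(range(n_total))
    count = 0
    total = 0

    def assignments(remaining: list[int], size_idx: int, chosen: list[list[int]]):
        nonlocal count, total
        if size_idx == len(sizes) - 1:
            parts = chosen + [remaining]
            h = _kw_statistic([pooled[list(p)] for p in parts])
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(remaining, sizes[size_idx]):
            rest = [i for i in remaining if i not in comb]
            assignments(rest, size_idx + 1, chosen + [list(comb)])

    assignments(idx_all, 0, [])
    return TestResult(h_obs, count / total)


def correlations(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r and Spearman rho on complete cases (pairs with a missing
    value are dropped); undefined (zero variance or n < 3) reported as None."""
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    if len(xa) < 3 or np.std(xa) == 0.0 or np.std(ya) == 0.0:
        return CorrelationResult(None, None, None, None)
    pr = stats.pearsonr(xa, ya)
    sr = stats.spearmanr(xa, ya)
    return CorrelationResult(
        float(pr.statistic), float(sr.statistic), float(pr.pvalue), float(sr.pvalue)
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-group and per-stratum medians/IQRs, counts and test results."""

    n: int
    counts: dict
    stratum_table: pd.DataFrame
    tests: dict
    correlations: dict

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": self.counts,
            "tests": {k: {"statistic": v.statistic, "p_value": v.p_value}
                      for k, v in self.tests.items()},
            "correlations": {
                k: None if v.pearson_r is None else {
                    "pearson_r": v.pearson_r, "spearman_rho": v.spearman_rho,
                    "pearson_p": v.pearson_p, "spearman_p": v.spearman_p,
                }
                for k, v in self.correlations.items()
            },
        }


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def summarize_cohort(records: Sequence[PatientRecord], permissive: bool = False) -> CohortSummary:
    """Overall and per-(model group x territory) summary of a cohort,
    with the rank tests and correlations of the validation analysis.
    Empty strata are reported as absent rather than zero."""
    if not records:
        raise ConfigurationError("cohort is empty")
    df = records_to_frame(records)
    df["model_group"] = [categorize_model_variant(r, permissive) for r in records]

    counts = {
        "total": len(df),
        "female": int((df["sex"] == "F").sum()),
        "clinical_R": int((df["clinical_variant"] != "L").sum()),
        "clinical_L": int((df["clinical_variant"] == "L").sum()),
        "model_RA": int((df["model_group"] == "RA").sum()),
        "model_VC": int((df["model_group"] == "VC").sum()),
    }

    rows = []
    for terr in (1, 2, 3):
        sub_t = df[df["n_territories"] == terr]
        if sub_t.empty:
            continue
        for group in ("VC", "RA"):
            sub = sub_t[sub_t["model_group"] == group]
            if sub.empty:
                continue
            row = dict(
                n_territories=terr, model_group=group, n=len(sub),
                pct_of_territory=round(100.0 * len(sub) / len(sub_t)),
            )
            inv = sub[sub["qp_qs_invasive"].notna()]
            row["n_invasive"] = len(inv)
            row["pct_invasive_of_territory"] = (
                round(100.0 * len(inv) / max(sub_t["qp_qs_invasive"].notna().sum(), 1))
            )
            for col, label in (("qp_qs_invasive", "invasive"), ("qp_qs_cmr", "cmr"),
                               ("pvr_wu", "pvr")):
                vals = sub[col].dropna().to_numpy()
                if len(vals):
                    med, lo, hi = _median_iqr(vals)
                    row[f"{label}_median"] = med
                    row[f"{label}_q25"] = lo
                    row[f"{label}_q75"] = hi
            rows.append(row)
    stratum_table = pd.DataFrame(rows)

    tests: dict = {}
    ra = df[df["model_group"] == "RA"]
    vc = df[df["model_group"] == "VC"]
    for col, label in (("qp_qs_invasive", "invasive"), ("qp_qs_cmr", "cmr")):
        a = ra[col].dropna().to_numpy()
        b = vc[col].dropna().to_numpy()
        if len(a) and len(b):
            tests[f"ra_vs_vc_{label}"] = rank_sum_test(a, b)
        terr_groups = [
            df[df["n_territories"] == t][col].dropna().to_numpy() for t in (1, 2, 3)
        ]
        terr_groups = [g for g in terr_groups if len(g)]
        if len(terr_groups) >= 2:
            tests[f"territories_{label}"] = kruskal_wallis(terr_groups, method="asymptotic")

    corr = {
        "invasive_vs_cmr": correlations(
            df["qp_qs_invasive"].to_numpy(), df["qp_qs_cmr"].to_numpy()
        ),
        "invasive_vs_territories": correlations(
            df["qp_qs_invasive"].to_numpy(), df["n_territories"].to_numpy(dtype=float)
        ),
        "cmr_vs_territories": correlations(
            df["qp_qs_cmr"].to_numpy(), df["n_territories"].to_numpy(dtype=float)
        ),
    }
    return CohortSummary(
        n=len(df), counts=counts, stratum_table=stratum_table, tests=tests,
        correlations=corr,
    )


# ---------------------------------------------------------------------------
# Synthetic cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """Counts for one (territory, clinical variant) cell, split by which
    Qp/Qs modality is available."""

    territory: int
    clinical_variant: str
    n_invasive_only: int
    n_both: int
    n_cmr_only: int

    @property
    def n(self) -> int:
        return self.n_invasive_only + self.n_both + self.n_cmr_only


# Default structure: 49 patients, 36 right-sided / 13 left-sided, the
# published per-territory catheterization stratum counts, and the
# 16 invasive-only / 20 both / 13 CMR-only missingness split.
_DEFAULT_STRATA = (
    StratumSpec(1, "SVC", 0, 1, 1),
    StratumSpec(1, "RA", 1, 0, 1),
    StratumSpec(1, "L", 1, 2, 2),
    StratumSpec(2, "SVC", 5, 5, 1),
    StratumSpec(2, "RA", 2, 2, 4),
    StratumSpec(2, "L", 1, 2, 1),
    StratumSpec(3, "SVC", 1, 2, 1),
    StratumSpec(3, "RA", 3, 4, 2),
    StratumSpec(3, "L", 2, 2, 0),
)

# invasive Qp/Qs (median, q25, q75) per (territory, model group)
_DEFAULT_QPQS = {
    (1, "VC"): (1.35, 1.20, 1.55),
    (1, "RA"): (1.20, 1.10, 1.30),
    (2, "VC"): (1.40, 1.20, 1.40),
    (2, "RA"): (2.00, 1.80, 2.00),
    (3, "VC"): (1.70, 1.30, 2.00),
    (3, "RA"): (2.00, 1.80, 2.30),
}

# PVR in WU (median, q25, q75) per (territory, model group)
_DEFAULT_PVR = {
    (1, "VC"): (1.00, 1.00, 1.10),
    (1, "RA"): (1.00, 0.90, 1.10),
    (2, "VC"): (1.20, 0.50, 1.60),
    (2, "RA"): (1.40, 1.00, 1.60),
    (3, "VC"): (1.15, 0.70, 1.25),
    (3, "RA"): (0.90, 0.70, 1.10),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Stratum counts and distribution targets for the generator.

    Qp/Qs is drawn per stratum from a log-normal matched to the target
    median and IQR; the CMR estimate is the latent shunt value times
    log-normal measurement noise scaled to hit ``cmr_rank_corr_target``.
    """

    strata: tuple[StratumSpec, ...] = _DEFAULT_STRATA
    qpqs_targets: dict = field(default_factory=lambda: dict(_DEFAULT_QPQS))
    pvr_targets: dict = field(default_factory=lambda: dict(_DEFAULT_PVR))
    n_female: int = 27
    age_median: float = 39.0
    age_iqr: tuple[float, float] = (31.0, 52.0)
    pa_median: float = 16.0
    pa_iqr: tuple[float, float] = (8.0, 18.0)
    ra_median: float = 8.0
    ra_iqr: tuple[float, float] = (2.0, 10.0)
    cmr_rank_corr_target: float = 0.75

    def validate(self) -> None:
        for key, (med, lo, hi) in {**self.qpqs_targets, **self.pvr_targets}.items():
            if not (lo <= med <= hi):
                raise ConfigurationError(
                    f"stratum {key}: infeasible median/IQR ({med}, [{lo}, {hi}])"
                )


_Z_IQR = 2.0 * stats.norm.ppf(0.75)  # IQR width of a standard normal


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    mu = math.log(median)
    if q75 > q25 > 0.0:
        sigma = math.log(q75 / q25) / _Z_IQR
    else:
        sigma = 0.05
    return mu, max(sigma, 0.02)


def generate_synthetic_cohort(
    config: SyntheticCohortConfig | None = None, seed: int = 0
) -> list[PatientRecord]:
    """Deterministic synthetic cohort (same seed, byte-identical table).

    Stratum membership, clinical variants and measurement availability are
    fixed by the config; Qp/Qs, PVR, pressures, ages and distances are
    drawn from the configured distributions.
    """
    if config is None:
        config = SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_total = sum(s.n for s in config.strata)

    sexes = np.array(["F"] * config.n_female + ["M"] * (n_total - config.n_female))
    rng.shuffle(sexes)
    age_mu, age_sigma = _lognormal_params(config.age_median, *config.age_iqr)
    pa_mu, pa_sigma = _lognormal_params(config.pa_median, *config.pa_iqr)
    ra_mu, ra_sigma = _lognormal_params(config.ra_median, *config.ra_iqr)

    records: list[dict] = []
    latents: list[float] = []
    idx = 0
    for spec in config.strata:
        group = "VC" if spec.clinical_variant in ("SVC", "L") else "RA"
        q_mu, q_sigma = _lognormal_params(*config.qpqs_targets[(spec.territory, group)])
        p_mu, p_sigma = _lognormal_params(*config.pvr_targets[(spec.territory, group)])
        modalities = (
            ["invasive"] * spec.n_invasive_only
            + ["both"] * spec.n_both
            + ["cmr"] * spec.n_cmr_only
        )
        for modality in modalities:
            idx += 1
            latent = q_mu + q_sigma * rng.standard_normal()
            latents.append(latent)
            if spec.clinical_variant == "L":
                distance = None
            elif spec.clinical_variant == "RA":
                distance = round(float(rng.uniform(0.0, 2.0)), 1)
            else:
                distance = round(float(2.2 + rng.lognormal(0.8, 0.5)), 1)
            records.append(
                dict(
                    id=f"P{idx:03d}",
                    age=round(float(np.exp(age_mu + age_sigma * rng.standard_normal()))),
                    sex=str(sexes[idx - 1]),
                    clinical_variant=spec.clinical_variant,
                    n_territories=spec.territory,
                    distance_to_ra_cm=distance,
                    latent=latent,
                    modality=modality,
                    pvr_wu=round(float(np.clip(
                        np.exp(p_mu + p_sigma * rng.standard_normal()), 0.2, 3.0
                    )), 2),
                    pa_mmhg=round(float(np.clip(
                        np.exp(pa_mu + pa_sigma * rng.standard_normal()), 4.0, 30.0
                    ))),
                    ra_mmhg=round(float(np.clip(
                        np.exp(ra_mu + ra_sigma * rng.standard_normal()), 1.0, 15.0
                    ))),
                )
            )

    # CMR noise scaled so that Spearman(invasive, CMR) ~ the target among
    # dual-modality patients: for jointly log-normal values,
    # rho ~ s / sqrt(s^2 + sigma_noise^2) with s the latent log-sd.
    s = float(np.std(latents))
    rho = config.cmr_rank_corr_target
    noise_sigma = s * math.sqrt(max(1.0 / rho**2 - 1.0, 0.0))

    out: list[PatientRecord] = []
    for rec in records:
        latent = rec.pop("latent")
        modality = rec.pop("modality")
        invasive = round(float(np.exp(latent)), 2) if modality in ("invasive", "both") else None
        cmr = (
            round(float(np.exp(latent + noise_sigma * rng.standard_normal())), 2)
            if modality in ("both", "cmr")
            else None
        )
        out.append(PatientRecord(qp_qs_invasive=invasive, qp_qs_cmr=cmr, **rec))
    return out


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

_COLUMNS = [
    "id", "age", "sex", "clinical_variant", "n_territories", "distance_to_ra_cm",
    "qp_qs_invasive", "qp_qs_cmr", "pvr_wu", "pa_mmhg", "ra_mmhg",
]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _COLUMNS:
            v = row.get(c)
            if pd.isna(v):
                v = None
            kwargs[c] = v
        kwargs["n_territories"] = int(kwargs["n_territories"])
        records.append(PatientRecord(**kwargs))
    return records


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a patient table (CSV, missing values as empty cells)."""
    return frame_to_records(pd.read_csv(path))


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
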