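"""Synthetic patient cohorts with the joint structure the analysis assumes.

The generator emulates a single-centre thrombectomy cohort of 137 patients in
four enhancement groups (C_NE/C_NW/C_W/C_LE of sizes 49/22/37/29): per-group
Gaussian three-phase clot densities (rejection-sampled so the stored category
always agrees with the rule-based classifier), Bernoulli recanalization
success, shifted-Poisson retrieval passes, Gaussian admission NIHSS, and
baseline-anchored discharge NIHSS / 3-month mRS with additive group effects.
Missingness reproduces the clinical accounting: deaths before discharge
remove the discharge NIHSS and the 3-month mRS, additional patients lose the
3-month follow-up, and patients without an intervention have no pass count.

All randomness flows from one `numpy` generator stream, so a cohort is fully
determined by its parameters and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CATEGORIES, DEFAULT_TAU, _classify_arrays
from .errors import ConfigurationError

__all__ = ["CohortParams", "simulate_cohort", "truth_table"]


def _per_group(values) -> dict[str, float]:
    return dict(zip(CATEGORIES, values))


@dataclass
class CohortParams:
    """Ground-truth parameters of the synthetic cohort.

    Defaults reproduce the observed per-group composition: sizes 49/22/37/29,
    per-phase density means/SDs, recanalization probabilities 39/49, 15/22,
    29/37, 26/29, mean pass counts 2.5/2.7/2.0/2.6, per-group admission NIHSS
    and 3-month mRS levels, and missingness totals (26 deaths before
    discharge, 35 additional missing 3-month mRS, 10 without intervention).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: _per_group((49, 22, 37, 29)))
    # (ncct, cta, ctv) HU means / SDs per category.
    phase_mu: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "C_NE": (68.6, 67.0, 68.7),
        "C_NW": (62.5, 73.1, 78.2),
        "C_W": (61.3, 95.3, 68.5),
        "C_LE": (62.5, 61.4, 79.8),
    })
    phase_sd: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "C_NE": (8.1, 8.7, 8.2),
        "C_NW": (9.6, 9.8, 14.6),
        "C_W": (10.8, 31.1, 13.4),
        "C_LE": (7.9, 8.1, 16.6),
    })
    recan_prob: dict[str, float] = field(
        default_factory=lambda: _per_group((39 / 49, 15 / 22, 29 / 37, 26 / 29))
    )
    passes_mean: dict[str, float] = field(default_factory=lambda: _per_group((2.5, 2.7, 2.0, 2.6)))
    passes_cap: int = 9
    nihss_admit_mu: dict[str, float] = field(default_factory=lambda: _per_group((13.5, 17.0, 12.2, 13.6)))
    nihss_admit_sd: dict[str, float] = field(default_factory=lambda: _per_group((6.9, 6.9, 6.3, 5.5)))
    # Discharge NIHSS = admission + shift + group effect + N(0, sd), clipped to 0..42.
    nihss_discharge_shift: float = -4.0
    nihss_discharge_sd: float = 4.0
    nihss_effects: dict[str, float] = field(
        default_factory=lambda: _per_group((-1.24, 0.0, -1.17, -3.05))
    )
    # 3-month mRS = admission mRS + shift + group effect + N(0, sd), clipped to 0..6.
    mrs_admit_mu: float = 3.5
    mrs_admit_sd: float = 1.2
    mrs_shift: float = 0.4
    mrs_sd: float = 1.3
    mrs_effects: dict[str, float] = field(
        default_factory=lambda: _per_group((-0.15, 0.0, -0.85, -1.30))
    )
    age_mu: dict[str, float] = field(default_factory=lambda: _per_group((70.2, 78.0, 71.5, 75.5)))
    age_sd: dict[str, float] = field(default_factory=lambda: _per_group((15.9, 12.3, 13.8, 12.1)))
    female_frac: float = 56 / 137
    site_probs: dict[str, float] = field(default_factory=lambda: {
        "ICA": 43 / 137, "M1": 69 / 137, "M2": 19 / 137, "BA": 6 / 137,
    })
    clot_length_mu: dict[str, float] = field(default_factory=lambda: _per_group((18.9, 20.2, 14.7, 19.9)))
    clot_length_sd: dict[str, float] = field(default_factory=lambda: _per_group((9.4, 11.4, 8.1, 13.0)))
    clot_length_range: tuple[float, float] = (3.0, 61.0)
    # Missingness totals over the whole cohort.
    n_deaths: int = 26
    n_missing_mrs: int = 35
    n_no_intervention: int = 10
    # Among successful recanalizations, the fraction graded TICI 3 (vs 2c).
    tici3_frac: float = 0.7
    tau: float = DEFAULT_TAU

    def validate(self) -> None:
        for cat in CATEGORIES:
            if self.group_sizes.get(cat, 0) < 0:
                raise ConfigurationError(f"group size for {cat} must be >= 0")
            if not 0.0 <= self.recan_prob[cat] <= 1.0:
                raise ConfigurationError(f"recan_prob[{cat}] must be in [0, 1]")
            if any(s <= 0 for s in self.phase_sd[cat]):
                raise ConfigurationError(f"phase SDs for {cat} must be positive")
            if self.passes_mean[cat] < 1.0:
                raise ConfigurationError(f"passes_mean[{cat}] must be >= 1")
        n = self.n_total
        for name in ("n_deaths", "n_missing_mrs", "n_no_intervention"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_deaths + self.n_missing_mrs > n:
            raise ConfigurationError("more missing follow-ups than patients")
        if self.n_no_intervention > n:
            raise ConfigurationError("more non-interventions than patients")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-6:
            raise ConfigurationError("site probabilities must sum to 1")

    @property
    def n_total(self) -> int:
        return int(sum(self.group_sizes.values()))

    def scaled(self, multiplier: int) -> "CohortParams":
        """Return a copy with group sizes and missingness totals scaled."""
        if multiplier < 1:
            raise ConfigurationError("multiplier must be >= 1")
        out = dataclasses.replace(
            self,
            group_sizes={k: v * multiplier for k, v in self.group_sizes.items()},
            n_deaths=self.n_deaths * multiplier,
            n_missing_mrs=self.n_missing_mrs * multiplier,
            n_no_intervention=self.n_no_intervention * multiplier,
        )
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CohortParams":
        """Build params from a (possibly partial) plain mapping, e.g. YAML."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in mapping.items():
            if key not in fields:
                raise ConfigurationError(f"unknown cohort parameter {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, dict) and isinstance(value, Mapping):
                merged = dict(default)
                merged.update({k: tuple(v) if isinstance(v, (list, tuple)) else v
                               for k, v in value.items()})
                kwargs[key] = merged
            elif isinstance(default, tuple) and isinstance(value, (list, tuple)):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


_MAX_REJECTION_ROUNDS = 200


def _sample_group_densities(
    rng: np.random.Generator, cat: str, n: int, params: CohortParams
) -> np.ndarray:
    """Draw (n, 3) phase densities whose classification equals ``cat``.

    Per-phase independent Gaussians (only marginal moments are specified)
    with rejection until the rule-based classification matches.
    """
    mu = np.asarray(params.phase_mu[cat], dtype=float)
    sd = np.asarray(params.phase_sd[cat], dtype=float)
    out = np.empty((0, 3))
    batch = max(4 * n, 64)
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.normal(mu, sd, size=(batch, 3))
        dna = draw[:, 1] - draw[:, 0]
        dav = draw[:, 2] - draw[:, 1]
        labels = _classify_arrays(dna, dna + dav, dav, params.tau)
        keep = draw[labels == cat]
        out = np.vstack([out, keep])
        if len(out) >= n:
            return out[:n]
        batch = min(4 * batch, 1 << 16)
    raise ConfigurationError(
        f"category {cat} is (nearly) unreachable under its density parameters; "
        "rejection sampling failed"
    )


def simulate_cohort(
    params: CohortParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one cohort; returns a tidy per-patient DataFrame.

    Columns: patient_id, dp_category, age, sex, occlusion_site,
    clot_length_mm, ncct_hu, cta_hu, ctv_hu, delta_na, delta_nv, delta_av,
    sp_tai, tici, success, n_passes, nihss_admit, nihss_discharge, mrs_admit,
    mrs_3mo.  Missing outcomes are NaN.
    """
    params = params or CohortParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    records = []
    for cat in CATEGORIES:
        n = int(params.group_sizes.get(cat, 0))
        if n == 0:
            continue
        dens = _sample_group_densities(rng, cat, n, params)
        age = rng.normal(params.age_mu[cat], params.age_sd[cat], n).clip(18, 100)
        female = rng.random(n) < params.female_frac
        sites = rng.choice(list(params.site_probs), p=list(params.site_probs.values()), size=n)
        lo, hi = params.clot_length_range
        length = rng.normal(params.clot_length_mu[cat], params.clot_length_sd[cat], n).clip(lo, hi)
        success = rng.random(n) < params.recan_prob[cat]
        tici = np.where(success, np.where(rng.random(n) < params.tici3_frac, "3", "2c"), "0-2b")
        passes = 1 + rng.poisson(params.passes_mean[cat] - 1.0, n)
        passes = np.minimum(passes, params.passes_cap)
        nihss_admit = np.rint(
            rng.normal(params.nihss_admit_mu[cat], params.nihss_admit_sd[cat], n)
        ).clip(0, 42)
        nihss_dis = np.rint(
            nihss_admit
            + params.nihss_discharge_shift
            + params.nihss_effects[cat]
            + rng.normal(0.0, params.nihss_discharge_sd, n)
        ).clip(0, 42)
        mrs_admit = np.rint(rng.normal(params.mrs_admit_mu, params.mrs_admit_sd, n)).clip(0, 6)
        mrs_3mo = np.rint(
            mrs_admit
            + params.mrs_shift
            + params.mrs_effects[cat]
            + rng.normal(0.0, params.mrs_sd, n)
        ).clip(0, 6)
        dna = dens[:, 1] - dens[:, 0]
        dav = dens[:, 2] - dens[:, 1]
        records.append(pd.DataFrame({
            "dp_category": cat,
            "age": np.round(age, 1),
            "sex": np.where(female, "F", "M"),
            "occlusion_site": sites,
            "clot_length_mm": np.round(length, 1),
            "ncct_hu": dens[:, 0],
            "cta_hu": dens[:, 1],
            "ctv_hu": dens[:, 2],
            "delta_na": dna,
            "delta_nv": dna + dav,
            "delta_av": dav,
            "sp_tai": dna,
            "tici": tici,
            "success": success,
            "n_passes": passes.astype(float),
            "nihss_admit": nihss_admit,
            "nihss_discharge": nihss_dis,
            "mrs_admit": mrs_admit,
            "mrs_3mo": mrs_3mo,
        }))

    cohort = pd.concat(records, ignore_index=True)
    n_total = len(cohort)
    cohort.insert(0, "patient_id", [f"P{i:05d}" for i in range(1, n_total + 1)])

    # Missingness: deaths void discharge NIHSS and 3-month mRS; a further set
    # of survivors misses the 3-month follow-up; non-interventions have no
    # pass count.  All assignments are uniform at random.
    deaths = rng.choice(n_total, size=min(params.n_deaths, n_total), replace=False)
    cohort.loc[deaths, "nihss_discharge"] = np.nan
    cohort.loc[deaths, "mrs_3mo"] = np.nan
    survivors = np.setdiff1d(np.arange(n_total), deaths)
    extra = rng.choice(survivors, size=min(params.n_missing_mrs, len(survivors)), replace=False)
    cohort.loc[extra, "mrs_3mo"] = np.nan
    no_interv = rng.choice(n_total, size=min(params.n_no_intervention, n_total), replace=False)
    cohort.loc[no_interv, "n_passes"] = np.nan

    return cohort


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    s = series.dropna()
    if len(s) == 0:
        return (np.nan, np.nan)
    return (float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else np.nan)


def truth_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group (plus overall) summary in the layout of the clinical table.

    Rows: Overall plus one per category.  Columns: N, mean/SD of age, clot
    length, per-phase densities and admission NIHSS, recanalization success
    N (%), mean (SD) passes, mean (SD) 3-month mRS.  Single-patient groups
    report SD as NaN; empty groups report N = 0 with absent statistics.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = {}
    groups = {"Overall": cohort}
    groups.update({cat: cohort[cohort["dp_category"] == cat] for cat in CATEGORIES})
    for name, g in groups.items():
        row: dict[str, float] = {"n": len(g)}
        if len(g) == 0:
            rows[name] = row
            continue
        for col, label in [
            ("age", "age"),
            ("clot_length_mm", "clot_length"),
            ("ncct_hu", "ncct"),
            ("cta_hu", "cta"),
            ("ctv_hu", "ctv"),
            ("nihss_admit", "nihss_admit"),
            ("n_passes", "passes"),
            ("mrs_3mo", "mrs_3mo"),
        ]:
            m, s = _mean_sd(g[col])
            row[f"{label}_mean"] = m
            row[f"{label}_sd"] = s
        n_success = int(g["success"].sum())
        row["success_n"] = n_success
        row["success_pct"] = 100.0 * n_success / len(g)
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "group"
    table["n"] = table["n"].astype(int)
    return table
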