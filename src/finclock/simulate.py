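"""Synthetic methylation datasets with clock-like structure.

Generates CpG-by-sample beta matrices plus sample sheets that carry the
statistical structure the clock pipeline assumes, standing in for a wild
dolphin cohort profiled on a mammalian methylation array:

* **age CpGs** — beta_ij = clip01(a_j + b_j * F(age_i) + eps), with F the
  log-linear age transform (knot at the average age of sexual maturity),
  baselines a_j uniform on [0.2, 0.8], slopes b_j symmetric around zero
  (hyper- and hypomethylating CpGs both occur) and gaussian noise;
* **sex CpGs** — baseline plus a mean shift of ``sex_effect`` in males;
* **null CpGs** — baseline plus noise, independent of age and sex;
* optional **technical outlier arrays** whose values are resampled
  uniformly on [0, 1], destroying the inter-array correlation that QC
  screens for.

Ages are continuous-uniform over the cohort age range by default; a
"cohort" preset draws from a truncated normal matching the study
population's mean and spread.  Sex is Bernoulli(1/2).  All draws flow from
one seeded generator, so identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .age_transform import AgeTransform
from .io import BetaMatrix, SampleSheet

__all__ = ["SimulationConfig", "TruthRecord", "simulate_dataset", "inject_outliers"]


@dataclass
class SimulationConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the calibration cohort of the dolphin study: 68
    known-age animals aged 0-37 years, a few hundred age-informative CpGs
    among a large majority of uninformative ones, and a per-observation
    beta noise of 0.03.  ``sex_effect`` is the mean beta difference between
    males and females at sex-differentiated CpGs.
    """

    n_samples: int = 68
    n_age_cpgs: int = 200
    n_sex_cpgs: int = 30
    n_null_cpgs: int = 1800
    age_range: tuple[float, float] = (0.0, 37.0)
    age_effect_sd: float = 0.05
    noise_sd: float = 0.03
    sex_effect: float = 0.3
    n_outliers: int = 0
    adult_age: float = 7.0
    offset: float = 1.0
    age_distribution: str = "uniform"  # or "cohort"
    cohort_mean: float = 14.6
    cohort_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if min(self.n_age_cpgs, self.n_sex_cpgs, self.n_null_cpgs) < 0:
            raise ValueError("CpG counts must be non-negative")
        if self.n_age_cpgs + self.n_sex_cpgs + self.n_null_cpgs == 0:
            raise ValueError("at least one CpG must be simulated")
        lo, hi = self.age_range
        if not (0.0 <= lo < hi <= 60.0):
            raise ValueError("age_range must satisfy 0 <= min < max <= 60")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.sex_effect <= 1.0:
            raise ValueError("sex_effect must be in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers >= self.n_samples:
            raise ValueError("n_outliers must be in [0, n_samples)")
        if self.age_distribution not in ("uniform", "cohort"):
            raise ValueError("age_distribution must be 'uniform' or 'cohort'")

    @property
    def n_cpgs(self) -> int:
        return self.n_age_cpgs + self.n_sex_cpgs + self.n_null_cpgs

    def transform(self) -> AgeTransform:
        return AgeTransform(adult_age=self.adult_age, offset=self.offset)


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset.

    ``cpgs``: per-CpG class ("age" | "sex" | "null"), intercept a_j, slope
    b_j (age CpGs) and sex offset (sex CpGs).  ``samples``: true age, sex
    and outlier flag per sample.
    """

    cpgs: pd.DataFrame
    samples: pd.DataFrame
    config: SimulationConfig | None = field(default=None, repr=False)

    def cpg_ids_of_class(self, cls: str) -> list[str]:
        return list(self.cpgs.index[self.cpgs["class"] == cls])

    def to_dict(self) -> dict:
        return {
            "cpgs": self.cpgs.reset_index().to_dict(orient="list"),
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "config": asdict(self.config) if self.config else None,
        }


def _draw_ages(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    if cfg.age_distribution == "uniform":
        return rng.uniform(lo, hi, cfg.n_samples)
    ages = np.empty(cfg.n_samples)
    filled = 0
    while filled < cfg.n_samples:  # truncated normal by resampling
        draw = rng.normal(cfg.cohort_mean, cfg.cohort_sd, cfg.n_samples)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, cfg.n_samples - filled)
        ages[filled : filled + take] = keep[:take]
        filled += take
    return ages


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[BetaMatrix, SampleSheet, TruthRecord]:
    """Draw one synthetic cohort; identical config (incl. seed) gives
    bit-identical output."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.transform()

    ages = _draw_ages(cfg, rng)
    male = rng.random(cfg.n_samples) < 0.5
    f_age = t.transform(ages)

    sample_ids = [f"s{i + 1:04d}" for i in range(cfg.n_samples)]
    n_cpg = cfg.n_cpgs
    cpg_ids = [f"cg{j + 1:06d}" for j in range(n_cpg)]
    classes = (
        ["age"] * cfg.n_age_cpgs
        + ["sex"] * cfg.n_sex_cpgs
        + ["null"] * cfg.n_null_cpgs
    )

    intercepts = np.empty(n_cpg)
    slopes = np.zeros(n_cpg)
    sex_offsets = np.zeros(n_cpg)

    na, ns = cfg.n_age_cpgs, cfg.n_sex_cpgs
    intercepts[:na] = rng.uniform(0.2, 0.8, na)
    slopes[:na] = rng.normal(0.0, cfg.age_effect_sd, na)
    # keep the male shift inside [0,1] so group means differ by sex_effect
    intercepts[na : na + ns] = rng.uniform(0.2, 0.8 - cfg.sex_effect, ns)
    sex_offsets[na : na + ns] = cfg.sex_effect
    intercepts[na + ns :] = rng.uniform(0.2, 0.8, n_cpg - na - ns)

    signal = (
        intercepts[:, None]
        + slopes[:, None] * f_age[None, :]
        + sex_offsets[:, None] * male[None, :].astype(float)
    )
    noise = rng.normal(0.0, cfg.noise_sd, signal.shape) if cfg.noise_sd > 0 else 0.0
    values = np.clip(signal + noise, 0.0, 1.0)

    matrix = BetaMatrix(cpg_ids, sample_ids, values)
    outlier_ids: list[str] = []
    if cfg.n_outliers:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        matrix, outlier_ids = inject_outliers(matrix, cfg.n_outliers, sub_seed)

    sheet = SampleSheet.from_records(
        sample_ids,
        ages,
        np.ones(cfg.n_samples),
        np.where(male, "M", "F"),
    )
    truth = TruthRecord(
        cpgs=pd.DataFrame(
            {
                "class": classes,
                "intercept": intercepts,
                "slope": slopes,
                "sex_offset": sex_offsets,
            },
            index=pd.Index(cpg_ids, name="cpg_id"),
        ),
        samples=pd.DataFrame(
            {
                "age": ages,
                "sex": np.where(male, "M", "F"),
                "outlier": np.isin(sample_ids, outlier_ids),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        config=cfg,
    )
    return matrix, sheet, truth


def inject_outliers(
    matrix: BetaMatrix, k: int, seed: int
) -> tuple[BetaMatrix, list[str]]:
    """Corrupt k arrays by resampling their values uniformly on [0, 1].

    Destroys the inter-array correlation of the chosen columns while
    leaving every other array untouched.  Returns the new matrix and the
    corrupted sample ids.
    """
    if k < 0 or k >= matrix.n_samples:
        raise ValueError(
            f"outlier count must be in [0, n_samples); got k={k} with "
            f"{matrix.n_samples} samples"
        )
    if k == 0:
        return matrix, []
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(matrix.n_samples, size=k, replace=False))
    values = matrix.values.copy()
    values[:, cols] = rng.random((matrix.n_cpgs, k))
    ids = [matrix.sample_ids[c] for c in cols]
    return BetaMatrix(matrix.cpg_ids, matrix.sample_ids, values), ids
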