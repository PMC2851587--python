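"""Synthetic label-free LC-MS intensity data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a 2 (age) x 2 (sex) x 2 (treatment) factorial with samples run in a
randomized-block injection sequence, a technical-replicate reference sample
bookending the blocks, smooth run-order intensity drift, per-run affine scale
distortion, sparse group effects dominated by age, iid Gaussian noise, and
intensity-dependent (missing-not-at-random) dropout: the lower a peptide's
underlying intensity in a run, the more likely the peak is not detected.

The default configuration mirrors the quail diencephalon study dimensions:
204 peptides x 42 runs (36 biological samples in 8 groups of 4-5, plus 6
injections of one reference sample over 5 blocks).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import GROUP_LABELS, IntensityMatrix, validate_design

__all__ = ["SimulationConfig", "GroundTruth", "generate_design",
           "simulate_intensities", "study_config"]

_STUDY_GROUP_SIZES = {
    "ed12MC": 5, "ed12FC": 5, "ed12ME": 5, "ed12FE": 4,
    "ed17MC": 4, "ed17FC": 4, "ed17ME": 4, "ed17FE": 5,
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults reproduce the study design.

    Effect sizes are level-mean differences in log2 units (ed17-ed12, F-M,
    E-C), so a planted age effect of +2 means the ed17 group mean sits 2 log2
    units above ed12.  Missingness follows a logistic curve in the true
    intensity: p(missing) = floor + (1-floor) * sigmoid(-steepness*(x-mid)).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_STUDY_GROUP_SIZES))
    n_blocks: int = 5
    reference_replicates: int = 6          # n_blocks + 1 bookending pattern
    reference_group: str = "ed17FC"
    n_peptides: int = 204
    baseline_mean: float = 17.0            # log2 ion intensity
    baseline_sd: float = 2.0
    age_effect_fraction: float = 0.4       # age dominates the signal
    age_effect_mean: float = 1.5           # mostly up in ed17
    age_effect_sd: float = 0.8
    sex_effect_fraction: float = 0.05
    sex_effect_mean: float = 0.0
    sex_effect_sd: float = 0.6
    treatment_effect_fraction: float = 0.10
    treatment_effect_mean: float = 0.0
    treatment_effect_sd: float = 0.6
    interaction_fraction: float = 0.05
    interaction_sd: float = 0.5
    drift_amplitude: float = 0.5           # log2 units
    drift_shape: str = "sinusoidal"        # linear | sinusoidal | spline
    run_slope_sd: float = 0.05
    run_intercept_sd: float = 0.3
    noise_sd: float = 0.5
    miss_midpoint: float = 13.0
    miss_steepness: float = 1.5
    miss_floor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        sds = [self.baseline_sd, self.age_effect_sd, self.sex_effect_sd,
               self.treatment_effect_sd, self.interaction_sd,
               self.run_slope_sd, self.run_intercept_sd, self.noise_sd]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")
        fracs = [self.age_effect_fraction, self.sex_effect_fraction,
                 self.treatment_effect_fraction, self.interaction_fraction,
                 self.miss_floor]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions and rates must lie in [0, 1]")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        bad = set(self.group_sizes) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if self.drift_shape not in ("linear", "sinusoidal", "spline"):
            raise ValueError(f"unknown drift shape {self.drift_shape!r}")
        if self.n_blocks < 1 or self.n_peptides < 1:
            raise ValueError("n_blocks and n_peptides must be >= 1")
        total = sum(self.group_sizes.values())
        if total < self.n_blocks:
            raise ValueError(
                f"{total} samples cannot be distributed over {self.n_blocks} blocks")


def study_config(**overrides) -> SimulationConfig:
    """The 'study2010' preset: 204 peptides x 42 runs, 5 blocks."""
    return SimulationConfig(**overrides)


@dataclass
class GroundTruth:
    """True per-peptide effects, per-run distortions and dropout probabilities."""

    effects: pd.DataFrame          # peptides x {age, sex, treatment, age_sex, ...}
    run_slope: pd.Series           # run_id -> multiplicative slope deviation
    run_intercept: pd.Series
    drift: pd.Series               # run_id -> drift value (log2)
    true_values: pd.DataFrame      # noiseless pre-dropout matrix
    miss_prob: pd.DataFrame


def _drift_values(config: SimulationConfig, n_runs: int,
                  rng: np.random.Generator) -> np.ndarray:
    order = np.arange(1, n_runs + 1, dtype=float)
    a = config.drift_amplitude
    if a == 0:
        return np.zeros(n_runs)
    if config.drift_shape == "linear":
        centered = (order - order.mean()) / (n_runs - 1 if n_runs > 1 else 1)
        return a * centered
    if config.drift_shape == "sinusoidal":
        return a * np.sin(2 * np.pi * (order - 1) / n_runs)
    # spline: smooth interpolation through a few random knots
    from scipy.interpolate import CubicSpline

    n_knots = max(4, n_runs // 10)
    knots = np.linspace(1, n_runs, n_knots)
    vals = rng.normal(0.0, a, size=n_knots)
    return CubicSpline(knots, vals)(order)


def generate_design(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Randomize samples to blocks; reference bookends each block.

    The reference sample opens block 1, and a further replicate closes each
    block, giving n_blocks + 1 reference runs by default.  Fewer replicates
    drop trailing positions; more are disallowed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_ref = config.reference_replicates
    if n_ref > config.n_blocks + 1:
        raise ValueError(
            f"at most n_blocks+1={config.n_blocks + 1} reference replicates "
            f"fit the bookending layout, got {n_ref}")

    samples = []
    for group in GROUP_LABELS:
        for k in range(config.group_sizes.get(group, 0)):
            samples.append((f"S{len(samples) + 1:03d}", group))
    rng.shuffle(samples)
    # Distribute as evenly as possible over blocks.
    splits = np.array_split(np.arange(len(samples)), config.n_blocks)

    ref_group = config.reference_group
    letters = string.ascii_lowercase
    rows = []
    ref_used = 0

    def add_ref():
        nonlocal ref_used
        if ref_used < n_ref:
            rows.append((f"REF{letters[ref_used]}", "REF", ref_group, 1))
            ref_used += 1

    for b, idx in enumerate(splits):
        if b == 0:
            add_ref()
        for i in idx:
            sid, group = samples[i]
            rows.append((sid, sid, group, 0))
        add_ref()

    design = pd.DataFrame(rows, columns=["run_id", "sample_id", "group", "is_reference"])
    design["age"] = design["group"].str[:4]
    design["sex"] = design["group"].str[4]
    design["treatment"] = design["group"].str[5]
    design["run_order"] = np.arange(1, len(design) + 1)
    # Assign block labels by position of the closing reference runs.
    block_sizes = [len(s) for s in splits]
    labels = []
    b = 0
    count = 0
    for _, row in design.iterrows():
        labels.append(f"B{b + 1}")
        count += 1
        # block b ends after its samples plus its closing reference
        expected = block_sizes[b] + (2 if b == 0 else 1)
        if count >= expected and b < config.n_blocks - 1:
            b += 1
            count = 0
    design["block"] = labels
    design = design[["run_order", "run_id", "sample_id", "age", "sex",
                     "treatment", "block", "is_reference"]]
    design["is_reference"] = design["is_reference"].astype(bool)
    validate_design(design)
    return design


def simulate_intensities(config: SimulationConfig,
                         design: pd.DataFrame | None = None,
                         catalog=None) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate a log2 intensity matrix and its ground truth.

    value(p, r) = baseline_p + group effects + slope_r*(baseline_p - mean)
                  + intercept_r + drift(order_r) + Normal(0, noise_sd^2),
    after which entries are deleted with the logistic-MNAR probability.
    Fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if design is None:
        design = generate_design(config, rng)
    n_runs = len(design)
    p = config.n_peptides

    if catalog is not None:
        names = [f"{rec.peptide_name}|{rec.sequence}" for rec in catalog]
        peptide_ids = [names[i % len(names)] + (f"#{i // len(names)}" if i >= len(names) else "")
                       for i in range(p)]
    else:
        peptide_ids = [f"pep{i + 1:04d}" for i in range(p)]
    run_ids = list(design["run_id"])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)

    def planted(fraction, mean, sd):
        eff = np.zeros(p)
        n_hit = int(round(fraction * p))
        if n_hit:
            hit = rng.choice(p, size=n_hit, replace=False)
            eff[hit] = rng.normal(mean, sd, size=n_hit)
        return eff

    eff = pd.DataFrame(
        {
            "age": planted(config.age_effect_fraction,
                           config.age_effect_mean, config.age_effect_sd),
            "sex": planted(config.sex_effect_fraction,
                           config.sex_effect_mean, config.sex_effect_sd),
            "treatment": planted(config.treatment_effect_fraction,
                                 config.treatment_effect_mean,
                                 config.treatment_effect_sd),
            "age_sex": planted(config.interaction_fraction, 0.0,
                               config.interaction_sd),
            "age_treatment": planted(config.interaction_fraction, 0.0,
                                     config.interaction_sd),
            "sex_treatment": planted(config.interaction_fraction, 0.0,
                                     config.interaction_sd),
        },
        index=peptide_ids,
    )

    hi_age = (design["age"] == "ed17").to_numpy(float)
    hi_sex = (design["sex"] == "F").to_numpy(float)
    hi_trt = (design["treatment"] == "E").to_numpy(float)

    bio = (
        baseline[:, None]
        + np.outer(eff["age"], hi_age)
        + np.outer(eff["sex"], hi_sex)
        + np.outer(eff["treatment"], hi_trt)
        + np.outer(eff["age_sex"], hi_age * hi_sex)
        + np.outer(eff["age_treatment"], hi_age * hi_trt)
        + np.outer(eff["sex_treatment"], hi_sex * hi_trt)
    )

    slope = rng.normal(0.0, config.run_slope_sd, size=n_runs)
    intercept = rng.normal(0.0, config.run_intercept_sd, size=n_runs)
    drift = _drift_values(config, n_runs, rng)
    order_idx = design["run_order"].to_numpy() - 1

    true_vals = (
        bio
        + slope[None, :] * (baseline[:, None] - config.baseline_mean)
        + intercept[None, :]
        + drift[order_idx][None, :]
    )
    noisy = true_vals + rng.normal(0.0, config.noise_sd, size=true_vals.shape)

    if np.isinf(config.miss_steepness):
        p_miss = np.where(noisy < config.miss_midpoint, 1.0, 0.0)
        p_miss = config.miss_floor + (1 - config.miss_floor) * p_miss
    else:
        p_miss = config.miss_floor + (1 - config.miss_floor) * expit(
            -config.miss_steepness * (noisy - config.miss_midpoint))
    dropped = rng.random(size=noisy.shape) < p_miss
    observed = np.where(dropped, np.nan, noisy)

    values = pd.DataFrame(observed, index=peptide_ids, columns=run_ids)
    truth = GroundTruth(
        effects=eff,
        run_slope=pd.Series(slope, index=run_ids, name="slope"),
        run_intercept=pd.Series(intercept, index=run_ids, name="intercept"),
        drift=pd.Series(drift[order_idx], index=run_ids, name="drift"),
        true_values=pd.DataFrame(true_vals, index=peptide_ids, columns=run_ids),
        miss_prob=pd.DataFrame(p_miss, index=peptide_ids, columns=run_ids),
    )
    return IntensityMatrix(values=values, state=("log2",)), truth
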