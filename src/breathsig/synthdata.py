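"""Synthetic cohorts and raw breath recordings with known ground truth.

The generator emulates the structure of the real study data: ~2,315
breath-associated m/z features, a planted differential subset with signed
log2 effects, 13C-isotopologue and adduct satellite features, multi-plateau
exhalation recordings at 0.5 s per scan, multiplicative noise, and latent
batch factors. Every stream of randomness derives from one master seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate.library import load_default_library
from .annotate.masses import (
    ADDUCT_RULES,
    MASS_13C_SHIFT,
    MASS_H2O,
    MASS_NH3,
)
from .io import MZ_MAX, MZ_MIN, ScanSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_recording",
    "write_truth",
    "read_truth",
]

_ABUNDANCE_RATIO = {"adduct": 0.30, "neutral_loss": 0.20}
_P13C = 0.0107  # natural 13C abundance


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic scenario (defaults mirror the study scale)."""

    n_case: int = 48
    n_control: int = 56
    n_features: int = 2315
    n_differential: int = 375
    n_up: int = 179  # higher in the case group
    n_down: int = 196
    effect_range: tuple[float, float] = (0.15, 1.1)
    scan_period: float = 0.5
    n_exhalations: int = 3
    recording_duration: float = 60.0
    resolving_power: float = 30_000.0
    noise_sd_log2: float = 0.25
    scan_noise_sd: float = 0.05
    n_batches: int = 1
    batch_sd_log2: float = 0.0
    satellite_fraction: float = 0.08
    baseline_log2_range: tuple[float, float] = (10.0, 16.0)
    polarity: str = "positive"
    library_fraction: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ConfigError("cohort sizes must be >= 0")
        if self.n_differential > self.n_features:
            raise ConfigError("n_differential must be <= n_features")
        if self.n_up + self.n_down != self.n_differential:
            # allow the split to be rescaled when n_differential is overridden
            up = round(self.n_differential * 179 / 375)
            self.n_up, self.n_down = up, self.n_differential - up
        if self.scan_period <= 0:
            raise ConfigError("scan_period must be > 0")
        if self.n_exhalations < 1:
            raise ConfigError("need at least one exhalation")
        for name in ("noise_sd_log2", "scan_noise_sd", "batch_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.effect_range
        if not (0 < lo <= hi):
            raise ConfigError("effect_range must satisfy 0 < lo <= hi")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    feature_mz: list[float]
    differential_effects: dict[int, float]  # index -> signed log2 (case - control)
    satellite_map: dict[int, tuple[int, str]]  # index -> (parent index, relation)
    batch_assignment: list[int]
    batch_effects: list[list[float]]  # features x batches, log2 shifts
    group_labels: list[str]
    carbon_counts: list[int]

    def __post_init__(self) -> None:
        nf = len(self.feature_mz)
        if not set(self.differential_effects) <= set(range(nf)):
            raise ValueError("differential set must be a subset of features")
        for eff in self.differential_effects.values():
            if not np.isfinite(eff) or eff == 0:
                raise ValueError("differential effects must be finite and nonzero")
        for idx, (parent, rel) in self.satellite_map.items():
            if parent not in range(nf):
                raise ValueError(f"satellite {idx} has missing parent {parent}")
            if rel not in ("isotope_13C", "adduct", "neutral_loss"):
                raise ValueError(f"unknown satellite relation {rel!r}")

    @property
    def differential_set(self) -> set[int]:
        return set(self.differential_effects)


@dataclass
class Cohort:
    """Sample table plus true per-subject log2 abundance vectors."""

    samples: pd.DataFrame  # sample_id, group, batch
    log2_abundance: np.ndarray  # samples x features

    @property
    def group_labels(self) -> np.ndarray:
        return self.samples["group"].to_numpy()


def _draw_feature_mzs(config: SimConfig, rng: np.random.Generator):
    """Feature m/z values, some taken from the bundled compound library."""
    lib = load_default_library()
    rule = ADDUCT_RULES["[M+H]+" if config.polarity == "positive" else "[M-H]-"]
    lib_mzs, lib_carbons = [], []
    for comp in lib.compounds:
        mz = rule.mz(comp.neutral_mass)
        if MZ_MIN + 2 < mz < MZ_MAX - 2:
            lib_mzs.append(mz)
            lib_carbons.append(_carbons(comp.formula))
    n_lib = min(int(round(config.library_fraction * config.n_features)), len(lib_mzs))
    pick = rng.choice(len(lib_mzs), size=n_lib, replace=False) if n_lib else np.array([], int)
    mzs = [lib_mzs[i] for i in pick]
    carbons = [lib_carbons[i] for i in pick]
    n_rand = config.n_features - n_lib
    rand_mz = rng.uniform(MZ_MIN + 10, MZ_MAX - 30, size=n_rand)
    mzs.extend(rand_mz.tolist())
    carbons.extend((rng.poisson(8.0, size=n_rand) + 1).tolist())
    return mzs, carbons


def _carbons(formula: str) -> int:
    from .annotate.masses import parse_formula

    counts = parse_formula(formula)
    return counts.get("C", 0) + counts.get("13C", 0)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a case/control cohort with planted effects and batch shifts.

    The returned log2 abundance matrix is
    baseline + group effect (differential features, applied to cases)
    + batch shift + subject-level noise; satellite features track their
    parent with a fixed intensity ratio.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    r_feat, r_truth, r_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_samples = config.n_case + config.n_control
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    batches = [i % config.n_batches for i in range(n_samples)]

    mzs, carbons = _draw_feature_mzs(config, r_feat)

    # satellites: overwrite the tail of the feature list with satellite ions
    n_sat = int(round(config.satellite_fraction * config.n_features))
    n_primary = config.n_features - n_sat
    satellite_map: dict[int, tuple[int, str]] = {}
    sat_delta = {
        "isotope_13C": MASS_13C_SHIFT,
        "adduct": MASS_NH3 if config.polarity == "positive" else MASS_H2O,
        "neutral_loss": -MASS_H2O,
    }
    relations = ["isotope_13C", "adduct", "neutral_loss"]
    if n_sat:
        parents = r_truth.choice(n_primary, size=n_sat, replace=False)
        for k, parent in enumerate(parents):
            idx = n_primary + k
            rel = relations[k % len(relations)]
            satellite_map[idx] = (int(parent), rel)
            mzs[idx] = mzs[parent] + sat_delta[rel]
            carbons[idx] = carbons[parent]

    # planted differential effects on primary (non-satellite) features
    diff_idx = r_truth.choice(n_primary, size=config.n_differential, replace=False)
    lo, hi = config.effect_range
    mags = r_truth.uniform(lo, hi, size=config.n_differential)
    signs = np.array([1.0] * config.n_up + [-1.0] * config.n_down)
    differential_effects = {
        int(i): float(s * m) for i, s, m in zip(diff_idx, signs, mags)
    }

    batch_effects = r_truth.normal(0.0, config.batch_sd_log2, size=(config.n_features, config.n_batches))
    if config.n_batches == 1:
        batch_effects[:] = 0.0

    baseline = r_truth.uniform(*config.baseline_log2_range, size=config.n_features)

    Y = np.tile(baseline, (n_samples, 1))
    for j, eff in differential_effects.items():
        case_rows = np.array([g == "case" for g in groups])
        Y[case_rows, j] += eff
    for i in range(n_samples):
        Y[i] += batch_effects[:, batches[i]]
    Y += r_noise.normal(0.0, config.noise_sd_log2, size=Y.shape)

    # satellites shadow their (noised) parent with a fixed log2 offset
    for idx, (parent, rel) in satellite_map.items():
        if rel == "isotope_13C":
            ratio = 1.0 - (1.0 - _P13C) ** carbons[parent]
        else:
            ratio = _ABUNDANCE_RATIO[rel]
        Y[:, idx] = Y[:, parent] + np.log2(ratio)

    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "group": groups,
            "batch": batches,
        }
    )
    truth = GroundTruth(
        feature_mz=[float(m) for m in mzs],
        differential_effects=differential_effects,
        satellite_map=satellite_map,
        batch_assignment=batches,
        batch_effects=batch_effects.tolist(),
        group_labels=groups,
        carbon_counts=[int(c) for c in carbons],
    )
    return Cohort(samples=samples, log2_abundance=Y), truth


def _plateau_profile(times: np.ndarray, config: SimConfig) -> np.ndarray:
    """Trapezoidal exhalation plateaus (1 s rise/fall) separated by breaks."""
    n = config.n_exhalations
    duration = config.recording_duration
    # keep exhalation a minority of the trace so the median tracks baseline
    exhale_len = 0.35 * duration / n
    gap = (duration - n * exhale_len) / (n + 1)
    if exhale_len <= 2.0:
        raise ConfigError("recording too short for the requested exhalations")
    profile = np.zeros_like(times)
    ramp = 1.0
    for k in range(n):
        start = gap + k * (exhale_len + gap)
        end = start + exhale_len
        up = np.clip((times - start) / ramp, 0, 1)
        down = np.clip((end - times) / ramp, 0, 1)
        profile = np.maximum(profile, np.minimum(up, down) * ((times >= start) & (times <= end)))
    return profile


def simulate_recording(
    subject_abundances: np.ndarray,
    feature_mz,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "",
    baseline_level: float = 1.0,
) -> ScanSeries:
    """Render one recording: Gaussian m/z peaks scaled by a plateau profile.

    ``subject_abundances`` are linear-scale peak areas per feature. During
    exhalation windows each feature contributes a Gaussian peak of area
    abundance x profile (sigma = mz / (resolving_power x 2.355)); outside
    the windows only baseline noise remains.
    """
    abund = np.asarray(subject_abundances, dtype=float)
    if np.any(~np.isfinite(abund)) or np.any(abund < 0):
        raise ValueError("abundances must be finite and >= 0")
    mzs = np.asarray(feature_mz, dtype=float)
    if len(mzs) != len(abund):
        raise ValueError("abundances and feature_mz must align")
    rng = np.random.default_rng(rng)

    times = np.arange(0.0, config.recording_duration, config.scan_period)
    profile = _plateau_profile(times, config)

    sigma = mzs / (config.resolving_power * 2.355)
    # local dense grids around each peak plus a sparse baseline grid
    local_grids = [
        np.arange(mz - 6 * s, mz + 6 * s + 1e-12, s / 3.0) for mz, s in zip(mzs, sigma)
    ]
    coarse = np.arange(MZ_MIN, MZ_MAX + 0.5, 1.0)
    # keep baseline points clear of the peak windows so they cannot poke
    # zero-intensity holes into rendered peaks
    inside = np.zeros(len(coarse), dtype=bool)
    for mz, s in zip(mzs, sigma):
        inside |= np.abs(coarse - mz) <= 7 * s
    coarse = coarse[~inside]

    mz_arrays, intensity_arrays = [], []
    for t_idx, (t, prof) in enumerate(zip(times, profile)):
        pieces_mz = [coarse]
        pieces_int = [np.abs(rng.normal(0.0, baseline_level, size=len(coarse)))]
        if prof > 0:
            jitter = (
                np.exp(rng.normal(0.0, config.scan_noise_sd, size=len(mzs)))
                if config.scan_noise_sd > 0
                else np.ones(len(mzs))
            )
            for mz, s, a, grid, j in zip(mzs, sigma, abund, local_grids, jitter):
                if a <= 0:
                    continue
                area = a * prof * j
                vals = area / (s * np.sqrt(2 * np.pi)) * np.exp(
                    -0.5 * ((grid - mz) / s) ** 2
                )
                pieces_mz.append(grid)
                pieces_int.append(vals)
        mz_all = np.concatenate(pieces_mz)
        int_all = np.concatenate(pieces_int)
        keep = (mz_all >= MZ_MIN) & (mz_all <= MZ_MAX)
        mz_all, int_all = mz_all[keep], int_all[keep]
        order = np.argsort(mz_all)
        mz_sorted = mz_all[order]
        int_sorted = int_all[order]
        uniq, inv = np.unique(mz_sorted, return_inverse=True)
        summed = np.zeros(len(uniq))
        np.add.at(summed, inv, int_sorted)
        mz_arrays.append(uniq)
        intensity_arrays.append(summed)

    return ScanSeries(
        times=times,
        mz_arrays=mz_arrays,
        intensity_arrays=intensity_arrays,
        polarity=config.polarity,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# ground-truth round trip
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth to JSON (lossless round trip with read_truth)."""
    payload = {
        "feature_mz": truth.feature_mz,
        "differential_effects": {str(k): v for k, v in truth.differential_effects.items()},
        "satellite_map": {str(k): [v[0], v[1]] for k, v in truth.satellite_map.items()},
        "batch_assignment": truth.batch_assignment,
        "batch_effects": truth.batch_effects,
        "group_labels": truth.group_labels,
        "carbon_counts": truth.carbon_counts,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        feature_mz=[float(m) for m in payload["feature_mz"]],
        differential_effects={int(k): float(v) for k, v in payload["differential_effects"].items()},
        satellite_map={int(k): (int(v[0]), str(v[1])) for k, v in payload["satellite_map"].items()},
        batch_assignment=[int(b) for b in payload["batch_assignment"]],
        batch_effects=[[float(x) for x in row] for row in payload["batch_effects"]],
        group_labels=[str(g) for g in payload["group_labels"]],
        carbon_counts=[int(c) for c in payload["carbon_counts"]],
    )
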