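"""Synthetic cohorts standing in for the I-SPY1 TRIAL imaging collection.

Three generators provide ground truth for every downstream stage:

* :func:`gen_feature_cohort` — a patients x features matrix with a known set
  of class-discriminative ("informative") columns, emulating the output of
  convolutional feature extraction without any imaging.
* :func:`gen_dce_patient` / :func:`gen_phantom_cohort` — phantom DCE-MRI
  series (one pre-contrast + two post-contrast volumes) with ellipsoidal
  tumors whose contrast enhancement depends on response class.
* :func:`gen_clinical_table` — an I-SPY1-like clinical table (age, race,
  hormone receptors, HER2, molecular subtype) with a tunable class
  association.

All generators are pure functions of their configuration, including the
seed; per-patient substreams are counter-based so patient ``k`` does not
change when the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from ._utils import substream

__all__ = [
    "ISPY1_COHORT",
    "SyntheticCohortConfig",
    "SyntheticPhantomConfig",
    "gen_feature_cohort",
    "gen_dce_patient",
    "gen_phantom_cohort",
    "gen_clinical_table",
    "largest_in_plane_diameter",
]

#: Composition of the I-SPY1 study cohort used throughout as the default
#: synthetic-cohort shape: 134 patients with both pre-treatment (T1) and
#: early-treatment (T2) exams, split into a 108-patient fine-tuning set
#: (30 pCR / 78 non-pCR) and a 26-patient independent test (7 / 19).
#: Subtype and race counts are per response class (pCR, non-pCR); two
#: patients have unspecified HER2 status and hence no molecular subtype.
ISPY1_COHORT = {
    "fine_tuning": {"pcr": 30, "non_pcr": 78},
    "independent_test": {"pcr": 7, "non_pcr": 19},
    "subtype_counts": {
        "HER2+": {"pcr": 16, "non_pcr": 22},
        "Luminal": {"pcr": 6, "non_pcr": 51},
        "Triple Negative": {"pcr": 14, "non_pcr": 23},
    },
    "race_counts": {
        "Caucasian": {"pcr": 29, "non_pcr": 73},
        "African American": {"pcr": 3, "non_pcr": 18},
        "Asian": {"pcr": 2, "non_pcr": 5},
        "Other": {"pcr": 3, "non_pcr": 1},
    },
    "age_mean_sd": {"pcr": (46.88, 8.77), "non_pcr": (48.84, 9.03)},
}

SUBTYPES = ("Luminal", "HER2+", "Triple Negative")

# P(marker positive | molecular subtype); class-independent given subtype.
# Triple Negative is ER-/PgR-/HER2- by definition; small flip probabilities
# keep every marker two-level even in small tables.
_MARKER_GIVEN_SUBTYPE = {
    "Luminal": {"er": 0.95, "pgr": 0.80, "her2": 0.02},
    "HER2+": {"er": 0.40, "pgr": 0.35, "her2": 0.98},
    "Triple Negative": {"er": 0.02, "pgr": 0.02, "her2": 0.02},
}


# --------------------------------------------------------------------------
# Feature-matrix cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration for a planted-signal feature cohort.

    Defaults mirror the fine-tuning cohort shape (30 pCR vs 78 non-pCR)
    with 10 informative columns out of 1,000 and a standardized mean shift
    of 3 between classes.
    """

    n_pcr: int = 30
    n_nonpcr: int = 78
    n_features: int = 1000
    informative_idx: frozenset = frozenset(range(10))
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pcr < 2 or self.n_nonpcr < 2:
            raise ValueError("each class needs at least 2 patients")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        idx = frozenset(int(i) for i in self.informative_idx)
        object.__setattr__(self, "informative_idx", idx)
        if idx and (min(idx) < 0 or max(idx) >= self.n_features):
            raise ValueError("informative_idx out of range [0, n_features)")


def gen_feature_cohort(config: SyntheticCohortConfig):
    """Generate ``(X, y, informative)`` with planted class effects.

    Features are i.i.d. ``N(0, noise_sd^2)``; informative columns of the
    pCR class are shifted by ``effect_size * noise_sd`` so the standardized
    class-mean difference equals ``effect_size``. Labels are 1 for pCR.
    """
    n = config.n_pcr + config.n_nonpcr
    X = np.empty((n, config.n_features))
    y = np.zeros(n, dtype=int)
    info = np.array(sorted(config.informative_idx), dtype=int)
    for i in range(config.n_pcr):
        rng = substream(config.seed, 0, i)
        X[i] = rng.normal(0.0, config.noise_sd, config.n_features)
        X[i, info] += config.effect_size * config.noise_sd
        y[i] = 1
    for j in range(config.n_nonpcr):
        rng = substream(config.seed, 1, j)
        X[config.n_pcr + j] = rng.normal(0.0, config.noise_sd, config.n_features)
    return X, y, info


# --------------------------------------------------------------------------
# Phantom DCE series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPhantomConfig:
    """Ellipsoidal-tumor phantom for one patient-timepoint DCE series.

    ``enhancement_*`` are multiplicative post-contrast gains applied to
    tumor voxels at the two post-contrast acquisitions (about 2.5 and 7.5
    minutes after injection); background voxels keep gain 1. Additive
    Gaussian texture of SD ``texture_sd`` is drawn independently per volume.
    """

    volume_shape: tuple = (8, 48, 48)
    pixel_spacing: float = 1.0
    tumor_center: tuple = (4, 24, 24)
    tumor_radii: tuple = (3.0, 10.0, 10.0)
    enhancement_pcr: tuple = (2.4, 2.0)
    enhancement_nonpcr: tuple = (2.2, 1.9)
    texture_sd: float = 2.0
    background: float = 100.0
    tumor_intensity: float = 140.0
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_shape) != 3:
            raise ValueError("volume_shape must be 3-D (slices, rows, cols)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if any(g <= 0 for g in self.enhancement_pcr + self.enhancement_nonpcr):
            raise ValueError("enhancement gains must be positive")
        for c, r, s in zip(self.tumor_center, self.tumor_radii, self.volume_shape):
            if c - r < 0 or c + r > s - 1:
                raise ValueError("tumor does not fit inside the volume")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def largest_in_plane_diameter(mask: np.ndarray, pixel_spacing: float) -> float:
    """Largest diameter (mm) of the mask within any single slice.

    The diameter is the maximum pairwise distance between in-plane voxel
    centers, scaled by the pixel spacing; a sphere of radius 10 voxels at
    1 mm spacing has LD = 20 mm.
    """
    if not mask.any():
        raise ValueError("empty mask has no diameter")
    best = 0.0
    for sl in np.unique(np.nonzero(mask)[0]):
        pts = np.argwhere(mask[sl]).astype(float)
        if len(pts) == 1:
            continue
        # convex hull cuts the pairwise computation down for blobby masks
        if len(pts) > 16:
            from scipy.spatial import ConvexHull, QhullError

            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass  # collinear points: brute force below
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).max()
        best = max(best, float(d))
    return best * pixel_spacing


def gen_dce_patient(config: SyntheticPhantomConfig, label: int):
    """Generate ``(series, mask, ld_mm)`` for one patient-timepoint.

    ``label`` is 1 for pCR, 0 for non-pCR; it selects which enhancement
    gains multiply the tumor voxels in the post-contrast volumes.
    """
    from .imaging import DceSeries

    rng = substream(config.seed, 7)
    mask = _ellipsoid_mask(config.volume_shape, config.tumor_center, config.tumor_radii)
    base = np.full(config.volume_shape, config.background)
    base[mask] = config.tumor_intensity
    gains = config.enhancement_pcr if label == 1 else config.enhancement_nonpcr

    def vol(gain_tumor: float) -> np.ndarray:
        v = base.copy()
        v[mask] *= gain_tumor
        v += rng.normal(0.0, config.texture_sd, config.volume_shape)
        return np.clip(v, 0.0, None)

    series = DceSeries(pre=vol(1.0), post1=vol(gains[0]), post2=vol(gains[1]),
                       pixel_spacing=config.pixel_spacing)
    ld = largest_in_plane_diameter(mask, config.pixel_spacing)
    return series, mask, ld


@dataclass(frozen=True)
class PhantomCohortConfig:
    """Cohort-level phantom settings: per-patient geometry jitter and the
    early-treatment (T2) response model.

    At T2 the tumor of a responder retains fraction ``t2_enh_retain_pcr``
    of its excess enhancement (gain - 1) and shrinks by
    ``t2_shrink_pcr`` in radius; non-responders change little. These two
    knobs are the class signal carried by the early-treatment exam.
    """

    n_pcr: int = 30
    n_nonpcr: int = 78
    phantom: SyntheticPhantomConfig = field(default_factory=SyntheticPhantomConfig)
    center_jitter: int = 2
    radius_jitter: float = 0.15
    t2_enh_retain_pcr: float = 0.6
    t2_enh_retain_nonpcr: float = 0.9
    t2_shrink_pcr: float = 0.7
    t2_shrink_nonpcr: float = 0.95
    seed: int = 0


def gen_phantom_cohort(config: PhantomCohortConfig):
    """Generate a list of patient records with T1 and T2 phantom series.

    Each record is a dict with ``patient_id``, ``label`` and per-timepoint
    ``(series, mask, ld_mm)`` tuples under keys ``"T1"`` and ``"T2"``.
    """
    records = []
    for label, count, cls in ((1, config.n_pcr, 0), (0, config.n_nonpcr, 1)):
        for i in range(count):
            rng = substream(config.seed, 3, cls, i)
            jitter = rng.integers(-config.center_jitter, config.center_jitter + 1, 2)
            rscale = 1.0 + rng.uniform(-config.radius_jitter, config.radius_jitter)
            base = config.phantom
            center = (base.tumor_center[0],
                      base.tumor_center[1] + int(jitter[0]),
                      base.tumor_center[2] + int(jitter[1]))
            radii = tuple(r * rscale for r in base.tumor_radii)
            seed_t1 = int(rng.integers(0, 2**31 - 1))
            seed_t2 = int(rng.integers(0, 2**31 - 1))
            t1_cfg = replace(base, tumor_center=center, tumor_radii=radii, seed=seed_t1)
            retain = config.t2_enh_retain_pcr if label else config.t2_enh_retain_nonpcr
            shrink = config.t2_shrink_pcr if label else config.t2_shrink_nonpcr
            t2_cfg = replace(
                base,
                tumor_center=center,
                tumor_radii=tuple(r * shrink for r in radii),
                enhancement_pcr=tuple(1 + (g - 1) * retain for g in base.enhancement_pcr),
                enhancement_nonpcr=tuple(1 + (g - 1) * retain for g in base.enhancement_nonpcr),
                seed=seed_t2,
            )
            pid = f"{'pcr' if label else 'non'}_{i:03d}"
            records.append({
                "patient_id": pid,
                "label": label,
                "T1": gen_dce_patient(t1_cfg, label),
                "T2": gen_dce_patient(t2_cfg, label),
            })
    return records


# --------------------------------------------------------------------------
# Clinical tables
# --------------------------------------------------------------------------


def _interp_probs(pooled: np.ndarray, per_class: np.ndarray, strength: float) -> np.ndarray:
    p = (1.0 - strength) * pooled + strength * per_class
    return p / p.sum()


def gen_clinical_table(n_pcr: int, n_nonpcr: int, assoc_strength: float = 1.0,
                       seed: int = 0, n_missing_her2: int = 0) -> pd.DataFrame:
    """Generate an I-SPY1-like clinical table.

    ``assoc_strength`` interpolates the subtype-given-class distribution
    between the pooled cohort distribution (0: no class association) and
    the observed per-class distribution of the study cohort (1). ER, PgR
    and HER2 are drawn conditional on subtype only, so they inherit (and
    only inherit) the subtype's class association. Age and race are
    class-independent. ``n_missing_her2`` patients get missing HER2 and
    subtype, emulating unspecified receptor status.
    """
    if n_pcr < 1 or n_nonpcr < 1:
        raise ValueError("both classes need at least 1 patient")
    if not 0.0 <= assoc_strength <= 1.0:
        raise ValueError("assoc_strength must be in [0, 1]")

    counts = ISPY1_COHORT["subtype_counts"]
    per_class = {
        "pcr": np.array([counts[s]["pcr"] for s in SUBTYPES], float),
        "non_pcr": np.array([counts[s]["non_pcr"] for s in SUBTYPES], float),
    }
    pooled = per_class["pcr"] + per_class["non_pcr"]
    pooled /= pooled.sum()
    for k in per_class:
        per_class[k] = per_class[k] / per_class[k].sum()

    race_counts = ISPY1_COHORT["race_counts"]
    races = list(race_counts)
    race_p = np.array([race_counts[r]["pcr"] + race_counts[r]["non_pcr"] for r in races], float)
    race_p /= race_p.sum()

    # pooled age distribution; class-independent by design
    age_mu, age_sd = 48.3, 9.0

    rows = []
    for label, count, cls_key, cls_code in ((1, n_pcr, "pcr", 0), (0, n_nonpcr, "non_pcr", 1)):
        probs = _interp_probs(pooled, per_class[cls_key], assoc_strength)
        for i in range(count):
            rng = substream(seed, 11, cls_code, i)
            subtype = SUBTYPES[rng.choice(len(SUBTYPES), p=probs)]
            mk = _MARKER_GIVEN_SUBTYPE[subtype]
            rows.append({
                "patient_id": f"{'pcr' if label else 'non'}_{i:03d}",
                "pcr": label,
                "age": float(rng.normal(age_mu, age_sd)),
                "race": races[rng.choice(len(races), p=race_p)],
                "er": int(rng.random() < mk["er"]),
                "pgr": int(rng.random() < mk["pgr"]),
                "her2": int(rng.random() < mk["her2"]),
                "subtype": subtype,
            })
    df = pd.DataFrame(rows)
    if n_missing_her2 > 0:
        rng = substream(seed, 13)
        miss = rng.choice(len(df), size=min(n_missing_her2, len(df)), replace=False)
        df.loc[miss, ["her2", "subtype"]] = np.nan
        df["her2"] = df["her2"].astype("Int64")
    return df
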