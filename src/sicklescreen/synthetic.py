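"""Synthetic stain images, reagent-aging trajectories, and observer scores.

The generator emulates the phenomenology of the paper-based hemoglobin
solubility assay: a drop of lysed, deoxygenated blood dries on chromatography
paper.  Insoluble deoxy-HbS polymers are trapped at the deposition point and
darken the center spot, while soluble hemoglobin wicks outward into a
uniform pink ring.  Renders are concentric discs (optionally with radial
boundary jitter) whose center/ring red-intensity contrast follows a
documented saturating function of %HbS, modulated by the reducing-agent
formulation (sodium metabisulfite, MS, vs sodium hydrosulfite, HS), the
reagent age and the storage condition.

Three deliberate simplifications, documented in the methods note:

* reagent decay is a step function — full activity up to a formulation- and
  storage-specific limit of stability, none afterward;
* the contrast function g(%HbS, formulation) is a shifted and rescaled
  logistic with g(0) = 1;
* pixel noise is additive truncated-Gaussian per channel, clipped to [0, 255].

All randomness flows through one explicit integer seed per operation.
"""

from __future__ import annotations

import math
import pathlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, RenderError, ValidationError
from .imaging import StainImage, StainSegmentation, s_index, write_image

# ---------------------------------------------------------------------------
# Reagent activity (step-decay shelf-life model)
# ---------------------------------------------------------------------------

#: Storage temperature (°C) at or above which the "hot storage" behavior of
#: wet MS applies.  Only this single hot condition (62 °C in the study) is
#: modeled.
HOT_STORAGE_THRESHOLD_C = 40.0

#: Limit of stability of wet MS reagents under hot storage, days.
MS_HOT_WET_LOS_DAYS = 7.0

#: Limits of stability of HS reagents at room temperature, days.
HS_DRY_LOS_DAYS = 36.0
HS_WET_LOS_DAYS = 6.0

_FORMULATIONS = ("MS", "HS")
_STORAGE_CONDITIONS = ("wet", "dry")


@dataclass(frozen=True)
class ReagentActivity:
    """Reducing-agent activity under the step-decay model: 1 (fresh behavior) or 0."""

    activity: float
    limit_of_stability_days: float


def reagent_activity(
    formulation: str,
    storage: str,
    age_days: float,
    temperature_c: float = 22.0,
) -> ReagentActivity:
    """Activity of a stored reagent set.

    MS at room temperature showed no loss of activity over the whole study
    window under either storage condition and is modeled as indefinitely
    stable; wet MS under hot storage is stable for one week.  HS steps to
    zero activity after 36 days (dry) or 6 days (wet).
    """
    formulation = str(formulation).upper()
    storage = str(storage).lower()
    if formulation not in _FORMULATIONS:
        raise ConfigurationError(f"unknown formulation {formulation!r}")
    if storage not in _STORAGE_CONDITIONS:
        raise ConfigurationError(f"unknown storage condition {storage!r}")
    if age_days < 0:
        raise ConfigurationError("age_days must be non-negative")

    if formulation == "MS":
        if storage == "wet" and temperature_c >= HOT_STORAGE_THRESHOLD_C:
            los = MS_HOT_WET_LOS_DAYS
        else:
            los = math.inf
    else:
        los = HS_DRY_LOS_DAYS if storage == "dry" else HS_WET_LOS_DAYS
    return ReagentActivity(
        activity=1.0 if age_days <= los else 0.0,
        limit_of_stability_days=los,
    )


# ---------------------------------------------------------------------------
# Center/ring contrast function g
# ---------------------------------------------------------------------------

#: Logistic contrast parameters (amplitude A, steepness k per %HbS, midpoint
#: x0 in %HbS) keyed by (formulation, reducing-agent % w/v).  Values chosen
#: so that the measured S-index clears the observer cutpoint at 10% HbS for
#: the final 15% w/v MS formulation, at 15% HbS for 3% w/v HS, and so that
#: 15% MS maximizes the S(20%) − S(0%) separation among the MS candidates.
CONTRAST_PARAMS: dict[tuple[str, float], tuple[float, float, float]] = {
    ("MS", 10.0): (1.1, 0.06, 25.0),
    ("MS", 15.0): (1.6, 0.06, 25.0),
    ("MS", 20.0): (1.7, 0.06, 35.0),
    ("HS", 3.0): (1.6, 0.06, 45.0),
}

_DEFAULT_CONCENTRATION = {"MS": 15.0, "HS": 3.0}


def contrast_ratio(
    hbs_percent: float,
    formulation: str = "MS",
    concentration_percent_wv: float | None = None,
) -> float:
    """Noise-free center/ring red-intensity ratio g(%HbS, formulation).

    g is a logistic in %HbS, shifted and rescaled so g(0) = 1 exactly and
    g saturates at 1 + A:

        g(x) = 1 + A · (σ(k(x − x0)) − σ(−k·x0)) / (1 − σ(−k·x0))

    g is strictly increasing in x for every parameterization.
    """
    formulation = str(formulation).upper()
    if formulation not in _FORMULATIONS:
        raise ConfigurationError(f"unknown formulation {formulation!r}")
    if not 0.0 <= hbs_percent <= 100.0:
        raise ConfigurationError("hbs_percent must lie in [0, 100]")
    if concentration_percent_wv is None:
        concentration_percent_wv = _DEFAULT_CONCENTRATION[formulation]
    key = (formulation, float(concentration_percent_wv))
    if key not in CONTRAST_PARAMS:
        raise ConfigurationError(
            f"no contrast parameters for {formulation} at "
            f"{concentration_percent_wv}% w/v"
        )
    amplitude, k, x0 = CONTRAST_PARAMS[key]
    base = expit(-k * x0)
    return 1.0 + amplitude * (expit(k * (hbs_percent - x0)) - base) / (1.0 - base)


# ---------------------------------------------------------------------------
# Stain rendering
# ---------------------------------------------------------------------------

#: Ring red intensity (255 − B) of the diffuse hemoglobin ring, 8-bit units.
RING_RED_INTENSITY = 90.0

#: R and G base values; arbitrary (the S-index reads only B).
_RING_RG = (235.0, 150.0)
_BACKGROUND = 255


@dataclass(frozen=True)
class StainRenderSpec:
    """Parameters of one synthetic stain render."""

    hbs_percent: float
    formulation: str = "MS"
    concentration_percent_wv: float | None = None
    reagent_age_days: float = 0.0
    storage: str = "dry"
    temperature_c: float = 22.0
    image_size_px: int = 128
    stain_radius_px: float = 48.0
    center_radius_px: float = 17.0
    noise_sd: float = 2.0
    shape_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hbs_percent <= 100.0:
            raise RenderError("hbs_percent must lie in [0, 100]")
        if not (0 < self.center_radius_px < self.stain_radius_px < self.image_size_px / 2):
            raise RenderError(
                "geometry must satisfy 0 < center_radius < stain_radius < image_size/2"
            )
        if self.noise_sd < 0:
            raise RenderError("noise_sd must be non-negative")
        if self.shape_jitter < 0:
            raise RenderError("shape_jitter must be non-negative")


def _jitter_profile(rng: np.random.Generator, amplitude: float, theta: np.ndarray) -> np.ndarray:
    """Smooth radial boundary perturbation with max |f| == 1, scaled by amplitude."""
    if amplitude == 0:
        return np.zeros_like(theta)
    harmonics = np.arange(2, 6)
    coeffs = rng.normal(size=harmonics.size)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
    f = np.zeros_like(theta)
    for h, c, p in zip(harmonics, coeffs, phases):
        f += c * np.sin(h * theta + p)
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return amplitude * f


def render_stain(spec: StainRenderSpec) -> tuple[StainImage, StainSegmentation]:
    """Render one synthetic stain plus its ground-truth segmentation.

    With full reagent activity and no noise, the pixel-mean ratio of the
    render equals ``contrast_ratio(spec.hbs_percent, spec.formulation)`` up
    to 8-bit quantization.  With zero activity the render is statistically
    indistinguishable from a 0% HbS render.
    """
    act = reagent_activity(
        spec.formulation, spec.storage, spec.reagent_age_days, spec.temperature_c
    )
    effective_hbs = spec.hbs_percent if act.activity > 0 else 0.0
    g = contrast_ratio(effective_hbs, spec.formulation, spec.concentration_percent_wv)

    n = spec.image_size_px
    rng = np.random.default_rng(spec.seed)
    center = (n - 1) / 2.0
    yy, xx = np.indices((n, n), dtype=np.float64)
    dist = np.hypot(yy - center, xx - center)
    theta = np.arctan2(yy - center, xx - center)

    outer_r = spec.stain_radius_px * (1.0 + _jitter_profile(rng, spec.shape_jitter, theta))
    inner_r = spec.center_radius_px * (1.0 + _jitter_profile(rng, spec.shape_jitter, theta))
    inside_stain = dist <= outer_r
    inside_center = dist <= np.minimum(inner_r, outer_r)

    center_red = min(g * RING_RED_INTENSITY, 250.0)
    base = np.full((n, n, 3), float(_BACKGROUND))
    ring_rgb = (_RING_RG[0], _RING_RG[1], 255.0 - RING_RED_INTENSITY)
    center_rgb = (
        max(_RING_RG[0] - 20.0 * (g - 1.0), 0.0),
        max(_RING_RG[1] - 30.0 * (g - 1.0), 0.0),
        255.0 - center_red,
    )
    for c in range(3):
        base[:, :, c][inside_stain] = ring_rgb[c]
        base[:, :, c][inside_center] = center_rgb[c]

    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    image = StainImage(
        pixels=pixels,
        metadata={
            "hbs_percent": spec.hbs_percent,
            "formulation": spec.formulation,
            "reagent_age_days": spec.reagent_age_days,
            "storage": spec.storage,
            "temperature_c": spec.temperature_c,
            "activity": act.activity,
            "seed": spec.seed,
        },
    )
    truth = StainSegmentation(
        center_mask=inside_center,
        ring_mask=inside_stain & ~inside_center,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

BINARY_LABELS = ("negative", "positive")
THREE_CLASS_LABELS = ("AA", "AS", "SS")

#: Default S-index cutpoints.  The first separates "no center spot" from
#: "center spot present"; the second separates SCT-like from SCA-like
#: contrast under the MS parameterization.
DEFAULT_BINARY_THRESHOLDS = (1.10,)
DEFAULT_THREE_CLASS_THRESHOLDS = (1.10, 2.28)


@dataclass(frozen=True)
class ObserverModel:
    """Stochastic rater: thresholds an S-index with logistic read noise.

    ``slope`` is the steepness of the call model; the latent read is
    s + Logistic(0, 1/slope), so slope → ∞ reproduces deterministic
    thresholding and a stain exactly at a cutpoint is called above it with
    probability 1/2.
    """

    thresholds: tuple[float, ...]
    slope: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValidationError("at least one threshold required")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError("thresholds must be strictly increasing")
        if not self.slope > 0:
            raise ValidationError("slope must be > 0")


def simulate_observer_calls(
    s_indices: Sequence[float],
    model: ObserverModel,
    class_labels: Sequence[str] = BINARY_LABELS,
    n_observers: int = 3,
    replicates: int = 1,
    stain_ids: Sequence[str] | None = None,
    true_hbs_percent: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Simulate categorical calls for a set of stains.

    Returns a score table with columns ``observer_id, stain_id, replicate,
    call, true_hbs_percent`` (truth NaN when not supplied).  Deterministic
    given ``model.seed``.
    """
    s = np.asarray(s_indices, dtype=np.float64)
    if s.size == 0:
        raise ValidationError("empty S-index input")
    if len(class_labels) != len(model.thresholds) + 1:
        raise ValidationError(
            f"{len(class_labels)} labels incompatible with "
            f"{len(model.thresholds)} thresholds"
        )
    if stain_ids is None:
        stain_ids = [f"stain_{i:04d}" for i in range(s.size)]
    truth = (
        np.full(s.size, np.nan)
        if true_hbs_percent is None
        else np.asarray(true_hbs_percent, dtype=np.float64)
    )

    rng = np.random.default_rng(model.seed)
    thresholds = np.asarray(model.thresholds)
    records = []
    for obs in range(n_observers):
        for rep in range(replicates):
            if math.isinf(model.slope):
                latent = s
            else:
                latent = s + rng.logistic(0.0, 1.0 / model.slope, size=s.size)
            idx = np.searchsorted(thresholds, latent, side="right")
            for i in range(s.size):
                records.append(
                    {
                        "observer_id": f"observer_{obs + 1}",
                        "stain_id": stain_ids[i],
                        "replicate": rep + 1,
                        "call": class_labels[idx[i]],
                        "true_hbs_percent": truth[i],
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Conditions for one simulated scoring study."""

    n_per_class: int = 20
    hbs_levels: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 80.0)
    formulation: str = "MS"
    concentration_percent_wv: float | None = None
    storage: str = "dry"
    reagent_age_days: float = 0.0
    temperature_c: float = 22.0
    image_size_px: int = 128
    stain_radius_px: float = 48.0
    center_radius_px: float = 17.0
    noise_sd: float = 2.0
    shape_jitter: float = 0.0
    n_observers: int = 3
    replicates: int = 1
    observer_slope: float = 40.0
    class_scheme: str = "binary"  # "binary" or "three_class"
    thresholds: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValidationError("n_per_class must be > 0")
        if self.class_scheme not in ("binary", "three_class"):
            raise ValidationError(f"unknown class scheme {self.class_scheme!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return BINARY_LABELS if self.class_scheme == "binary" else THREE_CLASS_LABELS

    @property
    def effective_thresholds(self) -> tuple[float, ...]:
        if self.thresholds is not None:
            return self.thresholds
        return (
            DEFAULT_BINARY_THRESHOLDS
            if self.class_scheme == "binary"
            else DEFAULT_THREE_CLASS_THRESHOLDS
        )


@dataclass
class StudyBundle:
    """In-memory result of :func:`generate_study`."""

    config: StudyConfig
    metadata: pd.DataFrame
    scores: pd.DataFrame
    images: list[StainImage]
    truth_segmentations: list[StainSegmentation]
    s_indices: np.ndarray

    def write(self, out_dir: str | pathlib.Path) -> None:
        """Write PNG images plus metadata.csv and scores.csv to a directory."""
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for stain_id, image in zip(self.metadata["stain_id"], self.images):
            write_image(image, img_dir / f"{stain_id}.png")
        self.metadata.to_csv(out_dir / "metadata.csv", index=False)
        self.scores.to_csv(out_dir / "scores.csv", index=False)


def generate_study(config: StudyConfig) -> StudyBundle:
    """Render a full stain set and simulate its visual scoring.

    Per-stain render seeds are drawn from one study-level seed, so identical
    configs reproduce byte-identical CSV output.  Observer calls are driven
    by the S-index measured on each render over the ground-truth masks.
    """
    rng = np.random.default_rng(config.seed)
    images: list[StainImage] = []
    truths: list[StainSegmentation] = []
    meta_rows = []
    s_values = []
    stain_ids = []
    idx = 0
    for level in config.hbs_levels:
        for _ in range(config.n_per_class):
            stain_seed = int(rng.integers(0, 2**31 - 1))
            spec = StainRenderSpec(
                hbs_percent=float(level),
                formulation=config.formulation,
                concentration_percent_wv=config.concentration_percent_wv,
                reagent_age_days=config.reagent_age_days,
                storage=config.storage,
                temperature_c=config.temperature_c,
                image_size_px=config.image_size_px,
                stain_radius_px=config.stain_radius_px,
                center_radius_px=config.center_radius_px,
                noise_sd=config.noise_sd,
                shape_jitter=config.shape_jitter,
                seed=stain_seed,
            )
            image, truth = render_stain(spec)
            stain_id = f"stain_{idx:04d}"
            idx += 1
            s_val = s_index(image, truth).s_index
            images.append(image)
            truths.append(truth)
            s_values.append(s_val)
            stain_ids.append(stain_id)
            meta_rows.append(
                {
                    "stain_id": stain_id,
                    "hbs_percent": float(level),
                    "formulation": config.formulation,
                    "storage": config.storage,
                    "age_days": config.reagent_age_days,
                    "seed": stain_seed,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    observer_seed = int(rng.integers(0, 2**31 - 1))
    model = ObserverModel(
        thresholds=config.effective_thresholds,
        slope=config.observer_slope,
        seed=observer_seed,
    )
    scores = simulate_observer_calls(
        s_values,
        model,
        class_labels=config.labels,
        n_observers=config.n_observers,
        replicates=config.replicates,
        stain_ids=stain_ids,
        true_hbs_percent=metadata["hbs_percent"].to_numpy(),
    )
    return StudyBundle(
        config=config,
        metadata=metadata,
        scores=scores,
        images=images,
        truth_segmentations=truths,
        s_indices=np.asarray(s_values),
    )


def simulate_stability_series(
    formulation: str,
    storage: str,
    days: Sequence[float],
    lod_hbs_percent: float,
    n_replicates: int = 12,
    noise_sd: float = 2.0,
    temperature_c: float = 22.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate S-index measurements over storage time for a stability study.

    For each storage day, renders ``n_replicates`` stains at 0% HbS and at
    the at-LOD HbS level with reagents aged to that day, and measures the
    S-index over ground-truth masks.  Returns a tidy frame with columns
    ``day, group, replicate, s_index`` where group is ``"zero"`` or ``"lod"``.
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        for group, level in (("zero", 0.0), ("lod", float(lod_hbs_percent))):
            for rep in range(n_replicates):
                spec = StainRenderSpec(
                    hbs_percent=level,
                    formulation=formulation,
                    storage=storage,
                    reagent_age_days=float(day),
                    temperature_c=temperature_c,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                image, truth = render_stain(spec)
                rows.append(
                    {
                        "day": float(day),
                        "group": group,
                        "replicate": rep + 1,
                        "s_index": s_index(image, truth).s_index,
                    }
                )
    return pd.DataFrame(rows)
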