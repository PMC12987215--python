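"""Semi-synthetic cohort expansion.

Each base cloud is expanded by similarity scaling (a shared set of
factors selected from an admissible grid derived from the preauricular
distance, applied under three axis configurations) followed by a small
uniform per-marker positional perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from craniomorph.cloud import HeadCloud
from craniomorph.errors import CraniomorphError
from craniomorph import geometry


class ScaleMode(str, Enum):
    """Axis configuration of the similarity scaling."""

    XYZ = "XYZ"
    XY = "XY"
    Z = "Z"

    @property
    def axes(self) -> tuple[int, ...]:
        return {"XYZ": (0, 1, 2), "XY": (0, 1), "Z": (2,)}[self.value]


@dataclass(frozen=True)
class ScalePlan:
    """Admissible scale-factor grid and how many factors to select.

    The defaults encode a +/- 1.5 mm preauricular tolerance over the
    cohort-average admissible range [0.983, 1.016] sampled at 0.001.
    """

    margin_mm: float = 1.5
    grid_lo: float = 0.983
    grid_hi: float = 1.016
    grid_step: float = 0.001
    n_selected: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin_mm <= 0:
            raise CraniomorphError("margin_mm must be positive")
        if not (self.grid_lo < 1.0 < self.grid_hi):
            raise CraniomorphError("grid must bracket 1.0")
        if self.grid_step <= 0:
            raise CraniomorphError("grid_step must be positive")

    def grid_values(self) -> np.ndarray:
        """The arithmetic factor grid, inclusive of both endpoints."""
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return np.round(self.grid_lo + self.grid_step * np.arange(n), 12)


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform per-marker positional perturbation."""

    amplitude_mm: float = 2.0
    targets: str = "all_markers"  # or "reference_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise CraniomorphError("noise amplitude must be non-negative")
        if self.targets not in ("all_markers", "reference_only"):
            raise CraniomorphError(f"unknown noise target {self.targets!r}")


@dataclass(frozen=True)
class AugmentationRecord:
    """Provenance of one augmented cloud."""

    base_id: str
    factor: float
    mode: ScaleMode
    noise_seed: int


def admissible_scale_range(d_preauricular: float, margin_mm: float = 1.5) -> tuple[float, float]:
    """Factor bounds keeping the preauricular distance within +/- margin."""
    if d_preauricular <= 0:
        raise CraniomorphError("preauricular distance must be positive")
    delta = margin_mm / d_preauricular
    return 1.0 - delta, 1.0 + delta


def select_scale_factors(plan: ScalePlan) -> np.ndarray:
    """Stratified random selection of ``n_selected`` distinct grid factors.

    The grid is partitioned into ``n_selected`` contiguous strata of
    near-equal size and one factor is drawn per stratum, which honours
    both the "random" and the "distributed evenly" requirements.
    Sorted, deterministic for a given seed.
    """
    grid = plan.grid_values()
    if plan.n_selected > grid.size:
        raise CraniomorphError(
            f"n_selected = {plan.n_selected} exceeds grid size {grid.size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    strata = np.array_split(np.arange(grid.size), plan.n_selected)
    picks = [int(rng.integers(s[0], s[-1] + 1)) for s in strata]
    return grid[np.array(picks)]


def apply_scaling(cloud: HeadCloud, factor: float, mode: ScaleMode) -> HeadCloud:
    """Multiply coordinates on the mode's axes by ``factor``."""
    if factor <= 0:
        raise CraniomorphError("scale factor must be positive")
    mode = ScaleMode(mode)
    out = cloud.copy()
    for ax in mode.axes:
        out.vertices[..., ax] *= factor
    out.provenance = AugmentationRecord(
        base_id=cloud.base_id, factor=float(factor), mode=mode, noise_seed=-1
    )
    return out


def apply_marker_noise(cloud: HeadCloud, spec: NoiseSpec) -> HeadCloud:
    """Rigidly shift each targeted present marker by one uniform offset.

    One offset vector with independent components uniform on
    [-amplitude, +amplitude] is added to all 4 vertices of a marker, so
    the coded quad stays intact.
    """
    out = cloud.copy()
    if spec.amplitude_mm == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    # Draw per slot (all 138) so the stream is independent of dropout.
    offsets = rng.uniform(-spec.amplitude_mm, spec.amplitude_mm, size=(out.present.size, 3))
    targeted = out.present.copy()
    if spec.targets == "reference_only":
        targeted[: -3] = False
    out.vertices[targeted] += offsets[targeted][:, None, :]
    return out


def augment_cloud(
    cloud: HeadCloud,
    plan: ScalePlan,
    noise: NoiseSpec,
    factors: Sequence[float] | None = None,
) -> list[HeadCloud]:
    """Expand one canonicalised base cloud into factor x mode variants.

    Returns ``len(factors) * 3`` clouds; each variant receives an
    independent noise draw. ``factors`` defaults to
    :func:`select_scale_factors` of the plan.
    """
    if factors is None:
        factors = select_scale_factors(plan)
    canon = geometry.canonicalize(cloud)
    seed_root = np.random.SeedSequence([noise.seed, _stable_hash(cloud.base_id)])
    noise_seeds = np.random.default_rng(seed_root).integers(
        0, 2**63 - 1, size=len(factors) * len(ScaleMode)
    )
    out: list[HeadCloud] = []
    k = 0
    for factor in factors:
        for mode in ScaleMode:
            variant = apply_scaling(canon, factor, mode)
            nseed = int(noise_seeds[k])
            k += 1
            variant = apply_marker_noise(
                variant, NoiseSpec(noise.amplitude_mm, noise.targets, seed=nseed)
            )
            variant.cloud_id = f"{cloud.base_id}-f{factor:.3f}-{mode.value.lower()}"
            variant.base_id = cloud.base_id
            variant.provenance = AugmentationRecord(
                base_id=cloud.base_id, factor=float(factor), mode=mode, noise_seed=nseed
            )
            out.append(variant)
    return out


def augment_cohort(
    bases: Sequence[HeadCloud], plan: ScalePlan, noise: NoiseSpec
) -> list[HeadCloud]:
    """Concatenated augmentation of all bases with one shared factor set."""
    if not bases:
        raise CraniomorphError("augment_cohort requires at least one base cloud")
    factors = select_scale_factors(plan)
    out: list[HeadCloud] = []
    for base in bases:
        out.extend(augment_cloud(base, plan, noise, factors=factors))
    return out


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a string (process-independent)."""
    import zlib

    return zlib.crc32(text.encode("utf-8"))
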