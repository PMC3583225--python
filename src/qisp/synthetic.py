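"""Synthetic ground-truth generator for the QISP pipeline.

Real inputs to this kind of study are Affymetrix RMA expression tables and
public-atlas ISH photographs, neither of which ships with the package.  This
module generates stand-ins with fully known structure: radial optical-density
archetypes (ventricular-zone, intermediate-zone and cortical-plate peaks,
Dab1-like dual peaks, deep-biased invalid patterns, flat profiles), rendered
grayscale section images with background, illumination ramp and pixel noise,
replicate series with placement jitter, and log2-scale expression matrices
with planted fold-changes around a "not expressed" baseline of 5.5 +/- 0.7
log2 units.

Every generator is deterministic under its ``seed`` argument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .extraction import N_SROIS, RoiSpec, segment_boundaries
from .screen import ExpressionMatrix

__all__ = [
    "ArchetypeSpec",
    "ARCHETYPES",
    "TruthBundle",
    "RenderParams",
    "ReplicateJitter",
    "archetype_profile",
    "generate_truth_profiles",
    "render_ish_image",
    "generate_replicates",
    "generate_expression_matrix",
]

_SROI_AXIS = np.arange(1, N_SROIS + 1, dtype=float)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Shape parameters of one radial-profile archetype.

    The noise-free profile is ``baseline + sum_j amp_j * exp(-(s - pos_j)^2 /
    (2 w_j^2))`` over the 1-based sROI axis ``s = 1..20``.  ``deep_invalid``
    archetypes are constructed so that the deep ratio
    ``mean(sROI 1-2) / mean(sROI 3-20)`` of the noise-free profile exceeds 1;
    every other archetype stays at or below 1.
    """

    name: str
    peak_positions: tuple[float, ...]
    peak_widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (
            len(self.peak_positions) == len(self.peak_widths) == len(self.amplitudes)
        ):
            raise ValueError("peak parameter lists must share a length")
        for p in self.peak_positions:
            if not 1 <= p <= N_SROIS:
                raise ValueError(f"peak position {p} outside [1, {N_SROIS}]")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be positive")
        if any(a < 0 for a in self.amplitudes) or self.baseline < 0:
            raise ValueError("amplitudes must be non-negative")


#: Default archetype vocabulary.  Positions are chosen so that single-peak
#: archetypes peak inside their namesake zone (deep 1-10, middle 11-15,
#: upper 16-20) and only ``deep_invalid`` violates the deep-ratio criterion.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "vz_peak": ArchetypeSpec("vz_peak", (6.0,), (2.5,), (0.85,)),
    "iz_peak": ArchetypeSpec("iz_peak", (12.0,), (2.5,), (0.85,)),
    "cp_peak": ArchetypeSpec("cp_peak", (17.0,), (2.0,), (0.85,)),
    "dual_peak": ArchetypeSpec("dual_peak", (4.0, 17.0), (1.5, 2.5), (0.55, 0.85)),
    "deep_invalid": ArchetypeSpec("deep_invalid", (1.0,), (1.5,), (0.85,)),
    "flat": ArchetypeSpec("flat", (), (), (), baseline=0.35),
}


def archetype_profile(
    spec: ArchetypeSpec, amplitude_factors: Sequence[float] | None = None
) -> np.ndarray:
    """Noise-free 20-bin profile of an archetype.

    ``amplitude_factors`` multiplies each peak amplitude (per-gene jitter).
    """
    prof = np.full(N_SROIS, spec.baseline, dtype=float)
    factors = (
        np.ones(len(spec.amplitudes))
        if amplitude_factors is None
        else np.asarray(amplitude_factors, dtype=float)
    )
    for pos, width, amp, f in zip(
        spec.peak_positions, spec.peak_widths, spec.amplitudes, factors
    ):
        prof += amp * f * np.exp(-((_SROI_AXIS - pos) ** 2) / (2.0 * width**2))
    return prof


@dataclass
class TruthBundle:
    """Ground truth shared by every downstream test.

    Maps each synthetic gene to its archetype, its noise-free 20-bin radial
    profile and its planted log2 fold-change (target group minus reference).
    """

    gene_ids: list[str]
    archetype_of: dict[str, str]
    true_profiles: dict[str, np.ndarray]
    planted_log2fc: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            if (
                g not in self.archetype_of
                or g not in self.true_profiles
                or g not in self.planted_log2fc
            ):
                raise ValueError(f"gene {g!r} missing from a truth map")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.gene_ids:
            row: dict = {
                "gene_id": g,
                "archetype": self.archetype_of[g],
                "log2fc": self.planted_log2fc[g],
            }
            for i, v in enumerate(self.true_profiles[g], start=1):
                row[f"profile_{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path) -> None:
        """Write the bundle as TSV plus a JSON sidecar of seed/parameters."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        sidecar = tsv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"seed": self.seed, "n_genes": len(self.gene_ids)}, indent=1)
            + "\n"
        )

    @classmethod
    def read(cls, tsv_path: str | Path) -> "TruthBundle":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t")
        sidecar = tsv_path.with_suffix(".json")
        seed = json.loads(sidecar.read_text())["seed"] if sidecar.exists() else -1
        prof_cols = [f"profile_{i}" for i in range(1, N_SROIS + 1)]
        return cls(
            gene_ids=list(df["gene_id"]),
            archetype_of=dict(zip(df["gene_id"], df["archetype"])),
            true_profiles={
                g: np.asarray(v, dtype=float)
                for g, v in zip(df["gene_id"], df[prof_cols].to_numpy())
            },
            planted_log2fc=dict(zip(df["gene_id"], df["log2fc"].astype(float))),
            seed=int(seed),
        )


def _largest_remainder_counts(
    mix: Mapping[str, float], n: int
) -> dict[str, int]:
    """Apportion ``n`` genes over archetypes with largest-remainder rounding."""
    names = list(mix)
    quotas = np.array([mix[a] * n for a in names], dtype=float)
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # break remainder ties by archetype order for determinism
    order = sorted(
        range(len(names)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def generate_truth_profiles(
    n_genes: int,
    archetype_mix: Mapping[str, float],
    seed: int,
    amplitude_jitter_sd: float = 0.05,
    log2fc_range: tuple[float, float] = (np.log2(3.0), np.log2(72.0)),
) -> TruthBundle:
    """Generate ``n_genes`` noise-free radial profiles with known archetypes.

    Archetype membership counts follow ``archetype_mix`` proportions under
    largest-remainder rounding.  Each gene's peak amplitudes carry a small
    multiplicative log-normal jitter (SD ``amplitude_jitter_sd`` on the log
    scale).  Non-flat genes receive a planted log2 fold-change drawn uniformly
    from ``log2fc_range`` (defaults spanning the 3- to 72-fold range of
    strongly regulated genes); flat genes get 0.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for a, p in archetype_mix.items():
        if a not in ARCHETYPES:
            raise KeyError(f"unknown archetype {a!r}")
        if p < 0:
            raise ValueError(f"negative proportion for archetype {a!r}")
    if abs(sum(archetype_mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype proportions must sum to 1")

    counts = _largest_remainder_counts(archetype_mix, n_genes)
    rng = np.random.default_rng(seed)

    gene_ids: list[str] = []
    archetype_of: dict[str, str] = {}
    true_profiles: dict[str, np.ndarray] = {}
    planted: dict[str, float] = {}
    idx = 0
    for name in archetype_mix:
        spec = ARCHETYPES[name]
        for _ in range(counts[name]):
            idx += 1
            g = f"g{idx:04d}"
            factors = np.exp(
                rng.normal(0.0, amplitude_jitter_sd, size=len(spec.amplitudes))
            )
            gene_ids.append(g)
            archetype_of[g] = name
            true_profiles[g] = archetype_profile(spec, factors)
            planted[g] = (
                0.0
                if name == "flat"
                else float(rng.uniform(log2fc_range[0], log2fc_range[1]))
            )
    return TruthBundle(gene_ids, archetype_of, true_profiles, planted, seed)


@dataclass(frozen=True)
class RenderParams:
    """Geometry and noise of the synthetic section image.

    The tissue band is vertical: sROI 1 (ventricular end) at the top of the
    band, sROI 20 at the bottom.  ``background_level`` is the optical density
    of non-tissue pixels; ``illumination_gradient`` adds a linear density ramp
    of that peak-to-peak amplitude down the image; ``noise_sd`` is per-pixel
    Gaussian density noise.  Pixel values clamp to the stated bit depth.
    """

    image_height_px: int = 200
    image_width_px: int = 120
    wall_span_px: int = 160
    band_width_px: int = 40
    background_level: float = 0.05
    illumination_gradient: float = 0.0
    noise_sd: float = 0.01
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.wall_span_px > self.image_height_px:
            raise ValueError("wall_span_px must not exceed image_height_px")
        if not 0 <= self.background_level < 1:
            raise ValueError("background_level must lie in [0, 1)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def white(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def render_ish_image(
    profile: Sequence[float], render: RenderParams | None = None, seed: int = 0
) -> tuple[np.ndarray, RoiSpec]:
    """Render a grayscale section image from a 20-bin optical-density profile.

    Density within the band is piecewise-constant per sROI (using the same
    pixel boundaries the extractor uses, so noise-free extraction inverts the
    rendering exactly), offset by ``background_level`` so that background
    subtraction recovers the profile.  Darkness increases with density.
    Returns the image and a :class:`RoiSpec` whose axis runs ventricular
    (top) to pial (bottom), plus a tissue-free background rectangle.
    """
    render = render or RenderParams()
    prof = np.asarray(profile, dtype=float)
    if prof.shape != (N_SROIS,):
        raise ValueError(f"profile must have length {N_SROIS}")
    if (prof < 0).any():
        raise ValueError("profile must be non-negative")

    h, w = render.image_height_px, render.image_width_px
    span = render.wall_span_px
    y0 = (h - span) // 2
    cx = int(round(w * 0.625))  # band sits right of centre, background at left

    density = np.full((h, w), render.background_level, dtype=float)
    bounds = segment_boundaries(span)
    half = render.band_width_px // 2
    x_lo, x_hi = cx - half, cx - half + render.band_width_px
    for k in range(N_SROIS):
        density[y0 + bounds[k] : y0 + bounds[k + 1], x_lo:x_hi] += prof[k]

    if render.illumination_gradient:
        ramp = np.linspace(
            -render.illumination_gradient / 2,
            render.illumination_gradient / 2,
            h,
        )
        density += ramp[:, None]

    rng = np.random.default_rng(seed)
    if render.noise_sd > 0:
        density = density + rng.normal(0.0, render.noise_sd, size=density.shape)

    white = render.white
    intensity = np.clip(np.rint(white * (1.0 - density)), 0, white)
    image = intensity.astype(render.dtype)

    bg_w = max(8, x_lo // 3)
    roi = RoiSpec(
        axis=((float(cx), float(y0)), (float(cx), float(y0 + span))),
        band_width_px=render.band_width_px,
        background_region=(4, 4, bg_w, max(8, h // 8)),
    )
    return image, roi


@dataclass(frozen=True)
class ReplicateJitter:
    """Section-to-section variation applied to replicate measurements.

    ``axis_shift_px`` — SD of a rigid shift of the ROI along the radial axis;
    ``rotation_deg`` — SD of an image rotation about the band centre (degrees);
    ``amplitude_scale_sd`` — SD (log scale) of a multiplicative staining
    intensity factor.  The defaults emulate the modest ROI-placement and
    staining variability seen between nearby sections.
    """

    axis_shift_px: float = 2.0
    rotation_deg: float = 1.5
    amplitude_scale_sd: float = 0.05


def generate_replicates(
    profile: Sequence[float],
    n_reps: int,
    jitter: ReplicateJitter | None = None,
    render: RenderParams | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, RoiSpec]]:
    """Render ``n_reps`` jittered replicate images of one true profile.

    Each replicate independently draws an amplitude scale, an image rotation
    and an ROI shift from :class:`ReplicateJitter`, emulating repeated manual
    ROI placements on nearby sections.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    jitter = jitter or ReplicateJitter()
    render = render or RenderParams()
    prof = np.asarray(profile, dtype=float)

    out: list[tuple[np.ndarray, RoiSpec]] = []
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        scale = float(np.exp(rng.normal(0.0, jitter.amplitude_scale_sd)))
        angle = float(rng.normal(0.0, jitter.rotation_deg))
        shift = float(rng.normal(0.0, jitter.axis_shift_px))
        render_seed = int(rng.integers(0, 2**31 - 1))

        image, roi = render_ish_image(prof * scale, render, seed=render_seed)
        if angle != 0.0:
            (x0, y0), (x1, y1) = roi.axis
            centre = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
            white = render.white
            img_f = _sk_rotate(
                image.astype(float) / white,
                angle,
                center=centre,
                mode="edge",
                preserve_range=True,
            )
            image = np.clip(np.rint(img_f * white), 0, white).astype(render.dtype)
        if shift:
            # keep the shifted band inside the raster
            max_down = (render.image_height_px - render.wall_span_px) // 2 - 1
            shift = float(np.clip(shift, -max_down, max_down))
            roi = roi.shifted(shift)
        out.append((image, roi))
    return out


def generate_expression_matrix(
    truth: TruthBundle,
    baseline_mean: float = 5.5,
    baseline_sd: float = 0.7,
    n_controls: int = 10,
    replicate_sd: float = 0.25,
    n_reps_per_group: int = 3,
    seed: int = 0,
    target_group: str = "GFP+",
    reference_group: str = "GFP-",
    reference_mean_range: tuple[float, float] = (7.5, 10.5),
) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate a log2-scale RMA expression table with planted fold-changes.

    Each truth gene receives a reference-group mean drawn uniformly from
    ``reference_mean_range`` (comfortably above the expressed threshold, as
    for screened genes); its target-group mean is that value plus the planted
    log2 fold-change.  Per-sample replicate noise is Gaussian with SD
    ``replicate_sd`` log2 units.  ``n_controls`` negative-control genes
    ("not expressed" internal standards, e.g. eye-specific genes) are drawn
    i.i.d. from Normal(``baseline_mean``, ``baseline_sd``) in every sample.

    Returns the matrix (truth genes then controls) and the control gene ids.
    """
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    if n_reps_per_group < 1:
        raise ValueError("n_reps_per_group must be >= 1")
    rng = np.random.default_rng(seed)

    samples = [f"{target_group}_{i+1}" for i in range(n_reps_per_group)] + [
        f"{reference_group}_{i+1}" for i in range(n_reps_per_group)
    ]
    group_of = {
        s: (target_group if s.startswith(target_group) else reference_group)
        for s in samples
    }

    genes = list(truth.gene_ids)
    ref_means = rng.uniform(*reference_mean_range, size=len(genes))
    rows = []
    for g, ref_mu in zip(genes, ref_means):
        tgt_mu = ref_mu + truth.planted_log2fc[g]
        tgt = tgt_mu + rng.normal(0.0, replicate_sd, n_reps_per_group)
        ref = ref_mu + rng.normal(0.0, replicate_sd, n_reps_per_group)
        rows.append(np.concatenate([tgt, ref]))

    control_ids = [f"ctrl_eye{i+1:02d}" for i in range(n_controls)]
    for _ in control_ids:
        rows.append(rng.normal(baseline_mean, baseline_sd, len(samples)))

    values = pd.DataFrame(rows, index=genes + control_ids, columns=samples)
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, group_of=group_of), control_ids
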