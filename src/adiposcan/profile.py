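"""Vertical body profiles: landmark detection and per-part slicing.

A scanned body is reduced to a 1-D vertical profile — for every sampled
height, the total cross-section perimeter (cm) and area (cm^2). The
anatomical landmarks used to slice parts are detected purely from the
perimeter trace:

* neck — first local perimeter minimum scanning down from the crown;
* armpit — first height below the shoulder maximum where the perimeter
  drops by more than a configured fraction per slice (the arm-attributable
  contribution vanishes);
* navel — the perimeter minimum inside the torso band that is followed by
  a recovery (the waist dip);
* thigh (groin) — the last height, scanning down from the navel, before
  the single torso cross-section splits into two legs (a per-slice
  perimeter jump above the same fraction);
* knee — the centre of the band of maximal local perimeter variation
  (rolling standard deviation) between thigh and calf.

Circumference and area per part are the profile values at the defining
landmark height; part volumes integrate the area trace with the trapezoid
rule, which is exact for the piecewise-linear profiles used as templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, LandmarkDetectionError


@dataclass
class BodyProfile:
    """Uniformly sampled vertical profile: heights (cm, strictly increasing),
    per-height cross-section perimeter (cm) and area (cm^2)."""

    heights: np.ndarray
    perimeter: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.perimeter = np.asarray(self.perimeter, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        n = self.heights.size
        if n < 3 or self.perimeter.size != n or self.area.size != n:
            raise DomainError("profile needs >= 3 aligned (height, perimeter, area) samples")
        steps = np.diff(self.heights)
        if np.any(steps <= 0):
            raise DomainError("profile heights must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise DomainError("profile heights must be uniformly spaced")
        if np.any(self.perimeter < 0) or np.any(self.area < 0):
            raise DomainError("perimeters and areas must be non-negative")

    @property
    def spacing(self) -> float:
        return float(self.heights[1] - self.heights[0])

    def index_of(self, height: float) -> int:
        if not self.heights[0] <= height <= self.heights[-1]:
            raise DomainError(
                f"height {height} outside profile range "
                f"[{self.heights[0]}, {self.heights[-1]}]"
            )
        return int(round((height - self.heights[0]) / self.spacing))


@dataclass(frozen=True)
class LandmarkSet:
    """Detected landmark heights (cm), ordered bottom < knee < thigh <
    navel < armpit < neck < top."""

    neck_h: float
    armpit_h: float
    navel_h: float
    thigh_h: float
    knee_h: float
    top: float
    bottom: float

    def __post_init__(self) -> None:
        seq = (self.bottom, self.knee_h, self.thigh_h, self.navel_h,
               self.armpit_h, self.neck_h, self.top)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise DomainError(f"landmarks violate anatomical ordering: {seq}")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for the qualitative detection rules."""

    drop_fraction: float = 0.15  # per-slice relative perimeter change at armpit / leg split
    recovery_fraction: float = 0.02  # minimum relative perimeter recovery after the navel dip
    knee_window: int = 7  # samples per rolling-sd window for the knee band
    knee_band_level: float = 0.5  # fraction of the rolling-sd maximum defining the band


def _first_local_min_from_top(perimeter: np.ndarray) -> int | None:
    for i in range(perimeter.size - 2, 0, -1):
        if perimeter[i] < perimeter[i + 1] and perimeter[i] < perimeter[i - 1]:
            return i
    return None


def detect_landmarks(profile: BodyProfile, config: DetectionConfig | None = None) -> LandmarkSet:
    """Locate the five interior landmarks on a vertical profile.

    Raises LandmarkDetectionError naming the first landmark that cannot be
    located (a constant-perimeter cylinder, for instance, has no neck
    minimum and no navel dip).
    """
    cfg = config if config is not None else DetectionConfig()
    p = profile.perimeter
    h = profile.heights

    neck_i = _first_local_min_from_top(p)
    if neck_i is None:
        raise LandmarkDetectionError(
            "neck: no local perimeter minimum descending from the head end "
            "(and hence no navel minimum either)"
        )

    # shoulder maximum below the neck, then the first per-slice collapse
    below_neck = p[:neck_i]
    if below_neck.size < 3:
        raise LandmarkDetectionError("armpit: no samples below the neck")
    shoulder_i = int(np.argmax(below_neck))
    armpit_i = None
    for i in range(shoulder_i, 0, -1):
        prev, cur = p[i], p[i - 1]
        if prev > 0 and (prev - cur) / prev > cfg.drop_fraction:
            armpit_i = i - 1
            break
    if armpit_i is None:
        raise LandmarkDetectionError(
            f"armpit: no per-slice perimeter drop above {cfg.drop_fraction:.0%} below the shoulder"
        )

    # leg split: scanning down from the armpit, first per-slice jump
    split_i = None
    for i in range(armpit_i, 0, -1):
        prev, cur = p[i], p[i - 1]
        if prev > 0 and abs(cur - prev) / prev > cfg.drop_fraction:
            split_i = i  # last single-torso sample
            break
    if split_i is None:
        raise LandmarkDetectionError(
            f"thigh: no per-slice perimeter jump above {cfg.drop_fraction:.0%} "
            "below the armpit (torso never splits into legs)"
        )

    # navel: argmin of the torso band, must recover afterwards
    band = slice(split_i + 1, armpit_i)
    if band.stop - band.start < 3:
        raise LandmarkDetectionError("navel: torso band between thigh and armpit too short")
    navel_i = band.start + int(np.argmin(p[band]))
    recovery = p[navel_i:armpit_i].max() - p[navel_i]
    if navel_i in (band.start, band.stop - 1) or recovery < cfg.recovery_fraction * max(p[navel_i], 1e-12):
        raise LandmarkDetectionError(
            "navel: no interior perimeter minimum followed by recovery in the torso band"
        )

    # knee: centre of the maximal rolling-variation band in the leg region
    leg = p[:split_i]
    w = cfg.knee_window
    if leg.size <= w:
        raise LandmarkDetectionError("knee: leg region shorter than the rolling window")
    sliding = np.lib.stride_tricks.sliding_window_view(leg, w)
    rolling_sd = sliding.std(axis=1)
    if rolling_sd.max() <= 0:
        raise LandmarkDetectionError("knee: no perimeter variation in the leg region")
    centers = np.arange(rolling_sd.size) + (w - 1) / 2.0
    peak = int(np.argmax(rolling_sd))
    level = cfg.knee_band_level * rolling_sd.max()
    left, right = peak, peak
    while left > 0 and rolling_sd[left - 1] >= level:
        left -= 1
    while right < rolling_sd.size - 1 and rolling_sd[right + 1] >= level:
        right += 1
    knee_i = float(centers[left:right + 1].mean())  # fractional index

    h0, dh = h[0], profile.spacing
    return LandmarkSet(
        neck_h=float(h[neck_i]),
        armpit_h=float(h[armpit_i]),
        navel_h=float(h[navel_i]),
        thigh_h=float(h[split_i]),
        knee_h=float(h0 + knee_i * dh),
        top=float(h[-1]),
        bottom=float(h[0]),
    )


# ---------------------------------------------------------------------------
# slicing


def circumference_at(profile: BodyProfile, height: float) -> float:
    """Perimeter at a height, linearly interpolated on the sample grid."""
    if not profile.heights[0] <= height <= profile.heights[-1]:
        raise DomainError(f"height {height} outside profile range")
    return float(np.interp(height, profile.heights, profile.perimeter))


def area_at(profile: BodyProfile, height: float) -> float:
    """Cross-section area at a height, linearly interpolated."""
    if not profile.heights[0] <= height <= profile.heights[-1]:
        raise DomainError(f"height {height} outside profile range")
    return float(np.interp(height, profile.heights, profile.area))


def volume_between(profile: BodyProfile, h1: float, h2: float) -> float:
    """Trapezoidal integral of the area trace over [h1, h2] (cm^3)."""
    if h2 < h1:
        raise DomainError(f"empty height band: [{h1}, {h2}]")
    for h in (h1, h2):
        if not profile.heights[0] <= h <= profile.heights[-1]:
            raise DomainError(f"height {h} outside profile range")
    if h1 == h2:
        return 0.0
    inner = profile.heights[(profile.heights > h1) & (profile.heights < h2)]
    grid = np.concatenate(([h1], inner, [h2]))
    values = np.interp(grid, profile.heights, profile.area)
    return float(np.trapezoid(values, grid))


def slice_measurements(profile: BodyProfile, landmarks: LandmarkSet) -> dict[str, float]:
    """Derive per-part circumferences, areas, volumes and lengths.

    Defining heights: waist at the navel; hip at 30% of the thigh-to-navel
    band above the thigh split (the buttock protrusion sits below the
    navel); chest at 75% of the navel-to-armpit band; knee at the detected
    knee. Volumes integrate area over the shoulder (armpit-neck), chest
    (navel-armpit), abdomen (thigh-navel) and leg (bottom-thigh) bands.
    """
    for name in ("neck_h", "armpit_h", "navel_h", "thigh_h", "knee_h"):
        hgt = getattr(landmarks, name)
        if not profile.heights[0] <= hgt <= profile.heights[-1]:
            raise DomainError(f"landmark {name}={hgt} outside profile range")
    hip_h = landmarks.thigh_h + 0.3 * (landmarks.navel_h - landmarks.thigh_h)
    chest_h = landmarks.navel_h + 0.75 * (landmarks.armpit_h - landmarks.navel_h)
    out: dict[str, float] = {}
    for name, hgt in (
        ("neck", landmarks.neck_h),
        ("chest", chest_h),
        ("waist", landmarks.navel_h),
        ("hip", hip_h),
        ("knee", landmarks.knee_h),
    ):
        out[f"{name}_circumference"] = circumference_at(profile, hgt)
        out[f"{name}_area"] = area_at(profile, hgt)
    out["shoulder_volume"] = volume_between(profile, landmarks.armpit_h, landmarks.neck_h)
    out["chest_volume"] = volume_between(profile, landmarks.navel_h, landmarks.armpit_h)
    out["abdominal_volume"] = volume_between(profile, landmarks.thigh_h, landmarks.navel_h)
    out["leg_volume"] = volume_between(profile, landmarks.bottom, landmarks.thigh_h)
    out["total_volume"] = volume_between(profile, landmarks.bottom, landmarks.top)
    out["torso_length"] = landmarks.neck_h - landmarks.thigh_h
    out["leg_length"] = landmarks.thigh_h - landmarks.bottom
    return out


# ---------------------------------------------------------------------------
# synthetic template profiles (fixtures are generated, never stored)


@dataclass(frozen=True)
class TemplateParams:
    """Construction parameters of the synthetic template body profile;
    the landmark heights below are the detection ground truth."""

    total_height: float = 170.0
    neck_h: float = 145.0
    armpit_h: float = 132.0
    navel_h: float = 103.0
    thigh_h: float = 78.0
    knee_h: float = 46.0
    spacing: float = 0.5
    knee_ripple_amplitude: float = 6.0
    knee_ripple_period: float = 4.0
    knee_ripple_halfwidth: float = 5.0
    # (height, perimeter) control points, bottom to top; a deliberate
    # discontinuity at thigh_h marks the two-legs -> torso transition and
    # a second one just above armpit_h adds the arm/shoulder contribution.
    control_points: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: (
            (0.0, 46.0),
            (34.0, 74.0),  # calf bulge
            (40.0, 66.0),
            (52.0, 66.0),  # knee plateau (ripple added on top)
            (60.0, 90.0),  # mid thigh
            (72.0, 106.0),  # thick thigh
            (77.5, 112.0),  # two legs, just below the split
            (78.0, 94.0),  # torso hull, at the split
            (88.0, 100.0),  # hip protrusion
            (103.0, 87.0),  # navel dip
            (120.0, 96.0),  # chest
            (132.0, 98.0),  # just below the armpit
            (132.5, 124.0),  # arms join the section
            (138.0, 126.0),  # shoulder maximum
            (145.0, 38.0),  # neck minimum
            (150.0, 56.0),  # head
            (160.0, 58.0),
            (168.0, 40.0),
            (170.0, 8.0),
        )
    )


def template_profile(params: TemplateParams | None = None) -> tuple[BodyProfile, TemplateParams]:
    """Piecewise-linear human-silhouette profile with known landmarks.

    Returns the profile and the parameters used, so tests can compare the
    detector output against the construction values.
    """
    params = params if params is not None else TemplateParams()
    pts = np.asarray(params.control_points, dtype=float)
    h = np.arange(0.0, params.total_height + params.spacing / 2, params.spacing)
    perimeter = np.interp(h, pts[:, 0], pts[:, 1])
    envelope = np.exp(-(((h - params.knee_h) / params.knee_ripple_halfwidth) ** 2))
    ripple = params.knee_ripple_amplitude * np.sin(
        2 * np.pi * (h - params.knee_h) / params.knee_ripple_period
    )
    perimeter = perimeter + np.where(h < params.thigh_h, envelope * ripple, 0.0)
    perimeter = np.clip(perimeter, 0.0, None)
    area = perimeter**2 / (4 * np.pi)  # circle-equivalent section
    return BodyProfile(h, perimeter, area), params


def cylinder_profile(radius: float = 15.0, height: float = 100.0, spacing: float = 0.5) -> BodyProfile:
    """Constant-perimeter cylinder; degenerate for landmark detection."""
    h = np.arange(0.0, height + spacing / 2, spacing)
    perimeter = np.full_like(h, 2 * np.pi * radius)
    area = np.full_like(h, np.pi * radius**2)
    return BodyProfile(h, perimeter, area)


def profile_to_table(profile: BodyProfile) -> str:
    """Three-column delimited text: height, perimeter, area."""
    import pandas as pd

    return pd.DataFrame(
        {"height": profile.heights, "perimeter": profile.perimeter, "area": profile.area}
    ).to_csv(index=False)


def profile_from_table(path_or_buffer) -> BodyProfile:
    import io as _io

    import pandas as pd

    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = _io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer)
    if "area" not in frame.columns:
        frame["area"] = frame["perimeter"] ** 2 / (4 * np.pi)
    return BodyProfile(
        frame["height"].to_numpy(), frame["perimeter"].to_numpy(), frame["area"].to_numpy()
    )
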