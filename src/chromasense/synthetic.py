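"""Synthetic study-design generator for colorimetric sensor-array monitoring.

Emulates a batch-culture monitoring study: repeated yeast culture batches
sampled on a fixed time grid, a reference OD600 measurement with the
dilution bookkeeping spectrophotometry requires (readings are linear in
cell concentration only within a narrow absorbance window), and a 4x3
array of chemo-responsive dye spots whose pre/post-exposure RGB change
encodes the culture headspace odor.  Every downstream stage (feature
extraction, regression, wrapper feature selection) is testable against
data from this module, with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DYE_NAMES",
    "CHANNELS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "DEFAULT_TIMES_H",
    "GrowthParams",
    "ResponseModel",
    "SensorLayout",
    "SampleRecord",
    "ImagePair",
    "simulate_growth_curve",
    "simulate_od_measurement",
    "simulate_feature_vector",
    "render_image_pair",
    "generate_dataset",
    "dataset_to_frame",
    "frame_to_records",
]

#: The 12 color-sensitive materials (11 porphyrins + 1 pH indicator),
#: row-major over the 4x3 array.  Kept as naming metadata only.
DYE_NAMES: tuple[str, ...] = (
    "TPP", "TPPMnCl", "FTPPFeCl", "TPPFeCl", "TPPCu", "FTPPCo",
    "TPPZn", "MTPPTE", "MTPPNiCl", "OEPPNi", "MTPP", "BTB",
)

CHANNELS: tuple[str, str, str] = ("R", "G", "B")

#: Feature ordering is dye-major, channels R,G,B -- 36 names "<dye>:<channel>".
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{dye}:{ch}" for dye in DYE_NAMES for ch in CHANNELS
)

N_FEATURES = len(FEATURE_NAMES)  # 36

#: 19 sampling time points: 0-72 h at a 4-h interval.
DEFAULT_TIMES_H: tuple[float, ...] = tuple(float(t) for t in range(0, 73, 4))

#: Admissible absorbance window for a single spectrophotometer read.
OD_WINDOW = (0.1, 0.65)


def feature_index(dye: str, channel: str) -> int:
    """Index of ``<dye>:<channel>`` in the 36-component feature vector."""
    return FEATURE_NAMES.index(f"{dye}:{channel}")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic batch-growth parameters, OD600 units and hours.

    Defaults are calibrated so a 0-72 h culture spans OD 0.001-9.12,
    the dynamic range a dense yeast batch culture reaches.
    """

    carrying_capacity: float = 9.118
    growth_rate: float = 0.22
    midpoint_time: float = 30.0
    baseline_od: float = 0.001

    def __post_init__(self) -> None:
        vals = (self.carrying_capacity, self.growth_rate,
                self.midpoint_time, self.baseline_od)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("growth parameters must be finite")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.baseline_od < 0:
            raise ValueError("baseline_od must be non-negative")


@dataclass(frozen=True)
class ResponseModel:
    """Saturating (Michaelis-type) link from OD to the 36 DeltaRGB responses.

    Component c responds ``coefficients[c] * od / (od + saturation_half_od)``
    plus additive Gaussian pixel noise; only components listed in
    ``informative_indices`` carry a nonzero coefficient, emulating the
    cross-sensitivity of the dye array where a few spot/channel
    combinations track the culture odor and the rest drift with noise.
    """

    coefficients: np.ndarray
    saturation_half_od: float = 1.5
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (N_FEATURES,):
            raise ValueError(f"coefficients must have shape ({N_FEATURES},)")
        object.__setattr__(self, "coefficients", coef)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.saturation_half_od <= 0:
            raise ValueError("saturation_half_od must be positive")
        # rendered responses must stay inside 8-bit headroom
        if np.any(np.abs(coef) + 5.0 * self.noise_sd > 255):
            raise ValueError("response exceeds 8-bit gray-level headroom")

    @property
    def informative_indices(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.coefficients))

    @classmethod
    def default(cls, noise_sd: float = 2.0) -> "ResponseModel":
        """Two strongly and two weakly informative components, 32 noise-only.

        The strong pair is FTPPFeCl:B and MTPPTE:B; the weak pair is
        TPPMnCl:B and BTB:B, mirroring the spot/channel combinations
        a metalloporphyrin array most plausibly couples to culture VOCs.
        """
        coef = np.zeros(N_FEATURES)
        coef[feature_index("FTPPFeCl", "B")] = 60.0
        coef[feature_index("MTPPTE", "B")] = -45.0
        coef[feature_index("TPPMnCl", "B")] = 12.0
        coef[feature_index("BTB", "B")] = -10.0
        return cls(coefficients=coef, noise_sd=noise_sd)

    @classmethod
    def two_component(cls, noise_sd: float = 2.0) -> "ResponseModel":
        """Exactly two informative components (FTPPFeCl:B, MTPPTE:B)."""
        coef = np.zeros(N_FEATURES)
        coef[feature_index("FTPPFeCl", "B")] = 60.0
        coef[feature_index("MTPPTE", "B")] = -45.0
        return cls(coefficients=coef, noise_sd=noise_sd)


# fixed mid-range base (pre-exposure) spot colors per dye, one RGB triple
# each; chosen inside [80, 170] so base + response + jitter stays in gamut
_BASE_PALETTE = np.array([
    [150, 100, 110], [140, 120, 90], [120, 90, 140], [160, 110, 100],
    [110, 130, 120], [130, 140, 95], [100, 120, 150], [145, 95, 130],
    [115, 145, 105], [155, 125, 115], [105, 105, 135], [135, 150, 120],
], dtype=float)


@dataclass(frozen=True)
class SensorLayout:
    """Geometry of the 4x3 spot array on the rendered sensor image."""

    grid_rows: int = 4
    grid_cols: int = 3
    dye_names: tuple[str, ...] = DYE_NAMES
    spot_centers: tuple[tuple[float, float], ...] = tuple(
        (50.0 + 100.0 * c, 50.0 + 100.0 * r)  # (x, y)
        for r in range(4) for c in range(3)
    )
    spot_radius_render: float = 22.0
    image_size: tuple[int, int] = (400, 300)  # (height, width)

    def __post_init__(self) -> None:
        n = self.grid_rows * self.grid_cols
        if len(self.dye_names) != n or len(self.spot_centers) != n:
            raise ValueError("dye_names/spot_centers must match grid size")
        h, w = self.image_size
        r = self.spot_radius_render
        centers = np.asarray(self.spot_centers, dtype=float)
        if np.any(centers[:, 0] - r < 0) or np.any(centers[:, 0] + r >= w) \
                or np.any(centers[:, 1] - r < 0) or np.any(centers[:, 1] + r >= h):
            raise ValueError("spot discs must lie fully inside the image")
        d = np.sqrt(((centers[None] - centers[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * r:
            raise ValueError("spot discs overlap")

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "dye_names": list(self.dye_names),
            "spot_centers": [list(c) for c in self.spot_centers],
            "spot_radius_render": self.spot_radius_render,
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        return cls(
            grid_rows=int(d["grid_rows"]),
            grid_cols=int(d["grid_cols"]),
            dye_names=tuple(d["dye_names"]),
            spot_centers=tuple((float(x), float(y)) for x, y in d["spot_centers"]),
            spot_radius_render=float(d["spot_radius_render"]),
            image_size=(int(d["image_size"][0]), int(d["image_size"][1])),
        )


@dataclass
class ImagePair:
    """Pre/post-exposure 8-bit RGB sensor-array images."""

    before: np.ndarray
    after: np.ndarray
    layout_hint: SensorLayout | None = None

    def __post_init__(self) -> None:
        if self.before.shape != self.after.shape:
            raise ValueError("before/after images must share dimensions")
        if self.before.ndim != 3 or self.before.shape[2] != 3:
            raise ValueError("images must be HxWx3 RGB")


@dataclass
class SampleRecord:
    """One culture sample: provenance, reference OD, and its 36 features."""

    sample_id: str
    batch_id: int
    time_h: float
    od_true: float
    od_measured: float
    dilution_factor: float
    features: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.shape != (N_FEATURES,):
            raise ValueError(f"features must have {N_FEATURES} entries")
        self.features = f


def simulate_growth_curve(times, params: GrowthParams = GrowthParams()):
    """Logistic OD600 trajectory: baseline + K / (1 + exp(-r (t - t0))).

    Parameters
    ----------
    times : array-like of hours, non-empty and non-negative.
    params : GrowthParams

    Returns
    -------
    ndarray of OD values, monotone non-decreasing in time.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    z = -params.growth_rate * (t - params.midpoint_time)
    return params.baseline_od + params.carrying_capacity / (1.0 + np.exp(z))


#: Dilution ladder mantissas; factors are {1, 2, 5} x 10^k.
_LADDER_MANTISSAS = (1, 2, 5)


def _dilution_factor(od_true: float) -> int:
    """Smallest ladder factor bringing the read at or below the window top."""
    hi = OD_WINDOW[1]
    k = 0
    while True:
        for m in _LADDER_MANTISSAS:
            f = m * 10 ** k
            if od_true / f <= hi:
                return f
        k += 1


def simulate_od_measurement(od_true: float, read_noise_sd: float = 0.005,
                            rng: np.random.Generator | None = None):
    """Emulate the reference OD600 protocol: dilute, read thrice, average.

    A suspension too dense for the linear window is diluted by the smallest
    ladder factor f with od_true/f <= 0.65; the diluted aliquot is read
    three times with additive read noise, and the reported value is the
    dilution factor times the mean read.  OD already below the window is
    reported undiluted (dilution cannot raise a low read).

    Returns
    -------
    (od_measured, dilution_factor)
    """
    if od_true < 0:
        raise ValueError("od_true must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    f = _dilution_factor(float(od_true))
    reads = od_true / f + rng.normal(0.0, read_noise_sd, size=3)
    return float(f * reads.mean()), f


def simulate_feature_vector(od_true: float, model: ResponseModel,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one 36-component DeltaRGB response at the given OD."""
    rng = np.random.default_rng() if rng is None else rng
    sat = od_true / (od_true + model.saturation_half_od)
    return model.coefficients * sat + rng.normal(0.0, model.noise_sd, N_FEATURES)


def _disc_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def render_image_pair(features: np.ndarray, layout: SensorLayout = SensorLayout(),
                      rng: np.random.Generator | None = None,
                      background_gray: int = 12,
                      base_jitter_sd: float = 1.5) -> ImagePair:
    """Render a pre/post image pair whose spot interiors differ by `features`.

    The inverse of feature extraction: each spot is a flat disc of its
    dye's base color (with small per-sample jitter), and the post image
    adds the integer-rounded DeltaR/DeltaG/DeltaB to the disc interior.

    Raises
    ------
    ValueError
        if any rendered spot color leaves [0, 255]; the message names the
        offending <dye>:<channel> component.
    """
    f = np.asarray(features, dtype=float)
    if f.shape != (N_FEATURES,):
        raise ValueError(f"features must have {N_FEATURES} entries")
    rng = np.random.default_rng() if rng is None else rng
    h, w = layout.image_size
    before = np.full((h, w, 3), background_gray, dtype=np.uint8)
    after = before.copy()
    delta = np.rint(f).reshape(len(layout.dye_names), 3)
    jitter = np.rint(rng.normal(0.0, base_jitter_sd, _BASE_PALETTE.shape))
    for s, (cx, cy) in enumerate(layout.spot_centers):
        base = _BASE_PALETTE[s % len(_BASE_PALETTE)] + jitter[s % len(jitter)]
        post = base + delta[s]
        for colors, name in ((base, "pre"), (post, "post")):
            bad = np.flatnonzero((colors < 0) | (colors > 255))
            if bad.size:
                comp = f"{layout.dye_names[s]}:{CHANNELS[bad[0]]}"
                raise ValueError(
                    f"{name}-image spot color out of 8-bit gamut at {comp}")
        mask = _disc_mask(h, w, cx, cy, layout.spot_radius_render)
        before[mask] = base.astype(np.uint8)
        after[mask] = post.astype(np.uint8)
    return ImagePair(before=before, after=after, layout_hint=layout)


@dataclass(frozen=True)
class DatasetDesign:
    """Full study design: time grid, growth model, response model, jitter."""

    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    growth: GrowthParams = GrowthParams()
    response: ResponseModel = field(default_factory=ResponseModel.default)
    read_noise_sd: float = 0.005
    # batch-to-batch multiplicative jitter (lognormal sd) on K and r,
    # additive jitter (h) on the midpoint time
    capacity_jitter: float = 0.02
    rate_jitter: float = 0.08
    midpoint_jitter_h: float = 1.5


def generate_dataset(n_batches: int = 8,
                     design: DatasetDesign = DatasetDesign(),
                     seed: int | None = 0) -> list[SampleRecord]:
    """Simulate `n_batches` culture batches sampled on the design time grid.

    Each batch perturbs the growth parameters (batch-to-batch biological
    variability), then every time point yields a reference OD measurement
    and a sensor feature vector.  Deterministic given the seed.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for b in range(1, n_batches + 1):
        g = design.growth
        params = replace(
            g,
            carrying_capacity=g.carrying_capacity
            * float(np.exp(rng.normal(0.0, design.capacity_jitter))),
            growth_rate=g.growth_rate
            * float(np.exp(rng.normal(0.0, design.rate_jitter))),
            midpoint_time=g.midpoint_time
            + float(rng.normal(0.0, design.midpoint_jitter_h)),
        )
        od_curve = simulate_growth_curve(design.times_h, params)
        for t, od in zip(design.times_h, od_curve):
            od_meas, dil = simulate_od_measurement(
                float(od), design.read_noise_sd, rng)
            feats = simulate_feature_vector(float(od), design.response, rng)
            records.append(SampleRecord(
                sample_id=f"b{b:02d}_t{int(t):02d}",
                batch_id=b,
                time_h=float(t),
                od_true=float(od),
                od_measured=od_meas,
                dilution_factor=float(dil),
                features=feats,
            ))
    return records


_META_COLUMNS = ["sample_id", "batch_id", "time_h", "od_true",
                 "od_measured", "dilution_factor"]


def dataset_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Tabulate records: metadata columns then the 36 <dye>:<channel> columns."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "batch_id": r.batch_id,
               "time_h": r.time_h, "od_true": r.od_true,
               "od_measured": r.od_measured,
               "dilution_factor": r.dilution_factor}
        row.update(zip(FEATURE_NAMES, r.features))
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + list(FEATURE_NAMES))


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    """Inverse of :func:`dataset_to_frame`."""
    feats = frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return [
        SampleRecord(
            sample_id=str(row.sample_id), batch_id=int(row.batch_id),
            time_h=float(row.time_h), od_true=float(row.od_true),
            od_measured=float(row.od_measured),
            dilution_factor=float(row.dilution_factor),
            features=feats[i],
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]
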