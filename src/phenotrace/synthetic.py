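"""Synthetic multi-channel fluorescence traces with known ground truth.

Emulates the statistical structure of confocal imaging of impacted articular
cartilage: each cell carries three stain channels — calcium concentration,
mitochondrial polarity (TMRM), and nuclear membrane permeability (NMP, a cell
death indicator) — recorded for ~3 h at ~12 s per frame over a 660 μm × 660 μm
field (512 × 512 px). Cells at the impact site additionally carry a 60 s
calcium trace sampled at 40 fps capturing the peracute response, whose shape
spans sharp fast-decaying peaks to broad plateaus.

A built-in library of 14 behavioral phenotypes covers the taxonomy observed in
impacted cartilage: viable cells with decaying mitochondrial polarity and
various calcium kinetics (phenotypes 1–9) and death phenotypes with elevated
or rising nuclear membrane permeability (10–14), including instantaneous death
(an initial NMP spike) and delayed death preceded by a late calcium transient.
Kinetics are built from exponential decays, logistic rises and falls, Gaussian
transients, and spike-then-decay terms; noise is additive i.i.d. Gaussian,
clamped at zero. Intensities are in arbitrary units scaled to about [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

CHANNELS = ("calcium", "mito", "nmp")  # fixed order everywhere

#: default additive noise, a.u. (~5% of full scale)
DEFAULT_NOISE_SD = 0.05
#: cells within this distance of the impact point carry impact calcium traces
IMPACT_RADIUS_UM = 100.0


# --------------------------------------------------------------------------
# phenotype specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeSpec:
    """Deterministic kinetics of one behavioral phenotype.

    Channel parameter dictionaries:

    - ``mito``: ``baseline`` (a.u.), ``decay_rate`` (1/h)
    - ``ca``: ``baseline``, ``decay_rate``, optional ``transient``
      {onset (h), duration (h), amplitude}, optional ``fall``
      {onset (h), steepness (1/h)} multiplying the baseline down
    - ``nmp``: ``baseline``, optional ``rise`` {onset (h), steepness (1/h),
      amplitude}, optional ``spike`` {amplitude, decay_rate (1/h)}

    ``spatial_bias`` is a monotone weight function of distance to the impact
    site (dimensionless); phenotypes with decaying bias are enriched near it.
    """

    name: str
    mito: dict = field(default_factory=dict)
    ca: dict = field(default_factory=dict)
    nmp: dict = field(default_factory=dict)
    spatial_bias: Callable[[np.ndarray], np.ndarray] | None = None
    is_death: bool = False

    def __post_init__(self) -> None:
        for params in (self.mito, self.ca, self.nmp):
            for key, val in params.items():
                if isinstance(val, dict):
                    for k2, v2 in val.items():
                        if k2 in ("amplitude",) and v2 < 0:
                            raise ValueError(f"{self.name}: negative amplitude")
                elif key in ("baseline", "decay_rate") and val < 0:
                    raise ValueError(f"{self.name}: negative {key}")

    def bias(self, distance: np.ndarray) -> np.ndarray:
        if self.spatial_bias is None:
            return np.ones_like(np.asarray(distance, dtype=float))
        return np.asarray(self.spatial_bias(distance), dtype=float)

    def mean_trace(self, time_grid: np.ndarray) -> np.ndarray:
        """Noiseless 3-channel kinetics on ``time_grid`` (hours), (3, T)."""
        t = np.asarray(time_grid, dtype=float)
        ca = _eval_ca(self.ca, t)
        mito = _eval_decay(self.mito, t)
        nmp = _eval_nmp(self.nmp, t)
        return np.clip(np.stack([ca, mito, nmp]), 0.0, None)


def _eval_decay(p: dict, t: np.ndarray) -> np.ndarray:
    base = p.get("baseline", 0.0)
    rate = p.get("decay_rate", 0.0)
    return base * np.exp(-rate * t)


def _logistic(t: np.ndarray, onset: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (t - onset)))


def _eval_ca(p: dict, t: np.ndarray) -> np.ndarray:
    y = _eval_decay(p, t)
    fall = p.get("fall")
    if fall:
        y = y * (1.0 - _logistic(t, fall["onset"], fall["steepness"]))
    tr = p.get("transient")
    if tr:
        y = y + tr["amplitude"] * np.exp(-((t - tr["onset"]) ** 2) / (2 * tr["duration"] ** 2))
    return y


def _eval_nmp(p: dict, t: np.ndarray) -> np.ndarray:
    y = np.full_like(t, p.get("baseline", 0.0), dtype=float)
    rise = p.get("rise")
    if rise:
        y = y + rise["amplitude"] * _logistic(t, rise["onset"], rise["steepness"])
    spike = p.get("spike")
    if spike:
        y = y + spike["amplitude"] * np.exp(-spike["decay_rate"] * t)
    return y


def _near_impact(scale_um: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda d: np.exp(-np.asarray(d, dtype=float) / scale_um)


def _build_library() -> dict[str, PhenotypeSpec]:
    """The 14-entry phenotype library.

    Phenotypes 1–9 are viable (low/no NMP) with varying calcium level and
    mitochondrial decay; 10–14 are death phenotypes enriched near the impact
    site, from instantaneous death (NMP spike at onset) through early death to
    delayed death at ~2 h and ~1.3–1.5 h.
    """
    P = PhenotypeSpec
    lib = [
        P("cluster_01", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.15, "decay_rate": 0.1}, nmp={"baseline": 0.10}),
        P("cluster_02", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.45, "decay_rate": 0.0}, nmp={"baseline": 0.02}),
        P("cluster_03", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.45, "decay_rate": 0.5}, nmp={"baseline": 0.02}),
        P("cluster_04", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.32, "decay_rate": 0.0}, nmp={"baseline": 0.02}),
        P("cluster_05", mito={"baseline": 0.9, "decay_rate": 0.6},
          ca={"baseline": 0.45, "decay_rate": 0.0}, nmp={"baseline": 0.02}),
        P("cluster_06", mito={"baseline": 0.9, "decay_rate": 0.6},
          ca={"baseline": 0.8, "decay_rate": 0.6}, nmp={"baseline": 0.02}),
        P("cluster_07", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.8, "decay_rate": 0.6}, nmp={"baseline": 0.02}),
        P("cluster_08", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.45, "decay_rate": 0.5}, nmp={"baseline": 0.15}),
        P("cluster_09", mito={"baseline": 0.6, "decay_rate": 0.3},
          ca={"baseline": 0.45, "decay_rate": 0.25}, nmp={"baseline": 0.02}),
        # death phenotypes -------------------------------------------------
        P("cluster_10", mito={"baseline": 0.0},
          ca={"baseline": 0.0},
          nmp={"baseline": 0.30, "spike": {"amplitude": 0.7, "decay_rate": 0.8}},
          spatial_bias=_near_impact(80.0), is_death=True),
        P("cluster_11", mito={"baseline": 0.0},
          ca={"baseline": 0.5, "decay_rate": 0.5},
          nmp={"baseline": 0.35, "spike": {"amplitude": 0.55, "decay_rate": 0.5}},
          spatial_bias=_near_impact(150.0), is_death=True),
        P("cluster_12", mito={"baseline": 0.0},
          ca={"baseline": 0.3, "decay_rate": 1.5},
          nmp={"baseline": 0.50, "spike": {"amplitude": 0.3, "decay_rate": 0.3}},
          spatial_bias=_near_impact(200.0), is_death=True),
        P("cluster_13", mito={"baseline": 0.0},
          ca={"baseline": 0.1, "decay_rate": 0.3,
              "transient": {"onset": 2.0, "duration": 0.25, "amplitude": 0.6}},
          nmp={"baseline": 0.05, "rise": {"onset": 2.2, "steepness": 6.0, "amplitude": 0.8}},
          spatial_bias=_near_impact(150.0), is_death=True),
        P("cluster_14", mito={"baseline": 0.0},
          ca={"baseline": 0.5, "decay_rate": 0.0,
              "fall": {"onset": 1.5, "steepness": 6.0}},
          nmp={"baseline": 0.05, "rise": {"onset": 1.3, "steepness": 6.0, "amplitude": 0.8}},
          spatial_bias=_near_impact(150.0), is_death=True),
    ]
    return {spec.name: spec for spec in lib}


_LIBRARY = _build_library()

#: canonical 6-phenotype subset spanning the main behavioral archetypes:
#: low-calcium viable, decaying-calcium viable, high-calcium viable,
#: instantaneous death, delayed death (~2 h), delayed death (~1.3 h)
SIX_PHENOTYPES = (
    "cluster_01",
    "cluster_03",
    "cluster_06",
    "cluster_10",
    "cluster_13",
    "cluster_14",
)


class UnknownPhenotypeError(KeyError):
    pass


def make_phenotype_library(subset: list[str] | None = None) -> list[PhenotypeSpec]:
    """Return the built-in 14-entry phenotype library or a named subset."""
    if subset is None:
        return list(_LIBRARY.values())
    out = []
    for name in subset:
        if name not in _LIBRARY:
            raise UnknownPhenotypeError(
                f"unknown phenotype {name!r}; known: {sorted(_LIBRARY)}"
            )
        out.append(_LIBRARY[name])
    return out


# --------------------------------------------------------------------------
# trace simulation
# --------------------------------------------------------------------------


@dataclass
class CellTrace:
    """One cell's multi-channel intensity series with metadata."""

    cell_id: int
    time: np.ndarray  # hours
    values: np.ndarray  # (3, T), channel order CHANNELS
    position: tuple[float, float] = (0.0, 0.0)  # μm
    site: str = "impact"


def simulate_trace(
    spec: PhenotypeSpec,
    time_grid: np.ndarray,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | None = None,
    cell_id: int = 0,
) -> CellTrace:
    """Noisy realisation of a phenotype's kinetics on ``time_grid`` (hours)."""
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time_grid must be non-empty")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    y = spec.mean_trace(t)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return CellTrace(cell_id=cell_id, time=t, values=np.clip(y, 0.0, None))


def long_term_time_grid(duration_h: float = 3.0, frame_interval_s: float = 12.0) -> np.ndarray:
    """Imaging timestamps in hours for the long-term protocol."""
    n = int(round(duration_h * 3600.0 / frame_interval_s))
    return np.arange(n) * frame_interval_s / 3600.0


# --------------------------------------------------------------------------
# impact-site calcium
# --------------------------------------------------------------------------


def impact_calcium_mean(
    sharpness: float, n_samples: int = 2400, duration_s: float = 60.0
) -> np.ndarray:
    """Noiseless impact calcium pulse parameterised by sharpness in [0, 1].

    A logistic rise followed by exponential decay. Sharpness moves the onset
    from ~17 s (broad) to ~1 s (sharp) and speeds the post-peak decay, so
    high sharpness gives an immediate peak with fast decay and sharpness 0
    gives a late, lower-amplitude plateau that barely decays within the
    minute. Both peak time and full width at half maximum shrink
    monotonically as sharpness grows.
    """
    if not 0.0 <= sharpness <= 1.0:
        raise ValueError("sharpness must lie in [0, 1]")
    t = np.linspace(0.0, duration_s, n_samples, endpoint=False)
    onset = 1.0 + (1.0 - sharpness) * 16.0  # seconds
    rise = 1.0 / (1.0 + np.exp(-1.5 * (t - onset)))
    decay_rate = 0.005 + 0.25 * sharpness  # 1/s
    decay = np.exp(-decay_rate * np.clip(t - onset, 0.0, None))
    amplitude = 0.4 + 0.6 * sharpness
    return amplitude * rise * decay


def simulate_impact_calcium(
    sharpness: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    n_samples: int = 2400,
    duration_s: float = 60.0,
) -> np.ndarray:
    """60 s × 40 fps calcium series for one impact-site cell."""
    y = impact_calcium_mean(sharpness, n_samples=n_samples, duration_s=duration_s)
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        y = np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, None)
    return y


# --------------------------------------------------------------------------
# spatial layout and dataset assembly
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    n_cells: int = 1200
    phenotype_names: tuple[str, ...] = tuple(_LIBRARY)
    phenotype_weights: tuple[float, ...] | None = None  # uniform if None
    noise_sd: float = DEFAULT_NOISE_SD
    duration_h: float = 3.0
    frame_interval_s: float = 12.0
    impact_duration_s: float = 60.0
    impact_rate_fps: float = 40.0
    field_um: float = 660.0
    field_px: int = 512
    impact_xy: tuple[float, float] = (330.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.duration_h, self.frame_interval_s, self.impact_duration_s) <= 0:
            raise ValueError("durations must be positive")
        w = self.weights()
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("phenotype_weights must sum to 1")

    def weights(self) -> np.ndarray:
        k = len(self.phenotype_names)
        if self.phenotype_weights is None:
            return np.full(k, 1.0 / k)
        w = np.asarray(self.phenotype_weights, dtype=float)
        if len(w) != k:
            raise ValueError("one weight per phenotype required")
        return w / w.sum() if abs(w.sum() - 1.0) <= 1e-9 else w


def place_cells(
    config: GeneratorConfig,
    specs: list[PhenotypeSpec],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions plus spatially biased phenotype assignment.

    Per-cell assignment probability is proportional to the global phenotype
    weight times that phenotype's spatial bias at the cell's distance to the
    impact point, renormalised per cell.
    """
    n = config.n_cells
    positions = rng.uniform(0.0, config.field_um, size=(n, 2))
    d = np.hypot(
        positions[:, 0] - config.impact_xy[0], positions[:, 1] - config.impact_xy[1]
    )
    w = config.weights()[: len(specs)]
    probs = np.stack([w[i] * specs[i].bias(d) for i in range(len(specs))], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    # vectorised categorical draw via inverse CDF
    cdf = np.cumsum(probs, axis=1)
    u = rng.uniform(size=n)
    labels = (u[:, None] > cdf).sum(axis=1)
    return positions, labels


@dataclass
class SyntheticDataset:
    """Generated traces, ground truth, layout, and impact calcium."""

    traces: list[CellTrace]
    labels: np.ndarray  # phenotype name per cell
    positions: np.ndarray  # (n, 2) μm
    impact_xy: tuple[float, float]
    impact_cell_ids: np.ndarray  # cells within IMPACT_RADIUS_UM of impact
    impact_calcium: np.ndarray  # (n_impact, n_samples)
    sharpness_truth: np.ndarray  # (n_impact,)
    config: GeneratorConfig | None = None

    @property
    def n_cells(self) -> int:
        return len(self.traces)

    def trace_array(self) -> np.ndarray:
        return np.stack([tr.values for tr in self.traces])

    def time_grid(self) -> np.ndarray:
        return self.traces[0].time


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full synthetic sample: layout, long-term traces, impact calcium.

    Death-phenotype cells at the impact site draw their peak sharpness from
    Beta(5, 2) (sharp, early peaks) and viable cells from Beta(2, 5) (broad
    plateaus), encoding the association between peracute calcium kinetics and
    eventual fate.
    """
    rng = np.random.default_rng(config.seed)
    specs = make_phenotype_library(list(config.phenotype_names))
    positions, label_idx = place_cells(config, specs, rng)
    t = long_term_time_grid(config.duration_h, config.frame_interval_s)

    traces = []
    for i in range(config.n_cells):
        traces.append(
            simulate_trace(
                specs[label_idx[i]], t, noise_sd=config.noise_sd, rng=rng, cell_id=i
            )
        )
        traces[-1].position = tuple(positions[i])

    d = np.hypot(positions[:, 0] - config.impact_xy[0], positions[:, 1] - config.impact_xy[1])
    impact_ids = np.flatnonzero(d <= IMPACT_RADIUS_UM)
    n_samples = int(round(config.impact_duration_s * config.impact_rate_fps))
    sharpness = np.empty(len(impact_ids))
    impact_ca = np.empty((len(impact_ids), n_samples))
    for j, ci in enumerate(impact_ids):
        dead = specs[label_idx[ci]].is_death
        sharpness[j] = rng.beta(5, 2) if dead else rng.beta(2, 5)
        impact_ca[j] = simulate_impact_calcium(
            sharpness[j],
            rng=rng,
            noise_sd=config.noise_sd,
            n_samples=n_samples,
            duration_s=config.impact_duration_s,
        )
        traces[ci].site = "impact_site"

    labels = np.array([specs[i].name for i in label_idx])
    return SyntheticDataset(
        traces=traces,
        labels=labels,
        positions=positions,
        impact_xy=config.impact_xy,
        impact_cell_ids=impact_ids,
        impact_calcium=impact_ca,
        sharpness_truth=sharpness,
        config=config,
    )


def sharpness_fate_cohort(
    n_cells: int = 400,
    slope: float = 6.0,
    midpoint: float = 0.5,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | None = None,
    null: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impact-site cohort linking peak sharpness to cell fate.

    Sharpness is uniform on [0, 1]; the death label is Bernoulli with
    probability logistic in sharpness (``slope``, ``midpoint``). With
    ``null=True`` the label is instead an independent fair coin, giving a
    matched null for calibration studies.

    Returns ``(sharpness, traces, dead)`` with traces of shape (n, 2400).
    """
    rng = rng or np.random.default_rng()
    sharp = rng.uniform(size=n_cells)
    if null:
        dead = rng.uniform(size=n_cells) < 0.5
    else:
        p = 1.0 / (1.0 + np.exp(-slope * (sharp - midpoint)))
        dead = rng.uniform(size=n_cells) < p
    traces = np.stack(
        [simulate_impact_calcium(s, rng=rng, noise_sd=noise_sd) for s in sharp]
    )
    return sharp, traces, dead


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------


def render_frame(
    dataset: SyntheticDataset,
    t: float,
    background_field: np.ndarray | float = 0.0,
    psf_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    channel: int = 0,
) -> np.ndarray:
    """Render one channel of the field at time ``t`` (hours) as a 512×512 image.

    Each cell contributes an isotropic Gaussian blob whose integrated
    intensity equals its channel value at ``t``; the background is piecewise
    constant on the 8×8 subset grid.
    """
    cfg = dataset.config or GeneratorConfig()
    time = dataset.time_grid() if dataset.traces else np.array([0.0])
    if dataset.traces and not (time[0] <= t <= time[-1]):
        raise ValueError(f"t={t} outside imaging window [{time[0]}, {time[-1]}]")
    npx = cfg.field_px
    bg = np.asarray(background_field, dtype=float)
    if bg.ndim == 0:
        image = np.full((npx, npx), float(bg))
    else:
        if bg.shape != (8, 8):
            raise ValueError("background_field must be scalar or 8×8")
        image = np.kron(bg, np.ones((npx // 8, npx // 8)))

    scale = npx / cfg.field_um  # px per μm
    half = int(np.ceil(4 * psf_sd))
    offsets = np.arange(-half, half + 1)
    for tr in dataset.traces:
        intensity = float(np.interp(t, tr.time, tr.values[channel]))
        cx, cy = tr.position[0] * scale, tr.position[1] * scale
        ix, iy = int(round(cx)), int(round(cy))
        gx = np.exp(-((offsets + ix - cx) ** 2) / (2 * psf_sd**2))
        gy = np.exp(-((offsets + iy - cy) ** 2) / (2 * psf_sd**2))
        blob = np.outer(gy, gx)
        blob *= intensity / (2 * np.pi * psf_sd**2)
        x0, x1 = ix - half, ix + half + 1
        y0, y1 = iy - half, iy + half + 1
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = blob.shape[1] - max(0, x1 - npx)
        sy1 = blob.shape[0] - max(0, y1 - npx)
        if sx1 <= sx0 or sy1 <= sy0:
            continue
        image[max(0, y0) : min(npx, y1), max(0, x0) : min(npx, x1)] += blob[
            sy0:sy1, sx0:sx1
        ]
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return np.clip(image, 0.0, None)
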