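"""Synthetic ground-truth generator for the replication-dynamics pipeline.

No imaging data are deposited with the source study, so every downstream
stage is exercised against simulated nuclei, time-lapse tracks and population
tables whose statistical structure matches the assumptions of the analysis:

* tetraploid nuclei carrying four heterochromatic X blocks, two of the
  facultative type (X*, macroH2A/H3K27me3) and two of the constitutive type
  (X, HP1/H3K9me3), rendered as ellipsoids inside an ellipsoidal nucleus;
* block-restricted PTM enrichment/depletion with a hyperacetylation effect
  under HDAC inhibition;
* the three PCNA replication-foci patterns of early / mid / late S-phase;
* EdU intensity proportional to per-cell fork speed times PCNA;
* integrated DAPI intensities forming G1 and G2 peaks with S-phase cells in
  between, pattern labels consistent with DNA content.

The generator's defaults are the measured study conditions: substage
durations 3.4/3.5/2.5 h (untreated) and 5.1/4.4/3.1 h (HDACi-treated), block
replication windows 1.9/1.8 h -> 2.7/2.2 h, cumulative genome-content
boundaries (0.37, 0.75) -> (0.50, 0.74), and relative fork-speed multipliers
1.0 / 1.4 / 0.9 / 0.84.  Every random draw flows from a single seed, and
identical (config, seed) pairs reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .types import CellTrack, ConfigurationError, ImageStack, RegionMask

__all__ = [
    "ImageGeometry",
    "GroundTruthConfig",
    "SyntheticCell",
    "gen_nucleus_image",
    "gen_timelapse_tracks",
    "gen_population_table",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation `cv`."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class ImageGeometry:
    """Rendering geometry for one synthetic nucleus.

    Blocks are ellipsoids with hard boundaries (no chromatin texture): the
    mask-based pipeline only needs compartment-level contrast.  Positions are
    fractions of the nuclear semi-axes; the two X* blocks sit on one diagonal,
    the two X blocks on the other.
    """

    shape: tuple[int, int, int] = (5, 96, 96)
    nucleus_semiaxes: tuple[float, float, float] = (2.2, 32.0, 40.0)
    block_radius_px: float = 7.0
    block_z_semiaxis: float = 1.2
    block_offset_frac: float = 0.5  # block centres at this fraction of the semi-axes
    voxel_size_um: tuple[float, float, float] = (0.3, 0.112, 0.112)
    background: float = 10.0
    dapi_nucleus: float = 100.0
    dapi_block_factor: float = 1.1
    marker_nucleus: float = 20.0
    marker_block: float = 140.0
    pcna_amplitude: float = 150.0
    n_early_foci: int = 150
    n_mid_rim_foci: int = 40
    n_late_extra_foci: int = 8
    focus_radius_px: float = 2.0
    rim_inner_frac: float = 0.85  # radial band holding mid-S perinuclear foci
    rim_outer_frac: float = 0.96


# Relative fork-speed multipliers; untreated early S is the reference (1.0).
_DEFAULT_SPEEDS = {
    "untreated_early": 1.0,
    "untreated_midlate": 1.4,
    "treated_early": 0.9,
    "treated_midlate": 0.84,
}

# Mean PTM intensity per compartment (a.u.), per histone mark and condition.
# Acetylation marks are depleted from both block types in untreated cells and
# rise under HDACi; methylation marks are block-specific and drop under HDACi.
_DEFAULT_PTM = {
    "untreated": {
        "H3K9ac": {"euchromatin": 100.0, "xstar": 10.0, "x": 10.0},
        "H4K8ac": {"euchromatin": 100.0, "xstar": 14.0, "x": 10.0},
        "H3K27me3": {"euchromatin": 20.0, "xstar": 120.0, "x": 20.0},
        "H3K9me3": {"euchromatin": 20.0, "xstar": 20.0, "x": 120.0},
    },
    "treated": {
        "H3K9ac": {"euchromatin": 150.0, "xstar": 40.0, "x": 40.0},
        "H4K8ac": {"euchromatin": 150.0, "xstar": 50.0, "x": 40.0},
        "H3K27me3": {"euchromatin": 15.0, "xstar": 80.0, "x": 15.0},
        "H3K9me3": {"euchromatin": 15.0, "xstar": 15.0, "x": 80.0},
    },
}

# Nascent-transcription (EU) means: constitutive blocks transcribe the repeat
# at a higher rate than facultative blocks.
_DEFAULT_EU = {"euchromatin": 80.0, "xstar": 100.0, "x": 120.0}

_DEFAULT_PROPORTIONS = {"G1": 0.30, "early": 0.13, "mid": 0.13, "late": 0.09, "G2": 0.35}

_S_LABELS = ("early", "mid", "late")


@dataclass
class GroundTruthConfig:
    """Generator parameters with full ground-truth bookkeeping.

    Durations are hours, the frame interval minutes.  ``content_boundaries``
    are cumulative genome fractions replicated at the end of early and mid
    S-phase.  ``block_durations_h`` is the (X*, X) pair; the X* window lies
    inside mid S and the X window inside late S, so each must fit its host
    substage.
    """

    condition: str = "untreated"
    n_cells: int = 100
    seed: int = 0
    frame_interval_min: float = 20.0
    substage_durations_h: tuple[float, float, float] = (3.4, 3.5, 2.5)
    block_durations_h: tuple[float, float] = (1.9, 1.8)
    content_boundaries: tuple[float, float] = (0.37, 0.75)
    speed_multipliers: dict = field(default_factory=lambda: dict(_DEFAULT_SPEEDS))
    phase_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    ptm_levels: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_PTM["untreated"].items()}
    )
    eu_levels: dict = field(default_factory=lambda: dict(_DEFAULT_EU))
    dapi_base_g1: float = 1000.0
    pcna_base_total: float = 1000.0
    dapi_cv: float = 0.02
    intensity_cv: float = 0.2
    image_noise_sigma: float = 5.0
    duration_jitter_cv: float = 0.0
    censoring_rate: float = 0.0
    pad_frames: int = 2
    geometry: ImageGeometry = field(default_factory=ImageGeometry)

    def __post_init__(self) -> None:
        e, m, l = self.substage_durations_h
        if min(e, m, l) <= 0:
            raise ConfigurationError("substage durations must all be positive")
        bxs, bx = self.block_durations_h
        if bxs <= 0 or bx <= 0:
            raise ConfigurationError("block durations must be positive")
        if bxs > m + 1e-12:
            raise ConfigurationError(f"X* block window ({bxs} h) exceeds mid S ({m} h)")
        if bx > l + 1e-12:
            raise ConfigurationError(f"X block window ({bx} h) exceeds late S ({l} h)")
        b1, b2 = self.content_boundaries
        if not (0.0 < b1 < b2 < 1.0):
            raise ConfigurationError("content boundaries must be strictly increasing in (0, 1)")
        if any(v <= 0 for v in self.speed_multipliers.values()):
            raise ConfigurationError("speed multipliers must be positive")
        if self.speed_multipliers.get("untreated_early") != 1.0:
            raise ConfigurationError("untreated_early speed is the reference and must be 1.0")
        total_p = sum(self.phase_proportions.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ConfigurationError(f"phase proportions sum to {total_p}, expected 1")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring rate must lie in [0, 1]")
        if self.frame_interval_min <= 0:
            raise ConfigurationError("frame interval must be positive")

    # -- condition factories: the measured study conditions ----------------

    @classmethod
    def untreated(cls, **overrides) -> "GroundTruthConfig":
        """Untreated (DMSO control) cells."""
        return cls(**overrides)

    @classmethod
    def treated(cls, **overrides) -> "GroundTruthConfig":
        """HDACi (panobinostat)-treated, globally hyperacetylated cells."""
        params = dict(
            condition="treated",
            substage_durations_h=(5.1, 4.4, 3.1),
            block_durations_h=(2.7, 2.2),
            content_boundaries=(0.50, 0.74),
            ptm_levels={m: dict(v) for m, v in _DEFAULT_PTM["treated"].items()},
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def hbo1_targeted(cls, **overrides) -> "GroundTruthConfig":
        """HAT (HBO1) targeted to the constitutive X block.

        Only the X block window is reported for this condition (3.2 h, up
        from 1.8 h); X* and early/mid S keep untreated values.  Late S is
        extended to 3.4 h so the longer X window fits its host substage,
        since no substage durations were measured under targeting.
        """
        params = dict(
            condition="hbo1_targeted",
            substage_durations_h=(3.4, 3.5, 3.4),
            block_durations_h=(1.9, 3.2),
            speed_multipliers={**_DEFAULT_SPEEDS,
                               "hbo1_targeted_early": 1.0,
                               "hbo1_targeted_midlate": 1.4},
        )
        params.update(overrides)
        return cls(**params)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = ImageGeometry(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["geometry"].items()
            })
        for key in ("substage_durations_h", "block_durations_h", "content_boundaries"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def speed_for(self, phase: str) -> float:
        """Relative fork speed for a cell of this condition in `phase`."""
        if phase not in _S_LABELS:
            return 0.0
        group = "early" if phase == "early" else "midlate"
        key = f"{self.condition}_{group}"
        try:
            return float(self.speed_multipliers[key])
        except KeyError:
            raise ConfigurationError(f"no speed multiplier for {key!r}") from None


@dataclass
class SyntheticCell:
    """Ground truth for one simulated cell."""

    cell_id: str
    condition: str
    true_pattern: str  # nonS | early | mid | late
    true_content: float = 1.0  # G1 equivalents, in [1, 2]
    true_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.true_pattern not in ("nonS",) + _S_LABELS:
            raise ConfigurationError(f"unknown pattern {self.true_pattern!r}")
        if not 1.0 <= self.true_content <= 2.0:
            raise ConfigurationError("true_content must lie in [1, 2]")
        if self.true_pattern in _S_LABELS and not 1.0 < self.true_content < 2.0:
            raise ConfigurationError("S-phase cells need content strictly inside (1, 2)")


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _block_centers(geom: ImageGeometry) -> list[tuple[str, tuple[float, float, float]]]:
    nz, ny, nx = geom.shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    _, ay, ax = geom.nucleus_semiaxes
    dy = geom.block_offset_frac * ay
    dx = geom.block_offset_frac * ax
    # X* on the main diagonal, X on the anti-diagonal
    return [
        ("block_Xstar", (cz, cy - dy, cx - dx)),
        ("block_Xstar", (cz, cy + dy, cx + dx)),
        ("block_X", (cz, cy - dy, cx + dx)),
        ("block_X", (cz, cy + dy, cx - dx)),
    ]


def _ground_truth_masks(geom: ImageGeometry) -> tuple[RegionMask, list[RegionMask]]:
    nz, ny, nx = geom.shape
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    az, ay, ax = geom.nucleus_semiaxes
    if ay >= (ny - 1) / 2.0 or ax >= (nx - 1) / 2.0:
        raise ConfigurationError("nucleus does not fit inside the image")
    nucleus = _ellipsoid(geom.shape, center, geom.nucleus_semiaxes)
    blocks: list[RegionMask] = []
    r = geom.block_radius_px
    for kind, c in _block_centers(geom):
        # block must sit fully inside the nucleus with a small margin
        rel = ((c[1] - center[1]) / ay) ** 2 + ((c[2] - center[2]) / ax) ** 2
        if np.sqrt(rel) + r / min(ay, ax) >= 1.0:
            raise ConfigurationError("block geometry overflows the nucleus")
        m = _ellipsoid(geom.shape, c, (geom.block_z_semiaxis, r, r))
        blocks.append(RegionMask(m & nucleus, kind=kind, source="ground_truth"))
    if len(blocks) != 4:
        raise ConfigurationError("exactly four heterochromatic blocks are required")
    for i in range(4):
        for j in range(i + 1, 4):
            if np.any(blocks[i].mask & blocks[j].mask):
                raise ConfigurationError("block masks overlap")
    return RegionMask(nucleus, kind="nucleus", source="ground_truth"), blocks


def _paint_disks(img: np.ndarray, centers: np.ndarray, radius: float, amplitude: float) -> None:
    """Add hard in-plane disks of `radius` at integer (z, y, x) centres."""
    ny, nx = img.shape[1:]
    yy, xx = np.ogrid[:ny, :nx]
    for z, y, x in centers:
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= radius * radius
        plane = img[int(z)]
        plane[disk] = np.maximum(plane[disk], amplitude)


def _sample_voxels(rng: np.random.Generator, allowed: np.ndarray, n: int) -> np.ndarray:
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        raise ConfigurationError("no voxels available to place replication foci")
    chosen = rng.choice(idx, size=min(n, idx.size), replace=False)
    return np.column_stack(np.unravel_index(chosen, allowed.shape))


def _render_pcna(rng, geom: ImageGeometry, pattern: str,
                 nucleus: RegionMask, blocks: list[RegionMask]) -> np.ndarray:
    """Render the PCNA channel for one S-phase pattern (no noise).

    early: many small foci dispersed through the nucleus, strictly outside the
    heterochromatic blocks; mid: perinuclear rim foci plus blobs filling the
    X* blocks; late: large blobs filling the X blocks plus a few large rim
    foci; nonS: dark.
    """
    img = np.zeros(geom.shape, dtype=float)
    if pattern == "nonS":
        return img
    from scipy import ndimage

    xstar = np.zeros(geom.shape, bool)
    x_blk = np.zeros(geom.shape, bool)
    for b in blocks:
        (xstar if b.kind == "block_Xstar" else x_blk)[b.mask] = True
    all_blocks = xstar | x_blk
    margin = int(np.ceil(geom.focus_radius_px)) + 1
    near_blocks = ndimage.binary_dilation(all_blocks, iterations=margin)

    nz, ny, nx = geom.shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    _, ay, ax = geom.nucleus_semiaxes
    yy, xx = np.indices((ny, nx), dtype=float)[0], np.indices((ny, nx), dtype=float)[1]
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    rim2d = (rho >= geom.rim_inner_frac) & (rho <= geom.rim_outer_frac)
    rim = np.zeros(geom.shape, bool)
    rim[int(cz)] = rim2d  # rim foci live on the mid-nuclear plane

    amp = geom.pcna_amplitude
    if pattern == "early":
        allowed = nucleus.mask & ~near_blocks
        centers = _sample_voxels(rng, allowed, geom.n_early_foci)
        _paint_disks(img, centers, geom.focus_radius_px, amp)
        img[all_blocks] = 0.0  # foci never invade unreplicated heterochromatin
    elif pattern == "mid":
        centers = _sample_voxels(rng, rim & ~near_blocks, geom.n_mid_rim_foci)
        _paint_disks(img, centers, geom.focus_radius_px, amp)
        img[xstar] = amp  # replication blobs on the facultative blocks
    elif pattern == "late":
        centers = _sample_voxels(rng, rim & ~near_blocks, geom.n_late_extra_foci)
        _paint_disks(img, centers, geom.focus_radius_px * 1.8, amp)
        img[x_blk] = amp  # large blobs on the constitutive blocks
    else:
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    return img


def gen_nucleus_image(config: GroundTruthConfig, cell: SyntheticCell,
                      seed: int | None = None) -> tuple[ImageStack, dict]:
    """Render one synthetic nucleus and its ground-truth masks.

    Returns ``(stack, truth)`` where ``truth`` has keys ``"nucleus"`` (one
    :class:`RegionMask`) and ``"blocks"`` (four disjoint block masks, two of
    each type, all inside the nucleus).

    Channels rendered: DAPI, one ``PTM:<mark>`` channel per configured mark,
    ``marker:macroH2A`` / ``marker:HP1`` block markers, EU, PCNA (per the
    cell's true pattern) and EdU = true_speed x PCNA.  Additive Gaussian
    voxel noise of ``config.image_noise_sigma`` is applied to every channel
    and intensities are clipped at zero.
    """
    geom = config.geometry
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nucleus, blocks = _ground_truth_masks(geom)
    xstar = np.zeros(geom.shape, bool)
    x_blk = np.zeros(geom.shape, bool)
    for b in blocks:
        (xstar if b.kind == "block_Xstar" else x_blk)[b.mask] = True
    eu_chrom = nucleus.mask & ~(xstar | x_blk)

    def compartments(levels: dict, base: float | None = None) -> np.ndarray:
        img = np.full(geom.shape, geom.background, dtype=float)
        img[eu_chrom] = levels["euchromatin"] if base is None else base
        img[xstar] = levels["xstar"]
        img[x_blk] = levels["x"]
        return img

    channels: dict[str, np.ndarray] = {}
    dapi = np.full(geom.shape, geom.background, dtype=float)
    dapi[nucleus.mask] = geom.dapi_nucleus
    dapi[xstar | x_blk] = geom.dapi_nucleus * geom.dapi_block_factor
    channels["DAPI"] = dapi

    for mark, levels in config.ptm_levels.items():
        channels[f"PTM:{mark}"] = compartments(levels)
    channels["EU"] = compartments(config.eu_levels)

    for role, region in (("marker:macroH2A", xstar), ("marker:HP1", x_blk)):
        img = np.full(geom.shape, geom.background, dtype=float)
        img[nucleus.mask] = geom.marker_nucleus
        img[region] = geom.marker_block
        channels[role] = img

    pcna = _render_pcna(rng, geom, cell.true_pattern, nucleus, blocks)
    channels["PCNA"] = pcna
    channels["EdU"] = cell.true_speed * pcna

    if config.image_noise_sigma > 0:
        for role in channels:
            noisy = channels[role] + rng.normal(0.0, config.image_noise_sigma,
                                                size=geom.shape)
            channels[role] = np.clip(noisy, 0.0, None)

    stack = ImageStack(channels, spacing_um=geom.voxel_size_um)
    return stack, {"nucleus": nucleus, "blocks": blocks}


# ---------------------------------------------------------------------------
# time-lapse tracks
# ---------------------------------------------------------------------------


def gen_timelapse_tracks(config: GroundTruthConfig, n_cells: int | None = None,
                         seed: int | None = None,
                         offsets: np.ndarray | None = None) -> list[CellTrack]:
    """Simulate per-cell 20-min time-lapse tracks through S-phase.

    Each cell enters S-phase at a uniformly random phase offset relative to
    the frame grid (mirroring an asynchronous culture), traverses
    nonS -> early -> mid -> late -> nonS with the configured durations
    (optionally jittered per cell by a unit-mean lognormal with CV
    ``duration_jitter_cv``), and raises the X*/X block-replication flags for
    contiguous windows placed uniformly at random inside mid and late S.

    A fraction ``censoring_rate`` of tracks is truncated so that S-phase
    entry or exit falls outside the observation window; these carry
    ``censored=True``.  Explicit `offsets` (minutes, one per cell) can be
    supplied for deterministic tests.
    """
    n = config.n_cells if n_cells is None else int(n_cells)
    if n < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = config.frame_interval_min
    tracks: list[CellTrack] = []
    for i in range(n):
        jit = _lognormal_factor(rng, config.duration_jitter_cv, size=3)
        durs = np.asarray(config.substage_durations_h, float) * 60.0 * np.asarray(jit)
        e, m, l = durs
        bxs = config.block_durations_h[0] * 60.0 * jit[1]  # scales with its host (mid)
        bx = config.block_durations_h[1] * 60.0 * jit[2]  # scales with late
        phi = float(offsets[i]) if offsets is not None else float(rng.uniform(0.0, dt))
        t_s = config.pad_frames * dt + phi
        bounds = np.cumsum([t_s, e, m, l])  # S start, early|mid, mid|late, S end
        xs_start = bounds[1] + rng.uniform(0.0, max(m - bxs, 0.0))
        x_start = bounds[2] + rng.uniform(0.0, max(l - bx, 0.0))

        n_frames = int(np.ceil((bounds[3] + config.pad_frames * dt) / dt)) + 1
        times = np.arange(n_frames) * dt
        labels = np.full(n_frames, "nonS", dtype=object)
        labels[(times >= bounds[0]) & (times < bounds[1])] = "early"
        labels[(times >= bounds[1]) & (times < bounds[2])] = "mid"
        labels[(times >= bounds[2]) & (times < bounds[3])] = "late"
        xs_flags = (times >= xs_start) & (times < xs_start + bxs)
        x_flags = (times >= x_start) & (times < x_start + bx)

        censored = bool(rng.uniform() < config.censoring_rate)
        lo, hi = 0, n_frames
        if censored:
            cut = rng.uniform(bounds[0], bounds[3])
            if rng.uniform() < 0.5:  # cell already in S at the start of imaging
                lo = int(np.searchsorted(times, cut))
            else:  # imaging ends before the cell exits S
                hi = int(np.searchsorted(times, cut))
            lo, hi = min(lo, n_frames - 1), max(hi, lo + 1)
        tracks.append(CellTrack(
            cell_id=f"cell_{i:04d}",
            condition=config.condition,
            times_min=times[lo:hi] - times[lo],
            labels=list(labels[lo:hi]),
            xstar_flags=xs_flags[lo:hi],
            x_flags=x_flags[lo:hi],
            interval_min=dt,
            censored=censored,
        ))
    return tracks


# ---------------------------------------------------------------------------
# population tables
# ---------------------------------------------------------------------------

POPULATION_COLUMNS = [
    "cell_id", "replicate", "condition", "phase", "pattern",
    "true_content", "true_speed", "dapi_integrated", "pcna_total", "edu_total",
]


def gen_population_table(config: GroundTruthConfig, n_cells: int | None = None,
                         seed: int | None = None, replicate: int = 1) -> pd.DataFrame:
    """Simulate a fixed-cell population table (one row per nucleus).

    Phases are drawn with the configured proportions.  DNA content in G1
    equivalents is 1.0 for G1, 2.0 for G2, and uniform within the substage
    content band for S cells: early in (1, 1+b1), mid in (1+b1, 1+b2), late
    in (1+b2, 2) with (b1, b2) = ``content_boundaries``.  Integrated DAPI is
    ``dapi_base_g1 x content`` with multiplicative lognormal noise of CV
    ``dapi_cv``; PCNA totals are drawn for S cells only and
    EdU = speed multiplier x PCNA x lognormal(CV ``intensity_cv``).
    """
    n = config.n_cells if n_cells is None else int(n_cells)
    if n < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    phases = list(config.phase_proportions)
    probs = np.array([config.phase_proportions[p] for p in phases], float)
    drawn = rng.choice(len(phases), size=n, p=probs / probs.sum())

    b1, b2 = config.content_boundaries
    bands = {"G1": (1.0, 1.0), "early": (1.0, 1.0 + b1), "mid": (1.0 + b1, 1.0 + b2),
             "late": (1.0 + b2, 2.0), "G2": (2.0, 2.0)}
    rows = []
    for i, k in enumerate(drawn):
        phase = phases[k]
        lo, hi = bands[phase]
        content = lo if lo == hi else float(rng.uniform(lo, hi))
        speed = config.speed_for(phase)
        dapi = config.dapi_base_g1 * content * _lognormal_factor(rng, config.dapi_cv)
        if phase in _S_LABELS:
            pcna = config.pcna_base_total * _lognormal_factor(rng, config.intensity_cv)
            edu = speed * pcna * _lognormal_factor(rng, config.intensity_cv)
        else:
            pcna, edu = 0.0, 0.0
        rows.append((f"cell_{i:05d}", replicate, config.condition, phase,
                     phase if phase in _S_LABELS else "nonS",
                     content, speed, float(dapi), float(pcna), float(edu)))
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)
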