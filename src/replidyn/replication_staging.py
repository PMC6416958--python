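"""S-phase pattern classification and frame-counting duration estimation.

Replicating nuclei show three successive PCNA replication-foci patterns:

* **early** — many small foci dispersed through the nuclear interior
  (euchromatin replicating);
* **mid** — foci organised at the nuclear periphery, with the first large
  blob on the facultative (X*) heterochromatic block;
* **late** — large blobs on the constitutive (X) heterochromatic blocks.

A frame is classified from a single max-projected PCNA image by a fixed
decision rule on mask overlaps and a perinuclear enrichment score; time-lapse
tracks sampled every 20 min are then converted to total, substage and
block-replication durations by counting labelled frames.  With a uniform
S-phase entry phase relative to the frame grid, the counting estimator of a
duration is unbiased.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .reporting_stats import welch_t
from .types import CellTrack, RegionMask

__all__ = [
    "StagingThresholds",
    "SPhasePattern",
    "classify_pattern",
    "durations_from_track",
    "summarize_durations",
    "DURATION_QUANTITIES",
]

DURATION_QUANTITIES = ("total", "early", "mid", "late", "Xstar", "X")

_GRAMMAR = re.compile(r"^n*e+m+l+n*$")
_ABBREV = {"nonS": "n", "early": "e", "mid": "m", "late": "l"}


@dataclass
class StagingThresholds:
    """Decision thresholds of the pattern classifier.

    The source protocol describes the patterns only qualitatively; these
    defaults were fixed on the synthetic generator and are fully
    configurable.  ``f_min`` is the minimum PCNA-positive fraction of the
    nucleus for a cell to count as S-phase; ``o_mid`` / ``o_late`` are the
    minimum fractions of block voxels that must be PCNA-positive to call the
    block replicating; ``p_mid`` is the minimum fraction of foci inside the
    outer ``shell_frac`` radial shell for the perinuclear (mid) pattern.
    """

    f_min: float = 0.005
    o_mid: float = 0.20
    o_late: float = 0.20
    p_mid: float = 0.5
    shell_frac: float = 0.15
    bg_k: float = 5.0  # PCNA-positive = above background median + k*MAD-sigma
    min_focus_px: int = 3


@dataclass
class SPhasePattern:
    """Classification of one frame: label plus the feature vector behind it."""

    label: str
    n_foci: int = 0
    focus_median_px: float = 0.0
    perinuclear_score: float = float("nan")
    xstar_overlap: float = 0.0
    x_overlap: float = 0.0
    positive_fraction: float = 0.0
    degraded: bool = False  # classified without block masks


def _max_project(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img.max(axis=0) if img.ndim == 3 else img


def _flatten_mask(mask: RegionMask | np.ndarray) -> np.ndarray:
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    return m.any(axis=0) if m.ndim == 3 else m


def classify_pattern(pcna: np.ndarray, nucleus_mask: RegionMask | np.ndarray,
                     block_masks: list[RegionMask] | None = None,
                     thresholds: StagingThresholds | None = None) -> SPhasePattern:
    """Classify one PCNA frame as nonS / early / mid / late.

    3D input is max-projected first.  PCNA-positive pixels are those above
    the extra-nuclear background (median + ``bg_k`` robust sigma); foci are
    connected positive components of at least ``min_focus_px`` pixels inside
    the nucleus.  Decision rule, in order: nonS if the positive fraction of
    the nucleus is below ``f_min``; late if the X-block overlap reaches
    ``o_late`` (large blobs on constitutive heterochromatin are the terminal
    pattern, so a frame with both block overlaps high is late); mid if the
    X*-overlap reaches ``o_mid`` or the perinuclear score reaches ``p_mid``;
    early otherwise.

    Without block masks the classifier runs in a degraded mode on focus size
    and perinuclear enrichment alone (flagged on the result).
    """
    thr = thresholds or StagingThresholds()
    img = _max_project(pcna)
    nuc = _flatten_mask(nucleus_mask)
    if img.shape != nuc.shape:
        raise ValueError("PCNA image and nucleus mask dimensions differ")
    degraded = not block_masks
    if degraded:
        warnings.warn("no block masks; classifying by focus size and perinuclear "
                      "enrichment only", stacklevel=2)

    outside = ~nuc
    bg = img[outside]
    if bg.size:
        med = np.median(bg)
        sigma = 1.4826 * np.median(np.abs(bg - med))
        cut = med + thr.bg_k * max(sigma, 1e-12)
    else:
        cut = float(np.percentile(img, 99)) * 0.5
    positive = (img > cut) & nuc

    n_nuc = int(nuc.sum())
    pos_frac = positive.sum() / n_nuc if n_nuc else 0.0
    feat = SPhasePattern(label="nonS", positive_fraction=float(pos_frac),
                         degraded=degraded)
    if pos_frac < thr.f_min:
        return feat

    labels = measure.label(positive)
    props = [p for p in measure.regionprops(labels) if p.area >= thr.min_focus_px]
    feat.n_foci = len(props)
    feat.focus_median_px = float(np.median([p.area for p in props])) if props else 0.0

    # perinuclear enrichment: fraction of PCNA-positive pixels in the outer
    # radial shell of the nucleus, measured on its distance transform
    # (pixel-weighted rather than per-focus: merged foci keep it stable)
    edt = ndimage.distance_transform_edt(nuc)
    d_max = edt.max()
    n_pos = int(positive.sum())
    if n_pos and d_max > 0:
        shell = edt <= thr.shell_frac * d_max
        feat.perinuclear_score = float((positive & shell & nuc).sum() / n_pos)

    if not degraded:
        xs = np.zeros_like(nuc)
        xb = np.zeros_like(nuc)
        for b in block_masks:
            flat = _flatten_mask(b)
            if b.kind == "block_Xstar":
                xs |= flat
            elif b.kind == "block_X":
                xb |= flat
        feat.xstar_overlap = float((positive & xs).sum() / max(xs.sum(), 1))
        feat.x_overlap = float((positive & xb).sum() / max(xb.sum(), 1))
        if feat.x_overlap >= thr.o_late:
            feat.label = "late"
        elif feat.xstar_overlap >= thr.o_mid or (
                not np.isnan(feat.perinuclear_score)
                and feat.perinuclear_score >= thr.p_mid):
            feat.label = "mid"
        else:
            feat.label = "early"
    else:
        # degraded: large foci -> late, perinuclear -> mid, else early
        if feat.focus_median_px >= 8 * thr.min_focus_px:
            feat.label = "late"
        elif not np.isnan(feat.perinuclear_score) and feat.perinuclear_score >= thr.p_mid:
            feat.label = "mid"
        else:
            feat.label = "early"
    return feat


class TrackExcluded(ValueError):
    """Track cannot contribute a duration (censored or grammar violation)."""


def _check_grammar(track: CellTrack) -> None:
    seq = "".join(_ABBREV[lab] for lab in track.labels)
    if not _GRAMMAR.match(seq):
        raise TrackExcluded(f"{track.cell_id}: label sequence {seq!r} violates "
                            "nonS* early+ mid+ late+ nonS*")


def durations_from_track(track: CellTrack) -> dict[str, float]:
    """Per-cell durations (hours) by frame counting.

    ``duration = (frames with the label or flag) x frame interval``; total is
    the sum of the three substages, exactly, by construction.  Censored
    tracks (flagged, or lacking a nonS frame before the first early frame or
    after the last late frame) and grammar-violating tracks raise
    :class:`TrackExcluded` with the reason.  Block durations additionally
    require the flagged window to start and end inside the track.
    """
    if track.censored:
        raise TrackExcluded(f"{track.cell_id}: censored")
    _check_grammar(track)
    if track.labels[0] != "nonS" or track.labels[-1] != "nonS":
        raise TrackExcluded(f"{track.cell_id}: S-phase entry or exit outside "
                            "the observation window")
    h_per_frame = track.interval_min / 60.0
    out = {q: track.count(q) * h_per_frame for q in ("early", "mid", "late")}
    out["total"] = out["early"] + out["mid"] + out["late"]
    for name, flags in (("Xstar", track.xstar_flags), ("X", track.x_flags)):
        if flags.any() and (flags[0] or flags[-1]):
            raise TrackExcluded(f"{track.cell_id}: {name} window truncated by track")
        out[name] = float(flags.sum()) * h_per_frame
    return out


def collect_durations(tracks: list[CellTrack]) -> pd.DataFrame:
    """Per-cell duration table over all usable tracks (excluded tracks logged)."""
    rows, excluded = [], 0
    for t in tracks:
        try:
            d = durations_from_track(t)
        except TrackExcluded:
            excluded += 1
            continue
        rows.append({"cell_id": t.cell_id, "condition": t.condition, **d})
    if excluded:
        warnings.warn(f"excluded {excluded}/{len(tracks)} tracks "
                      "(censored or grammar violations)", stacklevel=2)
    if not rows:
        raise ValueError("no usable tracks")
    return pd.DataFrame(rows)


def summarize_durations(tracks: list[CellTrack]) -> tuple[pd.DataFrame, dict]:
    """Duration estimates per condition plus between-condition Welch t-tests.

    Returns ``(summary, tests)``: `summary` has one row per (condition,
    quantity) with mean, SD and n; `tests` maps each quantity to the Welch
    t-test between the two conditions (only when exactly two conditions with
    >= 2 cells each are present).
    """
    per_cell = collect_durations(tracks)
    records = []
    for (cond, q), grp in (
        per_cell.melt(id_vars=["cell_id", "condition"], var_name="quantity",
                      value_name="hours")
        .groupby(["condition", "quantity"], sort=False)
    ):
        records.append({"condition": cond, "quantity": q,
                        "mean_h": grp["hours"].mean(), "sd_h": grp["hours"].std(ddof=1),
                        "n": len(grp)})
    summary = pd.DataFrame(records)
    tests: dict[str, object] = {}
    conds = list(per_cell["condition"].unique())
    if len(conds) == 2:
        a, b = conds
        for q in DURATION_QUANTITIES:
            if q not in per_cell:
                continue
            va = per_cell.loc[per_cell.condition == a, q].to_numpy()
            vb = per_cell.loc[per_cell.condition == b, q].to_numpy()
            if len(va) >= 2 and len(vb) >= 2:
                tests[q] = welch_t(va, vb)
    return summary, tests
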