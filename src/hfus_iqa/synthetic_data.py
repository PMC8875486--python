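"""Synthetic HFUS-like frames and simulated expert annotators.

The generator emulates the *statistical* structure of a facial-skin HFUS
quality-assessment dataset, not the physics: a correct B-mode frame is a
bright entry-echo band over speckled dermis layers, and the incorrect
classes reproduce the documented failure modes (probe not adhered / empty
frame, low contrast, disturbed geometry, acoustic shadowing).  Speckle is
multiplicative gamma noise, the standard stand-in for fully developed
ultrasound speckle.

Three annotators are simulated with a boundary-weighted flip-noise model:
each frame has a latent quality q in [0, 1], the nominal label is 'ok' iff
q >= 0.5, and annotator i flips it with probability
``flip_rate_i * b(q)`` where ``b(q) = (1 - |2q - 1|)**4`` peaks at the
decision boundary — frames near the boundary are the ambiguous ones, clearly
good or clearly bad frames are labeled unanimously.  Expert 1 and Expert 2
share one flip rate (they model the same person annotating twice) but use
independent randomness.

Default group proportions follow the published size of the four fused-label
groups in the public facial-skin HFUS dataset (17,425 frames:
8398 / 1261 / 1324 / 6442) and the observed ~15% expert-discordant share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .dataset_io import FRAME_SHAPE, AnnotationRow, FrameRecord, write_annotation_table
from .label_fusion import OK, NO_OK, AnnotationTriple, BinaryLabel, assign_group

__all__ = [
    "PUBLISHED_GROUP_SIZES",
    "PUBLISHED_SESSION_COUNTS",
    "SyntheticConfig",
    "SyntheticFrame",
    "FRAME_CLASSES",
    "boundary_weight",
    "generate_frame",
    "simulate_annotators",
    "generate_dataset",
]

#: Published per-group frame counts of the public facial-skin HFUS dataset
#: (group 1 = unanimous 'no ok' ... group 4 = unanimous 'ok').
PUBLISHED_GROUP_SIZES = {1: 8398, 2: 1261, 3: 1324, 4: 6442}

#: Published per-session frame counts of the same dataset (session ID = date).
PUBLISHED_SESSION_COUNTS = {"08032021": 4385, "15022021": 5840, "12042021": 4384, "07062021": 2816}

_TOTAL = sum(PUBLISHED_GROUP_SIZES.values())

#: The five emulated frame classes.
FRAME_CLASSES = ("correct", "no_contact", "low_contrast", "geometry_artifact", "shadow")

_INCORRECT_CLASSES = ("no_contact", "low_contrast", "geometry_artifact", "shadow")
_MILD_CLASSES = ("low_contrast", "geometry_artifact", "shadow")

_DEFAULT_SESSIONS = tuple(PUBLISHED_SESSION_COUNTS)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic dataset."""

    n_frames: int = 2000
    group_proportions: tuple[float, float, float, float] = (
        PUBLISHED_GROUP_SIZES[1] / _TOTAL,
        PUBLISHED_GROUP_SIZES[2] / _TOTAL,
        PUBLISHED_GROUP_SIZES[3] / _TOTAL,
        PUBLISHED_GROUP_SIZES[4] / _TOTAL,
    )
    annotator_flip_rates: tuple[float, float, float] = (0.35, 0.35, 0.35)
    ambiguity_fraction: float = 0.15
    n_patients: int = 8
    session_ids: tuple[str, ...] = _DEFAULT_SESSIONS
    locations: tuple[str, ...] = ("loc1", "loc2", "loc3")
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {self.group_proportions}")
        if any(p < 0 for p in self.group_proportions):
            raise ValueError("group proportions must be non-negative")
        if len(self.annotator_flip_rates) != 3:
            raise ValueError("need one flip rate per annotator (3)")
        if any(not 0.0 <= r < 0.5 for r in self.annotator_flip_rates):
            raise ValueError(f"flip rates must lie in [0, 0.5), got {self.annotator_flip_rates}")
        if not 0.0 <= self.ambiguity_fraction < 1.0:
            raise ValueError("ambiguity_fraction must lie in [0, 1)")


@dataclass
class SyntheticFrame:
    """A generated frame with its latent ground truth."""

    pixels: np.ndarray
    true_quality: float
    true_class: str
    record: FrameRecord | None = None

    def __post_init__(self) -> None:
        if self.true_class not in FRAME_CLASSES:
            raise ValueError(f"unknown frame class {self.true_class!r}")
        if self.true_class == "correct" and self.true_quality < 0.7:
            raise ValueError("a 'correct' frame must have quality >= 0.7")
        if self.true_class == "no_contact" and self.true_quality > 0.1:
            raise ValueError("a 'no_contact' frame must have quality <= 0.1")


def boundary_weight(quality) -> np.ndarray | float:
    """Ambiguity weight b(q): 1 at the decision boundary, ~0 at the extremes."""
    q = np.asarray(quality, dtype=float)
    b = (1.0 - np.abs(2.0 * q - 1.0)) ** 4
    return float(b) if b.ndim == 0 else b


# -- frame synthesis ------------------------------------------------------

_H, _W = FRAME_SHAPE[0], FRAME_SHAPE[1]
_ROWS = np.arange(_H, dtype=float)[:, None]
_COLS = np.arange(_W, dtype=float)[None, :]
_BAND_ROW = 34.0
_BAND_SIGMA = 8.0


def _speckle(rng: np.random.Generator, shape=( _H, _W), k: float = 5.0) -> np.ndarray:
    return rng.gamma(k, 1.0 / k, size=shape)


def _correct_pattern(rng: np.random.Generator, quality: float,
                     band_centers: np.ndarray | float = _BAND_ROW) -> np.ndarray:
    """Entry-echo band + depth-decaying dermis speckle (grayscale float)."""
    amp = 185.0 + 55.0 * quality
    band = amp * np.exp(-((_ROWS - band_centers) ** 2) / (2.0 * _BAND_SIGMA**2))
    depth = np.clip(_ROWS - (_BAND_ROW + 10.0), 0.0, None)
    dermis = 82.0 / (1.0 + np.exp(-(_ROWS - (_BAND_ROW + 10.0)) / 4.0)) * np.exp(-depth / 260.0)
    profile = 14.0 + band + dermis
    return np.broadcast_to(profile, (_H, _W)) * _speckle(rng)


def _to_frame(gray: np.ndarray) -> np.ndarray:
    gray = np.clip(gray, 0.0, 255.0).astype(np.uint8)
    return np.repeat(gray[:, :, None], 3, axis=2)


def generate_frame(frame_class: str, rng: np.random.Generator,
                   quality: float | None = None) -> SyntheticFrame:
    """Generate one frame of the given class; deterministic given ``rng`` state.

    ``quality`` defaults to a class-typical value; distortion severity scales
    with 1 - quality, so mildly degraded (expert-discordant) frames can be
    drawn from the same classes at mid-range quality.
    """
    if frame_class not in FRAME_CLASSES:
        raise ValueError(f"unknown frame class {frame_class!r}; choose from {FRAME_CLASSES}")

    if quality is None:
        quality = {
            "correct": rng.uniform(0.72, 0.95),
            "no_contact": rng.uniform(0.02, 0.08),
        }.get(frame_class, rng.uniform(0.10, 0.30))
    sev = float(np.clip(1.0 - quality, 0.0, 1.0))

    if frame_class == "correct":
        gray = _correct_pattern(rng, quality)
    elif frame_class == "no_contact":
        # Probe in air: no entry echo, just faint receiver noise.
        gray = 13.0 * _speckle(rng, k=2.0)
    elif frame_class == "low_contrast":
        base = _correct_pattern(rng, 0.85)
        factor = 1.0 + 6.0 * sev**1.5  # >= 4x compression at class-typical quality
        gray = base.mean() + (base - base.mean()) / factor
    elif frame_class == "geometry_artifact":
        if rng.uniform() < 0.5:  # tilted entry band (> 20 deg at typical severity)
            angle = np.deg2rad(45.0 * sev)
            centers = _BAND_ROW + np.tan(angle) * (_COLS - _W / 2.0)
            gray = _correct_pattern(rng, 0.85, band_centers=centers)
        else:  # broken entry band
            gray = _correct_pattern(rng, 0.85)
            n_gaps = 2 + int(3 * sev)
            gap_w = int(_W * (0.12 + 0.18 * sev))
            for _ in range(n_gaps):
                c0 = rng.integers(0, _W - gap_w)
                gray[: int(_BAND_ROW + 3 * _BAND_SIGMA), c0 : c0 + gap_w] *= 0.08
    else:  # shadow
        gray = _correct_pattern(rng, 0.85)
        width = int(20 + 140 * sev)
        darkness = 0.10 + 0.50 * quality
        c0 = int(rng.integers(0, _W - width))
        gray[int(_BAND_ROW) :, c0 : c0 + width] *= darkness

    return SyntheticFrame(pixels=_to_frame(gray), true_quality=float(quality), true_class=frame_class)


# -- annotator simulation -------------------------------------------------

def simulate_annotators(
    true_quality: float, flip_rates: Sequence[float], rng: np.random.Generator
) -> AnnotationTriple:
    """Three boundary-weighted flip-noise annotations for one frame."""
    if not 0.0 <= true_quality <= 1.0:
        raise ValueError(f"quality must lie in [0, 1], got {true_quality}")
    rates = tuple(float(r) for r in flip_rates)
    if len(rates) != 3 or any(not 0.0 <= r < 0.5 for r in rates):
        raise ValueError(f"need 3 flip rates in [0, 0.5), got {flip_rates}")
    nominal = OK if true_quality >= 0.5 else NO_OK
    other = NO_OK if nominal is OK else OK
    b = boundary_weight(true_quality)
    labels = tuple(other if rng.uniform() < r * b else nominal for r in rates)
    return AnnotationTriple(labels)


# -- dataset generation ---------------------------------------------------
#
# Frames come in four latent types: extreme-bad, ambiguous-bad, ambiguous-ok
# and extreme-ok, each with its own quality distribution.  The type mix is
# solved (non-negative least squares over the exact 8-pattern flip
# enumeration, integrated over each type's quality distribution) so that the
# EXPECTED fused-group proportions equal the configured targets, with groups
# 2+3 rescaled to the configured ambiguity fraction.  Realized proportions
# then match within multinomial sampling error.

_TYPE_QUALITY_GRIDS = {
    # (grid, weights) pairs; weights sum to 1.
    "ext_no": (
        np.concatenate([np.linspace(0.02, 0.08, 25), np.linspace(0.10, 0.30, 75)]),
        np.concatenate([np.full(25, 0.25 / 25), np.full(75, 0.75 / 75)]),
    ),
    "amb_no": (np.linspace(0.40, 0.49, 50), np.full(50, 1.0 / 50)),
    "amb_ok": (np.linspace(0.51, 0.60, 50), np.full(50, 1.0 / 50)),
    "ext_ok": (np.linspace(0.72, 0.95, 50), np.full(50, 1.0 / 50)),
}
_TYPES = ("ext_no", "amb_no", "amb_ok", "ext_ok")


def _expected_group_probs(qualities: np.ndarray, weights: np.ndarray,
                          rates: Sequence[float]) -> np.ndarray:
    """E[P(group g)] for a frame type, integrating the flip model over quality."""
    probs = np.zeros(4)
    for q, w in zip(qualities, weights):
        b = boundary_weight(q)
        p_no = np.array([r * b if q >= 0.5 else 1.0 - r * b for r in rates])
        for pattern in range(8):
            votes_no = [(pattern >> i) & 1 for i in range(3)]
            p = np.prod([p_no[i] if v else 1.0 - p_no[i] for i, v in enumerate(votes_no)])
            group = {3: 1, 1: 2, 2: 3, 0: 4}[sum(votes_no)]
            probs[group - 1] += w * p
    return probs


def _solve_type_mix(cfg: SyntheticConfig) -> np.ndarray:
    p1, p2, p3, p4 = cfg.group_proportions
    a = cfg.ambiguity_fraction
    disc = p2 + p3
    if disc > 0 and a > 0:
        t = np.array([p1 * (1 - a) / (p1 + p4), p2 * a / disc, p3 * a / disc, p4 * (1 - a) / (p1 + p4)])
    else:
        t = np.array([p1 / (p1 + p4) * (1 - a), a / 2, a / 2, p4 / (p1 + p4) * (1 - a)])
    A = np.column_stack([
        _expected_group_probs(*_TYPE_QUALITY_GRIDS[ty], cfg.annotator_flip_rates) for ty in _TYPES
    ])
    from scipy.optimize import nnls

    x, _ = nnls(A, t)
    if x.sum() <= 0:
        raise ValueError("cannot realize the requested group proportions")
    return x / x.sum()


def _draw_quality(frame_type: str, frame_class: str, rng: np.random.Generator) -> float:
    if frame_type == "ext_ok":
        return float(rng.uniform(0.72, 0.95))
    if frame_type == "ext_no":
        if frame_class == "no_contact":
            return float(rng.uniform(0.02, 0.08))
        return float(rng.uniform(0.10, 0.30))
    if frame_type == "amb_no":
        return float(rng.uniform(0.40, 0.49))
    return float(rng.uniform(0.51, 0.60))


def generate_dataset(
    cfg: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticFrame], list[AnnotationTriple]]:
    """Generate a full dataset; optionally write it in the on-disk layout.

    Returns frames and annotation triples ordered by (session, file name),
    the same order :func:`hfus_iqa.dataset_io.load_dataset` produces, so a
    written dataset round-trips.  Deterministic given ``cfg.seed``.
    """
    if cfg.n_frames < 20:
        raise ValueError(f"n_frames must be >= 20 for the fold machinery, got {cfg.n_frames}")
    rng = np.random.default_rng(cfg.seed)
    mix = _solve_type_mix(cfg)
    type_counts = rng.multinomial(cfg.n_frames, mix)

    entries: list[tuple[SyntheticFrame, AnnotationTriple]] = []
    for ty, count in zip(_TYPES, type_counts):
        for _ in range(count):
            if ty == "ext_ok":
                frame_class = "correct"
            elif ty == "ext_no":
                frame_class = _INCORRECT_CLASSES[rng.integers(len(_INCORRECT_CLASSES))]
            else:
                frame_class = _MILD_CLASSES[rng.integers(len(_MILD_CLASSES))]
            quality = _draw_quality(ty, frame_class, rng)
            frame = generate_frame(frame_class, rng, quality=quality)
            triple = simulate_annotators(quality, cfg.annotator_flip_rates, rng)
            entries.append((frame, triple))

    order = rng.permutation(len(entries))
    frames: list[SyntheticFrame] = []
    triples: list[AnnotationTriple] = []
    for i, j in enumerate(order):
        frame, triple = entries[j]
        session = cfg.session_ids[i % len(cfg.session_ids)]
        frame.record = FrameRecord(
            patient_id=f"{(i % cfg.n_patients) + 1:02d}",
            facial_location=cfg.locations[(i // cfg.n_patients) % len(cfg.locations)],
            image_id=f"{i:05d}",
            session_id=session,
            pixels=frame.pixels,
        )
        frames.append(frame)
        triples.append(triple)

    # Match the deterministic (session, file name) order of load_dataset.
    sort_idx = sorted(range(len(frames)), key=lambda k: (frames[k].record.session_id, frames[k].record.file_name))
    frames = [frames[k] for k in sort_idx]
    triples = [triples[k] for k in sort_idx]

    if out_dir is not None:
        _write_layout(frames, triples, Path(out_dir), cfg)
    return frames, triples


def _write_layout(frames: Sequence[SyntheticFrame], triples: Sequence[AnnotationTriple],
                  out_dir: Path, cfg: SyntheticConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    by_session: dict[str, list[tuple[SyntheticFrame, AnnotationTriple]]] = {}
    for f, t in zip(frames, triples):
        by_session.setdefault(f.record.session_id, []).append((f, t))
    group_counts = {g: 0 for g in (1, 2, 3, 4)}
    for session, items in sorted(by_session.items()):
        session_dir = out_dir / session
        session_dir.mkdir(exist_ok=True)
        rows = []
        for f, t in items:
            Image.fromarray(f.pixels).save(session_dir / f.record.file_name)
            rows.append(AnnotationRow(f.record.file_name, *t.labels))
            group_counts[assign_group(t)] += 1
        write_annotation_table(rows, session_dir / f"{session}_DataDesc.csv")
    manifest = {
        "seed": cfg.seed,
        "n_frames": len(frames),
        "group_counts": group_counts,
        "flip_rates": list(cfg.annotator_flip_rates),
        "ambiguity_fraction": cfg.ambiguity_fraction,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
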