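"""On-disk layout of the HFUS facial-skin dataset.

The dataset is organised as one folder per acquisition session (folder name
= session ID in day-month-year digits, e.g. ``08032021``).  Each folder holds
PNG frames named ``p<PatientID>_<FacialLocation>_<ImageID>.png`` and one
annotation table ``ID_DataDesc`` with a file-name column and one binary
label column per expert.  Frames are loaded as 224 x 224 x 3 uint8 arrays
(any input size is resampled bilinearly; grayscale is replicated to three
channels), matching the input size of the classification backbones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .label_fusion import OK, NO_OK, AnnotationTriple, BinaryLabel

__all__ = [
    "FRAME_SHAPE",
    "FrameRecord",
    "AnnotationRow",
    "parse_frame_filename",
    "read_annotation_table",
    "write_annotation_table",
    "load_frame",
    "load_dataset",
]

#: Fixed pixel-array shape of every loaded frame.
FRAME_SHAPE = (224, 224, 3)

#: Default column layout of an annotation table (the headers are
#: configurable; when none of them is present the first four columns are
#: used positionally in this order).
DEFAULT_COLUMNS = ("File_name", "Expert 1", "Expert 2", "Expert 3")

#: Accepted label spellings, matched case- and whitespace-insensitively.
LABEL_TOKENS = {
    "ok": OK,
    "no ok": NO_OK,
    "no_ok": NO_OK,
    "1": OK,
    "0": NO_OK,
}

_FILENAME_RE = re.compile(r"^p([^_]+)_([^_]+)_([^_]+)\.png$")


class DatasetError(ValueError):
    """Malformed dataset layout, file name or annotation table."""


@dataclass
class FrameRecord:
    """One HFUS frame with the identifiers parsed from its file name."""

    patient_id: str
    facial_location: str
    image_id: str
    session_id: str
    pixels: np.ndarray | None = None
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.pixels is not None and self.pixels.shape != FRAME_SHAPE:
            raise DatasetError(
                f"frame pixels must have shape {FRAME_SHAPE}, got {self.pixels.shape}"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Unique frame identity (session, patient, location, image)."""
        return (self.session_id, self.patient_id, self.facial_location, self.image_id)

    @property
    def file_name(self) -> str:
        return f"p{self.patient_id}_{self.facial_location}_{self.image_id}.png"


@dataclass(frozen=True)
class AnnotationRow:
    """One table row: frame file name plus the three expert labels."""

    file_name: str
    expert1: BinaryLabel
    expert2: BinaryLabel
    expert3: BinaryLabel

    @property
    def triple(self) -> AnnotationTriple:
        return AnnotationTriple((self.expert1, self.expert2, self.expert3))


def parse_frame_filename(name: str) -> tuple[str, str, str]:
    """Split ``p<PatientID>_<FacialLocation>_<ImageID>.png`` into its tokens.

    Tokens are returned verbatim (no numeric coercion); the leading ``p``
    and the ``.png`` suffix are stripped.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        raise DatasetError(
            f"cannot parse frame file name {name!r}: expected 'p<PatientID>_<FacialLocation>_<ImageID>.png'"
        )
    return m.group(1), m.group(2), m.group(3)


def _normalize_label(cell, row_label, column) -> BinaryLabel:
    token = str(cell).strip().lower()
    try:
        return LABEL_TOKENS[token]
    except KeyError:
        raise DatasetError(
            f"unknown annotation label {cell!r} in row {row_label!r}, column {column!r}; "
            f"accepted tokens: {sorted(LABEL_TOKENS)}"
        ) from None


def read_annotation_table(
    path: str | Path, columns: Sequence[str] = DEFAULT_COLUMNS
) -> list[AnnotationRow]:
    """Read an annotation table (XLSX or CSV) into normalized rows.

    ``columns`` names the file-name column and the three expert columns; when
    the table does not carry these headers, the first four columns are used
    in that positional order.  Label cells are normalized to ok / no_ok
    (case- and whitespace-insensitive); duplicate file names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    if df.empty:
        return []
    if len(columns) != 4:
        raise ValueError("expected four column names (file name + three experts)")
    if all(c in df.columns for c in columns):
        df = df[list(columns)]
    elif len(df.columns) >= 4:
        df = df.iloc[:, :4]
    else:
        raise DatasetError(
            f"annotation table {path} has {len(df.columns)} columns; need at least 4"
        )

    rows: list[AnnotationRow] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.itertuples(index=False)):
        file_name = str(rec[0]).strip()
        parse_frame_filename(file_name)  # validate the pattern early
        if file_name in seen:
            raise DatasetError(f"duplicate file name {file_name!r} in {path} (row {i})")
        seen.add(file_name)
        labels = [
            _normalize_label(rec[j + 1], file_name, df.columns[j + 1]) for j in range(3)
        ]
        rows.append(AnnotationRow(file_name, *labels))
    return rows


def write_annotation_table(
    rows: Sequence[AnnotationRow], path: str | Path, columns: Sequence[str] = DEFAULT_COLUMNS
) -> None:
    """Write rows to CSV or XLSX with the canonical ok / no ok spellings."""
    path = Path(path)
    token = {OK: "ok", NO_OK: "no ok"}
    df = pd.DataFrame(
        [
            [r.file_name, token[r.expert1], token[r.expert2], token[r.expert3]]
            for r in rows
        ],
        columns=list(columns),
    )
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def load_frame(path: str | Path, session_id: str | None = None) -> FrameRecord:
    """Load one PNG frame, resampling to 224 x 224 x 3 (bilinear).

    Grayscale inputs are replicated to three channels.  The session ID
    defaults to the name of the containing folder.
    """
    path = Path(path)
    patient_id, facial_location, image_id = parse_frame_filename(path.name)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (FRAME_SHAPE[1], FRAME_SHAPE[0]):
                im = im.resize((FRAME_SHAPE[1], FRAME_SHAPE[0]), Image.Resampling.BILINEAR)
            pixels = np.asarray(im, dtype=np.uint8)
    except OSError as exc:
        raise OSError(f"cannot read frame {path}: {exc}") from exc
    return FrameRecord(
        patient_id=patient_id,
        facial_location=facial_location,
        image_id=image_id,
        session_id=session_id if session_id is not None else path.parent.name,
        pixels=pixels,
        path=path,
    )


def _find_annotation_table(session_dir: Path) -> Path:
    candidates = sorted(
        p
        for p in session_dir.iterdir()
        if p.suffix.lower() in (".csv", ".xlsx", ".xls") and "datadesc" in p.name.lower()
    )
    if not candidates:
        candidates = sorted(
            p for p in session_dir.iterdir() if p.suffix.lower() in (".csv", ".xlsx", ".xls")
        )
    if len(candidates) != 1:
        raise DatasetError(
            f"session folder {session_dir} must contain exactly one annotation table, "
            f"found {len(candidates)}"
        )
    return candidates[0]


def load_dataset(
    root: str | Path, columns: Sequence[str] = DEFAULT_COLUMNS
) -> tuple[list[FrameRecord], list[AnnotationTriple]]:
    """Load every session folder under ``root`` into paired frames and triples.

    Every annotation row must match exactly one PNG on disk and vice versa;
    any mismatch aborts with a listing of the offending files.  Frames are
    ordered by (session, file name) so reloading is deterministic.
    """
    root = Path(root)
    session_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not session_dirs:
        raise DatasetError(f"no session folders found under {root}")

    frames: list[FrameRecord] = []
    triples: list[AnnotationTriple] = []
    for session_dir in session_dirs:
        rows = read_annotation_table(_find_annotation_table(session_dir), columns)
        pngs = {p.name: p for p in session_dir.glob("*.png")}
        annotated = {r.file_name for r in rows}
        missing_png = sorted(annotated - set(pngs))
        missing_row = sorted(set(pngs) - annotated)
        if missing_png or missing_row:
            raise DatasetError(
                f"session {session_dir.name}: annotation/image mismatch; "
                f"rows without image: {missing_png}; images without row: {missing_row}"
            )
        for row in sorted(rows, key=lambda r: r.file_name):
            frames.append(load_frame(pngs[row.file_name], session_id=session_dir.name))
            triples.append(row.triple)
    return frames, triples
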