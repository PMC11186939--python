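"""Video archive I/O and cohort manifest handling.

The canonical container is a lossless zip archive (``.echo`` extension by
convention) holding raw frame bytes (`.npy`) plus a JSON metadata sidecar, so
round-trips are bit-exact. TIFF stacks are supported as a lossless,
widely-viewable alternative. MP4/AVI import/export is attempted through
imageio and requires a video plugin (ffmpeg/pyav); without one a clear
RuntimeError is raised — lossy codecs are for viewing only, never for tests.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import EchoVideo, FormatError, MaskSequence, ValidationError, View

__all__ = [
    "read_echo_video",
    "write_echo_video",
    "read_mask_sequence",
    "CohortManifest",
    "load_manifest",
    "save_manifest",
]

ARCHIVE_SUFFIXES = (".echo", ".npz")
TIFF_SUFFIXES = (".tif", ".tiff")
LOSSY_SUFFIXES = (".mp4", ".avi")

# Fixed zip timestamp so identical content yields byte-identical archives.
_EPOCH = (1980, 1, 1, 0, 0, 0)


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Reduce a (T,H,W[,C]) stack to single-channel via Rec.601 luminance."""
    if frames.ndim == 4:
        if frames.shape[-1] == 1:
            return frames[..., 0]
        if frames.shape[-1] in (3, 4):
            rgb = frames[..., :3].astype(np.float64)
            lum = rgb @ np.array([0.299, 0.587, 0.114])
            return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
        raise FormatError(f"cannot interpret channel count {frames.shape[-1]}")
    if frames.ndim == 3:
        return frames
    raise FormatError(f"expected a frame stack, got array of shape {frames.shape}")


def _write_zip_member(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, data)


def _array_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def write_echo_video(
    video: EchoVideo,
    path: str | Path,
    lossless: bool = True,
    masks: Optional[MaskSequence] = None,
) -> Path:
    """Write a video to disk.

    ``lossless=True`` writes the canonical zip archive (exact intensities,
    fps/view/subject/label metadata, optional ventricle masks). For TIFF
    targets the frame data is lossless but metadata is limited to what the
    manifest carries. ``lossless=False`` with an ``.mp4``/``.avi`` path
    attempts a standard playable container via imageio.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if lossless and suffix not in LOSSY_SUFFIXES:
        if suffix in TIFF_SUFFIXES:
            import tifffile

            tifffile.imwrite(path, video.frames)
            return path
        meta = {
            "fps": video.fps,
            "view": video.view.value,
            "subject_id": video.subject_id,
            "label": video.label,
        }
        try:
            with zipfile.ZipFile(path, "w") as zf:
                _write_zip_member(zf, "meta.json", json.dumps(meta, sort_keys=True).encode())
                _write_zip_member(zf, "frames.npy", _array_bytes(video.frames))
                if masks is not None:
                    _write_zip_member(zf, "masks.npy", _array_bytes(masks.masks))
                    _write_zip_member(zf, "mask_source.txt", masks.source.encode())
        except OSError as exc:
            raise OSError(f"cannot write archive to {path}: {exc}") from exc
        return path
    # lossy / playable export
    import imageio.v2 as iio

    try:
        writer = iio.get_writer(str(path), fps=video.fps)
        try:
            for frame in video.frames:
                writer.append_data(frame)
        finally:
            writer.close()
    except (TypeError, ValueError, OSError, IndexError) as exc:
        raise RuntimeError(
            f"no working video codec backend for {suffix!r} "
            "(install an imageio ffmpeg/pyav plugin); use the lossless "
            "archive or TIFF instead"
        ) from exc
    return path


def read_echo_video(
    path: str | Path,
    view: View | str | None = None,
    subject_id: Optional[str] = None,
    label: Optional[int] = None,
    fps: Optional[float] = None,
) -> EchoVideo:
    """Read a video from a lossless archive, TIFF stack, or MP4/AVI.

    Metadata arguments override anything stored in the container; for
    containers without embedded metadata (TIFF, MP4) ``view`` is required and
    ``fps`` defaults to 25 if absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such video file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    suffix = path.suffix.lower()
    meta: dict = {}
    if suffix in TIFF_SUFFIXES:
        import tifffile

        frames = np.asarray(tifffile.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    elif suffix in LOSSY_SUFFIXES:
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(str(path))
            frames = np.stack([np.asarray(f) for f in reader])
            try:
                meta["fps"] = float(reader.get_meta_data().get("fps", 25.0))
            except Exception:
                pass
        except Exception as exc:
            raise RuntimeError(
                f"cannot decode {suffix!r} here (no video codec backend): {exc}"
            ) from exc
    else:
        if not zipfile.is_zipfile(path):
            raise FormatError(f"{path} is not a lossless echo archive")
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "frames.npy" not in names:
                raise FormatError(f"{path} lacks frames.npy")
            frames = np.load(_io.BytesIO(zf.read("frames.npy")))
            if "meta.json" in names:
                meta = json.loads(zf.read("meta.json"))
    if frames.shape[0] == 0:
        raise FormatError(f"{path} contains zero frames")
    frames = _to_grayscale(frames)
    resolved_view = view if view is not None else meta.get("view")
    if resolved_view is None:
        raise ValidationError(f"no view stored in {path}; pass view= explicitly")
    return EchoVideo(
        frames=frames,
        fps=float(fps if fps is not None else meta.get("fps", 25.0)),
        view=View.parse(resolved_view),
        subject_id=subject_id if subject_id is not None else meta.get("subject_id", path.stem),
        label=label if label is not None else meta.get("label"),
    )


def read_mask_sequence(path: str | Path) -> MaskSequence:
    """Read the ventricle masks stored alongside frames in an archive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such archive: {path}")
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "masks.npy" not in names:
            raise FormatError(f"{path} stores no mask sequence")
        masks = np.load(_io.BytesIO(zf.read("masks.npy")))
        source = zf.read("mask_source.txt").decode() if "mask_source.txt" in names else "external"
    return MaskSequence(masks=masks, source=source)


class CohortManifest:
    """Table binding subjects, views, file paths, labels and split tags.

    Thin wrapper over a validated DataFrame with columns
    ``subject_id, view, path, label[, split]``.
    """

    COLUMNS = ("subject_id", "view", "path", "label")

    def __init__(self, frame: pd.DataFrame, check_paths: bool = False):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        bad_views = [
            (i, v) for i, v in enumerate(frame["view"])
            if not self._is_view(v)
        ]
        if bad_views:
            raise ValidationError(f"unknown view in manifest rows: {bad_views}")
        frame["view"] = [View.parse(v).value for v in frame["view"]]
        labels = []
        for i, raw in enumerate(frame["label"]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                labels.append(None)
                continue
            try:
                lab = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"unparsable label {raw!r} at row {i}") from None
            if lab not in (0, 1, 2):
                raise ValidationError(f"label {lab} at row {i} not in {{0,1,2}}")
            labels.append(lab)
        frame["label"] = labels
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["path"] = frame["path"].astype(str)
        if "split" not in frame.columns:
            frame["split"] = None
        dup = frame.duplicated(subset=["subject_id", "view", "path"])
        if dup.any():
            raise ValidationError(
                f"duplicate (subject, view, path) rows at indices {list(frame.index[dup])}"
            )
        dup_rec = frame.duplicated(subset=["subject_id", "view"])
        if dup_rec.any():
            raise ValidationError(
                "one recording per (subject, view) expected; duplicates at "
                f"indices {list(frame.index[dup_rec])}"
            )
        if check_paths:
            missing_files = [p for p in frame["path"] if not Path(p).exists()]
            if missing_files:
                raise ValidationError(f"unresolvable paths: {missing_files}")
        self.frame = frame

    @staticmethod
    def _is_view(v: object) -> bool:
        try:
            View.parse(v)  # type: ignore[arg-type]
            return True
        except ValidationError:
            return False

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        a = self.frame.fillna("").astype(str)
        b = other.frame.fillna("").astype(str)
        return a.equals(b)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.frame["subject_id"]))

    def labels_by_subject(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, row in self.frame.iterrows():
            if row["label"] is not None:
                prev = out.get(row["subject_id"])
                if prev is not None and prev != row["label"]:
                    raise ValidationError(
                        f"subject {row['subject_id']} carries conflicting labels"
                    )
                out[row["subject_id"]] = row["label"]
        return out

    def rows(self) -> Iterable[pd.Series]:
        for _, row in self.frame.iterrows():
            yield row

    def subset(self, subject_ids: Iterable[str]) -> "CohortManifest":
        ids = set(subject_ids)
        return CohortManifest(self.frame[self.frame["subject_id"].isin(ids)])

    def for_view(self, view: View | str) -> "CohortManifest":
        v = View.parse(view).value
        return CohortManifest(self.frame[self.frame["view"] == v])


def load_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    frame = pd.read_csv(path, dtype={"subject_id": str})
    return CohortManifest(frame, check_paths=check_paths)


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    out = manifest.frame.copy()
    out["label"] = [("" if l is None else l) for l in out["label"]]
    out["split"] = [("" if s is None else s) for s in out["split"]]
    out.to_csv(path, index=False)
    return path
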