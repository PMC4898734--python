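"""Loading directory-per-class pollen image datasets and labeled feature tables.

Images are expected to arrive already segmented: a single pollen grain on a
near-uniform background (the layout of the POLEN23E collection — one
subdirectory per pollen type, one grain per file).  The foreground mask is
recovered from the uniform background rather than read from disk.

Feature tables are exchanged as delimited text (CSV, final column = class
label) or in the attribute-relation (ARFF) dialect used by the Weka toolkit.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ConfigurationError(ValueError):
    """Raised for bad paths / malformed configuration."""


class ParseError(ValueError):
    """Raised when a feature-table file cannot be parsed."""


DEFAULT_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

# Euclidean RGB distance (of 255) separating foreground from the estimated
# background; POLEN23E-style images are cut onto uniform backgrounds.
DEFAULT_BACKGROUND_TOLERANCE = 10.0


@dataclass
class SegmentedPollenImage:
    """One segmented pollen grain: RGB pixels, foreground mask, class label."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = pollen foreground
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels must be an H x W x 3 RGB raster")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match "
                f"pixel raster {self.pixels.shape[:2]}"
            )
        if not self.mask.any():
            raise ValidationError("mask contains no foreground pixel")
        if not self.label:
            raise ValidationError("label must be non-empty")


@dataclass
class LabeledImageSet:
    """Deterministically ordered list of segmented images plus class names."""

    images: list[SegmentedPollenImage]
    class_names: list[str]

    def __post_init__(self) -> None:
        known = set(self.class_names)
        for img in self.images:
            if img.label not in known:
                raise ValidationError(
                    f"image {img.source_id!r} has label {img.label!r} "
                    "absent from class_names"
                )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> list[str]:
        return [img.label for img in self.images]


@dataclass
class FeatureTable:
    """n_samples x d labeled feature matrix exchanged between stages."""

    values: np.ndarray
    column_names: list[str]
    labels: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, d = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if len(self.column_names) != d:
            raise ValidationError(
                f"{len(self.column_names)} column names for {d} columns"
            )
        if len(set(self.column_names)) != d:
            raise ValidationError("column_names must be unique")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValidationError("labels/sample_ids length must equal n_samples")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))


def derive_mask(
    pixels: np.ndarray,
    background_tolerance: float = DEFAULT_BACKGROUND_TOLERANCE,
) -> np.ndarray:
    """Recover the foreground mask of a segmented image.

    The background color is estimated as the median RGB of the 1-pixel image
    border (robust to the grain touching one edge); foreground pixels are
    those farther than ``background_tolerance`` from it in Euclidean RGB
    distance.  Only the largest 8-connected component is kept and its holes
    are filled, matching the one-grain-per-image segmentation contract.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    rgb = pixels.astype(float)
    border = np.concatenate(
        [rgb[0, :], rgb[-1, :], rgb[1:-1, 0], rgb[1:-1, -1]], axis=0
    )
    background = np.median(border, axis=0)
    distance = np.sqrt(((rgb - background) ** 2).sum(axis=-1))
    fg = distance > background_tolerance
    if not fg.any():
        raise ValidationError("no foreground object: all pixels match background")
    labeled, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = ndimage.sum_labels(fg, labeled, index=np.arange(1, n_comp + 1))
        fg = labeled == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(fg)


def load_image(path: Path) -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB raster."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_dataset(
    root_dir: str | Path,
    extensions: tuple[str, ...] = DEFAULT_EXTENSIONS,
    background_tolerance: float = DEFAULT_BACKGROUND_TOLERANCE,
) -> LabeledImageSet:
    """Load a directory-per-class image tree into a :class:`LabeledImageSet`.

    Each immediate subdirectory of ``root_dir`` is one class; ordering is
    lexicographic by class then file name, so two calls on the same tree are
    identical.  Masks are derived with :func:`derive_mask`.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ConfigurationError(f"dataset directory {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValidationError(f"{root} contains no class subdirectories")
    exts = {e.lower() for e in extensions}
    images: list[SegmentedPollenImage] = []
    class_names: list[str] = []
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in exts)
        if not files:
            raise ValidationError(
                f"class directory {cdir.name!r} contains no readable images"
            )
        class_names.append(cdir.name)
        for f in files:
            pixels = load_image(f)
            mask = derive_mask(pixels, background_tolerance)
            images.append(
                SegmentedPollenImage(
                    pixels=pixels, mask=mask, label=cdir.name, source_id=str(f)
                )
            )
    return LabeledImageSet(images=images, class_names=class_names)


def write_manifest(dataset: LabeledImageSet, path: str | Path) -> None:
    """Write a (sample_id, path, label) delimited-text manifest."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "path", "label"])
        for i, img in enumerate(dataset.images):
            writer.writerow([f"sample_{i}", img.source_id, img.label])


# ---------------------------------------------------------------------------
# Feature table serialization: delimited text and attribute-relation (ARFF)

def _fmt(v: float) -> str:
    # shortest decimal representation that round-trips to the same float
    return repr(float(v))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "arff" if path.suffix.lower() == ".arff" else "csv"


def write_feature_table(
    table: FeatureTable, path: str | Path, fmt: str | None = None
) -> None:
    """Write a feature table as delimited text (``csv``) or ARFF (``arff``).

    The CSV dialect has a header row, a leading ``sample_id`` column and a
    final ``class`` column; the ARFF dialect declares numeric attributes plus
    a nominal class attribute listing every class name.  Values round-trip
    through :func:`read_feature_table` exactly (shortest round-trip decimal representation).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        _write_csv(table, path)
    elif fmt == "arff":
        _write_arff(table, path)
    else:
        raise ConfigurationError(f"unknown feature-table format {fmt!r}")


def read_feature_table(path: str | Path, fmt: str | None = None) -> FeatureTable:
    """Inverse of :func:`write_feature_table` (format inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "arff":
        return _read_arff(path)
    raise ConfigurationError(f"unknown feature-table format {fmt!r}")


def _write_csv(table: FeatureTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *table.column_names, "class"])
        for i in range(table.n_samples):
            row = [table.sample_ids[i]]
            row += [_fmt(v) for v in table.values[i]]
            row.append(table.labels[i])
            writer.writerow(row)


def _read_csv(path: Path) -> FeatureTable:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2 or header[-1] != "class":
            raise ParseError(f"{path}:1: header must end with a 'class' column")
        has_ids = header[0] == "sample_id"
        col_names = header[1:-1] if has_ids else header[:-1]
        values, labels, ids = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ids.append(row[0] if has_ids else f"sample_{lineno - 2}")
            body = row[1:-1] if has_ids else row[:-1]
            try:
                values.append([float(v) for v in body])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            labels.append(row[-1])
        if not values:
            raise ParseError(f"{path}: no data rows")
        return FeatureTable(
            values=np.array(values), column_names=list(col_names),
            labels=labels, sample_ids=ids,
        )


def _arff_quote(name: str) -> str:
    if re.search(r"[\s,'\"{}%\\]", name) or name == "":
        return "'" + name.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return name


def _write_arff(table: FeatureTable, path: Path) -> None:
    classes = table.class_names
    with open(path, "w") as fh:
        fh.write("@RELATION pollen_features\n\n")
        fh.write("@ATTRIBUTE sample_id STRING\n")
        for name in table.column_names:
            fh.write(f"@ATTRIBUTE {_arff_quote(name)} NUMERIC\n")
        fh.write(
            "@ATTRIBUTE class {" + ",".join(_arff_quote(c) for c in classes) + "}\n"
        )
        fh.write("\n@DATA\n")
        for i in range(table.n_samples):
            fields = [_arff_quote(table.sample_ids[i])]
            fields += [_fmt(v) for v in table.values[i]]
            fields.append(_arff_quote(table.labels[i]))
            fh.write(",".join(fields) + "\n")


def _split_arff_fields(line: str, path: Path, lineno: int) -> list[str]:
    # csv with quotechar=' handles the ARFF single-quote convention
    reader = csv.reader(io.StringIO(line), quotechar="'", escapechar="\\")
    try:
        return next(reader)
    except (StopIteration, csv.Error) as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def _read_arff(path: Path) -> FeatureTable:
    attributes: list[tuple[str, str]] = []
    data_lines: list[tuple[int, str]] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                m = re.match(
                    r"@attribute\s+('(?:[^'\\]|\\.)*'|\S+)\s+(.*)",
                    line,
                    re.IGNORECASE,
                )
                if not m:
                    raise ParseError(f"{path}:{lineno}: malformed @ATTRIBUTE")
                name = m.group(1)
                if name.startswith("'"):
                    name = name[1:-1].replace("\\'", "'").replace("\\\\", "\\")
                attributes.append((name, m.group(2).strip()))
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if in_data:
                data_lines.append((lineno, line))
    if not attributes or not attributes[-1][1].startswith("{"):
        raise ParseError(f"{path}: missing nominal class attribute")
    has_ids = attributes[0][1].upper() == "STRING"
    feat_attrs = attributes[1:-1] if has_ids else attributes[:-1]
    col_names = [a[0] for a in feat_attrs]
    values, labels, ids = [], [], []
    for lineno, line in data_lines:
        fields = _split_arff_fields(line, path, lineno)
        if len(fields) != len(attributes):
            raise ParseError(
                f"{path}:{lineno}: expected {len(attributes)} fields, "
                f"got {len(fields)}"
            )
        ids.append(fields[0] if has_ids else f"sample_{len(ids)}")
        body = fields[1:-1] if has_ids else fields[:-1]
        try:
            values.append([float(v) for v in body])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        labels.append(fields[-1])
    if not values:
        raise ParseError(f"{path}: no data rows")
    return FeatureTable(
        values=np.array(values), column_names=col_names,
        labels=labels, sample_ids=ids,
    )
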