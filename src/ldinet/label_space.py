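"""Label vocabulary, multi-hot encoding, manifests and the stratified split.

The classifier predicts a *triple* — (plant, disease-or-none, severity) — for
every leaf image.  Rather than enumerating joint plant×disease×severity
combinations, each image carries a multi-hot target over the concatenated
vocabulary plants ‖ diseases ‖ severities (34 labels for the reference
dataset: 12 plants, 19 diseases, 3 severities).  A diseased image has three
ones (its plant, its disease, its severity); a healthy image has two (plant
and "Healthy" — the disease block stays all-zero, since "healthy" is not a
disease category).
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SEVERITY_NAMES",
    "LabelSpace",
    "TripleLabel",
    "ManifestRecord",
    "CountTableFixture",
    "build_label_space",
    "default_label_space",
    "encode_triple",
    "decode_scores",
    "read_manifest",
    "write_manifest",
    "split_stratified",
    "load_fixture",
    "sum_fixture_column",
]

SEVERITY_NAMES = ("Healthy", "General", "Serious")

HEALTHY = "Healthy"


class LabelSpaceError(ValueError):
    """Invalid vocabulary, triple or score vector."""


@dataclass(frozen=True)
class TripleLabel:
    """A (plant, disease, severity) annotation; ``disease is None`` iff healthy."""

    plant: str
    disease: str | None
    severity: str

    def __post_init__(self):
        if (self.disease is None) != (self.severity == HEALTHY):
            raise LabelSpaceError(
                f"disease must be None exactly when severity is '{HEALTHY}': "
                f"got disease={self.disease!r}, severity={self.severity!r}"
            )


@dataclass(frozen=True)
class LabelSpace:
    """Ordered vocabulary with contiguous index blocks per label group."""

    plants: tuple[str, ...]
    diseases: tuple[str, ...]
    severities: tuple[str, ...]
    index: dict = field(repr=False, compare=False, default=None)

    @property
    def total(self) -> int:
        return len(self.plants) + len(self.diseases) + len(self.severities)

    @property
    def plant_range(self) -> range:
        return range(0, len(self.plants))

    @property
    def disease_range(self) -> range:
        n = len(self.plants)
        return range(n, n + len(self.diseases))

    @property
    def severity_range(self) -> range:
        n = len(self.plants) + len(self.diseases)
        return range(n, self.total)

    @property
    def names(self) -> tuple[str, ...]:
        return self.plants + self.diseases + self.severities

    def label_index(self, group: str, name: str) -> int:
        try:
            return self.index[(group, name)]
        except KeyError:
            raise LabelSpaceError(f"unknown {group} name: {name!r}") from None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plants": list(self.plants),
            "diseases": list(self.diseases),
            "severities": list(self.severities),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelSpace":
        return build_label_space(d["plants"], d["diseases"], d["severities"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "LabelSpace":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "LabelSpace":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_label_space(plant_names, disease_names, severity_names=SEVERITY_NAMES) -> LabelSpace:
    """Concatenate the three name lists into one indexed vocabulary."""
    groups = {"plant": tuple(plant_names), "disease": tuple(disease_names),
              "severity": tuple(severity_names)}
    for gname, names in groups.items():
        if not names:
            raise LabelSpaceError(f"empty {gname} group")
    all_names = groups["plant"] + groups["disease"] + groups["severity"]
    if len(set(all_names)) != len(all_names):
        dupes = sorted({n for n in all_names if all_names.count(n) > 1})
        raise LabelSpaceError(f"duplicate label names: {dupes}")
    index = {}
    offset = 0
    for gname, names in groups.items():
        for i, n in enumerate(names):
            index[(gname, n)] = offset + i
        offset += len(names)
    return LabelSpace(groups["plant"], groups["disease"], groups["severity"], index)


def default_label_space() -> LabelSpace:
    """The 34-label vocabulary of the reference dataset (packaged fixtures)."""
    plants = load_fixture("plant").names
    diseases = load_fixture("disease").names
    return build_label_space(plants, diseases, SEVERITY_NAMES)


# --------------------------------------------------------------------------
# multi-hot encoding / decoding
# --------------------------------------------------------------------------

def encode_triple(space: LabelSpace, triple: TripleLabel) -> np.ndarray:
    """Multi-hot target: ones at the triple's label indices (2 if healthy, 3 else)."""
    bits = np.zeros(space.total, dtype=np.int8)
    bits[space.label_index("plant", triple.plant)] = 1
    bits[space.label_index("severity", triple.severity)] = 1
    if triple.disease is not None:
        bits[space.label_index("disease", triple.disease)] = 1
    return bits


def decode_scores(space: LabelSpace, scores: np.ndarray) -> TripleLabel:
    """Per-group argmax readout, gating the disease on a non-Healthy severity.

    Ties break toward the lowest index (numpy argmax convention).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (space.total,):
        raise LabelSpaceError(
            f"score vector must have shape ({space.total},), got {scores.shape}")
    pr, dr, sr = space.plant_range, space.disease_range, space.severity_range
    plant = space.plants[int(np.argmax(scores[pr.start:pr.stop]))]
    severity = space.severities[int(np.argmax(scores[sr.start:sr.stop]))]
    if severity == HEALTHY:
        disease = None
    else:
        disease = space.diseases[int(np.argmax(scores[dr.start:dr.stop]))]
    return TripleLabel(plant, disease, severity)


# --------------------------------------------------------------------------
# manifest I/O
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    triple: TripleLabel


class ManifestError(ValueError):
    pass


MANIFEST_HEADER = ["path", "plant", "disease", "severity"]


def read_manifest(csv_path, space: LabelSpace) -> list[ManifestRecord]:
    """Read and validate a ``path,plant,disease,severity`` manifest.

    An empty disease field denotes a healthy image.
    """
    records = []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANIFEST_HEADER:
            raise ManifestError(
                f"{csv_path}: expected header {','.join(MANIFEST_HEADER)}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ManifestError(f"{csv_path}:{lineno}: expected 4 fields, got {len(row)}")
            path, plant, disease, severity = row
            if not path:
                raise ManifestError(f"{csv_path}:{lineno}: empty image path")
            try:
                triple = TripleLabel(plant, disease or None, severity)
                encode_triple(space, triple)  # raises on unknown names
            except LabelSpaceError as e:
                raise ManifestError(f"{csv_path}:{lineno}: {e}") from e
            records.append(ManifestRecord(path, triple))
    return records


def write_manifest(records, csv_path) -> None:
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_HEADER)
        for rec in records:
            t = rec.triple
            writer.writerow([rec.image_path, t.plant, t.disease or "", t.severity])


# --------------------------------------------------------------------------
# stratified split
# --------------------------------------------------------------------------

def split_stratified(records, train_fraction: float, seed: int):
    """Proportional stratified split over plant-disease-severity classes.

    Within each combination class, round(train_fraction * n) records (half-up)
    go to the training part; the remainder to validation.  Deterministic for a
    given seed.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    by_class: dict[tuple, list] = {}
    for rec in records:
        key = (rec.triple.plant, rec.triple.disease, rec.triple.severity)
        by_class.setdefault(key, []).append(rec)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for key in sorted(by_class, key=lambda k: (k[0], k[1] or "", k[2])):
        members = by_class[key]
        order = rng.permutation(len(members))
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        for pos, idx in enumerate(order):
            (train if pos < n_train else val).append(members[idx])
    return train, val


# --------------------------------------------------------------------------
# packaged count-table fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTableFixture:
    """Per-class train/val/test image counts for one label group."""

    group: str
    rows: dict  # name -> (train, val, test)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rows)


_FIXTURE_FILES = {
    "plant": "table_plants.csv",
    "disease": "table_diseases.csv",
    "severity": "table_severities.csv",
}
_COLUMNS = {"train": 0, "val": 1, "test": 2}


def load_fixture(group: str) -> CountTableFixture:
    """Load the packaged per-group count table (group: plant|disease|severity)."""
    try:
        fname = _FIXTURE_FILES[group]
    except KeyError:
        raise ValueError(f"unknown fixture group: {group!r}") from None
    ref = importlib.resources.files("ldinet").joinpath("data", fname)
    rows = {}
    with ref.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            counts = (int(row["train"]), int(row["val"]), int(row["test"]))
            if any(c < 0 for c in counts):
                raise ValueError(f"negative count in fixture {group}: {row}")
            rows[row["name"]] = counts
    return CountTableFixture(group, rows)


def sum_fixture_column(fixture: CountTableFixture, column: str) -> int:
    """Exact integer sum of one column (train, val or test)."""
    try:
        idx = _COLUMNS[column]
    except KeyError:
        raise ValueError(f"unknown column {column!r}; expected one of {list(_COLUMNS)}") from None
    return sum(counts[idx] for counts in fixture.rows.values())
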