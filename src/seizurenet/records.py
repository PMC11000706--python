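"""Reading, validating and labelling Bonn-layout single-channel EEG records.

The Bonn corpus ships five sets (A, B: surface recordings from healthy
volunteers, eyes open/closed; C, D: intracranial interictal recordings from
the contralateral hippocampus and the epileptogenic zone; E: ictal seizure
recordings).  Each set holds 100 plain-text files, one integer ADC sample
per line, 4,097 samples at 173.61 Hz.  On disk the set folders are
conventionally named Z, O, N, F and S; the mapping is configurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SET_IDS = ("A", "B", "C", "D", "E")

#: Conventional on-disk folder name for each set.
DEFAULT_FOLDER_MAP: dict[str, str] = {
    "A": "Z", "B": "O", "C": "N", "D": "F", "E": "S",
}

DEFAULT_FS = 173.61
DEFAULT_N_POINTS = 4097


class RecordParseError(ValueError):
    """A sample line in a record file could not be parsed."""


class RecordValidationError(ValueError):
    """A record or task definition violates its contract."""


@dataclass
class EEGRecord:
    """One single-channel EEG signal with its provenance.

    Parameters
    ----------
    samples : np.ndarray
        Amplitudes in arbitrary ADC units, file order.
    fs : float
        Sampling frequency in Hz.
    set_id : str
        One of A-E (or the synthetic surrogate of that set).
    source_id : str
        Unique identifier of the originating file or synthetic seed.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    set_id: str = "A"
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise RecordValidationError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            raise RecordValidationError("samples must be finite")
        if not self.fs > 0:
            raise RecordValidationError("sampling frequency must be positive")
        if self.set_id not in SET_IDS:
            raise RecordValidationError(
                f"set_id must be one of {SET_IDS}, got {self.set_id!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs


#: Table-1 task groupings.  Class indices run left to right in the task name
#: (healthy lowest, seizure highest) so confusion matrices share orientation.
TASK_CLASS_MAPS: dict[str, dict[str, int]] = {
    "A-E": {"A": 0, "E": 1},
    "B-E": {"B": 0, "E": 1},
    "AB-CD-E": {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2},
    "AB-C-D-E": {"A": 0, "B": 0, "C": 1, "D": 2, "E": 3},
    "A-B-C-D-E": {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4},
}

TASK_NAMES = tuple(TASK_CLASS_MAPS)


def normalize_task_name(name: str) -> str:
    """Accept hyphen/en-dash/em-dash spellings and any case."""
    cleaned = name.strip().upper().replace("–", "-").replace(
        "—", "-").replace("‒", "-")
    if cleaned not in TASK_CLASS_MAPS:
        raise RecordValidationError(
            f"unknown task {name!r}; expected one of {', '.join(TASK_NAMES)}")
    return cleaned


@dataclass
class TaskSpec:
    """A classification task: which sets participate and their class index."""

    name: str
    class_map: dict[str, int] = field(default_factory=dict)
    n_classes: int = 0

    @classmethod
    def from_name(cls, name: str) -> "TaskSpec":
        canonical = normalize_task_name(name)
        cmap = dict(TASK_CLASS_MAPS[canonical])
        return cls(name=canonical, class_map=cmap,
                   n_classes=max(cmap.values()) + 1)

    def __post_init__(self):
        if self.class_map and sorted(set(self.class_map.values())) != list(
                range(max(self.class_map.values()) + 1)):
            raise RecordValidationError("class indices must be contiguous")


def read_record(path: str | Path, expected_length: int | None = None,
                fs: float = DEFAULT_FS, set_id: str = "A") -> EEGRecord:
    """Read one Bonn-dialect record file (one sample per line).

    Blank lines and surrounding whitespace are tolerated.  A line that does
    not parse as a number raises :class:`RecordParseError` naming the line;
    a length mismatch raises :class:`RecordValidationError`.
    """
    path = Path(path)
    values: list[float] = []
    with path.open("r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                value = float(stripped)
            except ValueError as exc:
                raise RecordParseError(
                    f"{path}: line {lineno}: cannot parse {stripped!r} "
                    "as a sample") from exc
            if not math.isfinite(value):
                raise RecordParseError(
                    f"{path}: line {lineno}: non-finite sample {stripped!r}")
            values.append(value)
    if not values:
        raise RecordValidationError(f"{path}: no samples found")
    if expected_length is not None and len(values) != expected_length:
        raise RecordValidationError(
            f"{path}: expected {expected_length} samples, found {len(values)}")
    return EEGRecord(samples=np.array(values), fs=fs, set_id=set_id,
                     source_id=path.stem)


def write_record(record: EEGRecord, path: str | Path) -> None:
    """Write a record in the Bonn dialect (one integer per line).

    Samples are rounded to the nearest integer, matching the corpus's
    12-bit ADC output; integer-valued inputs round-trip exactly.
    """
    path = Path(path)
    with path.open("w", encoding="ascii") as fh:
        for v in np.rint(record.samples).astype(np.int64):
            fh.write(f"{v}\n")


def load_set(root: str | Path, set_id: str,
             folder_map: dict[str, str] | None = None,
             expected_length: int | None = None,
             fs: float = DEFAULT_FS) -> list[EEGRecord]:
    """Load every record of one set, sorted lexicographically by filename."""
    if set_id not in SET_IDS:
        raise RecordValidationError(f"unknown set id {set_id!r}")
    folder_map = folder_map or DEFAULT_FOLDER_MAP
    root = Path(root)
    folder = root / folder_map[set_id]
    if not folder.is_dir():
        # also accept the literal set letter as the folder name
        alt = root / set_id
        if alt.is_dir():
            folder = alt
        else:
            raise FileNotFoundError(
                f"no folder for set {set_id} under {root} "
                f"(looked for {folder_map[set_id]!r} and {set_id!r})")
    files = sorted(p for p in folder.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    if not files:
        raise RecordValidationError(f"{folder}: no record files found")
    return [read_record(p, expected_length=expected_length, fs=fs,
                        set_id=set_id) for p in files]


def load_sets(root: str | Path, set_ids: tuple[str, ...] = SET_IDS,
              **kwargs) -> list[EEGRecord]:
    """Load several sets in A..E order."""
    records: list[EEGRecord] = []
    for sid in set_ids:
        records.extend(load_set(root, sid, **kwargs))
    return records


def make_task(records: list[EEGRecord],
              task_name: str) -> tuple[TaskSpec, list[tuple[EEGRecord, int]]]:
    """Pair records with class indices for a task.

    Records from sets the task does not use are excluded (e.g. C and D for
    A-E).  Label assignment is deterministic in the input order.
    """
    task = TaskSpec.from_name(task_name)
    labelled = [(rec, task.class_map[rec.set_id]) for rec in records
                if rec.set_id in task.class_map]
    return task, labelled
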