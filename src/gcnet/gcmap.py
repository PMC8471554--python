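"""Granger-causality map data model, file I/O and aggregation.

A GC map is a weighted directed graph over iEEG electrodes: ``weights[i, j]``
is the Granger-causality magnitude of node ``i`` (source, "cause") acting on
node ``j`` (target). Row = source, column = target, everywhere in this
package; :func:`reverse` transposes the map so files stored with the opposite
orientation can be accommodated with one call.

File dialect: dense CSV or TSV, optionally with a first header row of node
labels. Label sets (seizure onset zone, resection zone) are JSON lists of
strings or newline-delimited text. A patient manifest is one YAML/JSON file
listing segment matrix paths plus the label-set files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "FormatError",
    "DataError",
    "GCMap",
    "TransitionModel",
    "PatientRecord",
    "load_gc_map",
    "save_gc_map",
    "reverse",
    "to_transition",
    "aggregate",
    "load_label_set",
    "load_patient",
    "save_patient",
]


class FormatError(ValueError):
    """Structurally malformed input (non-square matrix, ragged rows...)."""


class DataError(ValueError):
    """Well-formed input carrying invalid values (NaN, negative weight...)."""


@dataclass
class GCMap:
    """N x N nonnegative directed weight matrix with ordered node labels.

    ``weights[i, j]`` is the GC influence of node ``i`` on node ``j``
    (unitless GC magnitude). The diagonal is exactly zero: no self-edges.
    """

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"weight matrix must be square, got shape {w.shape}")
        if np.isnan(w).any():
            raise DataError("weight matrix contains NaN")
        if (w < 0).any():
            raise DataError("weight matrix contains negative entries")
        if np.diag(w).any():
            raise DataError("diagonal (self-edge) entries must be zero")
        labels = [str(x) for x in self.labels]
        if len(labels) != w.shape[0]:
            raise FormatError(
                f"{len(labels)} labels for a {w.shape[0]}-node matrix"
            )
        if len(set(labels)) != len(labels):
            raise FormatError("node labels must be unique")
        self.weights = w
        self.labels = labels

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def reverse(self) -> "GCMap":
        return reverse(self)

    def to_transition(self) -> "TransitionModel":
        return to_transition(self)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GCMap)
            and self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
        )


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition probabilities derived from a GCMap.

    Rows with positive out-weight sum to 1; rows of nodes with no surviving
    outgoing edges (dangling nodes) are all-zero and their indices listed in
    ``dangling``. Dangling nodes terminate random-walk chains.
    """

    probs: np.ndarray
    dangling: frozenset[int]

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class PatientRecord:
    """Per-segment GC maps plus clinician-labelled SOZ and RZ node sets.

    ``rz`` may be empty: not every monitored patient proceeds to resection.
    All segment maps must share one label list, in one order.
    """

    segments: list[GCMap]
    soz: set[str]
    rz: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.segments:
            raise FormatError("a patient record needs at least one segment map")
        labels = self.segments[0].labels
        for i, seg in enumerate(self.segments[1:], start=1):
            if seg.labels != labels:
                raise FormatError(f"segment {i} labels differ from segment 0")
        known = set(labels)
        self.soz = set(map(str, self.soz))
        self.rz = set(map(str, self.rz))
        for name, targets in (("soz", self.soz), ("rz", self.rz)):
            extra = targets - known
            if extra:
                raise DataError(f"{name} labels not in node set: {sorted(extra)}")

    @property
    def labels(self) -> list[str]:
        return self.segments[0].labels

    @property
    def n(self) -> int:
        return self.segments[0].n


def _parse_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    lines = [ln for ln in Path(path).read_text().strip().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    first = [tok.strip() for tok in lines[0].split(delim)]
    header: list[str] | None
    try:
        [float(tok) for tok in first]
        header = None
    except ValueError:
        header = first
    rows = []
    for ln in lines[1 if header else 0:]:
        try:
            rows.append([float(tok) for tok in ln.split(delim)])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.array(rows, dtype=float), header


def load_gc_map(path: str | Path, labels_path: str | Path | None = None) -> GCMap:
    """Read a dense CSV/TSV GC matrix (row = source node, column = target).

    Labels come from, in order of precedence: ``labels_path`` (JSON list or
    newline-delimited text), a non-numeric header row in the matrix file, or
    the defaults ``n0..n{N-1}``.
    """
    w, header = _parse_matrix(path)
    if w.shape[0] != w.shape[1]:
        raise FormatError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, not square")
    if labels_path is not None:
        labels = load_label_set(labels_path, ordered=True)
    elif header is not None:
        labels = header
    else:
        labels = [f"n{i}" for i in range(w.shape[0])]
    return GCMap(w, list(labels))


def save_gc_map(g: GCMap, path: str | Path, *, header: bool = True) -> None:
    """Write a GCMap in the CSV dialect (17 significant digits, round-trip safe)."""
    out = []
    if header:
        out.append(",".join(g.labels))
    for row in g.weights:
        out.append(",".join(f"{x:.17g}" for x in row))
    Path(path).write_text("\n".join(out) + "\n")


def reverse(g: GCMap) -> GCMap:
    """Transpose the map: an edge "i causes j" becomes "j causes i".

    This is the "uphill" orientation: walking or ranking the reversed map
    favours generators of activity over receivers.
    """
    return GCMap(g.weights.T.copy(), list(g.labels))


def to_transition(g: GCMap) -> TransitionModel:
    """Row-normalize weights to transition probabilities.

    Each node's outgoing edge weights are divided by their sum so they add up
    to one; nodes without outgoing edges are recorded as dangling and keep an
    all-zero row (they are never patched with uniform probabilities — a walk
    that lands on one stops).
    """
    sums = g.weights.sum(axis=1)
    dangling = frozenset(int(i) for i in np.flatnonzero(sums == 0))
    probs = np.zeros_like(g.weights)
    live = sums > 0
    probs[live] = g.weights[live] / sums[live, None]
    return TransitionModel(probs, dangling)


def aggregate(maps: list[GCMap], method: str = "mean") -> GCMap:
    """Elementwise mean (default) or sum of segment maps sharing one label list."""
    if not maps:
        raise FormatError("aggregate needs at least one map")
    labels = maps[0].labels
    for i, m in enumerate(maps[1:], start=1):
        if m.labels != labels:
            raise FormatError(f"map {i} labels differ from map 0")
    stack = np.stack([m.weights for m in maps])
    if method == "mean":
        w = stack.mean(axis=0)
    elif method == "sum":
        w = stack.sum(axis=0)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return GCMap(w, list(labels))


def load_label_set(path: str | Path, *, ordered: bool = False):
    """Read node labels from a JSON list or newline-delimited text file."""
    text = Path(path).read_text()
    try:
        labels = json.loads(text)
        if not isinstance(labels, list):
            raise FormatError(f"{path}: JSON label file must hold a list")
        labels = [str(x) for x in labels]
    except json.JSONDecodeError:
        labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    return labels if ordered else set(labels)


def load_patient(manifest_path: str | Path) -> PatientRecord:
    """Build a PatientRecord from a YAML/JSON manifest.

    Manifest keys: ``segments`` (list of matrix paths), optional ``labels``
    (label file applied to every segment), ``soz`` and optional ``rz``
    (label-set files). Relative paths resolve against the manifest directory.
    """
    manifest_path = Path(manifest_path)
    try:
        spec = yaml.safe_load(manifest_path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{manifest_path}: unparseable manifest ({exc})") from exc
    if not isinstance(spec, dict) or "segments" not in spec or "soz" not in spec:
        raise FormatError(f"{manifest_path}: manifest needs 'segments' and 'soz' keys")
    base = manifest_path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    labels_path = _resolve(spec["labels"]) if spec.get("labels") else None
    segments = [load_gc_map(_resolve(p), labels_path) for p in spec["segments"]]
    soz = load_label_set(_resolve(spec["soz"]))
    rz = load_label_set(_resolve(spec["rz"])) if spec.get("rz") else set()
    return PatientRecord(segments, soz, rz)


def save_patient(record: PatientRecord, out_dir: str | Path, *, name: str = "patient") -> Path:
    """Write a PatientRecord as segment CSVs + label-set files + manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seg_paths = []
    for i, seg in enumerate(record.segments):
        p = f"segment{i:03d}.csv"
        save_gc_map(seg, out_dir / p)
        seg_paths.append(p)
    (out_dir / "soz.json").write_text(json.dumps(sorted(record.soz)))
    manifest = {"segments": seg_paths, "soz": "soz.json"}
    if record.rz:
        (out_dir / "rz.json").write_text(json.dumps(sorted(record.rz)))
        manifest["rz"] = "rz.json"
    manifest_path = out_dir / f"{name}.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
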