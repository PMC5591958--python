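"""Readers and writers for every external format the pipeline touches.

One authoritative parser/writer per format:

* expression matrices and detection flags — CSV/TSV, features in rows,
  samples in columns, first column holds the feature identifier;
* sample metadata — TSV with ``sample_id``, ``group`` and EMP counts/μl;
* genomic loci — BED, 0-based half-open, with the region label carried in
  column 7 (non-standard but BED-tolerant);
* gene sets — GMT;
* networks — GraphML (attributes preserved) and SIF (``nodeA pp nodeB``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

VALID_GROUPS = ("TAV", "BAV", "BAV_dil")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature-by-sample log-intensity matrix with per-cell detection flags.

    ``values[i, j]`` is the log2 intensity of feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``; ``detected`` has the same shape and marks the
    cells in which the platform called the feature present.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.detected is None:
            self.detected = np.ones(self.values.shape, dtype=bool)
        self.detected = np.asarray(self.detected, dtype=bool)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise ParseError(f"duplicate feature ID {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample IDs")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ParseError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.detected.shape != self.values.shape:
            raise ParseError("detection matrix shape differs from value matrix")
        if not np.isfinite(self.values[self.detected]).all():
            raise ParseError("non-finite value in a detected cell")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, feature_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``feature_ids`` (order preserved)."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing[:5]}")
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(
            list(feature_ids), list(self.sample_ids),
            self.values[rows].copy(), self.detected[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _sniff_sep(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_expression(path: str, detection_path: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix (and optional 0/1 detection-flag matrix).

    The delimiter is sniffed from the extension (``.tsv`` → tab, else comma).
    When no detection file is given every cell counts as detected.
    """
    values = _read_matrix(path)
    detected = None
    if detection_path is not None:
        det = _read_matrix(detection_path)
        if list(det.index) != list(values.index) or list(det.columns) != list(values.columns):
            raise ParseError("detection matrix IDs do not match the expression matrix")
        detected = det.to_numpy().astype(bool)
    return ExpressionMatrix(
        list(values.index), list(values.columns), values.to_numpy(), detected
    )


def _read_matrix(path: str) -> pd.DataFrame:
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except ValueError as exc:  # ragged rows and friends
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature ID {dup!r}")
    non_numeric = df.columns[[df[c].dtype == object for c in df.columns]]
    if len(non_numeric):
        for line_no, (_, row) in enumerate(df.iterrows(), start=2):
            try:
                row.astype(float)
            except (TypeError, ValueError):
                raise ParseError(f"{path}: non-numeric cell on line {line_no}") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(expr: ExpressionMatrix, path: str,
                     detection_path: str | None = None) -> None:
    sep = _sniff_sep(path)
    expr.to_frame().rename_axis("feature_id").to_csv(path, sep=sep)
    if detection_path is not None:
        pd.DataFrame(
            expr.detected.astype(int), index=expr.feature_ids, columns=expr.sample_ids
        ).rename_axis("feature_id").to_csv(detection_path, sep=_sniff_sep(detection_path))


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table (sample_id, group, emp_per_ul [, log_emp])."""
    required = {"sample_id", "group", "emp_per_ul"}
    missing = required - set(samples.columns)
    if missing:
        raise ParseError(f"sample table lacks columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample ID {dup!r}")
    bad = set(samples["group"]) - set(VALID_GROUPS)
    if bad:
        raise ParseError(f"unknown group labels {sorted(bad)}; expected {VALID_GROUPS}")
    if (samples["emp_per_ul"] <= 0).any():
        sid = samples.loc[samples["emp_per_ul"] <= 0, "sample_id"].iloc[0]
        raise ParseError(f"non-positive EMP count for sample {sid!r}")
    if "log_emp" in samples.columns:
        if not np.allclose(samples["log_emp"], np.log(samples["emp_per_ul"]), atol=1e-12):
            raise ParseError("log_emp column is not ln(emp_per_ul)")
    return samples


def read_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic loci (BED) and gene sets (GMT)
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Parse a BED file into a locus table.

    Coordinates are 0-based half-open.  Column 7, when present, is read as
    the region label (e.g. ``14q32-clusterB``); otherwise the region label
    defaults to the chromosome name.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{line_no}: expected >=4 BED columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{line_no}: non-integer interval") from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{line_no}: malformed interval [{start}, {end})"
                )
            region = parts[6] if len(parts) >= 7 else chrom
            records.append((name, chrom, start, end, region))
    loci = pd.DataFrame(
        records, columns=["feature_id", "chrom", "start", "end", "region"]
    )
    if loci["feature_id"].duplicated().any():
        dup = loci.loc[loci["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ParseError(f"{path}: feature {dup!r} annotated more than once")
    return loci


def write_bed(loci: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for rec in loci.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.feature_id}\t0\t+\t{rec.region}\n"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise ParseError(f"gene set {name!r} is empty")
            self.sets[name] = deduped
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{line_no}: GMT line needs name, description, members")
            name, description, members = parts[0], parts[1], [m for m in parts[2:] if m]
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str, fmt: str = "graphml") -> None:
    """Export a network as GraphML (attributes kept) or SIF (topology only)."""
    if fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\tpp\t{v}\n")
            for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'graphml' or 'sif'")


def read_network(path: str) -> nx.Graph:
    return nx.read_graphml(path)


def checksum(path: str) -> str:
    """SHA-256 of a file, used by the pipeline manifest."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def relpath_all(paths: dict[str, str], root: str) -> dict[str, str]:
    return {k: os.path.relpath(v, root) for k, v in paths.items()}
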