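"""Expression matrices and clinical annotation.

Reads and writes gene-by-sample expression tables, collapses platform
probesets to gene symbols, and assigns patients to survival-derived risk
groups. Expression values are assumed preprocessed (log-intensity or
level-3 counts); no normalization is performed here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

RISK_HIGH = "high"
RISK_LOW = "low"
RISK_EXCLUDED = "excluded"

_SEPS = {"tsv": "\t", "csv": ","}


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of real expression values.

    ``gene_ids`` may contain duplicates before probeset collapsing;
    ``sample_ids`` never may. Values must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.sample_ids)
        if dup:
            raise DataError(f"duplicate sample ids: {sorted(dup)}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes not in matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise DataError(f"samples not in matrix: {missing[:10]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class SampleAnnotation:
    """Clinical annotation for one sample.

    ``event`` is True when death was observed, False for censoring.
    ``risk_label`` is populated by :func:`assign_risk`.
    """

    sample_id: str
    survival_days: int | None = None
    event: bool | None = None
    subtype: str | None = None
    risk_label: str | None = None


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _infer_fmt(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPS:
            raise DataError(f"unknown format {fmt!r}; expected one of {sorted(_SEPS)}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    return suffix if suffix in _SEPS else "tsv"


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression table.

    First column holds gene/probeset ids, header row holds sample ids.
    Duplicate gene ids are permitted (pre-collapse); duplicate sample ids
    and non-numeric cells raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = _SEPS[_infer_fmt(path, fmt)]
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    fields = header.split(sep)
    if len(fields) < 2:
        raise DataError(f"malformed header in {path}: expected >=2 {sep!r}-separated columns")
    sample_ids = fields[1:]
    dup = _duplicates(sample_ids)
    if dup:
        raise DataError(f"duplicate sample ids in header of {path}: {sorted(dup)}")

    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    df.columns = sample_ids
    raw = df.to_numpy()
    try:
        # numpy's parser is correctly rounded, so written files re-read exactly
        values = raw.astype(float)
    except ValueError:
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"non-numeric cell {cell!r} at gene {df.index[r]!r}, "
                    f"sample {df.columns[c]!r} in {path}"
                ) from None
        raise
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise DataError(
            f"missing or non-finite value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    return ExpressionMatrix(list(df.index), sample_ids, values)


def write_expression(mat: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    sep = _SEPS[_infer_fmt(path, fmt)]
    mat.to_frame().to_csv(path, sep=sep, index_label="gene_id", lineterminator="\n")


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column probeset -> gene-symbol TSV."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (i == 0 and row[0].lower() in {"probeset_id", "probeset"}):
                continue
            if len(row) < 2:
                raise DataError(f"mapping line {i + 1} has fewer than two columns")
            mapping[row[0]] = row[1]
    return mapping


_COLLAPSE_SCORES = {"mean": np.mean, "max": np.max, "median": np.median}


def collapse_probesets(
    mat: ExpressionMatrix,
    mapping: Mapping[str, str],
    method: str = "mean",
) -> ExpressionMatrix:
    """Collapse probesets mapping to the same gene symbol to a single row.

    For every symbol the probeset with the maximal summary ``method``
    (mean by default) across samples is retained; ties are broken by the
    lexicographically smallest probeset id. Unmapped probesets are dropped.
    """
    if not mapping:
        raise DataError("probeset mapping is empty")
    if method not in _COLLAPSE_SCORES:
        raise DataError(f"unknown collapse method {method!r}; expected one of {sorted(_COLLAPSE_SCORES)}")
    score = _COLLAPSE_SCORES[method]

    best: dict[str, tuple[float, str, int]] = {}  # symbol -> (score, probeset id, row)
    for row, probeset in enumerate(mat.gene_ids):
        symbol = mapping.get(probeset)
        if symbol is None:
            continue
        s = float(score(mat.values[row]))
        cur = best.get(symbol)
        # maximal score; tie -> lexicographically smallest probeset id
        if cur is None or s > cur[0] or (s == cur[0] and probeset < cur[1]):
            best[symbol] = (s, probeset, row)
    symbols = sorted(best)
    rows = [best[sym][2] for sym in symbols]
    return ExpressionMatrix(symbols, list(mat.sample_ids), mat.values[rows])


def assign_risk(
    annotations: Sequence[SampleAnnotation],
    mode: str = "survival_cutoff",
    cutoff_days: int = 365,
    low_risk_subtype: str = "PN",
) -> list[SampleAnnotation]:
    """Label every sample high/low/excluded risk.

    Survival mode: survival strictly longer than ``cutoff_days`` -> low;
    otherwise high, except patients censored (alive) strictly before the
    cutoff, which are flagged excluded rather than dropped. Subtype mode:
    ``low_risk_subtype`` -> low, all other subtypes -> high.
    """
    if mode not in {"survival_cutoff", "subtype"}:
        raise DataError(f"unknown risk mode {mode!r}")
    out: list[SampleAnnotation] = []
    if mode == "survival_cutoff":
        missing = [a.sample_id for a in annotations if a.survival_days is None or a.event is None]
        if missing:
            raise DataError(f"samples missing survival_days/event: {missing}")
        for a in annotations:
            if a.survival_days > cutoff_days:
                label = RISK_LOW
            elif not a.event and a.survival_days < cutoff_days:
                label = RISK_EXCLUDED
            else:
                label = RISK_HIGH
            out.append(replace(a, risk_label=label))
    else:
        missing = [a.sample_id for a in annotations if a.subtype is None]
        if missing:
            raise DataError(f"samples missing subtype: {missing}")
        for a in annotations:
            label = RISK_LOW if a.subtype == low_risk_subtype else RISK_HIGH
            out.append(replace(a, risk_label=label))
    return out


def read_annotation(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (sample_id, survival_days, event, subtype)."""
    if not Path(path).exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise DataError(f"annotation file {path} lacks a sample_id column")
    out = []
    for _, row in df.iterrows():
        days = row.get("survival_days")
        event = row.get("event")
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                survival_days=None if pd.isna(days) else int(float(days)),
                event=None if pd.isna(event) else bool(int(float(event))),
                subtype=None if pd.isna(row.get("subtype")) else str(row.get("subtype")),
                risk_label=None if pd.isna(row.get("risk_label")) else str(row.get("risk_label")),
            )
        )
    dup = _duplicates(a.sample_id for a in out)
    if dup:
        raise DataError(f"duplicate sample ids in annotation: {sorted(dup)}")
    return out


def write_annotation(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "survival_days": "" if a.survival_days is None else a.survival_days,
            "event": "" if a.event is None else int(a.event),
            "subtype": "" if a.subtype is None else a.subtype,
            "risk_label": "" if a.risk_label is None else a.risk_label,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def risk_labels(annotations: Sequence[SampleAnnotation]) -> dict[str, str]:
    """sample_id -> risk label mapping; labels must have been assigned."""
    missing = [a.sample_id for a in annotations if a.risk_label is None]
    if missing:
        raise DataError(f"samples without risk label: {missing}")
    return {a.sample_id: a.risk_label for a in annotations}
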