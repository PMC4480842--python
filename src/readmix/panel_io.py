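"""Reference-panel and query I/O.

A reference panel is a table with one row per modern population: a unique
name, geographic coordinates (decimal degrees, WGS84), and K admixture
proportions giving the population's mean position on the standard
(K-1)-simplex.  Optional columns carry per-component variances and the
number of individuals the mean was computed from.

Query individuals arrive as rows of an ADMIXTURE-style Q matrix:
whitespace-separated proportions, one individual per line, no header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelFormatError",
    "SimplexValidationError",
    "PopulationRecord",
    "ReferencePanel",
    "validate_simplex",
    "read_panel",
    "read_q_matrix",
    "write_report",
    "read_report",
]

#: tolerance on |sum - 1| within which a raw vector is renormalized
SUM_TOL = 0.01
#: tolerance a validated vector must satisfy
STRICT_TOL = 1e-6


class PanelFormatError(ValueError):
    """Malformed panel or Q-matrix file (columns, names, shapes)."""


class SimplexValidationError(ValueError):
    """A proportion vector violates the simplex constraints."""


def validate_simplex(v: Sequence[float], tol: float = SUM_TOL) -> np.ndarray:
    """Validate a raw vector of proportions and return it as a simplex point.

    Negative entries are rejected outright.  If the entries sum to 1
    within ``tol`` the vector is renormalized to sum to exactly 1;
    otherwise a :class:`SimplexValidationError` is raised.
    """
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise SimplexValidationError(
            f"expected a 1-D vector with K >= 2 components, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise SimplexValidationError("non-finite component in proportion vector")
    if np.any(arr < 0):
        raise SimplexValidationError(
            f"negative component in proportion vector: {arr[arr < 0].min():g}"
        )
    total = arr.sum()
    if abs(total - 1.0) > tol:
        raise SimplexValidationError(
            f"components sum to {total:g}, outside 1 +/- {tol:g}"
        )
    return arr / total


@dataclasses.dataclass(frozen=True)
class PopulationRecord:
    """One modern reference population."""

    name: str
    latitude: float
    longitude: float
    admixture: np.ndarray
    variance: np.ndarray | None = None
    sample_n: int | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise PanelFormatError(
                f"{self.name}: latitude {self.latitude} outside [-90, 90]"
            )
        lon = self.longitude
        if not -180.0 <= lon <= 360.0:
            raise PanelFormatError(f"{self.name}: longitude {lon} out of range")
        # normalize longitude to (-180, 180]
        if lon > 180.0:
            object.__setattr__(self, "longitude", lon - 360.0)
        object.__setattr__(self, "admixture", validate_simplex(self.admixture))
        if self.variance is not None:
            var = np.asarray(self.variance, dtype=float)
            if var.shape != self.admixture.shape or np.any(var < 0):
                raise PanelFormatError(
                    f"{self.name}: variance must be {self.admixture.size} "
                    "nonnegative values"
                )
            object.__setattr__(self, "variance", var)
        if self.sample_n is not None and self.sample_n < 1:
            raise PanelFormatError(f"{self.name}: sample_n must be >= 1")

    @property
    def coords(self) -> tuple[float, float]:
        return (self.latitude, self.longitude)


class ReferencePanel:
    """Ordered collection of :class:`PopulationRecord` sharing one K.

    Exposes the admixture proportions as an (N, K) matrix ``R`` whose rows
    are the population vectors used throughout the decomposition.
    """

    def __init__(self, records: Sequence[PopulationRecord]):
        records = list(records)
        if not records:
            raise PanelFormatError("panel must contain at least one population")
        K = records[0].admixture.size
        for rec in records:
            if rec.admixture.size != K:
                raise PanelFormatError(
                    f"{rec.name}: K={rec.admixture.size} differs from panel K={K}"
                )
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelFormatError(f"duplicate population names: {dupes}")
        self.records = records
        self.K = K
        self._index = {name: i for i, name in enumerate(names)}
        self.R = np.vstack([r.admixture for r in records])
        self.coords = np.array([(r.latitude, r.longitude) for r in records])
        if all(r.variance is not None for r in records):
            self.variances: np.ndarray | None = np.vstack(
                [r.variance for r in records]
            )
        else:
            self.variances = None

    def __len__(self) -> int:
        return len(self.records)

    def pairwise_km(self) -> np.ndarray:
        """N x N great-circle distance matrix (km), computed once."""
        cached = getattr(self, "_pairwise_km", None)
        if cached is None:
            lat = np.radians(self.coords[:, 0])[:, None]
            lon = np.radians(self.coords[:, 1])[:, None]
            s = (
                np.sin((lat.T - lat) / 2) ** 2
                + np.cos(lat) * np.cos(lat.T) * np.sin((lon.T - lon) / 2) ** 2
            )
            cached = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
            self._pairwise_km = cached
        return cached

    def __getitem__(self, i: int) -> PopulationRecord:
        return self.records[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"population {name!r} not in panel") from None


def _panel_columns(columns: Sequence[str]) -> tuple[list[str], list[str], bool]:
    cols = list(columns)
    for required in ("population", "lat", "lon"):
        if required not in cols:
            raise PanelFormatError(f"panel is missing required column {required!r}")
    comp = sorted(
        (c for c in cols if c.startswith("c") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not comp:
        raise PanelFormatError("panel has no admixture columns c1..cK")
    if [int(c[1:]) for c in comp] != list(range(1, len(comp) + 1)):
        raise PanelFormatError(f"admixture columns not contiguous c1..cK: {comp}")
    var = sorted(
        (c for c in cols if c.startswith("v") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if var and len(var) != len(comp):
        raise PanelFormatError("variance columns v1..vK must match c1..cK")
    return comp, var, "n" in cols


def read_panel(path: str | Path, dialect: str = "csv") -> ReferencePanel:
    """Read a reference panel from a delimited text file.

    The header must name the columns ``population, lat, lon, c1..cK``
    with optional ``v1..vK`` (per-component variances) and ``n``
    (sample size).  Row order is preserved.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    comp_cols, var_cols, has_n = _panel_columns(df.columns)
    records = []
    for i, row in df.iterrows():
        name = str(row["population"])
        try:
            admix = validate_simplex(row[comp_cols].to_numpy(dtype=float))
        except SimplexValidationError as exc:
            raise SimplexValidationError(f"row {i} ({name}): {exc}") from exc
        records.append(
            PopulationRecord(
                name=name,
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                admixture=admix,
                variance=row[var_cols].to_numpy(dtype=float) if var_cols else None,
                sample_n=int(row["n"]) if has_n and not pd.isna(row["n"]) else None,
            )
        )
    return ReferencePanel(records)


def write_panel(panel: ReferencePanel, path: str | Path, dialect: str = "csv") -> None:
    """Write a panel back to the delimited format accepted by read_panel."""
    sep = "," if dialect == "csv" else "\t"
    data: dict[str, list] = {
        "population": panel.names,
        "lat": [r.latitude for r in panel.records],
        "lon": [r.longitude for r in panel.records],
    }
    for k in range(panel.K):
        data[f"c{k + 1}"] = panel.R[:, k]
    if panel.variances is not None:
        for k in range(panel.K):
            data[f"v{k + 1}"] = panel.variances[:, k]
    if all(r.sample_n is not None for r in panel.records):
        data["n"] = [r.sample_n for r in panel.records]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_q_matrix(path: str | Path) -> list[np.ndarray]:
    """Read admixture vectors from a plain whitespace-separated Q matrix.

    One individual per line, K numeric columns, no header — the format
    written by supervised ADMIXTURE runs.
    """
    vectors: list[np.ndarray] = []
    K: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = np.array([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise PanelFormatError(f"line {lineno}: non-numeric entry") from exc
            if K is None:
                K = row.size
            elif row.size != K:
                raise PanelFormatError(
                    f"line {lineno}: {row.size} values, expected {K}"
                )
            try:
                vectors.append(validate_simplex(row))
            except SimplexValidationError as exc:
                raise SimplexValidationError(f"line {lineno}: {exc}") from exc
    if not vectors:
        raise PanelFormatError("Q matrix is empty")
    return vectors


def _report_to_dict(result) -> dict:
    return {
        "mode": result.mode,
        "unmixed": bool(result.unmixed),
        "prior_discarded": bool(result.prior_discarded),
        "minimax_error": round(float(result.minimax_error), 6),
        "stable": [
            {
                "population": name,
                "weight": round(float(w), 6),
                "membership": round(float(frac), 6),
                "lat": round(float(lat), 6),
                "lon": round(float(lon), 6),
            }
            for name, w, frac, (lat, lon) in result.stable_with_coords()
        ],
        "regional": [
            {"population": name, "membership": round(float(frac), 6)}
            for name, frac in result.regional
        ],
    }


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize an ensemble report to JSON or TSV.

    The JSON form round-trips through :func:`read_report` losslessly at
    six decimal places.
    """
    payload = _report_to_dict(result)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        lines = [
            "population\tweight\tmembership\tlat\tlon\tkind",
        ]
        for entry in payload["stable"]:
            lines.append(
                f"{entry['population']}\t{entry['weight']:.6f}\t"
                f"{entry['membership']:.6f}\t{entry['lat']:.6f}\t"
                f"{entry['lon']:.6f}\tstable"
            )
        for entry in payload["regional"]:
            lines.append(
                f"{entry['population']}\t\t{entry['membership']:.6f}\t\t\tregional"
            )
        lines.append(
            f"# mode={payload['mode']} unmixed={payload['unmixed']} "
            f"prior_discarded={payload['prior_discarded']} "
            f"minimax_error={payload['minimax_error']:.6f}"
        )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"format must be 'json' or 'tsv', got {format!r}")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
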