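"""Summary-statistics datasets (SSDs).

An SSD reduces a patient-level table to variable names, a sample size,
means, SDs, and a covariance matrix — sufficient to fit covariance-based
path models without access to the underlying records.  Published moment
tables are transcriptions and can arrive slightly asymmetric, so the
container tolerates raw input and provides explicit symmetrization and
positive-semidefiniteness validation/repair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SSDError(ValueError):
    """Raised for malformed or inconsistent summary datasets."""


@dataclass
class SummaryDataset:
    """Names, n, means, SDs, and covariance matrix, aligned by position."""

    names: list[str]
    n: int
    means: np.ndarray
    sds: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.names)
        if len(set(self.names)) != k:
            raise SSDError("duplicate variable names")
        if self.n < 2:
            raise SSDError(f"n must be >= 2, got {self.n}")
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise SSDError("means/sds length does not match variable names")
        if self.cov.shape != (k, k):
            raise SSDError(
                f"covariance shape {self.cov.shape} does not match {k} names"
            )
        if np.any(self.sds <= 0):
            raise SSDError("all SDs must be > 0")

    @property
    def k(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SSDError(f"unknown variable {name!r}") from None

    def subset(self, names: Sequence[str]) -> "SummaryDataset":
        idx = [self.index(n) for n in names]
        return SummaryDataset(
            names=list(names),
            n=self.n,
            means=self.means[idx],
            sds=self.sds[idx],
            cov=self.cov[np.ix_(idx, idx)],
        )

    def copy(self) -> "SummaryDataset":
        return SummaryDataset(list(self.names), self.n, self.means.copy(),
                              self.sds.copy(), self.cov.copy())

    def cov_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.names, columns=self.names)

    def get(self, a: str, b: str) -> float:
        return float(self.cov[self.index(a), self.index(b)])

    def set(self, a: str, b: str, value: float) -> None:
        i, j = self.index(a), self.index(b)
        self.cov[i, j] = self.cov[j, i] = value


@dataclass
class AsymmetryReport:
    """Off-diagonal disagreements found when symmetrizing a printed matrix."""

    max_abs_asymmetry: float
    offending_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)


def build_ssd(patient_table: pd.DataFrame, variables: Sequence[str] | None = None) -> SummaryDataset:
    """Construct an SSD from a per-patient variable table (n-1 denominator).

    Non-numeric columns are ignored unless explicitly listed.  Missing values
    are not supported: the source tables are complete by construction.
    """
    df = patient_table[list(variables)] if variables is not None else patient_table.select_dtypes("number")
    n = len(df)
    if n < 2:
        raise SSDError(f"need >= 2 rows to form covariances, got {n}")
    if df.isna().any().any():
        raise SSDError("patient table contains missing values")
    cov = df.cov(ddof=1)  # symmetric by construction
    return SummaryDataset(
        names=list(df.columns),
        n=n,
        means=df.mean().to_numpy(),
        sds=df.std(ddof=1).to_numpy(),
        cov=cov.to_numpy(),
    )


def symmetrize(ssd: SummaryDataset, tol: float = 1e-12) -> tuple[SummaryDataset, AsymmetryReport]:
    """Average the two triangles of the covariance; report every disagreement."""
    c = ssd.cov
    pairs = []
    for i in range(ssd.k):
        for j in range(i + 1, ssd.k):
            if abs(c[i, j] - c[j, i]) > tol:
                pairs.append((ssd.names[i], ssd.names[j], float(c[i, j]), float(c[j, i])))
    out = ssd.copy()
    out.cov = (c + c.T) / 2.0
    delta = np.abs(c - c.T)
    return out, AsymmetryReport(float(delta.max(initial=0.0)), pairs)


def to_correlation(ssd: SummaryDataset) -> pd.DataFrame:
    """Correlation matrix r_ij = c_ij / (sd_i sd_j); unit diagonal."""
    d = ssd.sds
    r = ssd.cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ssd.names, columns=ssd.names)


@dataclass
class PsdDiagnostics:
    min_eigenvalue: float
    repaired: bool
    perturbation_norm: float


def validate_psd(
    ssd: SummaryDataset,
    repair: bool = False,
    rel_tol: float = 1e-8,
) -> tuple[SummaryDataset, PsdDiagnostics]:
    """Check (and optionally repair) positive semidefiniteness.

    A matrix passes if its smallest eigenvalue is >= -rel_tol * largest.
    Repair clips negative eigenvalues at zero and reassembles; the Frobenius
    norm of the perturbation is reported.  SDs are left at their stated
    values; the repair may move diagonal entries through reassembly.
    """
    sym = np.allclose(ssd.cov, ssd.cov.T, atol=1e-10)
    if not sym:
        raise SSDError("validate_psd requires a symmetric matrix; symmetrize first")
    w, v = np.linalg.eigh(ssd.cov)
    lo, hi = float(w[0]), float(w[-1])
    if lo >= -rel_tol * max(hi, 1.0):
        return ssd, PsdDiagnostics(lo, False, 0.0)
    if not repair:
        raise SSDError(
            f"covariance is not positive semidefinite (min eigenvalue {lo:.3e})"
        )
    clipped = np.clip(w, 0.0, None)
    fixed = (v * clipped) @ v.T
    fixed = (fixed + fixed.T) / 2.0
    norm = float(np.linalg.norm(fixed - ssd.cov))
    out = ssd.copy()
    out.cov = fixed
    return out, PsdDiagnostics(lo, True, norm)


# ---------------------------------------------------------------------------
# File I/O: JSON object {names, n, means, sds, cov} (row-major nested arrays),
# or a CSV with a small header block followed by the covariance matrix.
# ---------------------------------------------------------------------------

def write_ssd(ssd: SummaryDataset, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_ssd_csv(ssd, path)
        return
    payload = {
        "names": ssd.names,
        "n": ssd.n,
        "means": ssd.means.tolist(),
        "sds": ssd.sds.tolist(),
        "cov": ssd.cov.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))


def read_ssd(path: str | Path) -> SummaryDataset:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_ssd_csv(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SSDError(f"malformed SSD JSON: {e}") from e
    for key in ("names", "n", "means", "sds", "cov"):
        if key not in payload:
            raise SSDError(f"SSD file missing field {key!r}")
    try:
        return SummaryDataset(
            names=payload["names"],
            n=int(payload["n"]),
            means=np.asarray(payload["means"], dtype=float),
            sds=np.asarray(payload["sds"], dtype=float),
            cov=np.asarray(payload["cov"], dtype=float),
        )
    except (ValueError, TypeError) as e:
        raise SSDError(f"inconsistent SSD file {path.name}: {e}") from e


def _write_ssd_csv(ssd: SummaryDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n,{ssd.n}\n")
        fh.write("variable,mean,sd," + ",".join(ssd.names) + "\n")
        for i, name in enumerate(ssd.names):
            row = ",".join(repr(float(x)) for x in ssd.cov[i])
            fh.write(f"{name},{float(ssd.means[i])!r},{float(ssd.sds[i])!r},{row}\n")


def _read_ssd_csv(path: Path) -> SummaryDataset:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or not lines[0].startswith("# n,"):
        raise SSDError("SSD CSV must start with a '# n,<count>' header line")
    n = int(lines[0].split(",", 1)[1])
    header = lines[1].split(",")
    names = header[3:]
    means, sds, rows = [], [], []
    for line in lines[2:]:
        parts = line.split(",")
        if len(parts) != 3 + len(names):
            raise SSDError(f"SSD CSV row has {len(parts)} fields, expected {3 + len(names)}")
        means.append(float(parts[1]))
        sds.append(float(parts[2]))
        rows.append([float(x) for x in parts[3:]])
    if [line.split(",", 1)[0] for line in lines[2:]] != names:
        raise SSDError("SSD CSV row names do not match header names")
    return SummaryDataset(names=names, n=n, means=np.array(means),
                          sds=np.array(sds), cov=np.array(rows))
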