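"""Correlation-matrix samples: reading, writing, validation and pooling.

The unit of analysis throughout the package is a named correlation matrix
together with its effective sample size.  Batteries of cognitive subtests
are standardized per age band, and publishers print per-band correlation
tables; bands are combined by averaging in Fisher-z space and the pooled
sample size is supplied explicitly by the analyst (e.g. five tables of
N=200 pooled to N=1000).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CorrelationSample",
    "FormatError",
    "ValidationError",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "pool_correlations",
]

_SYM_TOL = 1e-12


class FormatError(ValueError):
    """A matrix file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """A correlation matrix violates a structural invariant."""


@dataclass(frozen=True)
class CorrelationSample:
    """A p x p Pearson correlation matrix with its effective N.

    Parameters
    ----------
    names : sequence of str
        Ordered variable (subtest) labels, length p.
    R : ndarray of shape (p, p)
        Symmetric correlation matrix, unit diagonal, positive definite.
    n_obs : int
        Effective number of observations behind ``R`` (used as the
        chi-square multiplier ``N - 1`` downstream).
    label : str
        Free-text population tag, e.g. ``"ages 20-54"``.
    """

    names: tuple[str, ...]
    R: np.ndarray
    n_obs: int
    label: str = ""

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        p = len(names)
        if p < 2:
            raise ValidationError("need at least 2 variables")
        if R.shape != (p, p):
            raise ValidationError(f"matrix shape {R.shape} != ({p}, {p})")
        if not np.all(np.isfinite(R)):
            raise ValidationError("non-finite correlation entries")
        asym = np.max(np.abs(R - R.T))
        if asym > _SYM_TOL:
            raise ValidationError(f"matrix asymmetric (max deviation {asym:g})")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValidationError("correlation magnitudes exceed 1")
        if np.any(np.diag(R) != 1.0):
            raise ValidationError("diagonal entries must be exactly 1")
        lam_min = float(np.linalg.eigvalsh(R)[0])
        if lam_min <= 0.0:
            raise ValidationError(
                f"matrix not positive definite (smallest eigenvalue {lam_min:g})"
            )
        if int(self.n_obs) != self.n_obs or self.n_obs < p + 1:
            raise ValidationError(f"n_obs must be an integer >= p + 1, got {self.n_obs}")
        object.__setattr__(self, "n_obs", int(self.n_obs))

    @property
    def p(self) -> int:
        """Number of observed variables."""
        return len(self.names)

    def reorder(self, names: Sequence[str]) -> "CorrelationSample":
        """Return a copy with variables rearranged into ``names`` order."""
        idx = [self.names.index(n) for n in names]
        return replace(self, names=tuple(names), R=self.R[np.ix_(idx, idx)])


def _parse_metadata(lines: list[str]) -> tuple[int | None, str]:
    n_obs: int | None = None
    label = ""
    for line in lines:
        m = re.match(r"#\s*N\s*=\s*(\d+)\s*$", line)
        if m:
            n_obs = int(m.group(1))
            continue
        m = re.match(r"#\s*label\s*=\s*(.*?)\s*$", line)
        if m:
            label = m.group(1)
    return n_obs, label


def _tokens(line: str) -> list[str]:
    return [t for t in re.split(r"[,\s]+", line.strip()) if t]


def _header_names(line: str) -> list[str]:
    # names may contain spaces ("Block Design"), so the header is
    # comma-separated whenever any comma is present
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip()]
    return _tokens(line)


def read_correlation_matrix(path: str | Path, dialect: str = "full") -> CorrelationSample:
    """Read a correlation matrix file.

    The file carries ``# N=<int>`` (mandatory) and ``# label=<text>``
    (optional) metadata lines, a header row of variable names, then the
    numeric body: a full square matrix (``dialect="full"``) or the lower
    triangle including the diagonal (``dialect="lower_triangle"``).
    Fields are whitespace- or comma-separated.
    """
    if dialect not in ("full", "lower_triangle"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    meta = [ln for ln in lines if ln.lstrip().startswith("#")]
    body = [ln for ln in lines if not ln.lstrip().startswith("#")]
    n_obs, label = _parse_metadata(meta)
    if n_obs is None:
        raise FormatError(f"{path}: missing mandatory '# N=<int>' metadata line")
    if not body:
        raise FormatError(f"{path}: no header row of names")
    names = _header_names(body[0])
    p = len(names)
    rows = [list(map(float, _tokens(ln))) for ln in body[1:]]
    if len(rows) != p:
        raise FormatError(f"{path}: expected {p} body rows, found {len(rows)}")
    R = np.zeros((p, p))
    if dialect == "full":
        for i, row in enumerate(rows):
            if len(row) != p:
                raise FormatError(f"{path}: row {i + 1} has {len(row)} entries, expected {p}")
            R[i] = row
        asym = np.max(np.abs(R - R.T))
        if asym > _SYM_TOL:
            raise FormatError(f"{path}: full matrix asymmetric (max deviation {asym:g})")
    else:
        for i, row in enumerate(rows):
            if len(row) != i + 1:
                raise FormatError(
                    f"{path}: lower-triangle row {i + 1} has {len(row)} entries, expected {i + 1}"
                )
            R[i, : i + 1] = row
            R[: i + 1, i] = row
    return CorrelationSample(names=tuple(names), R=R, n_obs=n_obs, label=label)


def write_correlation_matrix(
    sample: CorrelationSample, path: str | Path, dialect: str = "lower_triangle"
) -> None:
    """Write ``sample`` in the plain-text dialects of :func:`read_correlation_matrix`.

    Values are printed at 6 significant digits; a written file read back and
    re-written reproduces identical bytes.
    """
    if dialect not in ("full", "lower_triangle"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [f"# N={sample.n_obs}"]
    if sample.label:
        lines.append(f"# label={sample.label}")
    sep = ", " if any(" " in n for n in sample.names) else " "
    lines.append(sep.join(sample.names))
    p = sample.p
    for i in range(p):
        stop = p if dialect == "full" else i + 1
        lines.append(" ".join(f"{sample.R[i, j]:.6g}" for j in range(stop)))
    Path(path).write_text("\n".join(lines) + "\n")


def pool_correlations(
    samples: Iterable[CorrelationSample],
    n_obs: int | None = None,
    label: str | None = None,
) -> CorrelationSample:
    """Average correlation matrices through the Fisher z transform.

    Each off-diagonal entry of the result is ``tanh(mean(atanh(r_k)))`` over
    the input matrices; the average is unweighted because pooled tables are
    assumed to share a per-table N (validated).  The pooled ``n_obs`` is
    supplied by the caller (e.g. 1000 for five tables of 200); it defaults to
    the common input N only when a single sample is pooled.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample to pool")
    names = samples[0].names
    for s in samples[1:]:
        if s.names != names:
            raise ValidationError("variable name lists differ between pooled samples")
        if s.n_obs != samples[0].n_obs:
            raise ValidationError(
                "per-table n_obs differ; unweighted z-averaging assumes equal table sizes"
            )
    if n_obs is None:
        if len(samples) > 1:
            raise ValueError("pooled n_obs must be given explicitly when pooling >1 sample")
        n_obs = samples[0].n_obs
    p = samples[0].p
    off = ~np.eye(p, dtype=bool)
    stack = np.stack([s.R for s in samples])
    if np.any(np.abs(stack[:, off]) >= 1.0):
        raise ValidationError("off-diagonal |r| = 1 is outside the Fisher z domain")
    Z = np.zeros_like(stack)
    Z[:, off] = np.arctanh(stack[:, off])
    R = np.tanh(Z.mean(axis=0))
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    if label is None:
        label = samples[0].label
    return CorrelationSample(names=names, R=R, n_obs=n_obs, label=label)
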