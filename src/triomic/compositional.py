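"""Compositional transforms: closure, multiplicative zero replacement, clr,
Aitchison distance.

Genus count tables are compositional: only relative information is
meaningful.  All downstream statistics therefore operate on centred
log-ratio (clr) coordinates, where Euclidean geometry is the Aitchison
geometry of the simplex.  Natural logarithms are used throughout (the
Aitchison distance is base-invariant up to a global constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "close",
    "multiplicative_zero_replace",
    "clr",
    "clr_transform_counts",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "ClrMatrix",
]

#: default zero-replacement delta as a fraction of the per-sample count
#: detection limit (1/depth).  65% of the detection limit is the standard
#: multiplicative-replacement convention.
DEFAULT_DELTA_FRACTION = 0.65


def close(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Close a (matrix of) composition(s) so parts sum to 1 along ``axis``."""
    x = np.asarray(x, dtype=float)
    total = x.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot close a composition with non-positive total")
    return x / total


def multiplicative_zero_replace(p: np.ndarray, delta: float) -> np.ndarray:
    """Replace zeros in a closed composition by ``delta``, rescaling the
    non-zero parts by ``1 - delta * n_zeros`` so the result still sums to 1.

    Preserves all ratios between originally non-zero parts.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("input composition must be closed (sum to 1)")
    zeros = p == 0
    nz = int(zeros.sum())
    if nz == 0:
        return p.copy()
    if delta <= 0 or delta * nz >= 1:
        raise ValueError(
            f"delta={delta} infeasible for {nz} zero parts (delta*n_zeros must be < 1)"
        )
    out = p * (1.0 - delta * nz)
    out[zeros] = delta
    return out


def clr(p: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform of a strictly positive composition.

    clr_i = log(x_i) - mean_j log(x_j); the result sums to zero.
    Scale-invariant: clr(x) == clr(c*x) for any c > 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("clr requires strictly positive parts")
    logp = np.log(p)
    return logp - logp.mean()


@dataclass
class ClrMatrix:
    """clr-transformed abundances (genus x sample) with provenance.

    Each column (sample) sums to zero; values are in clr units (natural log).
    """

    values: pd.DataFrame
    delta_policy: str = "per-sample 0.65/depth"
    detection_limits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        colsums = self.values.to_numpy().sum(axis=0)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("ClrMatrix contains non-finite entries")
        if np.any(np.abs(colsums) > 1e-9 * max(1, self.values.shape[0])):
            raise ValueError("ClrMatrix columns must sum to 0")

    @property
    def genus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def clr_transform_counts(
    counts: pd.DataFrame, delta_fraction: float = DEFAULT_DELTA_FRACTION
) -> ClrMatrix:
    """Zero-replace and clr-transform a genus x sample count table.

    The per-sample delta is ``delta_fraction / depth`` — a fixed fraction of
    that sample's count detection limit, so deeper samples get smaller
    imputed values.
    """
    arr = counts.to_numpy(dtype=float)
    depths = arr.sum(axis=0)
    if np.any(depths <= 0):
        raise ValueError("zero-depth sample in count table")
    out = np.empty_like(arr)
    limits = {}
    for j in range(arr.shape[1]):
        p = arr[:, j] / depths[j]
        delta = delta_fraction / depths[j]
        out[:, j] = clr(multiplicative_zero_replace(p, delta))
        limits[counts.columns[j]] = delta
    values = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return ClrMatrix(
        values=values,
        delta_policy=f"per-sample {delta_fraction}/depth",
        detection_limits=limits,
    )


def aitchison_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Aitchison distance between two (zero-free) compositions: the
    Euclidean distance between their clr vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("compositions must have the same number of parts")
    return float(np.linalg.norm(clr(close(a)) - clr(close(b))))


def aitchison_distance_matrix(clr_values: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric sample-by-sample distance matrix from a genus x
    sample clr matrix (Euclidean on clr columns)."""
    d = squareform(pdist(clr_values.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=clr_values.columns, columns=clr_values.columns)
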