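"""Shared helpers: errors, logging, seed derivation, Pearson correlation.

The Pearson implementation here is the single source of truth for every
correlation the package computes, so that DEG prefiltering and signature
association profiles agree exactly.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np

logger = logging.getLogger("degsig")


class DegsigError(ValueError):
    """Base class for contract violations raised by this package."""


class DataFormatError(DegsigError):
    """A file does not conform to the declared format."""


class UndefinedCorrelationError(DegsigError):
    """Pearson r requested against a constant vector."""


class DegenerateStratificationError(DegsigError):
    """A mean±SEM split cannot produce two non-empty groups."""


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a single pipeline seed.

    Stage names salt a SHA-256 digest so that each stage draws an
    independent, reproducible stream; the result fits in 31 bits.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant (zero variance).
    DegsigError
        If lengths differ or fewer than 3 observations are given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegsigError(f"pearson_r requires equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DegsigError(f"pearson_r requires >= 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.dot(xc, yc) / (sx * sy))


def pearson_r_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of a (genes x samples) matrix against one vector.

    Rows with zero variance get NaN (caller decides how to report them).
    Numerically identical to calling :func:`pearson_r` per row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sy = np.sqrt(np.dot(yc, yc))
    sx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0.0] = np.nan
    if sy == 0.0:
        r[:] = np.nan
    return r
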