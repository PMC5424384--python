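"""Aitchison-geometry primitives for time-use compositions.

A day's movement behaviours (sleep, sedentary time, light and
moderate-to-vigorous physical activity) are compositional: the four
durations are constrained to sum to 1440 min, so they live on a simplex
rather than in unconstrained real space.  This module provides the
operations that move between the two geometries:

* closure — rescale a positive vector to a fixed total ``kappa``;
* the isometric log-ratio (ilr) map and its inverse, parameterised by a
  sequential binary partition (SBP);
* the compositional mean (inverse-ilr of the mean ilr coordinates, equal
  to closed per-part geometric means);
* the pairwise log-ratio variation matrix, the compositional analogue of
  a dispersion summary, and its conversion to/from log-ratio covariance.

All operations work for any number of parts D >= 2; nothing is
hard-coded to the four movement behaviours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEFAULT_PARTS",
    "MINUTES_PER_DAY",
    "Composition",
    "SequentialBinaryPartition",
    "IlrCoordinates",
    "VariationMatrix",
    "IlrTransformer",
    "close",
    "ilr",
    "ilr_inverse",
    "compositional_mean",
    "variation_matrix",
    "variation_to_lr_covariance",
    "lr_covariance_to_variation",
    "replace_zeros",
]

logger = logging.getLogger(__name__)

DEFAULT_PARTS: tuple[str, ...] = ("sleep", "st", "lpa", "mvpa")
MINUTES_PER_DAY: float = 1440.0

_REL_TOL = 1e-9


class CompositionError(ValueError):
    """Invalid compositional input (nonpositive part, dimension mismatch...)."""


def _as_values(x: "Composition | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(x, Composition):
        return x.values
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class Composition:
    """One point on the simplex: strictly positive durations with labels.

    ``values`` need not sum to ``kappa`` on construction; :meth:`close`
    rescales while preserving all ratios.  ``is_closed`` reports whether
    the sum already equals ``kappa`` to relative tolerance 1e-9.
    """

    values: np.ndarray
    parts: tuple[str, ...] = DEFAULT_PARTS
    kappa: float = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "parts", tuple(self.parts))
        if values.ndim != 1:
            raise CompositionError("composition values must be a 1-d vector")
        if len(self.parts) != values.size:
            raise CompositionError(
                f"{values.size} values but {len(self.parts)} part labels"
            )
        if len(set(self.parts)) != len(self.parts):
            raise CompositionError(f"part labels are not unique: {self.parts}")
        if self.kappa <= 0:
            raise CompositionError(f"closure constant must be positive, got {self.kappa}")
        if not np.all(np.isfinite(values)):
            raise CompositionError("composition values must be finite")
        bad = np.asarray(values <= 0).nonzero()[0]
        if bad.size:
            names = ", ".join(self.parts[i] for i in bad)
            raise CompositionError(f"nonpositive duration for part(s): {names}")

    @property
    def n_parts(self) -> int:
        return self.values.size

    @property
    def is_closed(self) -> bool:
        return bool(np.isclose(self.values.sum(), self.kappa, rtol=_REL_TOL, atol=0.0))

    def close(self) -> "Composition":
        return Composition(self.values * (self.kappa / self.values.sum()),
                           self.parts, self.kappa)

    def proportions(self) -> np.ndarray:
        """Parts as fractions of the total (sum exactly 1)."""
        return self.values / self.values.sum()

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def replace(self, **minutes: float) -> "Composition":
        values = self.values.copy()
        for part, v in minutes.items():
            values[self.parts.index(part)] = v
        return Composition(values, self.parts, self.kappa)


def close(values, kappa: float = MINUTES_PER_DAY,
          parts: Sequence[str] = DEFAULT_PARTS) -> Composition:
    """Rescale a strictly positive vector so its parts sum to ``kappa``.

    Ratios between parts are preserved exactly (single scalar multiply).
    """
    return Composition(_as_values(values), tuple(parts), kappa).close()


def replace_zeros(values: np.ndarray, delta: float = 0.5) -> np.ndarray:
    """Multiplicative zero replacement: zeros become ``delta``, the other
    parts are shrunk to keep the row total unchanged.

    Disabled by default throughout the package (log-ratios are undefined
    at zero and silent imputation hides data problems); callers opt in
    explicitly and the replacement is logged loudly.
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    zero = values == 0
    n_zero = int(zero.sum(axis=-1).sum())
    if n_zero == 0:
        return out
    if delta <= 0:
        raise CompositionError(f"zero-replacement delta must be positive, got {delta}")
    total = values.sum(axis=-1, keepdims=True)
    k = np.atleast_1d(zero.sum(axis=-1))[..., None] if values.ndim > 1 else zero.sum()
    shrink = 1.0 - delta * np.asarray(k) / total
    out = np.where(zero, delta, values * shrink)
    logger.warning("replaced %d zero duration(s) with delta=%.3g min "
                   "(multiplicative replacement)", n_zero, delta)
    return out


# ---------------------------------------------------------------------------
# Sequential binary partitions and the ilr map
# ---------------------------------------------------------------------------

class SequentialBinaryPartition:
    """An orthonormal ilr basis defined by a sequential binary partition.

    The sign matrix has one column per balance; entries +1/-1 place parts
    in the numerator/denominator of that balance, 0 leaves them out.
    Columns must form a valid hierarchy: the parts split at step k are
    exactly one of the groups produced by the earlier steps.

    Any valid SBP yields the same model space and the same back-transformed
    results; the choice only fixes the coordinate system, which is why all
    downstream quantities are tested for basis invariance.
    """

    def __init__(self, sign_matrix, parts: Sequence[str] | None = None):
        S = np.asarray(sign_matrix, dtype=float)
        if S.ndim != 2 or S.shape[1] != S.shape[0] - 1:
            raise CompositionError(
                f"sign matrix must be D x (D-1), got shape {S.shape}"
            )
        if not np.all(np.isin(S, (-1.0, 0.0, 1.0))):
            raise CompositionError("sign matrix entries must be in {-1, 0, +1}")
        self.sign_matrix = S
        D = S.shape[0]
        self.parts = tuple(parts) if parts is not None else tuple(
            f"part{i + 1}" for i in range(D)
        )
        if len(self.parts) != D:
            raise CompositionError("part labels do not match sign-matrix rows")
        self._validate_hierarchy(S)
        self.contrast_matrix = self._contrasts(S)

    @staticmethod
    def _validate_hierarchy(S: np.ndarray) -> None:
        D = S.shape[0]
        groups: list[frozenset[int]] = [frozenset(range(D))]
        for k in range(D - 1):
            col = S[:, k]
            plus = frozenset(np.nonzero(col > 0)[0])
            minus = frozenset(np.nonzero(col < 0)[0])
            if not plus or not minus:
                raise CompositionError(
                    f"balance {k}: needs at least one + and one - part"
                )
            involved = plus | minus
            if involved not in groups:
                raise CompositionError(
                    f"balance {k}: parts {sorted(involved)} do not form a "
                    "single group from the preceding splits"
                )
            groups.remove(involved)
            groups.extend(g for g in (plus, minus) if len(g) > 1)

    @staticmethod
    def _contrasts(S: np.ndarray) -> np.ndarray:
        D, K = S.shape
        psi = np.zeros((D, K))
        for k in range(K):
            r = (S[:, k] > 0).sum()
            s = (S[:, k] < 0).sum()
            psi[S[:, k] > 0, k] = np.sqrt(s / (r * (r + s)))
            psi[S[:, k] < 0, k] = -np.sqrt(r / (s * (r + s)))
        return psi

    @classmethod
    def pivot(cls, parts: Sequence[str] = DEFAULT_PARTS) -> "SequentialBinaryPartition":
        """Pivot balances: coordinate k contrasts part k against the
        geometric mean of the remaining parts k+1..D."""
        D = len(parts)
        S = np.zeros((D, D - 1))
        for k in range(D - 1):
            S[k, k] = 1.0
            S[k + 1:, k] = -1.0
        return cls(S, parts)

    @classmethod
    def pivot_reversed(cls, parts: Sequence[str] = DEFAULT_PARTS) -> "SequentialBinaryPartition":
        """Pivot balances taken in reversed part order (used to exercise
        basis invariance: same parts, different coordinate system)."""
        D = len(parts)
        S = np.zeros((D, D - 1))
        for k in range(D - 1):
            S[D - 1 - k, k] = 1.0
            S[: D - 1 - k, k] = -1.0
        return cls(S, parts)

    @property
    def n_parts(self) -> int:
        return self.sign_matrix.shape[0]

    def __eq__(self, other) -> bool:
        return (isinstance(other, SequentialBinaryPartition)
                and self.parts == other.parts
                and np.array_equal(self.sign_matrix, other.sign_matrix))

    def __repr__(self) -> str:
        return f"SequentialBinaryPartition(parts={self.parts}, balances={self.sign_matrix.shape[1]})"


@dataclass(frozen=True)
class IlrCoordinates:
    """D-1 real ilr coordinates together with the basis that produced them.

    Carrying the basis matters because the inverse map is only defined
    with respect to the same partition.
    """

    values: np.ndarray
    basis: SequentialBinaryPartition

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape[-1] != self.basis.n_parts - 1:
            raise CompositionError(
                f"{self.values.shape[-1]} coordinates do not match basis with "
                f"{self.basis.n_parts} parts"
            )


def _ilr_values(values: np.ndarray, sbp: SequentialBinaryPartition) -> np.ndarray:
    return np.log(values) @ sbp.contrast_matrix


def ilr(comp: Composition | np.ndarray,
        sbp: SequentialBinaryPartition | None = None) -> IlrCoordinates:
    """Map a composition to its ilr coordinates ``psi.T @ ln(x)``.

    Scale-invariant: closure (or any positive rescaling) of the input
    does not change the coordinates, because the contrast columns sum
    to zero.
    """
    values = _as_values(comp)
    if sbp is None:
        parts = comp.parts if isinstance(comp, Composition) else DEFAULT_PARTS[: values.size]
        sbp = SequentialBinaryPartition.pivot(parts)
    if values.shape[-1] != sbp.n_parts:
        raise CompositionError(
            f"composition has {values.shape[-1]} parts, basis expects {sbp.n_parts}"
        )
    if isinstance(comp, Composition) and comp.parts != sbp.parts:
        raise CompositionError(
            f"part labels {comp.parts} do not match basis labels {sbp.parts}"
        )
    return IlrCoordinates(_ilr_values(values, sbp), sbp)


def ilr_inverse(coords: IlrCoordinates | np.ndarray,
                kappa: float = MINUTES_PER_DAY,
                basis: SequentialBinaryPartition | None = None) -> Composition:
    """Back-transfer ilr coordinates to the simplex, closed to ``kappa``."""
    if isinstance(coords, IlrCoordinates):
        basis = coords.basis
        values = coords.values
    else:
        if basis is None:
            raise CompositionError(
                "raw coordinate vectors need an explicit basis for the inverse map"
            )
        values = np.asarray(coords, dtype=float)
    raw = np.exp(values @ basis.contrast_matrix.T)
    return close(raw, kappa, basis.parts)


def compositional_mean(samples: Iterable[Composition] | np.ndarray,
                       kappa: float = MINUTES_PER_DAY,
                       parts: Sequence[str] | None = None,
                       sbp: SequentialBinaryPartition | None = None) -> Composition:
    """Central tendency on the simplex.

    Computed as the inverse-ilr of the arithmetic mean of the ilr
    coordinates, then closed to ``kappa``; this equals the closed vector
    of per-part geometric means and is independent of the SBP choice.
    """
    X, parts = _sample_matrix(samples, parts)
    if X.shape[0] < 1:
        raise CompositionError("compositional mean needs at least one sample")
    if sbp is None:
        sbp = SequentialBinaryPartition.pivot(parts)
    mean_coords = _ilr_values(X, sbp).mean(axis=0)
    return ilr_inverse(IlrCoordinates(mean_coords, sbp), kappa)


def _sample_matrix(samples, parts: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(samples, np.ndarray):
        X = np.asarray(samples, dtype=float)
        if X.ndim != 2:
            raise CompositionError("sample matrix must be 2-d (n_samples, n_parts)")
        labels = tuple(parts) if parts is not None else tuple(
            f"part{i + 1}" for i in range(X.shape[1])
        )
    else:
        comps = list(samples)
        if not comps:
            raise CompositionError("empty sample collection")
        labels = comps[0].parts
        for c in comps:
            if c.parts != labels:
                raise CompositionError(
                    f"inconsistent part labels: {c.parts} vs {labels}"
                )
        X = np.vstack([c.values for c in comps])
    if np.any(X <= 0):
        raise CompositionError("all sample values must be strictly positive")
    return X, labels


# ---------------------------------------------------------------------------
# Dispersion: variation matrix and log-ratio covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariationMatrix:
    """Pairwise variances of log-ratios: entry (i, j) = var(ln(x_i / x_j)).

    Symmetric with zero diagonal; a small entry means the two parts vary
    in near-constant proportion across samples.  Invariant to closure of
    the samples and to perturbation by any fixed composition.
    """

    entries: np.ndarray
    parts: tuple[str, ...]

    def __post_init__(self) -> None:
        T = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", T)
        object.__setattr__(self, "parts", tuple(self.parts))
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise CompositionError("variation matrix must be square")
        if T.shape[0] != len(self.parts):
            raise CompositionError("part labels do not match matrix dimension")
        if not np.allclose(T, T.T, rtol=0, atol=1e-10):
            raise CompositionError("variation matrix must be symmetric")
        if not np.allclose(np.diag(T), 0.0, atol=1e-10):
            raise CompositionError("variation matrix diagonal must be zero")
        if np.any(T < -1e-12):
            raise CompositionError("variation matrix entries must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.parts.index(p) for p in pair)
        return float(self.entries[i, j])


def variation_matrix(samples, parts: Sequence[str] | None = None,
                     ddof: int = 1) -> VariationMatrix:
    """Compute the variation matrix of a sample of compositions.

    Uses the sample variance (ddof=1) of each pairwise log-ratio.
    """
    X, labels = _sample_matrix(samples, parts)
    n, D = X.shape
    if n < 2:
        raise CompositionError("variation matrix needs at least two samples")
    L = np.log(X)
    # var(ln xi - ln xj) for all pairs, vectorised through the log covariance
    C = np.cov(L, rowvar=False, ddof=ddof)
    d = np.diag(C)
    T = d[:, None] + d[None, :] - 2.0 * C
    T = np.maximum(0.5 * (T + T.T), 0.0)
    np.fill_diagonal(T, 0.0)
    return VariationMatrix(T, labels)


def variation_to_lr_covariance(vm: VariationMatrix | np.ndarray,
                               sbp: SequentialBinaryPartition) -> np.ndarray:
    """Convert a variation matrix to the (D-1)x(D-1) ilr covariance.

    The centred log-ratio covariance is -1/2 * G T G with G = I - J/D the
    double-centering projector; projecting through the contrast matrix
    gives the ilr covariance.  ``lr_covariance_to_variation`` inverts the
    map exactly (the variation matrix and the clr covariance carry the
    same information).
    """
    T = vm.entries if isinstance(vm, VariationMatrix) else np.asarray(vm, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise CompositionError("variation matrix must be square")
    if not np.allclose(T, T.T, rtol=0, atol=1e-10):
        raise CompositionError("variation matrix must be symmetric")
    if np.any(T < -1e-12):
        raise CompositionError("variation matrix entries must be nonnegative")
    D = T.shape[0]
    if sbp.n_parts != D:
        raise CompositionError("basis dimension does not match variation matrix")
    G = np.eye(D) - np.full((D, D), 1.0 / D)
    clr_cov = -0.5 * G @ T @ G
    psi = sbp.contrast_matrix
    return psi.T @ clr_cov @ psi


def lr_covariance_to_variation(ilr_cov: np.ndarray,
                               sbp: SequentialBinaryPartition) -> VariationMatrix:
    """Variation matrix implied by an ilr covariance under a given basis."""
    S = np.asarray(ilr_cov, dtype=float)
    psi = sbp.contrast_matrix
    clr_cov = psi @ S @ psi.T
    d = np.diag(clr_cov)
    T = d[:, None] + d[None, :] - 2.0 * clr_cov
    T = np.maximum(0.5 * (T + T.T), 0.0)
    np.fill_diagonal(T, 0.0)
    return VariationMatrix(T, sbp.parts)


# ---------------------------------------------------------------------------
# scikit-learn transformer
# ---------------------------------------------------------------------------

class IlrTransformer(BaseEstimator, TransformerMixin):
    """Transform rows of part durations into ilr coordinates.

    Parameters
    ----------
    parts : sequence of str
        Part labels in column order.
    sbp : SequentialBinaryPartition, optional
        Basis to use; defaults to pivot balances over ``parts``.
    zero_policy : {"error", "replace"}
        How to treat zero durations. ``"replace"`` applies multiplicative
        replacement with ``zero_delta`` minutes and logs a warning.
    zero_delta : float
        Replacement value in minutes when ``zero_policy="replace"``.
    """

    def __init__(self, parts: Sequence[str] = DEFAULT_PARTS,
                 sbp: SequentialBinaryPartition | None = None,
                 zero_policy: str = "error", zero_delta: float = 0.5):
        self.parts = parts
        self.sbp = sbp
        self.zero_policy = zero_policy
        self.zero_delta = zero_delta

    def fit(self, X, y=None) -> "IlrTransformer":
        X = self._prepare(np.asarray(self._extract(X), dtype=float))
        if X.shape[1] != len(self.parts):
            raise CompositionError(
                f"X has {X.shape[1]} columns, expected {len(self.parts)} parts"
            )
        self.basis_ = self.sbp or SequentialBinaryPartition.pivot(tuple(self.parts))
        if self.basis_.n_parts != len(self.parts):
            raise CompositionError("basis dimension does not match parts")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise RuntimeError("IlrTransformer is not fitted")
        X = self._prepare(np.asarray(self._extract(X), dtype=float))
        if np.any(X <= 0):
            raise CompositionError("zero or negative duration encountered "
                                   "(zero_policy='error')")
        return _ilr_values(X, self.basis_)

    def inverse_transform(self, Z, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
        raw = np.exp(np.asarray(Z, dtype=float) @ self.basis_.contrast_matrix.T)
        return raw * (kappa / raw.sum(axis=-1, keepdims=True))

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"ilr{k + 1}" for k in range(len(self.parts) - 1)])

    def _extract(self, X):
        if hasattr(X, "loc"):  # DataFrame: select the part columns by name
            return X[list(self.parts)].to_numpy()
        return X

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.zero_policy == "replace":
            return replace_zeros(X, self.zero_delta)
        return X
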