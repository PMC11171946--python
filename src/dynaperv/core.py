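"""Core dynamic-perviousness primitives.

Thrombus perviousness quantifies how far iodinated contrast penetrates an
occlusive clot between CT acquisitions.  *Standard* perviousness (SP) is the
thrombus attenuation increase (TAI): the change in mean clot density between
non-contrast CT (NCCT) and arterial-phase CT angiography (CTA).  *Dynamic*
perviousness (DP) adds a late venous phase (CTV) and classifies the
three-point enhancement curve into four patterns:

========  =====================================================
``C_NE``  no enhancement (no rise above threshold in any phase)
``C_LE``  late enhancement (rise only by the venous phase)
``C_W``   early enhancement with washout (arterial rise, venous clearance)
``C_NW``  early enhancement without washout
========  =====================================================

The enhancement threshold ``tau`` defaults to 5 HU.  With
``delta_na = cta - ncct``, ``delta_nv = ctv - ncct`` and
``delta_av = ctv - cta`` the rules are:

* ``C_NE``: ``delta_na <= tau`` and ``delta_nv <= tau``
* ``C_LE``: ``delta_na <= tau`` and ``delta_nv > tau``
* ``C_W`` : ``delta_na > tau`` and ``delta_av <= -tau``
* ``C_NW``: ``delta_na > tau`` and ``delta_av > -tau``

All inequalities are inclusive on the "maximum increase/decrease" side, which
makes the four rules an exact partition of the (delta_na, delta_av) plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import InvalidDensityError, PlausibilityWarning

__all__ = [
    "CATEGORIES",
    "DEFAULT_TAU",
    "PhaseDensities",
    "TAIDeltas",
    "compute_tai",
    "classify_dynamic",
    "standard_perviousness",
    "classify_table",
    "DynamicPerviousnessClassifier",
]

#: The four dynamic-perviousness categories, in reporting order.
CATEGORIES = ("C_NE", "C_NW", "C_W", "C_LE")

#: Default enhancement threshold in Hounsfield units.
DEFAULT_TAU = 5.0

# Mean clot density outside this HU range is physically implausible for
# thrombus (fat < -100, dense calcification > 300) and triggers a warning.
_HU_PLAUSIBLE = (-100.0, 300.0)


def _check_finite(values: Iterable[float], what: str) -> None:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidDensityError(f"{what} must be finite, got {arr!r}")


def _warn_implausible(values: Sequence[float]) -> None:
    lo, hi = _HU_PLAUSIBLE
    arr = np.asarray(values, dtype=float)
    if np.any((arr < lo) | (arr > hi)):
        warnings.warn(
            f"density outside plausible clot range [{lo:g}, {hi:g}] HU: {arr!r}",
            PlausibilityWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class PhaseDensities:
    """Mean clot density (HU) on the three acquisition phases.

    Each value is the average of the per-clot ROI measurements on that phase.
    Non-finite values raise :class:`InvalidDensityError`; values outside
    [-100, 300] HU are accepted with a :class:`PlausibilityWarning`.
    """

    ncct_hu: float
    cta_hu: float
    ctv_hu: float

    def __post_init__(self) -> None:
        _check_finite((self.ncct_hu, self.cta_hu, self.ctv_hu), "phase densities")
        _warn_implausible((self.ncct_hu, self.cta_hu, self.ctv_hu))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ncct_hu, self.cta_hu, self.ctv_hu)


@dataclass(frozen=True)
class TAIDeltas:
    """Pairwise thrombus attenuation increases between the three phases.

    ``delta_nv == delta_na + delta_av`` holds by construction; constructing an
    inconsistent triple raises ``ValueError``.
    """

    delta_na: float  # NCCT -> CTA
    delta_nv: float  # NCCT -> CTV
    delta_av: float  # CTA  -> CTV

    def __post_init__(self) -> None:
        _check_finite((self.delta_na, self.delta_nv, self.delta_av), "TAI deltas")
        scale = max(1.0, abs(self.delta_na), abs(self.delta_av))
        if abs(self.delta_nv - (self.delta_na + self.delta_av)) > 1e-9 * scale:
            raise ValueError(
                "inconsistent deltas: delta_nv must equal delta_na + delta_av "
                f"(got {self.delta_nv} vs {self.delta_na + self.delta_av})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_na, self.delta_nv, self.delta_av)


def _coerce_densities(d) -> tuple[float, float, float]:
    if isinstance(d, PhaseDensities):
        return d.as_tuple()
    ncct, cta, ctv = (float(v) for v in d)
    _check_finite((ncct, cta, ctv), "phase densities")
    _warn_implausible((ncct, cta, ctv))
    return ncct, cta, ctv


def compute_tai(d: PhaseDensities | Sequence[float]) -> TAIDeltas:
    """Compute the three pairwise attenuation changes from phase densities.

    Parameters
    ----------
    d:
        A :class:`PhaseDensities` or an ``(ncct_hu, cta_hu, ctv_hu)`` triple.

    Returns
    -------
    TAIDeltas
        ``delta_na = cta - ncct``, ``delta_nv = ctv - ncct``,
        ``delta_av = ctv - cta``.
    """
    ncct, cta, ctv = _coerce_densities(d)
    # Compute delta_nv as the sum so the additivity identity is exact in
    # floating point, not merely up to rounding of two independent subtractions.
    delta_na = cta - ncct
    delta_av = ctv - cta
    return TAIDeltas(delta_na=delta_na, delta_nv=delta_na + delta_av, delta_av=delta_av)


def standard_perviousness(d: PhaseDensities | Sequence[float]) -> float:
    """Two-point (standard) perviousness: the NCCT -> CTA attenuation increase.

    Ignores the venous phase entirely; this is the comparator biomarker the
    dynamic classification is evaluated against.
    """
    ncct, cta, _ = _coerce_densities(d)
    return cta - ncct


def _classify_arrays(delta_na, delta_nv, delta_av, tau: float):
    """Vectorised four-way rule; returns an object array of category labels."""
    delta_na = np.asarray(delta_na, dtype=float)
    delta_nv = np.asarray(delta_nv, dtype=float)
    delta_av = np.asarray(delta_av, dtype=float)
    early = delta_na > tau
    labels = np.select(
        [~early & (delta_nv <= tau), ~early, early & (delta_av <= -tau)],
        ["C_NE", "C_LE", "C_W"],
        default="C_NW",
    )
    return labels


def classify_dynamic(t: TAIDeltas | Sequence[float], tau: float = DEFAULT_TAU) -> str:
    """Assign the dynamic-perviousness category for one delta triple.

    Parameters
    ----------
    t:
        A :class:`TAIDeltas` or an ``(delta_na, delta_nv, delta_av)`` triple.
    tau:
        Enhancement threshold in HU (default 5).  Must be positive.

    Notes
    -----
    The function is total: every finite delta pair maps to exactly one of the
    four categories.  Boundary conventions: a rise of exactly ``tau`` counts
    as "no enhancement"; a fall of exactly ``tau`` from CTA to CTV counts as
    washout.
    """
    if not (math.isfinite(tau) and tau > 0):
        raise ValueError(f"tau must be a positive finite threshold, got {tau!r}")
    if isinstance(t, TAIDeltas):
        dna, dnv, dav = t.as_tuple()
    else:
        dna, dnv, dav = (float(v) for v in t)
        _check_finite((dna, dnv, dav), "TAI deltas")
    return str(_classify_arrays(dna, dnv, dav, tau)[()])


def classify_table(df: pd.DataFrame, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Classify a per-patient density table.

    Expects columns ``ncct_hu``, ``cta_hu``, ``ctv_hu``; returns a copy with
    ``delta_na``, ``delta_nv``, ``delta_av``, ``sp_tai`` (the standard
    perviousness, identical to ``delta_na``) and ``dp_category`` appended.
    """
    required = ("ncct_hu", "cta_hu", "ctv_hu")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"density table is missing columns {missing}")
    ncct = df["ncct_hu"].to_numpy(dtype=float)
    cta = df["cta_hu"].to_numpy(dtype=float)
    ctv = df["ctv_hu"].to_numpy(dtype=float)
    _check_finite(ncct, "ncct_hu")
    _check_finite(cta, "cta_hu")
    _check_finite(ctv, "ctv_hu")
    out = df.copy()
    dna = cta - ncct
    dav = ctv - cta
    out["delta_na"] = dna
    out["delta_nv"] = dna + dav
    out["delta_av"] = dav
    out["sp_tai"] = dna
    out["dp_category"] = _classify_arrays(dna, dna + dav, dav, tau)
    return out


class DynamicPerviousnessClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier mapping three-phase densities to DP categories.

    A deterministic, threshold-based classifier exposed through the sklearn
    estimator API so it composes with pipelines and model selection.  ``fit``
    only validates the threshold and records metadata; there are no learned
    parameters.

    Parameters
    ----------
    tau:
        Enhancement threshold in HU (default 5).

    Attributes
    ----------
    classes_ : ndarray of shape (4,)
        The category labels, sorted.
    tau_ : float
        Validated threshold.

    Examples
    --------
    >>> clf = DynamicPerviousnessClassifier().fit(None)
    >>> clf.predict([[62.5, 73.1, 78.2]])
    array(['C_NW'], dtype='<U4')
    """

    def __init__(self, tau: float = DEFAULT_TAU):
        self.tau = tau

    def fit(self, X=None, y=None) -> "DynamicPerviousnessClassifier":
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be a positive finite threshold, got {self.tau!r}")
        if X is not None:
            X = check_array(X, ensure_min_features=3)
            if X.shape[1] != 3:
                raise ValueError(f"expected 3 phase-density columns, got {X.shape[1]}")
            self.n_features_in_ = 3
        self.tau_ = float(self.tau)
        self.classes_ = np.array(sorted(CATEGORIES))
        return self

    def predict(self, X) -> np.ndarray:
        """Predict categories for an (n, 3) array of (ncct, cta, ctv) HU."""
        check_is_fitted(self, "tau_")
        X = check_array(X, ensure_min_features=3)
        if X.shape[1] != 3:
            raise ValueError(f"expected 3 phase-density columns, got {X.shape[1]}")
        dna = X[:, 1] - X[:, 0]
        dav = X[:, 2] - X[:, 1]
        return _classify_arrays(dna, dna + dav, dav, self.tau_).astype("U4")

    def deltas(self, X) -> np.ndarray:
        """Return the (n, 3) array of (delta_na, delta_nv, delta_av)."""
        X = check_array(X, ensure_min_features=3)
        dna = X[:, 1] - X[:, 0]
        dav = X[:, 2] - X[:, 1]
        return np.column_stack([dna, dna + dav, dav])
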