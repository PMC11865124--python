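"""Orthogonal-polynomial characterization of per-subject pitch curves.

Each participant's tempo-shift values are regressed on an orthonormal
polynomial basis over the integer pitch codes, overall (degree 5 for the
six-level ladder) and within condition slices (degree 2).  Coefficients feed
the multivariate inference layer; a Cousineau-Morey routine provides
within-subject confidence intervals for condition profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFitError, InvalidArgumentError, MissingSliceError

__all__ = [
    "OrthoBasis",
    "PolyCurveFit",
    "ortho_basis",
    "fit_pitch_curve",
    "fit_condition_curves",
    "within_subject_ci",
]


@dataclass(frozen=True)
class OrthoBasis:
    """Orthonormal polynomial contrast columns over a set of pitch codes.

    ``basis`` has one row per distinct code (sorted ascending) and ``degree``
    columns P1..Pd, each unit norm, mutually orthogonal, and orthogonal to
    the constant.  Signs follow the usual contrast convention: each column is
    positive at the highest code.
    """

    codes: tuple
    degree: int
    basis: np.ndarray = field(repr=False)

    def rows_for(self, codes) -> np.ndarray:
        """Basis rows for (possibly repeated) trial-level codes."""
        index = {c: i for i, c in enumerate(self.codes)}
        try:
            idx = [index[int(c)] for c in np.asarray(codes).ravel()]
        except KeyError as err:
            raise InvalidArgumentError(f"code {err} not in basis") from err
        return self.basis[idx]


@dataclass(frozen=True)
class PolyCurveFit:
    """Polynomial coefficients of one participant's pitch curve."""

    participant: object
    slice_label: object
    degree: int
    intercept: float
    coefficients: np.ndarray
    n_trials: int


def ortho_basis(codes, degree: int) -> OrthoBasis:
    """Orthonormalize the Vandermonde columns of the codes (QR), dropping
    the constant.  Matches R's ``poly(codes, degree)`` up to column norms."""
    codes = np.unique(np.asarray(codes, dtype=float))
    if degree < 1:
        raise InvalidArgumentError("degree must be >= 1")
    if degree >= codes.size:
        raise InvalidArgumentError(
            f"degree {degree} requires more than {codes.size} distinct codes"
        )
    V = np.vander(codes, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    P = Q[:, 1:]
    # sign convention: positive at the highest code
    signs = np.sign(P[-1, :])
    signs[signs == 0] = 1.0
    P = P * signs
    return OrthoBasis(codes=tuple(int(c) for c in codes), degree=degree, basis=P)


def fit_pitch_curve(
    pitch_codes,
    tau,
    basis: OrthoBasis,
    participant=None,
    slice_label="all",
) -> PolyCurveFit:
    """Least-squares fit of tau on the orthonormal basis (with intercept).

    Requires every pitch level of the basis to be represented; a slice that
    lost a level (e.g., to outlier exclusion) is refused rather than silently
    fit at reduced rank.
    """
    codes = np.asarray(pitch_codes).ravel()
    y = np.asarray(tau, dtype=float).ravel()
    keep = ~np.isnan(y)
    codes, y = codes[keep], y[keep]
    present = set(int(c) for c in codes)
    missing = [c for c in basis.codes if c not in present]
    if missing:
        raise MissingSliceError(
            f"participant {participant!r} slice {slice_label!r} missing "
            f"pitch levels {missing}"
        )
    X = np.column_stack([np.ones(y.size), basis.rows_for(codes)])
    if y.size <= X.shape[1]:
        raise DegenerateFitError("not enough trials for the requested degree")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PolyCurveFit(
        participant=participant,
        slice_label=slice_label,
        degree=basis.degree,
        intercept=float(coef[0]),
        coefficients=coef[1:].copy(),
        n_trials=int(y.size),
    )


def fit_condition_curves(
    scored,
    by: str,
    basis: OrthoBasis,
    participant_col: str = "participant_id",
    tau_col: str = "tau",
    drop_failed_taps: bool = False,
) -> "list[PolyCurveFit]":
    """One fit per participant x level of the slicing column.

    With ``drop_failed_taps``, trials where an instructed tapper failed to
    tap (``tap_instruction == 'tap'`` and ``tapped`` falsy) are removed
    before fitting.
    """
    df = scored
    if drop_failed_taps and "tap_instruction" in df.columns:
        failed = (df["tap_instruction"] == "tap") & ~df["tapped"].astype(bool)
        df = df[~failed]
    fits = []
    for (pid, level), grp in df.groupby([participant_col, by], sort=True):
        if grp.empty:
            raise MissingSliceError(f"participant {pid!r} slice {level!r} empty")
        fits.append(
            fit_pitch_curve(
                grp["pitch_code"].to_numpy(),
                grp[tau_col].to_numpy(),
                basis,
                participant=pid,
                slice_label=level,
            )
        )
    return fits


def within_subject_ci(table, level: float = 0.95):
    """Cousineau-Morey within-subject confidence intervals per condition.

    Parameters
    ----------
    table : array-like or DataFrame, shape (n_subjects, k_conditions)
        Complete table of per-subject condition means.

    Returns
    -------
    (means, half_widths) : (ndarray, ndarray)
        Condition means and t-based CI half-widths computed on
        subject-centered values with the sqrt(k/(k-1)) bias correction.
    """
    from scipy import stats

    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("expected a 2-D subjects x conditions table")
    if np.isnan(X).any():
        raise InvalidArgumentError("table has missing cells")
    n, k = X.shape
    if k < 2:
        raise InvalidArgumentError("need at least 2 conditions")
    if n < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    grand = X.mean()
    norm = X - X.mean(axis=1, keepdims=True) + grand
    correction = np.sqrt(k / (k - 1.0))
    means = X.mean(axis=0)
    centered = (norm - norm.mean(axis=0, keepdims=True)) * correction
    sd = centered.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return means, half
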