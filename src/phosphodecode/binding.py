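"""Anisotropy titration fitting and exact 1:1 binding equilibrium.

Two regimes, deliberately distinct:

* ``fit_binding`` fits the no-depletion hyperbola
  ``r = R0 + dR * P / (Kd + P)`` — valid because the fluorescent tracer is
  at 20 nM, far below any Kd in the panel.
* ``occupancy_exact`` solves the full quadratic equilibrium with ligand
  depletion — required at NMR concentrations (100 uM protein) where the
  hyperbolic approximation breaks down.

Weak binders whose Kd cannot be resolved within the titration range are
censored at the 250 uM assay bound and reported as ">250".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "CENSOR_BOUND_UM",
    "TitrationCurve",
    "BindingFit",
    "OccupancyQuery",
    "ConvergenceError",
    "binding_model",
    "fit_binding",
    "censor_weak",
    "occupancy_exact",
    "kd_for_occupancy",
    "read_titration_csv",
    "write_fits_tsv",
]

#: Assay detection bound for Kd (uM); fits at or beyond it are reported ">250".
CENSOR_BOUND_UM = 250.0


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last parameter state."""

    def __init__(self, message: str, params: tuple[float, ...] | None = None):
        super().__init__(message)
        self.params = params


@dataclass
class TitrationCurve:
    """One titration: protein concentration series (uM) vs anisotropy.

    Concentrations are sorted ascending on construction; a zero-protein
    buffer control is expected (and produced by the synthetic generator)
    but not required.
    """

    protein_conc: np.ndarray
    anisotropy: np.ndarray
    tracer_conc_nM: float = 20.0
    label: str | None = None

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.protein_conc.shape != self.anisotropy.shape:
            raise ValueError("protein_conc and anisotropy must have equal length")
        if np.any(self.protein_conc < 0):
            raise ValueError("protein concentrations must be >= 0")
        order = np.argsort(self.protein_conc)
        self.protein_conc = self.protein_conc[order]
        self.anisotropy = self.anisotropy[order]

    def __len__(self) -> int:
        return len(self.protein_conc)


@dataclass
class BindingFit:
    """1:1 binding fit result. Censored fits carry Kd at the assay bound."""

    R0: float
    dR: float
    Kd: float
    Kd_se: float
    censored: bool = False
    R0_se: float = math.nan
    dR_se: float = math.nan
    label: str | None = None

    @property
    def kd_display(self) -> str:
        if self.censored:
            return f">{CENSOR_BOUND_UM:g}"
        return f"{self.Kd:.4g}"


def binding_model(P: np.ndarray, R0: float, dR: float, Kd: float) -> np.ndarray:
    """No-depletion 1:1 model: r = R0 + dR * P / (Kd + P)."""
    P = np.asarray(P, dtype=float)
    return R0 + dR * P / (Kd + P)


def fit_binding(curve: TitrationCurve) -> BindingFit:
    """Nonlinear least squares fit of (R0, dR, Kd) to a titration.

    Requires >= 5 concentration points spanning at least a decade. A
    degenerate outcome (negative, non-finite or unidentifiable Kd) is
    returned censored at the assay bound rather than raised.
    """
    P = curve.protein_conc
    r = curve.anisotropy
    if not np.all(np.isfinite(r)):
        raise ValueError("anisotropy readings must be finite")
    pos = P[P > 0]
    if len(P) < 5:
        raise ValueError(f"need >=5 concentration points, got {len(P)}")
    if len(pos) == 0 or pos.max() / pos.min() < 10:
        raise ValueError("concentration series must span at least one decade")

    r0_guess = float(r[P == 0].mean()) if np.any(P == 0) else float(r.min())
    dr_guess = float(r.max() - r.min()) or 1e-6
    kd_guess = float(np.median(pos))
    p0 = (r0_guess, dr_guess, kd_guess)
    try:
        with warnings.catch_warnings():
            # degenerate (flat) curves legitimately yield a singular
            # covariance; they are censored below, not warned about
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(binding_model, P, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        raise ConvergenceError(f"binding fit did not converge: {exc}", p0) from exc
    R0, dR, Kd = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    fit = BindingFit(
        R0=R0,
        dR=dR,
        Kd=Kd,
        Kd_se=float(se[2]),
        R0_se=float(se[0]),
        dR_se=float(se[1]),
        label=curve.label,
    )
    if not math.isfinite(Kd) or Kd <= 0:
        # flat curves / negative Kd: unidentifiable, censor at the bound
        return replace(fit, Kd=CENSOR_BOUND_UM, Kd_se=math.inf, censored=True)
    return censor_weak(fit, top_conc=float(P.max()))


def censor_weak(
    fit: BindingFit, bound: float = CENSOR_BOUND_UM, top_conc: float | None = None
) -> BindingFit:
    """Censor fits whose Kd is at/above *bound* (exclusive binder boundary).

    Also censors when the 1-sigma interval reaches the bound while the
    titration never reached half-saturation (top tested concentration below
    the fitted Kd).
    """
    # infinite Kd_se means the curve carries no curvature information
    # (e.g. flat readings): Kd is unidentifiable, so censor
    censor = (
        fit.Kd >= bound
        or not math.isfinite(fit.Kd)
        or not math.isfinite(fit.Kd_se)
    )
    if not censor and top_conc is not None and math.isfinite(fit.Kd_se):
        censor = (fit.Kd + fit.Kd_se >= bound) and (top_conc < fit.Kd)
    if censor:
        return replace(fit, Kd=bound, censored=True)
    return replace(fit, censored=False)


@dataclass(frozen=True)
class OccupancyQuery:
    """Total concentrations (uM) for an exact occupancy computation."""

    protein_total: float
    ligand_total: float
    Kd: float

    def __post_init__(self) -> None:
        if self.protein_total < 0 or self.ligand_total < 0 or self.Kd < 0:
            raise ValueError("concentrations and Kd must be non-negative")


def occupancy_exact(
    protein_total: float | OccupancyQuery,
    ligand_total: float | None = None,
    kd: float | None = None,
) -> float:
    """Fraction of protein bound from the exact 1:1 equilibrium.

    PL = [(Pt+Lt+Kd) - sqrt((Pt+Lt+Kd)^2 - 4 Pt Lt)] / 2, returned as
    PL/Pt (physical minus root). Limits handled analytically: Lt=0 -> 0,
    Kd=0 -> min(Pt,Lt)/Pt, Pt->0 -> Lt/(Kd+Lt).
    """
    if isinstance(protein_total, OccupancyQuery):
        q = protein_total
        pt, lt, kd_ = q.protein_total, q.ligand_total, q.Kd
    else:
        if ligand_total is None or kd is None:
            raise TypeError("occupancy_exact requires (Pt, Lt, Kd) or an OccupancyQuery")
        pt, lt, kd_ = float(protein_total), float(ligand_total), float(kd)
    if pt < 0 or lt < 0 or kd_ < 0:
        raise ValueError("inputs must be non-negative")
    if lt == 0:
        return 0.0
    if pt == 0:
        return lt / (kd_ + lt)
    if kd_ == 0:
        return min(pt, lt) / pt
    s = pt + lt + kd_
    disc = s * s - 4.0 * pt * lt
    # numerically stable form avoids cancellation when PL is small
    pl = 2.0 * pt * lt / (s + math.sqrt(disc))
    return pl / pt


def kd_for_occupancy(target_fraction: float, pt: float, lt: float) -> float:
    """Kd producing a given bound fraction; inverse of occupancy_exact.

    Closed form Kd = (Lt - f*Pt) * (1 - f) / f. f = 0 returns +inf;
    fractions at or above min(1, Lt/Pt) are infeasible.
    """
    f = float(target_fraction)
    if f == 0:
        return math.inf
    limit = min(1.0, lt / pt) if pt > 0 else 1.0
    if not 0 < f < limit:
        raise ValueError(
            f"target fraction {f} infeasible: must lie in (0, {limit}) "
            f"for Pt={pt}, Lt={lt}"
        )
    return (lt - f * pt) * (1.0 - f) / f


def read_titration_csv(path, tracer_conc_nM: float = 20.0, label=None) -> TitrationCurve:
    """Read a titration CSV with columns ``conc_uM,anisotropy``."""
    df = pd.read_csv(path)
    missing = {"conc_uM", "anisotropy"} - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    return TitrationCurve(
        df["conc_uM"].to_numpy(),
        df["anisotropy"].to_numpy(),
        tracer_conc_nM=tracer_conc_nM,
        label=label,
    )


def write_titration_csv(curve: TitrationCurve, path) -> None:
    pd.DataFrame(
        {"conc_uM": curve.protein_conc, "anisotropy": curve.anisotropy}
    ).to_csv(path, index=False)


def write_fits_tsv(fits: list[BindingFit], path) -> None:
    """Write fit results: label, R0, dR, Kd, Kd_se, censored."""
    rows = [
        {
            "label": f.label or "",
            "R0": f.R0,
            "dR": f.dR,
            "Kd": f.kd_display,
            "Kd_se": f.Kd_se if not f.censored else "",
            "censored": int(f.censored),
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
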