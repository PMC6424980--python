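"""Exhaustive best-subset regression of array intensities with AIC.

Replicate spot intensities are averaged per pattern, every one of the
2^7 = 128 site subsets is fitted by OLS (intercept always included), models
are ranked by AIC, and the top-k coefficient matrix is exported. A
threshold sweep re-runs the whole analysis after filtering low-signal
peptides to check that the site ranking is robust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import SITE_NAMES, PhosphoPattern

__all__ = [
    "ArraySpot",
    "SubsetModel",
    "ImportanceMatrix",
    "CollinearityError",
    "average_replicates",
    "fit_subset",
    "aic",
    "fit_all_subsets",
    "importance_matrix",
    "aggregate_importance",
    "threshold_robustness",
    "read_array_csv",
    "write_models_tsv",
    "write_importance_tsv",
]

#: Minimum distinct patterns so that the full 7-site model is overdetermined.
MIN_PATTERNS = 9


class CollinearityError(ValueError):
    """Design matrix is rank deficient for the requested support."""

    def __init__(self, support: tuple[str, ...]):
        super().__init__(
            f"rank-deficient design for support {support}: "
            "some site columns are collinear on the supplied patterns"
        )
        self.support = support


@dataclass
class ArraySpot:
    """One array position: a pattern with its replicate intensities."""

    pattern: PhosphoPattern
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 1:
            raise ValueError("spot needs at least one replicate intensity")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class SubsetModel:
    """OLS fit of one site subset (intercept always included)."""

    support: tuple[str, ...]  # site names in sequence order
    coefficients: dict[str, float]
    intercept: float
    rss: float
    n_obs: int
    aic: float
    coef_se: dict[str, float] = field(default_factory=dict)
    intercept_se: float = math.nan

    def coefficient_row(self) -> dict[str, float]:
        """Coefficients over all 7 sites, 0 where excluded, plus intercept."""
        row = {name: self.coefficients.get(name, 0.0) for name in SITE_NAMES}
        row["intercept"] = self.intercept
        return row


@dataclass
class ImportanceMatrix:
    """Top-k models by AIC and their coefficient matrix (k x 8)."""

    models: list[SubsetModel]
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        aics = [m.aic for m in self.models]
        if aics != sorted(aics):
            raise ValueError("models must be sorted ascending by AIC")


def average_replicates(spots: list[ArraySpot]) -> pd.DataFrame:
    """Mean intensity per pattern: DataFrame(label, bitstring, response).

    Spots sharing a bitstring are pooled before averaging.
    """
    if not spots:
        raise ValueError("no spots supplied")
    pooled: dict[str, list] = {}
    labels: dict[str, str] = {}
    for s in spots:
        key = s.pattern.bitstring
        pooled.setdefault(key, []).extend(s.intensities.tolist())
        labels.setdefault(key, s.pattern.label or key)
    rows = [
        {"label": labels[k], "bitstring": k, "response": float(np.mean(v))}
        for k, v in pooled.items()
    ]
    return pd.DataFrame(rows)


def _design(bitstrings: pd.Series, support: tuple[str, ...]) -> np.ndarray:
    bits = np.array([[int(c) for c in s] for s in bitstrings], dtype=float)
    cols = [np.ones(len(bits))]
    cols += [bits[:, SITE_NAMES.index(name)] for name in support]
    return np.column_stack(cols)


def fit_subset(responses: pd.DataFrame, support) -> SubsetModel:
    """OLS fit of ``response ~ intercept + sum(bits[support])``.

    *responses* is the table from :func:`average_replicates`. Raises
    :class:`CollinearityError` when the design is rank deficient.
    """
    support = tuple(sorted(set(support), key=SITE_NAMES.index))
    y = responses["response"].to_numpy(dtype=float)
    X = _design(responses["bitstring"], support)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError(support)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    # floor so sigma=0 data do not produce log(0); constant across models
    rss_floor = max(np.finfo(float).eps * max(tss, 1.0), np.finfo(float).tiny)
    crit = aic(max(rss, rss_floor), n, len(support))
    if n > p:
        sigma2 = max(rss, rss_floor) / (n - p)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ses = np.sqrt(np.diag(cov))
    else:
        ses = np.full(p, math.nan)
    return SubsetModel(
        support=support,
        coefficients={name: float(b) for name, b in zip(support, beta[1:])},
        intercept=float(beta[0]),
        rss=rss,
        n_obs=n,
        aic=crit,
        coef_se={name: float(s) for name, s in zip(support, ses[1:])},
        intercept_se=float(ses[0]),
    )


def aic(rss: float, n_obs: int, n_sites: int) -> float:
    """Gaussian profile-likelihood AIC: n*ln(rss/n) + 2*(n_sites + 1).

    ``n_sites`` is the support size; the +1 counts the intercept. Lower is
    better; constant offsets shared by all models are dropped.
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    n_params = n_sites + 1
    if n_obs <= n_params:
        raise ValueError(f"n_obs ({n_obs}) must exceed n_params ({n_params})")
    rss = max(rss, np.finfo(float).tiny)
    return n_obs * math.log(rss / n_obs) + 2.0 * n_params


def _model_sort_key(m: SubsetModel):
    # ties in AIC: prefer smaller support, then lexicographic site order
    return (m.aic, len(m.support), tuple(SITE_NAMES.index(s) for s in m.support))


def fit_all_subsets(responses: pd.DataFrame) -> list[SubsetModel]:
    """Fit all 128 site subsets; returns models sorted ascending by AIC."""
    n_distinct = responses["bitstring"].nunique()
    if n_distinct < MIN_PATTERNS:
        raise ValueError(
            f"need >= {MIN_PATTERNS} distinct patterns for the exhaustive "
            f"search, got {n_distinct}"
        )
    models = []
    for k in range(len(SITE_NAMES) + 1):
        for support in combinations(SITE_NAMES, k):
            models.append(fit_subset(responses, support))
    models.sort(key=_model_sort_key)
    return models


def importance_matrix(models: list[SubsetModel], k: int = 20) -> ImportanceMatrix:
    """Coefficient matrix of the top-k models by AIC (k x 7 sites + intercept)."""
    if k > len(models):
        raise ValueError(f"k={k} exceeds the {len(models)} available models")
    top = sorted(models, key=_model_sort_key)[:k]
    matrix = pd.DataFrame([m.coefficient_row() for m in top])
    matrix.index = ["".join("1" if s in m.support else "0" for s in SITE_NAMES) for m in top]
    matrix.index.name = "support"
    return ImportanceMatrix(models=top, matrix=matrix)


def aggregate_importance(models: list[SubsetModel]) -> pd.Series:
    """Akaike-weighted mean coefficient per site over all models.

    Weights are exp(-dAIC/2) normalized to 1; excluded sites contribute 0.
    Used to produce a scalar site ranking for robustness reports.
    """
    aics = np.array([m.aic for m in models])
    w = np.exp(-(aics - aics.min()) / 2.0)
    w = w / w.sum()
    scores = {}
    for name in SITE_NAMES:
        coefs = np.array([m.coefficients.get(name, 0.0) for m in models])
        scores[name] = float(np.dot(w, coefs))
    return pd.Series(scores).sort_values(ascending=False)


def threshold_robustness(
    spots: list[ArraySpot], thresholds
) -> dict[float, list[str] | None]:
    """Site ranking after filtering out low-signal peptides, per threshold.

    A peptide is kept when its mean intensity >= threshold. Thresholds that
    leave fewer than MIN_PATTERNS patterns are reported as infeasible
    (``None``), not fatal.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    responses = average_replicates(spots)
    out: dict[float, list[str] | None] = {}
    for t in thresholds:
        kept = responses[responses["response"] >= t]
        if kept["bitstring"].nunique() < MIN_PATTERNS:
            out[t] = None
            continue
        models = fit_all_subsets(kept.reset_index(drop=True))
        out[t] = list(aggregate_importance(models).index)
    return out


# ---------------------------------------------------------------------------
# file I/O

def read_array_csv(path) -> list[ArraySpot]:
    """Read spots from a CSV with columns label, bitstring, rep1..repN."""
    df = pd.read_csv(path, dtype={"label": str, "bitstring": str})
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols or {"label", "bitstring"} - set(df.columns):
        raise ValueError("array CSV needs columns label, bitstring, rep1..repN")
    spots = []
    for _, row in df.iterrows():
        pattern = PhosphoPattern.from_bitstring(str(row["bitstring"]), str(row["label"]))
        vals = row[rep_cols].to_numpy(dtype=float)
        spots.append(ArraySpot(pattern, vals[np.isfinite(vals)]))
    return spots


def write_models_tsv(models: list[SubsetModel], path) -> None:
    rows = []
    for m in models:
        row = {
            "support": "".join("1" if s in m.support else "0" for s in SITE_NAMES),
            "aic": m.aic,
            "rss": m.rss,
            "intercept": m.intercept,
        }
        row.update({s: m.coefficients.get(s, 0.0) for s in SITE_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_importance_tsv(im: ImportanceMatrix, path) -> None:
    im.matrix.to_csv(path, sep="\t")
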