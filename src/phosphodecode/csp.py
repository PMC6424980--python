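"""Chemical shift perturbation analysis of amide titration series.

The combined perturbation per residue is the weighted Euclidean distance
``sqrt((w * dN)^2 + dH^2)`` with w = 0.2 between the peptide-bound and the
free spectrum. Trajectories are tracked against the peptide-free reference
across stoichiometric ratios, line-broadened residues are flagged from
intensity loss, and final perturbations are binned into five classes
(nonsignificant .. very_large).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import occupancy_exact

__all__ = [
    "CSP_CLASSES",
    "PeakPosition",
    "CSPRecord",
    "CSPConfig",
    "compute_csp",
    "track_trajectory",
    "classify_csp",
    "percentile_edges",
    "analyze_titration",
    "saturation_report",
    "read_sparky_peaklist",
    "read_peaklist_csv",
    "write_csp_tsv",
    "write_class_map",
]

CSP_CLASSES = ("nonsignificant", "minor", "moderate", "large", "very_large", "broadened")


@dataclass(frozen=True)
class PeakPosition:
    """One amide cross peak in one spectrum of the titration."""

    residue: str
    dH: float  # 1H shift, ppm
    dN: float  # 15N shift, ppm
    intensity: float = 1.0
    ratio: float = 0.0  # peptide:protein stoichiometric ratio

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH) and math.isfinite(self.dN)):
            raise ValueError(f"non-finite shift for residue {self.residue}")
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")


@dataclass
class CSPConfig:
    """Analysis knobs.

    ``class_edges`` are four ascending ppm thresholds; when ``None`` the
    dataset-level analysis derives them as the 20/40/60/80th percentiles of
    the nonzero perturbations.
    """

    n_weight: float = 0.2
    class_edges: tuple[float, float, float, float] | None = None
    broadening_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.n_weight <= 1:
            raise ValueError("n_weight must lie in (0, 1]")
        if self.class_edges is not None:
            e = tuple(self.class_edges)
            if len(e) != 4 or list(e) != sorted(e) or len(set(e)) != 4:
                raise ValueError("class_edges must be four strictly ascending values")
            self.class_edges = e
        if not 0 < self.broadening_ratio < 1:
            raise ValueError("broadening_ratio must lie in (0, 1)")


@dataclass
class CSPRecord:
    """Per-residue perturbation trajectory and classification."""

    residue: str
    delta: dict[float, float]  # ratio -> combined shift change (ppm)
    final_delta: float
    broadened: bool = False
    csp_class: str | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.delta.values()):
            raise ValueError("perturbations must be >= 0")
        if self.broadened:
            self.csp_class = "broadened"


def compute_csp(
    free: PeakPosition, bound: PeakPosition, cfg: CSPConfig | None = None
) -> float:
    """Weighted combined shift change between a free and a bound peak."""
    cfg = cfg or CSPConfig()
    if free.residue != bound.residue:
        raise ValueError(
            f"residue mismatch: free={free.residue!r} vs bound={bound.residue!r}"
        )
    return math.hypot(cfg.n_weight * (bound.dN - free.dN), bound.dH - free.dH)


def track_trajectory(
    peaks: Sequence[PeakPosition], cfg: CSPConfig | None = None
) -> CSPRecord:
    """Follow one residue across ratios; perturbations vs the ratio-0 peak.

    Broadening is evaluated before classification: a residue is broadened
    when its endpoint intensity falls below ``broadening_ratio`` times the
    reference intensity. Classification itself is left to
    :func:`classify_csp` (it may need cohort-level edges).
    """
    cfg = cfg or CSPConfig()
    if not peaks:
        raise ValueError("empty trajectory")
    residues = {p.residue for p in peaks}
    if len(residues) > 1:
        raise ValueError(f"trajectory mixes residues: {sorted(residues)}")
    peaks = sorted(peaks, key=lambda p: p.ratio)
    if peaks[0].ratio != 0:
        raise ValueError(f"missing ratio-0 reference for residue {peaks[0].residue}")
    ref = peaks[0]
    delta = {p.ratio: compute_csp(ref, p, cfg) for p in peaks}
    endpoint = peaks[-1]
    broadened = bool(
        ref.intensity > 0
        and endpoint.intensity < cfg.broadening_ratio * ref.intensity
    )
    return CSPRecord(
        residue=ref.residue,
        delta=delta,
        final_delta=delta[endpoint.ratio],
        broadened=broadened,
    )


def classify_csp(record: CSPRecord, cfg: CSPConfig) -> str:
    """Bin the endpoint perturbation; broadening overrides the bins."""
    if record.broadened:
        record.csp_class = "broadened"
        return record.csp_class
    if cfg.class_edges is None:
        raise ValueError(
            "no class_edges configured; supply fixed edges or use "
            "analyze_titration for percentile-based defaults"
        )
    e1, e2, e3, e4 = cfg.class_edges
    d = record.final_delta
    if d < e1:
        cls = "nonsignificant"
    elif d < e2:
        cls = "minor"
    elif d < e3:
        cls = "moderate"
    elif d < e4:
        cls = "large"
    else:
        cls = "very_large"
    record.csp_class = cls
    return cls


def percentile_edges(final_deltas: Sequence[float]) -> tuple[float, float, float, float]:
    """Default class edges: 20/40/60/80th percentiles of nonzero deltas."""
    nonzero = np.asarray([d for d in final_deltas if d > 0], dtype=float)
    if nonzero.size == 0:
        raise ValueError("no nonzero perturbations to derive edges from")
    e = tuple(float(v) for v in np.percentile(nonzero, [20, 40, 60, 80]))
    if len(set(e)) != 4:
        raise ValueError("degenerate perturbation distribution: edges not distinct")
    return e  # type: ignore[return-value]


_UNASSIGNED = re.compile(r"^(unass|\?)", re.IGNORECASE)


def is_unassigned(residue: str) -> bool:
    return bool(_UNASSIGNED.match(residue))


def analyze_titration(
    spectra: Mapping[float, Sequence[PeakPosition]],
    cfg: CSPConfig | None = None,
) -> list[CSPRecord]:
    """Full dataset analysis: match residues by id, track, flag, classify.

    Each spectrum's intensities are median-normalized before broadening
    assessment. A residue present in the reference but missing from the
    endpoint spectrum is flagged broadened (peak lost). Unassigned peaks
    get a trajectory but are excluded from classification (class ``None``)
    and from percentile-edge derivation.
    """
    cfg = cfg or CSPConfig()
    if 0 not in spectra and 0.0 not in spectra:
        raise ValueError("titration is missing the ratio-0 reference spectrum")
    normed: dict[float, dict[str, PeakPosition]] = {}
    for ratio, peaks in spectra.items():
        med = float(np.median([p.intensity for p in peaks])) or 1.0
        normed[float(ratio)] = {
            p.residue: PeakPosition(
                p.residue, p.dH, p.dN, p.intensity / med, float(ratio)
            )
            for p in peaks
        }
    ratios = sorted(normed)
    ref_ratio, end_ratio = ratios[0], ratios[-1]
    records = []
    for residue, ref_peak in normed[ref_ratio].items():
        traj = [normed[r][residue] for r in ratios if residue in normed[r]]
        if residue not in normed[end_ratio]:
            # endpoint peak vanished: collapsed intensity -> broadened
            rec = track_trajectory(traj, cfg) if len(traj) > 1 else CSPRecord(
                residue, {ref_ratio: 0.0}, 0.0
            )
            rec.broadened = True
            rec.csp_class = "broadened"
            records.append(rec)
            continue
        records.append(track_trajectory(traj, cfg))
    # derive cohort edges if not fixed, then classify assigned residues
    eff_cfg = cfg
    if cfg.class_edges is None:
        pool = [
            r.final_delta
            for r in records
            if not r.broadened and not is_unassigned(r.residue)
        ]
        eff_cfg = CSPConfig(
            n_weight=cfg.n_weight,
            class_edges=percentile_edges(pool),
            broadening_ratio=cfg.broadening_ratio,
        )
    for rec in records:
        if is_unassigned(rec.residue) and not rec.broadened:
            rec.csp_class = None
            continue
        classify_csp(rec, eff_cfg)
    return records


def saturation_report(
    kd: float, protein_conc: float, ratios: Sequence[float]
) -> dict[float, float]:
    """Protein-bound fraction at each peptide:protein ratio."""
    return {
        float(r): occupancy_exact(protein_conc, float(r) * protein_conc, kd)
        for r in ratios
    }


# ---------------------------------------------------------------------------
# file I/O

_ASSIGNMENT = re.compile(r"^(?P<res>.+?)(?:N-HN?|H-N)?$")


def _residue_from_assignment(assignment: str) -> str:
    m = _ASSIGNMENT.match(assignment)
    return m.group("res") if m else assignment


def read_sparky_peaklist(path, ratio: float = 0.0) -> list[PeakPosition]:
    """Read a Sparky-like list: Assignment, w1 (15N ppm), w2 (1H ppm), Height."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].lower() == "assignment":
                continue
            if len(parts) < 3:
                raise ValueError(f"malformed peak list line: {line!r}")
            residue = _residue_from_assignment(parts[0])
            w1, w2 = float(parts[1]), float(parts[2])
            height = float(parts[3]) if len(parts) > 3 else 1.0
            peaks.append(PeakPosition(residue, dH=w2, dN=w1, intensity=height, ratio=ratio))
    return peaks


def read_peaklist_csv(path, ratio: float = 0.0) -> list[PeakPosition]:
    """CSV equivalent with columns residue, dH, dN[, intensity]."""
    df = pd.read_csv(path)
    missing = {"residue", "dH", "dN"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list CSV missing columns: {sorted(missing)}")
    inten = df["intensity"] if "intensity" in df.columns else pd.Series(1.0, index=df.index)
    return [
        PeakPosition(str(r), float(h), float(n), float(i), ratio)
        for r, h, n, i in zip(df["residue"], df["dH"], df["dN"], inten)
    ]


def write_csp_tsv(records: list[CSPRecord], path) -> None:
    """residue, delta per ratio, final_delta, class, broadened."""
    ratios = sorted({r for rec in records for r in rec.delta})
    rows = []
    for rec in records:
        row = {"residue": rec.residue}
        for r in ratios:
            row[f"delta_{r:g}"] = rec.delta.get(r, math.nan)
        row["final_delta"] = rec.final_delta
        row["class"] = rec.csp_class or ""
        row["broadened"] = int(rec.broadened)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_class_map(records: list[CSPRecord], path) -> None:
    """Two-column residue-number -> class map for structure coloring."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.csp_class is None:
                continue
            m = re.search(r"(\d+)", rec.residue)
            if not m:
                continue
            fh.write(f"{m.group(1)}\t{rec.csp_class}\n")
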