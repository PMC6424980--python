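"""Synthetic datasets with known ground truth for the three assays.

Forward models mirror exactly what the analysis modules assume:

* array spots: additive per-site intensities + intercept + Gaussian
  replicate noise (clipped at zero);
* anisotropy titrations: the no-depletion hyperbola over a geometric
  dilution series plus a buffer-only control;
* NMR titrations: fast-exchange population-weighted amide shifts with the
  bound fraction from the exact 1:1 equilibrium, plus a broadened-residue
  subset whose peak intensities collapse at high peptide ratios.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationCurve, binding_model, occupancy_exact
from .core import SITE_NAMES, PeptidePanel

__all__ = [
    "ArrayGroundTruth",
    "TitrationGroundTruth",
    "CSPGroundTruth",
    "gen_array",
    "gen_titration",
    "gen_csp_dataset",
    "write_array_csv",
    "write_peaklists",
]


@dataclass
class ArrayGroundTruth:
    """True additive model behind a simulated peptide array."""

    theta: tuple[float, ...]  # per-site contribution, sequence order
    intercept: float = 0.0  # "non-specific" baseline
    noise_sd: float = 0.0
    replicates: int = 4

    def __post_init__(self) -> None:
        if len(self.theta) != len(SITE_NAMES):
            raise ValueError(f"theta must have {len(SITE_NAMES)} entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def expected_intensity(self, bits) -> float:
        return self.intercept + float(np.dot(bits, self.theta))


@dataclass
class TitrationGroundTruth:
    """True parameters behind a simulated anisotropy titration."""

    Kd: float  # uM
    R0: float = 0.05
    dR: float = 0.10
    tracer_conc_nM: float = 20.0
    n_steps: int = 11
    top_conc: float = 500.0  # uM
    dilution_factor: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")

    def concentrations(self) -> np.ndarray:
        """Geometric dilution series (descending) plus the buffer control."""
        series = self.top_conc / self.dilution_factor ** np.arange(self.n_steps)
        return np.append(series, 0.0)


@dataclass
class CSPGroundTruth:
    """True structure behind a simulated NMR titration series."""

    n_residues: int = 60
    perturbed_fraction: float = 0.5
    dmax_H: float = 0.12  # ppm, max bound-state 1H shift change
    dmax_N: float = 0.8  # ppm, max bound-state 15N shift change
    Kd: float = 50.0  # uM
    protein_conc: float = 100.0  # uM
    ratios: tuple[float, ...] = (0.0, 1.0, 4.0, 10.0)
    broadened_fraction: float = 0.1
    shift_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("perturbed_fraction", "broadened_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be > 0")
        if 0.0 not in self.ratios:
            raise ValueError("ratios must include the peptide-free reference 0")

    def occupancy(self, ratio: float) -> float:
        return occupancy_exact(self.protein_conc, ratio * self.protein_conc, self.Kd)


def gen_array(truth: ArrayGroundTruth, panel: PeptidePanel, seed: int):
    """Simulate replicate spot intensities for every peptide in *panel*.

    Returns a list of :class:`~phosphodecode.array_fit.ArraySpot`. Noise is
    additive Gaussian, clipped at zero (intensities are non-negative).
    """
    from .array_fit import ArraySpot  # local import to avoid a cycle

    if len(panel) == 0:
        raise ValueError("panel must be nonempty")
    rng = np.random.default_rng(seed)
    spots = []
    for pep in panel:
        mean = truth.expected_intensity(pep.bits)
        vals = mean + rng.normal(0.0, truth.noise_sd, size=truth.replicates)
        spots.append(ArraySpot(pep, np.clip(vals, 0.0, None)))
    return spots


def gen_titration(truth: TitrationGroundTruth, seed: int, label=None) -> TitrationCurve:
    """Simulate one anisotropy titration from the hyperbolic forward model."""
    rng = np.random.default_rng(seed)
    conc = truth.concentrations()
    r = binding_model(conc, truth.R0, truth.dR, truth.Kd)
    r = r + rng.normal(0.0, truth.noise_sd, size=conc.shape)
    return TitrationCurve(conc, r, tracer_conc_nM=truth.tracer_conc_nM, label=label)


#: Endpoint intensity (x reference) planted for broadened residues; must sit
#: below the default broadening threshold of 0.3.
_BROADENED_END_FACTOR = 0.1


def _plant(truth: CSPGroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-residue latent state shared by dataset and truth table."""
    n = truth.n_residues
    free_H = rng.uniform(6.5, 10.5, size=n)
    free_N = rng.uniform(105.0, 135.0, size=n)
    ref_intensity = rng.uniform(0.8, 1.2, size=n)
    n_pert = int(round(truth.perturbed_fraction * n))
    n_broad = int(round(truth.broadened_fraction * n))
    perm = rng.permutation(n)
    perturbed = np.zeros(n, dtype=bool)
    perturbed[perm[:n_pert]] = True
    broadened = np.zeros(n, dtype=bool)  # broadened residues are also perturbed
    broadened[perm[:n_broad]] = True
    # per-residue bound-state shift change; spread over [0.25, 1]*dmax so a
    # cohort spans the whole perturbation-class rainbow
    scale = rng.uniform(0.25, 1.0, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return pd.DataFrame(
        {
            "residue": [f"R{i+1}" for i in range(n)],
            "free_H": free_H,
            "free_N": free_N,
            "ref_intensity": ref_intensity,
            "dmax_H": np.where(perturbed, scale * truth.dmax_H, 0.0),
            "dmax_N": np.where(perturbed, scale * truth.dmax_N * sign, 0.0),
            "perturbed": perturbed,
            "broadened": broadened,
        }
    )


def gen_csp_dataset(truth: CSPGroundTruth, seed: int) -> dict[float, pd.DataFrame]:
    """Simulate per-ratio amide peak tables for a fast-exchange titration.

    Returns ``{ratio: DataFrame(residue, dH, dN, intensity)}``. Perturbed
    residues move by ``occupancy * dmax`` (population-weighted average of
    free and bound shifts); broadened residues lose intensity linearly in
    occupancy down to 0.1x reference at the endpoint.
    """
    rng = np.random.default_rng(seed)
    plant = _plant(truth, rng)
    n = truth.n_residues
    end_occ = truth.occupancy(max(truth.ratios))
    out: dict[float, pd.DataFrame] = {}
    for ratio in sorted(truth.ratios):
        occ = truth.occupancy(ratio)
        obs_H = plant.free_H + occ * plant.dmax_H
        obs_N = plant.free_N + occ * plant.dmax_N
        if truth.shift_noise_sd:
            obs_H = obs_H + rng.normal(0.0, truth.shift_noise_sd, size=n)
            obs_N = obs_N + rng.normal(0.0, 5.0 * truth.shift_noise_sd, size=n)
        inten = plant.ref_intensity.to_numpy().copy()
        if end_occ > 0:
            decay = 1.0 - (1.0 - _BROADENED_END_FACTOR) * occ / end_occ
            inten[plant.broadened.to_numpy()] *= decay
        out[ratio] = pd.DataFrame(
            {
                "residue": plant.residue,
                "dH": obs_H,
                "dN": obs_N,
                "intensity": inten,
            }
        )
    return out


def csp_ground_truth_table(truth: CSPGroundTruth, seed: int) -> pd.DataFrame:
    """Planted per-residue truth for the same seed as :func:`gen_csp_dataset`."""
    rng = np.random.default_rng(seed)
    cols = ["residue", "dmax_H", "dmax_N", "perturbed", "broadened"]
    return _plant(truth, rng)[cols]


def write_array_csv(spots, path) -> None:
    """Write spots in the array CSV dialect: label, bitstring, rep1..repN."""
    n_rep = max(len(s.intensities) for s in spots)
    rows = []
    for s in spots:
        row = {
            "label": s.pattern.label or s.pattern.bitstring,
            "bitstring": s.pattern.bitstring,
        }
        for j in range(n_rep):
            row[f"rep{j+1}"] = (
                s.intensities[j] if j < len(s.intensities) else np.nan
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_peaklists(dataset: dict[float, pd.DataFrame], outdir, fmt: str = "sparky"):
    """Write one peak list per titration ratio; returns the file paths.

    ``fmt="sparky"`` emits the Sparky-like whitespace dialect read by
    :func:`phosphodecode.csp.read_sparky_peaklist`; ``fmt="csv"`` emits the
    CSV equivalent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ratio, df in dataset.items():
        tag = f"{ratio:g}".replace(".", "p")
        if fmt == "sparky":
            path = outdir / f"ratio_{tag}.list"
            with open(path, "w") as fh:
                fh.write(f"{'Assignment':>17} {'w1':>8} {'w2':>8} {'Height':>12}\n\n")
                for _, row in df.iterrows():
                    fh.write(
                        f"{row.residue + 'N-H':>17} {row.dN:8.3f} "
                        f"{row.dH:8.3f} {row.intensity:12.4e}\n"
                    )
        elif fmt == "csv":
            path = outdir / f"ratio_{tag}.csv"
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown peak list format: {fmt!r}")
        paths[ratio] = path
    return paths
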