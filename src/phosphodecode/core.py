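"""Domain types and combinatorics for rhodopsin C-terminal phosphopatterns.

Seven serine/threonine sites on the rhodopsin C-terminus can carry a
phosphate; a peptide's identity is its 7-bit occupancy vector over those
sites (sequence order S334, T335, T336, S338, T340, T342, S343). Everything
downstream — the array regression design matrix, the binding panel, the
motif rules — is keyed on these patterns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

__all__ = [
    "SITE_NAMES",
    "BACKBONE_SEQUENCE",
    "PhosphoSite",
    "PhosphoPattern",
    "PeptidePanel",
    "SITES",
    "encode_pattern",
    "enumerate_patterns",
    "phospho_count",
    "default_panel",
]

#: Canonical phosphosite names in sequence order.
SITE_NAMES: tuple[str, ...] = ("S334", "T335", "T336", "S338", "T340", "T342", "S343")

#: Invariant peptide backbone (rhodopsin C-terminus with N-terminal Cys).
BACKBONE_SEQUENCE = "CDDEASTTVSKTETSQVAPA"

#: Residue number of each site, parsed from its name.
SITE_POSITIONS: tuple[int, ...] = tuple(int(name[1:]) for name in SITE_NAMES)


@dataclass(frozen=True)
class PhosphoSite:
    """One of the seven phosphorylatable residues.

    Attributes
    ----------
    name : str
        Residue name, e.g. ``"T340"``.
    index : int
        Ordinal 0-6 in sequence order.
    """

    name: str
    index: int

    def __post_init__(self) -> None:
        if self.name not in SITE_NAMES:
            raise ValueError(f"unknown phosphosite name: {self.name!r}")
        if SITE_NAMES[self.index] != self.name:
            raise ValueError(
                f"site {self.name!r} must have index {SITE_NAMES.index(self.name)}, "
                f"got {self.index}"
            )

    @property
    def position(self) -> int:
        """Residue number in the receptor sequence (e.g. 340)."""
        return int(self.name[1:])


#: Registry of the seven canonical sites, keyed by name.
SITES: dict[str, PhosphoSite] = {
    name: PhosphoSite(name, i) for i, name in enumerate(SITE_NAMES)
}


def _coerce_site_name(site: str | PhosphoSite) -> str:
    name = site.name if isinstance(site, PhosphoSite) else site
    if name not in SITES:
        raise ValueError(f"unknown phosphosite name: {name!r}")
    return name


@dataclass(frozen=True)
class PhosphoPattern:
    """A 7-bit phosphorylation occupancy vector, optionally labelled.

    ``bits[i]`` is 1 iff ``SITE_NAMES[i]`` carries a phosphate.
    """

    bits: tuple[int, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.bits) != len(SITE_NAMES):
            raise ValueError(f"expected {len(SITE_NAMES)} bits, got {len(self.bits)}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be 0/1, got {self.bits}")
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        # Label conventions: 0P is the unphosphorylated control, 7P the
        # fully phosphorylated peptide.
        if self.label == "0P" and any(self.bits):
            raise ValueError("label '0P' requires the all-zero pattern")
        if self.label == "7P" and not all(self.bits):
            raise ValueError("label '7P' requires the all-one pattern")

    @classmethod
    def from_sites(
        cls, sites: Iterable[str | PhosphoSite], label: str | None = None
    ) -> "PhosphoPattern":
        names = {_coerce_site_name(s) for s in sites}
        bits = tuple(1 if name in names else 0 for name in SITE_NAMES)
        return cls(bits, label)

    @classmethod
    def from_bitstring(cls, s: str, label: str | None = None) -> "PhosphoPattern":
        s = s.strip()
        if len(s) != len(SITE_NAMES) or set(s) - {"0", "1"}:
            raise ValueError(f"bitstring must be 7 characters of 0/1, got {s!r}")
        return cls(tuple(int(c) for c in s), label)

    @property
    def bitstring(self) -> str:
        """Serialized form used in all files, e.g. ``"0000111"``."""
        return "".join(str(b) for b in self.bits)

    def sites(self) -> frozenset[PhosphoSite]:
        """The set of phosphorylated sites (decode of the bit vector)."""
        return frozenset(SITES[SITE_NAMES[i]] for i, b in enumerate(self.bits) if b)

    def site_names(self) -> frozenset[str]:
        return frozenset(SITE_NAMES[i] for i, b in enumerate(self.bits) if b)

    def has(self, site: str | PhosphoSite) -> bool:
        return bool(self.bits[SITES[_coerce_site_name(site)].index])

    @property
    def count(self) -> int:
        return sum(self.bits)

    def positions(self) -> tuple[int, ...]:
        """Residue numbers of the phosphorylated sites, ascending."""
        return tuple(SITE_POSITIONS[i] for i, b in enumerate(self.bits) if b)


def encode_pattern(
    sites_phosphorylated: Iterable[str | PhosphoSite], label: str | None = None
) -> PhosphoPattern:
    """Build a pattern with a 1 exactly at each given site.

    Raises ``ValueError`` naming the first unknown site.
    """
    return PhosphoPattern.from_sites(sites_phosphorylated, label)


def phospho_count(pattern: PhosphoPattern) -> int:
    """Number of phosphorylated sites in *pattern*."""
    return pattern.count


def enumerate_patterns(
    n_sites: int, max_phospho: int
) -> list[PhosphoPattern] | list[tuple[int, ...]]:
    """Every occupancy pattern with 0..max_phospho set bits, exactly once.

    Order is deterministic: by phospho count, then lexicographically by the
    site-index combination. For ``n_sites == 7`` (the canonical panel) the
    result is a list of :class:`PhosphoPattern`; for other ``n_sites`` raw
    bit tuples are returned.
    """
    if n_sites < 0 or max_phospho < 0:
        raise ValueError("n_sites and max_phospho must be non-negative")
    if max_phospho > n_sites:
        raise ValueError(f"max_phospho ({max_phospho}) exceeds n_sites ({n_sites})")
    out: list[tuple[int, ...]] = []
    for k in range(max_phospho + 1):
        for idx in combinations(range(n_sites), k):
            bits = [0] * n_sites
            for i in idx:
                bits[i] = 1
            out.append(tuple(bits))
    if n_sites == len(SITE_NAMES):
        return [PhosphoPattern(bits) for bits in out]
    return out


def n_patterns(n_sites: int, max_phospho: int) -> int:
    """Closed form Σ_{i=0..k} C(n, i) — count without enumerating."""
    return sum(comb(n_sites, i) for i in range(max_phospho + 1))


@dataclass
class PeptidePanel:
    """An ordered collection of named patterns over the invariant backbone."""

    peptides: list[PhosphoPattern] = field(default_factory=list)
    sequence: str = BACKBONE_SEQUENCE

    def __post_init__(self) -> None:
        labels = [p.label for p in self.peptides]
        if any(lab is None for lab in labels):
            raise ValueError("every panel peptide must carry a label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValueError(f"duplicate peptide labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def __getitem__(self, label: str) -> PhosphoPattern:
        for p in self.peptides:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.peptides]  # type: ignore[misc]

    @classmethod
    def from_csv(cls, path) -> "PeptidePanel":
        """Read a panel definition CSV with columns ``label,bitstring``."""
        peptides = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                peptides.append(
                    PhosphoPattern.from_bitstring(row["bitstring"], row["label"])
                )
        return cls(peptides)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "bitstring"])
            for p in self.peptides:
                w.writerow([p.label, p.bitstring])


def default_panel() -> PeptidePanel:
    """The packaged peptide panel (0P, 7P and the named 3P-6P peptides)."""
    ref = resources.files("phosphodecode.data").joinpath("panel.csv")
    peptides = []
    with ref.open(newline="") as fh:
        for row in csv.DictReader(fh):
            peptides.append(PhosphoPattern.from_bitstring(row["bitstring"], row["label"]))
    return PeptidePanel(peptides)


def combinatorial_panel(max_phospho: int = 3) -> PeptidePanel:
    """Panel of all patterns up to *max_phospho* phosphates, labelled by bitstring."""
    peptides = [
        PhosphoPattern(p.bits, label=p.bitstring)
        for p in enumerate_patterns(len(SITE_NAMES), max_phospho)
    ]
    return PeptidePanel(peptides)
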