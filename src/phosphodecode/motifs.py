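"""Site-role rules, pattern-level predictions and concordance reporting.

The seven sites carry fixed functional roles (key / inhibitory / secondary /
modulator). Three pure predicates over a pattern predict arrestin-1 binding
class, C-tail release and ternary-complex formation; a concordance report
compares the predictions against measured annotations. ``motif_scan``
evaluates user-supplied boolean motif definitions so external barcode
proposals can be tested without code changes.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .core import SITE_NAMES, SITES, PeptidePanel, PhosphoPattern, PhosphoSite

__all__ = [
    "SiteRole",
    "ROLE_MAP",
    "assign_roles",
    "predict_arr1_binding",
    "predict_ctail_release",
    "predict_ternary",
    "predict_arr2_binding",
    "ConcordanceReport",
    "concordance_table",
    "text_reference_annotations",
    "MotifSyntaxError",
    "compile_motif",
    "motif_scan",
]

KEY_SITES = ("T340", "S343")
INHIBITORY_SITE = "T342"
SECONDARY_SITES = ("T335", "S338")
MODULATOR_SITES = ("S334", "T336")

#: Phosphate count above which the inhibitory site no longer abrogates
#: binding (tri-phosphorylated peptides are inhibited; 4P/6P/7P are not).
INHIBITION_MAX_COUNT = 3


@dataclass(frozen=True)
class SiteRole:
    site: PhosphoSite
    role: str  # key | inhibitory | secondary | modulator
    modulator_member: bool = False  # secondary sites also belong to the
    # wider modulator group in the alternative taxonomy

    def __post_init__(self) -> None:
        if self.role not in {"key", "inhibitory", "secondary", "modulator"}:
            raise ValueError(f"unknown role {self.role!r}")


def assign_roles() -> list[SiteRole]:
    """The fixed role map, one primary role per site."""
    roles = []
    for name in SITE_NAMES:
        if name in KEY_SITES:
            role = "key"
        elif name == INHIBITORY_SITE:
            role = "inhibitory"
        elif name in SECONDARY_SITES:
            role = "secondary"
        else:
            role = "modulator"
        roles.append(
            SiteRole(SITES[name], role, modulator_member=name in SECONDARY_SITES)
        )
    return roles


ROLE_MAP: dict[str, str] = {r.site.name: r.role for r in assign_roles()}


def _both_keys(pattern: PhosphoPattern) -> bool:
    return all(pattern.has(s) for s in KEY_SITES)


def _inhibited(pattern: PhosphoPattern) -> bool:
    return pattern.has(INHIBITORY_SITE) and pattern.count <= INHIBITION_MAX_COUNT


def predict_arr1_binding(pattern: PhosphoPattern) -> str:
    """'tight' iff both key sites are set and the inhibitory gate is off."""
    return "tight" if _both_keys(pattern) and not _inhibited(pattern) else "weak"


def predict_ctail_release(pattern: PhosphoPattern) -> str:
    """C-tail displacement tracks tight binding exactly."""
    return "yes" if predict_arr1_binding(pattern) == "tight" else "no"


def predict_ternary(pattern: PhosphoPattern) -> str:
    """Ternary complex class: robust / moderate / low.

    Moderate requires exactly one key site plus both secondary sites.
    """
    if predict_arr1_binding(pattern) == "tight":
        return "robust"
    n_keys = sum(pattern.has(s) for s in KEY_SITES)
    if n_keys == 1 and all(pattern.has(s) for s in SECONDARY_SITES):
        return "moderate"
    return "low"


#: Patterns the paper reports as arrestin-2 binders despite failing the
#: arrestin-1 rule (5P lacking S343; 3Pf carrying the inhibitory site).
_ARR2_EXCEPTION_BITSTRINGS = frozenset({"1111100", "0000111"})


def predict_arr2_binding(pattern: PhosphoPattern) -> str:
    """Limited arrestin-2 rule: key sites, plus the 5P/3Pf exceptions."""
    if _both_keys(pattern) or pattern.bitstring in _ARR2_EXCEPTION_BITSTRINGS:
        return "tight"
    return "weak"


# ---------------------------------------------------------------------------
# concordance

@dataclass
class ConcordanceReport:
    table: pd.DataFrame
    accuracy: dict[str, float]
    orphans: list[str]


_MEASURED_COLS = {"arr1_binding", "ctail_release", "ternary"}


def concordance_table(
    panel: PeptidePanel, measured: pd.DataFrame | None = None
) -> ConcordanceReport:
    """Predictions per peptide, joined against measured annotations.

    *measured*, when supplied, is indexed by peptide label with any subset
    of the columns arr1_binding (tight/weak), ctail_release (yes/no),
    ternary (robust/moderate/low). Labels absent from the panel are listed
    as orphans; agreement flags and per-assay accuracy cover the labels
    present in both.
    """
    rows = []
    for pep in panel:
        rows.append(
            {
                "label": pep.label,
                "bitstring": pep.bitstring,
                "n_phospho": pep.count,
                "pred_arr1_binding": predict_arr1_binding(pep),
                "pred_ctail_release": predict_ctail_release(pep),
                "pred_ternary": predict_ternary(pep),
            }
        )
    table = pd.DataFrame(rows).set_index("label")
    orphans: list[str] = []
    accuracy: dict[str, float] = {}
    if measured is not None:
        unknown = set(measured.columns) - _MEASURED_COLS
        if unknown:
            raise ValueError(f"unknown measured columns: {sorted(unknown)}")
        orphans = sorted(set(measured.index) - set(table.index))
        joined = measured.reindex(table.index)
        for col in measured.columns:
            table[f"measured_{col}"] = joined[col]
            pred_col = {
                "arr1_binding": "pred_arr1_binding",
                "ctail_release": "pred_ctail_release",
                "ternary": "pred_ternary",
            }[col]
            have = joined[col].notna()
            agree = table.loc[have, pred_col] == joined.loc[have, col]
            table[f"agree_{col}"] = pd.Series(agree, index=table.index)
            accuracy[col] = float(agree.mean()) if have.any() else float("nan")
    return ConcordanceReport(table=table, accuracy=accuracy, orphans=orphans)


def text_reference_annotations() -> pd.DataFrame:
    """Packaged qualitative annotations (binding / C-tail / ternary calls)."""
    ref = resources.files("phosphodecode.data").joinpath("text_reference.csv")
    with ref.open(newline="") as fh:
        df = pd.DataFrame(list(csv.DictReader(fh)))
    return df.set_index("label")


# ---------------------------------------------------------------------------
# declarative motif language
#
# grammar:  expr   := term (OR term)*
#           term   := factor (AND factor)*
#           factor := NOT factor | '(' expr ')' | SITE | SPACED(count, sep)
#
# SPACED(c, s) matches c phosphorylated residues whose consecutive residue
# numbers each differ by s+1 (exactly s residues between neighbours).


class MotifSyntaxError(ValueError):
    """Malformed motif specification; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<comma>,)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*)|(?P<num>\d+))"
)


def _tokenize(spec: str):
    tokens = []
    pos = 0
    while pos < len(spec):
        if spec[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(spec, pos)
        if not m:
            raise MotifSyntaxError(f"unexpected character {spec[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, spec: str):
        self.spec = spec
        self.tokens = _tokenize(spec)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.spec))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self):
        node = self._expr()
        kind, val, pos = self._peek()
        if kind is not None:
            raise MotifSyntaxError(f"unexpected token {val!r}", pos)
        return node

    def _expr(self):
        node = self._term()
        while self._peek()[0] == "word" and self._peek()[1].upper() == "OR":
            self._next()
            rhs = self._term()
            node = ("or", node, rhs)
        return node

    def _term(self):
        node = self._factor()
        while self._peek()[0] == "word" and self._peek()[1].upper() == "AND":
            self._next()
            rhs = self._factor()
            node = ("and", node, rhs)
        return node

    def _factor(self):
        kind, val, pos = self._next()
        if kind is None:
            raise MotifSyntaxError("unexpected end of expression", pos)
        if kind == "lpar":
            node = self._expr()
            k2, v2, p2 = self._next()
            if k2 != "rpar":
                raise MotifSyntaxError("expected ')'", p2)
            return node
        if kind == "word":
            upper = val.upper()
            if upper == "NOT":
                return ("not", self._factor())
            if upper == "SPACED":
                return self._spaced(pos)
            if val in SITES:
                return ("site", val)
            raise MotifSyntaxError(f"unknown site or keyword {val!r}", pos)
        raise MotifSyntaxError(f"unexpected token {val!r}", pos)

    def _spaced(self, start_pos: int):
        k, _, p = self._next()
        if k != "lpar":
            raise MotifSyntaxError("SPACED requires '(count, sep)'", p)
        k, count, p = self._next()
        if k != "num":
            raise MotifSyntaxError("SPACED count must be an integer", p)
        k, _, p = self._next()
        if k != "comma":
            raise MotifSyntaxError("expected ',' in SPACED(count, sep)", p)
        k, sep, p = self._next()
        if k != "num":
            raise MotifSyntaxError("SPACED sep must be an integer", p)
        k, _, p = self._next()
        if k != "rpar":
            raise MotifSyntaxError("expected ')' closing SPACED", p)
        return ("spaced", int(count), int(sep))


def _eval(node, pattern: PhosphoPattern) -> bool:
    op = node[0]
    if op == "site":
        return pattern.has(node[1])
    if op == "not":
        return not _eval(node[1], pattern)
    if op == "and":
        return _eval(node[1], pattern) and _eval(node[2], pattern)
    if op == "or":
        return _eval(node[1], pattern) or _eval(node[2], pattern)
    if op == "spaced":
        count, sep = node[1], node[2]
        positions = pattern.positions()
        if count <= 0:
            return True
        step = sep + 1
        for start in positions:
            if all(start + j * step in positions for j in range(count)):
                return True
        return False
    raise AssertionError(f"unknown node {node!r}")


def compile_motif(spec: str):
    """Compile a motif expression into a predicate over patterns."""
    tree = _Parser(spec).parse()

    def predicate(pattern: PhosphoPattern) -> bool:
        return _eval(tree, pattern)

    predicate.spec = spec  # type: ignore[attr-defined]
    return predicate


def motif_scan(
    target: PhosphoPattern | PeptidePanel, motif_spec: str
) -> bool | dict[str, bool]:
    """Evaluate a declarative motif against a pattern or a whole panel."""
    predicate = compile_motif(motif_spec)
    if isinstance(target, PhosphoPattern):
        return predicate(target)
    return {pep.label or pep.bitstring: predicate(pep) for pep in target}
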