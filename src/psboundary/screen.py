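"""In-silico receptor screen: identifier standardisation, three-criterion
intersection, and quality-control filters.

Candidate genes must (1) be expressed in AP stripes, (2) encode a
cell-surface protein and (3) be pair-rule regulated.  Criterion lists arrive
as free-text gene symbols; symbols are standardised to unique canonical
identifiers through an alias table before the exact three-way intersection
is taken.  The intersection is then whittled down by three quality-control
rules: (1) not striped on visual re-inspection, (2) less than 5% of total
embryonic (0-24 h AEL) expression occurring in the first 6 h (computed from
the temporal table; equality at 5% keeps the gene), (3) a known role away
from the cell surface.  Every exclusion is recorded with the rule(s) that
fired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AmbiguousAliasError",
    "ScreenResult",
    "standardize_ids",
    "intersect_criteria",
    "temporal_filter",
    "apply_manual_flags",
    "run_screen",
]

RULE_NOT_STRIPED = "not_striped_by_eye"
RULE_LOW_EARLY = "low_early_expression"
RULE_NON_SURFACE = "non_surface_role"


class AmbiguousAliasError(ValueError):
    """A symbol maps to more than one canonical identifier."""


@dataclass
class ScreenResult:
    striped: set[str]
    surface: set[str]
    pairrule: set[str]
    intersection: set[str]
    post_qc: set[str]
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    unresolved: dict[str, list[str]] = field(default_factory=dict)  # per criterion list

    def funnel(self) -> dict[str, int]:
        """Candidate counts at each successive step of the screen."""
        return {"striped": len(self.striped), "surface": len(self.surface),
                "pairrule": len(self.pairrule), "intersection": len(self.intersection),
                "post_qc": len(self.post_qc)}


def _alias_map(alias_table: pd.DataFrame) -> dict[str, str]:
    if alias_table is None or alias_table.empty:
        return {}
    dup = alias_table.groupby("symbol")["canonical_id"].nunique()
    offenders = sorted(dup[dup > 1].index)
    if offenders:
        raise AmbiguousAliasError(
            f"symbols mapping to multiple canonical ids: {offenders}")
    return dict(zip(alias_table.symbol, alias_table.canonical_id))


def standardize_ids(symbols: list[str], alias_table: pd.DataFrame | None = None,
                    strict: bool = False) -> tuple[set[str], list[str]]:
    """Map free-text symbols to a de-duplicated canonical set.

    Symbols absent from the alias table are assumed to be canonical already
    (identity mapping) and are returned in the ``unresolved`` report rather
    than silently dropped; with ``strict=True`` they are excluded from the
    set instead.
    """
    amap = _alias_map(alias_table) if alias_table is not None else {}
    known = set(amap) | set(amap.values())
    out: set[str] = set()
    unresolved: list[str] = []
    for s in symbols:
        if s in amap:
            out.add(amap[s])
        elif s in known:  # already canonical
            out.add(s)
        else:
            unresolved.append(s)
            if not strict:
                out.add(s)
    return out, unresolved


def intersect_criteria(striped: set[str], surface: set[str], pairrule: set[str]
                       ) -> set[str]:
    """Exact three-way intersection of canonical id sets."""
    return set(striped) & set(surface) & set(pairrule)


def temporal_filter(expr_0_6h: float, expr_0_24h: float,
                    threshold: float = 0.05) -> tuple[bool, str]:
    """Keep/exclude by early-expression fraction.

    Excludes genes with strictly less than ``threshold`` of their total
    embryonic (0-24 h) expression occurring in 0-6 h; equality keeps.
    Returns (keep, reason); zero total expression excludes with its own
    reason code.
    """
    if expr_0_24h <= 0:
        return False, "no_embryonic_expression"
    if expr_0_6h / expr_0_24h < threshold:
        return False, RULE_LOW_EARLY
    return True, ""


def apply_manual_flags(intersection: set[str], flags_table: pd.DataFrame,
                       temporal_table: pd.DataFrame,
                       early_threshold: float = 0.05
                       ) -> tuple[set[str], dict[str, list[str]]]:
    """Apply the three QC rules; return the post-QC set and an exclusion ledger.

    Rules 1 and 3 come from curation flags (not_striped_by_eye,
    non_surface_role); rule 2 is the temporal filter, computed from the
    temporal expression table.  The ledger maps each excluded gene to every
    rule that fired.
    """
    flags = flags_table.set_index("canonical_id") if flags_table is not None else None
    temporal = temporal_table.set_index("canonical_id") if temporal_table is not None else None
    exclusions: dict[str, list[str]] = {}
    keep = set()
    for g in sorted(intersection):
        fired: list[str] = []
        if flags is not None and g in flags.index:
            if bool(flags.loc[g, RULE_NOT_STRIPED]):
                fired.append(RULE_NOT_STRIPED)
        if temporal is not None and g in temporal.index:
            ok, reason = temporal_filter(float(temporal.loc[g, "expr_0_6h"]),
                                         float(temporal.loc[g, "expr_0_24h"]),
                                         early_threshold)
            if not ok:
                fired.append(reason)
        if flags is not None and g in flags.index:
            if bool(flags.loc[g, RULE_NON_SURFACE]):
                fired.append(RULE_NON_SURFACE)
        if fired:
            exclusions[g] = fired
            log.warning("screen: %s excluded (%s)", g, ", ".join(fired))
        else:
            keep.add(g)
    return keep, exclusions


def run_screen(striped_symbols: list[str], surface_symbols: list[str],
               pairrule_symbols: list[str], alias_table: pd.DataFrame | None = None,
               temporal_table: pd.DataFrame | None = None,
               flags_table: pd.DataFrame | None = None,
               early_threshold: float = 0.05, strict: bool = False) -> ScreenResult:
    """Full screen: standardise, intersect, filter; deterministic on its inputs."""
    striped, un_s = standardize_ids(striped_symbols, alias_table, strict)
    surface, un_u = standardize_ids(surface_symbols, alias_table, strict)
    pairrule, un_p = standardize_ids(pairrule_symbols, alias_table, strict)
    unresolved = {"striped": un_s, "surface": un_u, "pairrule": un_p}
    for name, syms in unresolved.items():
        if syms:
            log.warning("screen: %d unresolved symbols in %s list", len(syms), name)
    inter = intersect_criteria(striped, surface, pairrule)
    post_qc, exclusions = apply_manual_flags(inter, flags_table, temporal_table,
                                             early_threshold)
    return ScreenResult(striped=striped, surface=surface, pairrule=pairrule,
                        intersection=inter, post_qc=post_qc,
                        exclusions=exclusions, unresolved=unresolved)
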